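"""Tag-to-genome mapping, annotation-based classification, conserved-family
aggregation, and the two-library comparison / length-distribution summaries.

Classification follows the removal order used in small-RNA studies: known
structural ncRNAs first (rRNA > tRNA > snRNA > snoRNA), then exact matches to
known mature miRNAs, then annotated siRNA loci, then genic context
(exon/intron x sense/antisense), and finally "other" — the pool from which
novel miRNAs are later sought.  Each tag receives exactly one class; a
multi-mapping tag takes the highest-precedence class among all of its hits.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .hairpin import revcomp
from .preprocess import SmallRNATag, round_half_up

CLASS_PRECEDENCE = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "known_miRNA",
    "siRNA",
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "other",
)

ANNOTATION_CLASSES = (
    "snoRNA",
    "snRNA",
    "tRNA",
    "rRNA",
    "siRNA",
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "known_miRNA",
    "novel_miRNA",
    "other",
)


def map_to_genome(
    tags: list[SmallRNATag], genome: dict[str, str]
) -> dict[str, list[tuple[str, int, int, str]]]:
    """Perfect full-length matches of each tag to both genome strands.

    Returns tag sequence -> list of (chrom, start, end, strand) with 0-based
    half-open coordinates on the forward strand.  Tags without hits map to an
    empty list.
    """
    hits: dict[str, list[tuple[str, int, int, str]]] = {t.sequence: [] for t in tags}
    for chrom, seq in genome.items():
        seq = seq.upper()
        for tag in tags:
            q = tag.sequence.upper()
            for query, strand in ((q, "+"), (revcomp(q), "-")):
                pos = seq.find(query)
                while pos >= 0:
                    hits[tag.sequence].append((chrom, pos, pos + len(q), strand))
                    pos = seq.find(query, pos + 1)
    return hits


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    kind: str  # rRNA/tRNA/snRNA/snoRNA/siRNA/exon/intron


def load_gff3_features(path) -> list[Feature]:
    """Read a GFF3 annotation into features (1-based closed -> 0-based
    half-open at this boundary)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _src, kind, start, end, _score, strand = f[:7]
            feats.append(Feature(chrom, int(start) - 1, int(end), strand, kind))
    return feats


def _trees(features: list[Feature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        trees[f.chrom].addi(f.start, f.end, f)
    return trees


def classify_tags(
    tags: list[SmallRNATag],
    hits: dict[str, list[tuple[str, int, int, str]]],
    features: list[Feature],
    known_mature: dict[str, str],
) -> dict[str, str]:
    """Assign each tag exactly one annotation class.

    ``known_mature`` maps mature miRNA id -> sequence (DNA or RNA); a tag is
    known_miRNA on exact full-length equality with any entry.  Unmapped tags
    are "other".
    """
    known_seqs = {s.upper().replace("U", "T") for s in known_mature.values()}
    trees = _trees(features)
    rank = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
    out: dict[str, str] = {}
    for tag in tags:
        seq = tag.sequence.upper().replace("U", "T")
        if seq in known_seqs:
            # exact mature match outranks genic context but not ncRNA removal
            best = "known_miRNA"
        else:
            best = "other"
        for chrom, start, end, strand in hits.get(tag.sequence, []):
            for iv in trees.get(chrom, IntervalTree()).overlap(start, end):
                f: Feature = iv.data
                if f.kind in ("rRNA", "tRNA", "snRNA", "snoRNA", "siRNA"):
                    cls = f.kind
                elif f.kind in ("exon", "intron"):
                    orient = "sense" if f.strand == strand else "antisense"
                    cls = f"{f.kind}_{orient}"
                else:
                    continue
                if rank[cls] < rank[best]:
                    best = cls
        out[tag.sequence] = best
    return out


_MIR_NAME = re.compile(r"(?:^|-)miR-?(\d+)", re.IGNORECASE)


def parse_family(mirna_id: str) -> str:
    """Family from a miRBase-style name: zma-miR156a-5p -> MIR156."""
    m = _MIR_NAME.search(mirna_id)
    if not m:
        return "UNKNOWN"
    return f"MIR{m.group(1)}"


@dataclass
class FamilyRecord:
    family: str
    members: list[tuple[str, str]]  # (mature id, sequence)
    counts: tuple[int, ...]  # per-library summed tag counts


def aggregate_families(
    tags: list[SmallRNATag],
    classes: dict[str, str],
    known_mature: dict[str, str],
) -> list[FamilyRecord]:
    """Group known-miRNA tags into families by miRBase numerical identifier.

    Counts are summed per library over all member tags; a family appears only
    if at least one member tag was sequenced.
    """
    seq_to_ids: dict[str, list[str]] = defaultdict(list)
    for mid, s in known_mature.items():
        seq_to_ids[s.upper().replace("U", "T")].append(mid)
    fam_counts: dict[str, list[int]] = {}
    fam_members: dict[str, set[tuple[str, str]]] = defaultdict(set)
    n_lib = len(tags[0].counts) if tags else 2
    for tag in tags:
        if classes.get(tag.sequence) != "known_miRNA":
            continue
        seq = tag.sequence.upper().replace("U", "T")
        ids = seq_to_ids.get(seq, [])
        fams = {parse_family(i) for i in ids} or {"UNKNOWN"}
        for fam in fams:
            row = fam_counts.setdefault(fam, [0] * n_lib)
            for i, c in enumerate(tag.counts):
                row[i] += c
            for i in ids:
                if parse_family(i) == fam:
                    fam_members[fam].add((i, seq))
    return [
        FamilyRecord(fam, sorted(fam_members[fam]), tuple(fam_counts[fam]))
        for fam in sorted(fam_counts)
    ]


@dataclass
class LibraryComparison:
    shared_unique: int
    ds_specific_unique: int
    gs_specific_unique: int
    shared_total: int
    ds_specific_total: int
    gs_specific_total: int

    @property
    def unique_total(self) -> int:
        return self.shared_unique + self.ds_specific_unique + self.gs_specific_unique

    @property
    def reads_total(self) -> int:
        return self.shared_total + self.ds_specific_total + self.gs_specific_total

    def percentages(self) -> dict[str, float]:
        out = {}
        ut, rt = self.unique_total, self.reads_total
        for name, part, total in (
            ("shared_unique", self.shared_unique, ut),
            ("ds_specific_unique", self.ds_specific_unique, ut),
            ("gs_specific_unique", self.gs_specific_unique, ut),
            ("shared_total", self.shared_total, rt),
            ("ds_specific_total", self.ds_specific_total, rt),
            ("gs_specific_total", self.gs_specific_total, rt),
        ):
            out[name] = round_half_up(100.0 * part / total) if total else 0.0
        return out


def compare_libraries(tags: list[SmallRNATag]) -> LibraryComparison:
    """Shared vs library-specific tag accounting (two libraries: DS, GS)."""
    su = dsu = gsu = st = dst = gst = 0
    for t in tags:
        ds, gs = t.counts[0], t.counts[1]
        if ds > 0 and gs > 0:
            su += 1
            st += ds + gs
        elif ds > 0:
            dsu += 1
            dst += ds
        elif gs > 0:
            gsu += 1
            gst += gs
    return LibraryComparison(su, dsu, gsu, st, dst, gst)


def length_distribution(tags: list[SmallRNATag]) -> dict[int, dict[str, int]]:
    """Histogram of tag lengths: unique tag count and total read count."""
    unique: Counter = Counter()
    total: Counter = Counter()
    for t in tags:
        unique[t.length] += 1
        total[t.length] += t.total
    return {
        length: {"unique": unique[length], "total": total[length]}
        for length in sorted(unique)
    }
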