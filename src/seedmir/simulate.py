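"""Synthetic small-RNA study generator with planted ground truth.

Emulates the data structure of a two-condition (dry seed "DS" vs imbibed
seed "GS") small-RNA sequencing experiment on a toy genome:

* a random genome hosting planted miRNA hairpin precursors (validated against
  the discovery criteria before acceptance), known-miRNA loci, structural
  ncRNA loci, and genes with exons/introns;
* a miRBase-style reference of known mature miRNAs grouped into families,
  with planted between-library fold changes;
* a transcriptome carrying planted miRNA target sites of controlled duplex
  score, plus a gene-to-term map with one deliberately enriched term;
* two FASTQ libraries of 3'-adapter-ligated reads with a 20-24-nt-dominated
  insert length profile, spiked no-adapter / 5'-adapter-contaminant /
  short-insert / polyA / low-quality reads, and substitution errors.

Every output is a deterministic function of the master seed: each file draws
from its own RNG stream derived from the seed, so files can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .annotate import Feature
from .hairpin import HairpinThresholds, Rejection, evaluate_candidate, extract_windows, revcomp
from .targets import DuplexRules, TargetDuplex, score_duplex

BASES = np.frombuffer(b"ACGT", dtype="S1")

# default insert-length weights (nt 16-30), peaked at 21-24 with 24 dominant
DEFAULT_LENGTH_WEIGHTS = {
    16: 0.5, 17: 0.5, 18: 1.0, 19: 2.0, 20: 6.0, 21: 12.0, 22: 12.0,
    23: 8.0, 24: 14.0, 25: 3.0, 26: 2.0, 27: 1.0, 28: 1.0, 29: 0.5, 30: 0.5,
}

# DS:GS abundance-rate ratios planted per known family, cycled over families:
# three >= 4-fold down in GS, two up in GS, rest flat
DEFAULT_FAMILY_RATIOS = [6.0, 4.0, 1.0, 1.0, 0.25, 1.0, 5.0, 1.0, 0.2, 1.0]

FAMILY_NUMBERS = [156, 159, 164, 166, 167, 168, 169, 172, 319, 393, 394, 398, 408, 528]


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    seed: int = 1
    genome_length: int = 100_000
    n_planted_hairpins: int = 25
    n_known_mirnas: int = 30
    n_known_families: int = 10
    n_ncrna_loci: int = 20
    n_genes: int = 8
    n_other_tags: int = 220
    n_unmapped_tags: int = 30
    n_transcripts: int = 40
    transcript_length: tuple[int, int] = (600, 1200)
    library_depths: tuple[int, int] = (100_000, 100_000)
    fold_change_spec: list[tuple[str, float]] | None = None
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    insert_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    error_rate: float = 0.001
    read_length: int = 40
    # junk-read fractions (of total depth), emulating the removed categories
    frac_no_adapter: float = 0.006
    frac_insert_null: float = 0.0005
    frac_adapter5: float = 0.003
    frac_short: float = 0.01
    frac_polya: float = 0.0008
    frac_lowq: float = 0.03
    quality_char: str = "I"

    def validate(self) -> None:
        if self.library_depths[0] < 0 or self.library_depths[1] < 0:
            raise ValueError("library depths must be non-negative")
        w = sum(self.insert_length_distribution.values())
        if not w > 0:
            raise ValueError("insert length weights must have positive sum")
        junk = (
            self.frac_no_adapter + self.frac_insert_null + self.frac_adapter5
            + self.frac_short + self.frac_polya + self.frac_lowq
        )
        if junk >= 1.0:
            raise ValueError("junk fractions must sum to < 1")

    def length_probs(self) -> dict[int, float]:
        z = sum(self.insert_length_distribution.values())
        return {k: v / z for k, v in sorted(self.insert_length_distribution.items())}


@dataclass
class TagTruth:
    tag_id: str
    sequence: str  # DNA, as sequenced
    annotation_class: str
    weight: float
    ratio: float  # true DS:GS abundance-rate ratio


@dataclass
class TruthSet:
    """Planted ground truth for recovery testing."""

    planted_mirnas: list[tuple[str, tuple[str, int, int, str], str]] = field(default_factory=list)
    planted_targets: list[dict] = field(default_factory=list)
    planted_ratios: dict[str, float] = field(default_factory=dict)
    planted_classes: dict[str, str] = field(default_factory=dict)
    tags: dict[str, TagTruth] = field(default_factory=dict)
    known_mature: dict[str, str] = field(default_factory=dict)  # id -> RNA seq
    family_ratios: dict[str, float] = field(default_factory=dict)
    genome_features: list[Feature] = field(default_factory=list)
    precursors: list[dict] = field(default_factory=list)
    p_ds: dict[str, float] = field(default_factory=dict)  # per-tag read prob
    p_gs: dict[str, float] = field(default_factory=dict)
    emitted_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def mature_sequences(self) -> set[str]:
        return {m for m, _, _ in self.planted_mirnas}


class GenomeTooShort(ValueError):
    """The genome cannot host all planted loci without overlap."""


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


_NONPAIR = {  # for a mature base (RNA), bases its partner may NOT be to mismatch
    "A": "AGC",  # partner must avoid U (WC); A:G/A:C/A:A all mismatch
    "C": "ACU",  # avoid G
    "G": "AG",  # avoid C (WC) and U (wobble)
    "U": "CU",  # avoid A (WC) and G (wobble)
}


def _bad_tag(seq_dna: str, cfg: SimConfig) -> bool:
    """A tag whose read would not survive trimming cleanly: contains the 3'
    adapter match motif (leftmost-match truncation), looks like 5'-adapter
    carry-through, is polyA, or has an N."""
    if "N" in seq_dna:
        return True
    if seq_dna.count("A") / max(len(seq_dna), 1) >= 0.9:
        return True
    if cfg.adapter3[:8] in seq_dna:
        return True
    probe5 = cfg.adapter5[-8:]
    prefix = (seq_dna + cfg.adapter3)[: len(cfg.adapter5)]
    return probe5 in prefix


class _Placer:
    """Non-overlapping interval allocator over the genome."""

    def __init__(self, rng: np.random.Generator, length: int, margin: int = 10):
        self.rng = rng
        self.length = length
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def place(self, size: int, tries: int = 2000) -> int:
        if size > self.length:
            raise GenomeTooShort(f"locus of {size} nt exceeds genome ({self.length} nt)")
        for _ in range(tries):
            start = int(self.rng.integers(0, self.length - size + 1))
            lo, hi = start - self.margin, start + size + self.margin
            if all(hi <= a or lo >= b for a, b in self.taken):
                self.taken.append((start, start + size))
                return start
        raise GenomeTooShort(
            f"could not place a {size}-nt locus in {self.length} nt genome "
            f"({len(self.taken)} loci already placed)"
        )


def _make_precursor(rng: np.random.Generator, thresholds: HairpinThresholds):
    """Stem-first precursor construction: mature + loop + star (or reversed),
    star = reverse complement of the mature with a controlled number of
    non-pairing substitutions."""
    mat_len = int(rng.integers(20, 23))
    mature = list(_random_dna(rng, mat_len).replace("T", "U"))
    mature = ["U" if rng.random() < 0.6 else mature[0]] + mature[1:]  # 5' U bias
    mature = "".join(mature).replace("T", "U")
    n_mm = int(rng.integers(0, 3))
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    star = [comp[b] for b in reversed(mature)]
    mm_pos = rng.choice(np.arange(3, mat_len - 3), size=n_mm, replace=False)
    for p in mm_pos:
        # star index opposite mature position p
        q = mat_len - 1 - int(p)
        star[q] = str(rng.choice(list(_NONPAIR[mature[int(p)]])))
    star = "".join(star)
    loop_len = int(rng.integers(24, 61))
    loop = _random_dna(rng, loop_len).replace("T", "U")
    arm = "5p" if rng.random() < 0.5 else "3p"
    if arm == "5p":
        precursor = mature + loop + star
    else:
        precursor = star + loop + mature
    return precursor, mature, arm


def build_genome(
    cfg: SimConfig, thresholds: HairpinThresholds = HairpinThresholds(), flank: int = 250
) -> tuple[dict[str, str], TruthSet]:
    """Random genome with planted precursors, known-miRNA loci, ncRNA loci
    and genes; every planted precursor is validated through the discovery
    path (window extraction + folding + criteria) before the genome is
    accepted."""
    cfg.validate()
    rng = _rng(cfg, 0)
    truth = TruthSet()
    genome_arr = rng.choice(BASES, size=cfg.genome_length)
    placer = _Placer(rng, cfg.genome_length, margin=20)

    def embed(seq_dna: str) -> int:
        start = placer.place(len(seq_dna))
        genome_arr[start : start + len(seq_dna)] = np.frombuffer(
            seq_dna.encode(), dtype="S1"
        )
        return start

    # --- known miRNA loci + reference ---
    fam_numbers = FAMILY_NUMBERS[: cfg.n_known_families]
    letters = "abcdefgh"
    fam_ratio_cycle = DEFAULT_FAMILY_RATIOS
    for i in range(cfg.n_known_mirnas):
        fam_idx = i % len(fam_numbers)
        fam = f"MIR{fam_numbers[fam_idx]}"
        member = i // len(fam_numbers)
        mid = f"zma-miR{fam_numbers[fam_idx]}{letters[member]}"
        seq = _random_dna(rng, 21)
        while _bad_tag(seq, cfg):
            seq = _random_dna(rng, 21)
        embed(seq)
        truth.known_mature[mid] = seq.replace("T", "U")
        truth.family_ratios.setdefault(fam, fam_ratio_cycle[fam_idx % len(fam_ratio_cycle)])

    # --- ncRNA loci (classification exercise) ---
    kinds = ["rRNA", "tRNA", "snRNA", "snoRNA", "siRNA"]
    for i in range(cfg.n_ncrna_loci):
        kind = kinds[i % len(kinds)]
        size = int(rng.integers(80, 160))
        start = placer.place(size)
        strand = "+" if rng.random() < 0.5 else "-"
        truth.genome_features.append(Feature("chr1", start, start + size, strand, kind))

    # --- genes with exons and introns ---
    for g in range(cfg.n_genes):
        e1, intr, e2 = (int(rng.integers(150, 300)) for _ in range(3))
        start = placer.place(e1 + intr + e2)
        strand = "+" if rng.random() < 0.5 else "-"
        truth.genome_features.append(Feature("chr1", start, start + e1, strand, "exon"))
        truth.genome_features.append(
            Feature("chr1", start + e1, start + e1 + intr, strand, "intron")
        )
        truth.genome_features.append(
            Feature("chr1", start + e1 + intr, start + e1 + intr + e2, strand, "exon")
        )

    # --- planted hairpin precursors, validated via the discovery path ---
    genome_view = {"chr1": ""}
    for i in range(cfg.n_planted_hairpins):
        placed = False
        for _attempt in range(40):
            precursor, mature, arm = _make_precursor(rng, thresholds)
            pre_dna = precursor.replace("U", "T")
            mat_dna = mature.replace("U", "T")
            if _bad_tag(mat_dna, cfg):
                continue
            start = placer.place(len(pre_dna))
            genome_arr[start : start + len(pre_dna)] = np.frombuffer(
                pre_dna.encode(), dtype="S1"
            )
            genome_view["chr1"] = genome_arr.tobytes().decode()
            if arm == "5p":
                m_lo = start
            else:
                m_lo = start + len(pre_dna) - len(mat_dna)
            hit = ("chr1", m_lo, m_lo + len(mat_dna), "+")
            # bare precursor must pass, and at least one discovery window too
            ok = not isinstance(
                evaluate_candidate(precursor, mature, ("chr1", start, start + len(pre_dna), "+"), thresholds),
                Rejection,
            )
            if ok:
                ok = any(
                    not isinstance(
                        evaluate_candidate(w, mat_dna, wl, thresholds, mature_offset=off),
                        Rejection,
                    )
                    for w, off, wl, _t in extract_windows(hit, genome_view, flank=flank)
                )
            if ok and genome_view["chr1"].count(mat_dna) == 1 and revcomp(mat_dna) not in genome_view["chr1"]:
                locus = ("chr1", start, start + len(pre_dna), "+")
                truth.planted_mirnas.append((mature, locus, arm))
                truth.precursors.append(
                    {"precursor": precursor, "mature": mature, "arm": arm, "locus": locus}
                )
                placed = True
                break
            # reject: release the locus and retry with a fresh construct
            placer.taken.pop()
            genome_arr[start : start + len(pre_dna)] = rng.choice(BASES, size=len(pre_dna))
        if not placed:
            raise GenomeTooShort(f"failed to plant hairpin {i} after 40 attempts")

    genome = {"chr1": genome_arr.tobytes().decode()}
    _build_tag_catalog(cfg, rng, genome, truth)
    return genome, truth


def _weighted_length(rng: np.random.Generator, probs: dict[int, float], lo: int = 16) -> int:
    ks = list(probs)
    return int(rng.choice(ks, p=[probs[k] for k in ks]))


def _build_tag_catalog(
    cfg: SimConfig, rng: np.random.Generator, genome: dict[str, str], truth: TruthSet
) -> None:
    """Assemble the sequenced-tag pool with weights and DS:GS ratios.

    Class mass roughly follows the composition of deep plant small-RNA
    libraries: ncRNA fragments and unannotated ("other") tags dominate reads,
    known miRNAs contribute a large read share through few distinct tags,
    novel miRNAs and stars are rare.
    """
    gseq = genome["chr1"]
    probs = cfg.length_probs()
    seen: set[str] = set()

    def add(tag_id: str, seq: str, cls: str, weight: float, ratio: float) -> None:
        if seq in seen or _bad_tag(seq, cfg):
            return  # adapter-motif / polyA collisions would corrupt trimming
        seen.add(seq)
        truth.tags[tag_id] = TagTruth(tag_id, seq, cls, weight, ratio)
        truth.planted_classes[tag_id] = cls
        truth.planted_ratios[tag_id] = ratio

    # known miRNAs: few tags, heavy read mass (lognormal spread)
    for mid, rna in truth.known_mature.items():
        fam = f"MIR{''.join(c for c in mid.split('miR')[1] if c.isdigit())}"
        ratio = truth.family_ratios.get(fam, 1.0)
        w = float(rng.lognormal(mean=3.0, sigma=1.2))
        add(f"known_{mid}", rna.replace("U", "T"), "known_miRNA", w, ratio)

    # novel matures and their stars
    for i, (mature, locus, arm) in enumerate(truth.planted_mirnas):
        w = float(rng.lognormal(mean=0.5, sigma=0.8))
        ratio = float(rng.choice([1.0, 1.0, 2.0, 0.5]))
        add(f"novel_{i}", mature.replace("U", "T"), "novel_miRNA", w, ratio)
        # the star is the opposite stem segment (same length as the mature)
        pre = truth.precursors[i]["precursor"]
        star = pre[-len(mature) :] if arm == "5p" else pre[: len(mature)]
        add(f"star_{i}", star.replace("U", "T"), "novel_miRNA_star", w * 0.02, ratio)

    # ncRNA fragments: many tags, large read mass
    nc_feats = [f for f in truth.genome_features if f.kind in ("rRNA", "tRNA", "snRNA", "snoRNA", "siRNA")]
    mass = {"rRNA": 40.0, "tRNA": 18.0, "snRNA": 1.0, "snoRNA": 1.0, "siRNA": 5.0}
    for fi, f in enumerate(nc_feats):
        for j in range(6):
            ln = _weighted_length(rng, probs)
            if f.end - f.start <= ln:
                continue
            s = int(rng.integers(f.start, f.end - ln))
            seq = gseq[s : s + ln]
            if f.strand == "-":
                seq = revcomp(seq)
            add(f"ncrna_{fi}_{j}", seq, f.kind, mass[f.kind] * float(rng.lognormal(0, 0.7)) / 6, 1.0)

    # exon/intron fragments, both orientations
    genic = [f for f in truth.genome_features if f.kind in ("exon", "intron")]
    for fi, f in enumerate(genic):
        for j in range(4):
            ln = _weighted_length(rng, probs)
            if f.end - f.start <= ln:
                continue
            s = int(rng.integers(f.start, f.end - ln))
            seq = gseq[s : s + ln]
            sense = rng.random() < 0.6
            tag_strand_seq = seq if sense else revcomp(seq)
            orient = "sense" if sense == (f.strand == "+") else "antisense"
            add(f"genic_{fi}_{j}", tag_strand_seq, f"{f.kind}_{orient}", 2.5 * float(rng.lognormal(0, 0.7)) / 4, 1.0)

    # unannotated genomic tags ("other"): the bulk of distinct tags
    free = _free_intervals(cfg.genome_length, truth)
    for i in range(cfg.n_other_tags):
        ln = _weighted_length(rng, probs)
        for _ in range(50):
            lo, hi = free[int(rng.integers(0, len(free)))]
            if hi - lo <= ln:
                continue
            s = int(rng.integers(lo, hi - ln))
            seq = gseq[s : s + ln]
            if rng.random() < 0.3:
                seq = revcomp(seq)
            if seq not in seen:
                add(f"other_{i}", seq, "other", 1.8 * float(rng.lognormal(0, 1.0)), 1.0)
                break

    # tags with no genome hit at all
    for i in range(cfg.n_unmapped_tags):
        ln = _weighted_length(rng, probs)
        seq = _random_dna(rng, ln)
        if seq in gseq or revcomp(seq) in gseq:
            continue
        add(f"unmapped_{i}", seq, "unmapped", 0.6 * float(rng.lognormal(0, 0.8)), 1.0)

    # explicit per-tag ratio overrides
    for tag_id, ratio in cfg.fold_change_spec or []:
        if tag_id not in truth.tags:
            raise KeyError(f"fold_change_spec names unknown tag {tag_id!r}")
        truth.tags[tag_id].ratio = ratio
        truth.planted_ratios[tag_id] = ratio

    _compute_probabilities(cfg, truth)


def _free_intervals(genome_length: int, truth: TruthSet) -> list[tuple[int, int]]:
    taken = sorted(
        [(f.start, f.end) for f in truth.genome_features]
        + [(loc[1], loc[2]) for _, loc, _ in truth.planted_mirnas]
    )
    free = []
    pos = 0
    for a, b in taken:
        if a - pos > 40:
            free.append((pos, a))
        pos = max(pos, b)
    if genome_length - pos > 40:
        free.append((pos, genome_length))
    return free or [(0, genome_length)]


def _compute_probabilities(cfg: SimConfig, truth: TruthSet) -> None:
    """Per-library per-tag read probabilities.

    A tag with weight w and DS:GS ratio r contributes unnormalized rates
    w*2r/(1+r) to DS and w*2/(1+r) to GS (rate ratio exactly r); rates are
    normalized within each library over the clean fraction of reads.
    """
    junk = (
        cfg.frac_no_adapter + cfg.frac_insert_null + cfg.frac_adapter5
        + cfg.frac_short + cfg.frac_polya + cfg.frac_lowq
    )
    clean_frac = 1.0 - junk
    rates_ds = {t.tag_id: t.weight * 2 * t.ratio / (1 + t.ratio) for t in truth.tags.values()}
    rates_gs = {t.tag_id: t.weight * 2 / (1 + t.ratio) for t in truth.tags.values()}
    z_ds, z_gs = sum(rates_ds.values()), sum(rates_gs.values())
    truth.p_ds = {k: clean_frac * v / z_ds for k, v in rates_ds.items()}
    truth.p_gs = {k: clean_frac * v / z_gs for k, v in rates_gs.items()}


# ----------------------------------------------------------------------------
# transcriptome + targets + term map


def build_transcriptome(
    cfg: SimConfig, truth: TruthSet, rules: DuplexRules = DuplexRules()
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Random transcripts carrying planted miRNA target sites of controlled
    duplex score, plus a gene-to-term map with one enriched term.

    Every planted "should_pass" site is validated with the duplex scorer at
    build time; a passing-flagged site that violates the rules is a failure.
    """
    if not truth.planted_mirnas and not truth.known_mature:
        raise ValueError("truth contains no planted miRNAs")
    rng = _rng(cfg, 1)
    tlen_lo, tlen_hi = cfg.transcript_length
    transcripts = {
        f"TX{i:03d}": _random_dna(rng, int(rng.integers(tlen_lo, tlen_hi)))
        for i in range(cfg.n_transcripts)
    }
    tx_ids = list(transcripts)

    # choose miRNAs to target: novel matures first, then known
    mirnas: list[tuple[str, str]] = [
        (f"novel_{i}", m) for i, (m, _, _) in enumerate(truth.planted_mirnas)
    ] + [(f"known_{mid}", s) for mid, s in truth.known_mature.items()]
    chosen = mirnas[: max(8, len(truth.planted_mirnas) // 2)]
    used: dict[str, list[tuple[int, int]]] = {t: [] for t in tx_ids}
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}

    def plant_site(mirna_id: str, mature_rna: str, kind: str) -> None:
        L = len(mature_rna)
        site = [comp[b] for b in reversed(mature_rna)]  # perfect complement, RNA
        expected = 0.0
        if kind == "gu":
            # one wobble: site base opposite a miRNA position k
            ks = [k for k in range(3, L - 2) if mature_rna[k] in "UG"]
            k = int(rng.choice(ks))
            site[L - 1 - k] = "G" if mature_rna[k] == "U" else "U"
            expected = 0.5
        elif kind == "mm2":
            # two isolated full mismatches outside positions 9-12
            ks = rng.choice([k for k in range(2, L - 1) if not 8 <= k <= 11], size=2, replace=False)
            while abs(int(ks[0]) - int(ks[1])) < 2:
                ks = rng.choice([k for k in range(2, L - 1) if not 8 <= k <= 11], size=2, replace=False)
            for k in ks:
                site[L - 1 - int(k)] = str(rng.choice(list(_NONPAIR[mature_rna[int(k)]])))
            expected = 2.0
        elif kind == "fail10":
            site[L - 1 - 9] = str(rng.choice(list(_NONPAIR[mature_rna[9]])))  # position 10
            expected = 1.0
        site_rna = "".join(site)
        should_pass = kind != "fail10"
        res = score_duplex(mature_rna, site_rna, rules)
        if should_pass:
            if not isinstance(res, TargetDuplex) or res.score != expected:
                raise RuntimeError(
                    f"planted site for {mirna_id} flagged should_pass but scorer "
                    f"returned {res!r} (expected score {expected})"
                )
        elif isinstance(res, TargetDuplex):
            raise RuntimeError(f"planted should_fail site for {mirna_id} was accepted")
        # place into a transcript without overlapping existing sites
        for _ in range(200):
            tid = tx_ids[int(rng.integers(0, len(tx_ids)))]
            seq = transcripts[tid]
            s = int(rng.integers(0, len(seq) - L))
            if all(s + L <= a or s >= b for a, b in used[tid]):
                break
        else:
            raise RuntimeError("could not place target site")
        used[tid].append((s, s + L))
        transcripts[tid] = seq[:s] + site_rna.replace("U", "T") + seq[s + L :]
        truth.planted_targets.append(
            {
                "mirna_id": mirna_id,
                "mirna": mature_rna,
                "transcript_id": tid,
                "site_start": s,
                "site_seq": site_rna,
                "expected_score": expected,
                "should_pass": should_pass,
            }
        )

    kinds_cycle = ["perfect", "gu", "mm2", "perfect", "gu", "fail10"]
    for j, (mirna_id, mature) in enumerate(chosen):
        plant_site(mirna_id, mature.replace("T", "U"), kinds_cycle[j % len(kinds_cycle)])

    # term map: every transcript gets >= 1 term; targets of passing sites share
    # an enriched term
    terms = [f"T{i:02d}:generic_process_{i}" for i in range(8)]
    term_map: dict[str, list[str]] = {}
    for tid in tx_ids:
        k = int(rng.integers(1, 4))
        term_map[tid] = list(rng.choice(terms, size=k, replace=False))
    target_tx = {t["transcript_id"] for t in truth.planted_targets if t["should_pass"]}
    for tid in target_tx:
        term_map[tid] = sorted(set(term_map[tid]) | {"T99:planted_enriched_process"})
    return transcripts, term_map


# ----------------------------------------------------------------------------
# libraries


def simulate_libraries(
    cfg: SimConfig, truth: TruthSet
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Two read libraries as lists of (sequence, quality) tuples.

    Reads are insert + 3' adapter truncated to the read length; per-tag counts
    follow the planted per-library probabilities multinomially; junk reads
    (no-adapter, 5'-adapter contaminants, empty/short inserts, polyA,
    low-quality) are spiked in configured proportions.  Substitution errors
    are applied at ``cfg.error_rate`` per base.
    """
    if not truth.tags:
        raise ValueError("truth has no tag catalog; run build_genome first")
    libs = []
    for lib_idx, (depth, pmap) in enumerate(
        zip(cfg.library_depths, (truth.p_ds, truth.p_gs))
    ):
        rng = _rng(cfg, 2 + lib_idx)
        reads = _simulate_one(cfg, truth, rng, depth, pmap, lib_idx)
        libs.append(reads)
    return libs[0], libs[1]


def _simulate_one(cfg, truth, rng, depth, pmap, lib_idx):
    if depth == 0:
        return []
    tag_ids = list(truth.tags)
    slots = tag_ids + ["_noadapter", "_insertnull", "_adapter5", "_short", "_polya", "_lowq"]
    p = np.array(
        [pmap[t] for t in tag_ids]
        + [cfg.frac_no_adapter, cfg.frac_insert_null, cfg.frac_adapter5, cfg.frac_short,
           cfg.frac_polya, cfg.frac_lowq]
    )
    p = p / p.sum()
    counts = rng.multinomial(depth, p)
    a3 = cfg.adapter3
    rl = cfg.read_length
    qual = cfg.quality_char * rl

    def finish(core: str) -> str:
        read = core + a3 * (1 + rl // max(len(a3), 1))
        return read[:rl]

    reads: list[tuple[str, str]] = []
    for tag_id, n in zip(tag_ids, counts[: len(tag_ids)]):
        if n:
            truth.emitted_counts.setdefault(tag_id, [0, 0])[lib_idx] = int(n)
        seq = finish(truth.tags[tag_id].sequence)
        reads.extend([(seq, qual)] * int(n))
    n_na, n_in, n_a5, n_sh, n_pa, n_lq = counts[len(tag_ids) :]
    for _ in range(int(n_na)):
        while True:
            s = _random_dna(rng, rl)
            if a3[:8] not in s:
                break
        reads.append((s, qual))
    for _ in range(int(n_in)):
        reads.append((finish(""), qual))
    for _ in range(int(n_a5)):
        k = int(rng.integers(8, len(cfg.adapter5) + 1))
        core = cfg.adapter5[-k:] + _random_dna(rng, int(rng.integers(18, 26)))
        reads.append((finish(core), qual))
    for _ in range(int(n_sh)):
        reads.append((finish(_random_dna(rng, int(rng.integers(1, 18)))), qual))
    for _ in range(int(n_pa)):
        reads.append((finish("A" * int(rng.integers(18, 26))), qual))
    for _ in range(int(n_lq)):
        core = list(_random_dna(rng, 21))
        core[int(rng.integers(0, 21))] = "N"
        reads.append((finish("".join(core)), qual))

    # substitution errors over all reads
    if cfg.error_rate > 0:
        n_err = rng.binomial(rl, cfg.error_rate, size=len(reads))
        for i in np.nonzero(n_err)[0]:
            s = list(reads[i][0])
            for pos in rng.integers(0, rl, size=n_err[i]):
                s[pos] = str(rng.choice([b for b in "ACGT" if b != s[pos]]))
            reads[i] = ("".join(s), reads[i][1])
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


# ----------------------------------------------------------------------------
# file output


def write_fasta(path: Path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: Path, reads: list[tuple[str, str]], prefix: str) -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{qual}\n")


def write_gff3(path: Path, features: list[Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            fh.write(
                f"{f.chrom}\tseedmir_sim\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\tID={f.kind}_{i}\n"
            )


def write_term_map(path: Path, term_map: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\tterm_name\n")
        for gene in sorted(term_map):
            for term in sorted(term_map[gene]):
                tid, _, name = term.partition(":")
                fh.write(f"{gene}\t{tid}\t{name}\n")


def simulate_all(cfg: SimConfig, outdir: str | Path) -> TruthSet:
    """Generate the full synthetic study into ``outdir`` and return the truth.

    Files: genome.fa, annotations.gff3, known_mirnas.fa, transcripts.fa,
    terms.tsv, lib_ds.fastq, lib_gs.fastq, truth.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = build_genome(cfg)
    transcripts, term_map = build_transcriptome(cfg, truth)
    ds, gs = simulate_libraries(cfg, truth)
    write_fasta(outdir / "genome.fa", genome)
    write_fasta(
        outdir / "known_mirnas.fa",
        {mid: seq for mid, seq in truth.known_mature.items()},
    )
    write_fasta(outdir / "transcripts.fa", transcripts)
    write_gff3(outdir / "annotations.gff3", truth.genome_features)
    write_term_map(outdir / "terms.tsv", term_map)
    write_fastq(outdir / "lib_ds.fastq", ds, "ds")
    write_fastq(outdir / "lib_gs.fastq", gs, "gs")
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "planted_mirnas": [
                    {"mature": m, "locus": list(loc), "arm": arm}
                    for m, loc, arm in truth.planted_mirnas
                ],
                "planted_targets": truth.planted_targets,
                "planted_ratios": truth.planted_ratios,
                "planted_classes": truth.planted_classes,
                "family_ratios": truth.family_ratios,
            },
            fh,
            sort_keys=True,
        )
    with open(outdir / "tag_truth.tsv", "w") as fh:
        fh.write("tag_id\tsequence\tclass\tratio\temitted_ds\temitted_gs\n")
        for t in truth.tags.values():
            eds, egs = truth.emitted_counts.get(t.tag_id, (0, 0))
            fh.write(f"{t.tag_id}\t{t.sequence}\t{t.annotation_class}\t{t.ratio}\t{eds}\t{egs}\n")
    return truth
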