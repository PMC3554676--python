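"""Novel-miRNA hairpin discovery.

Unannotated small-RNA tags with perfect genome hits are candidate mature
miRNAs.  For each hit a genomic window is folded and the precursor is judged
against the field's stem-loop criteria: the mature sits on one arm of a
hairpin, pairs with an inferable star (miRNA*) region with at most six
mismatches and at most six unpaired duplex nucleotides, no multiloop branch
interrupts the duplex, mature and star are 5-240 nt apart, the fold reaches
-20 kcal/mol or lower, the mature is 20-22 nt, and the minimal-folding-
free-energy index (MFEI) clears a floor (default 0.85, the common plant-miRNA
convention).

Energetics:
  AMFE = MFE * 100 / precursor length   (kcal/mol per 100 nt)
  MFEI = AMFE / GC percentage           (GC on the 0-100 scale)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .fold import SecondaryStructure, fold, structure_energy

REJECTION_REASONS = {
    "not_hairpin": "mature not confined to one arm of a single stem-loop",
    "no_star": "no paired star region inferable for the mature",
    "too_many_mismatches": "mature/star mismatches exceed budget",
    "too_many_unpaired": "unpaired nucleotides in duplex exceed budget",
    "structural_break": "loop/branch interrupts the mature or star",
    "bad_distance": "mature-star distance outside allowed range",
    "mfe_too_high": "folding free energy above maximum",
    "bad_mature_length": "mature length outside allowed range",
    "mfei_too_low": "|MFEI| below floor",
}


@dataclass(frozen=True)
class HairpinThresholds:
    """Acceptance thresholds for precursor candidates."""

    max_mismatch: int = 6
    max_unpaired: int = 6
    min_distance: int = 5
    max_distance: int = 240
    mfe_max: float = -20.0
    mature_len_min: int = 20
    mature_len_max: int = 22
    mfei_floor: float = 0.85


@dataclass
class HairpinCandidate:
    precursor: str
    locus: tuple[str, int, int, str]  # chrom, start, end, strand (0-based half-open)
    structure: SecondaryStructure
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    loop_span: tuple[int, int]
    n_mismatch: int
    n_unpaired: int
    distance: int
    mfe: float
    amfe: float
    mfei: float
    arm: str  # "5p" | "3p"
    mature_seq: str = ""
    star_reads: int = 0
    star_tags: list = field(default_factory=list)


@dataclass(frozen=True)
class Rejection:
    reason: str
    detail: str = ""


class MatureNotInWindow(ValueError):
    """The mature sequence could not be located in the window (an error,
    distinct from a criteria rejection)."""


def gc_percent(seq: str) -> float:
    s = seq.upper()
    n = len(s)
    if n == 0:
        return 0.0
    return 100.0 * sum(c in "GC" for c in s) / n


def compute_energies(structure: SecondaryStructure, sequence: str) -> tuple[float, float, float]:
    """Return (MFE, AMFE, MFEI) for a folded precursor.

    Raises ValueError when GC content is zero (MFEI undefined).
    """
    mfe = structure.mfe
    n = len(sequence)
    amfe = mfe * 100.0 / n if n else 0.0
    gc = gc_percent(sequence)
    if gc == 0.0:
        raise ValueError("GC content is zero; MFEI undefined")
    return mfe, amfe, amfe / gc


def extract_windows(
    hit: tuple[str, int, int, str],
    genome: dict[str, str],
    flank: int = 250,
    edge: int = 20,
) -> list[tuple[str, int, tuple[str, int, int, str], bool]]:
    """Candidate precursor windows around a genome hit.

    Two windows are cut per hit, one with the tag near the window 5' end
    (precursor extending 3', mature on the 5p arm) and one with the tag near
    the 3' end; each is at most flank+tag+flank nt.  Windows are returned as
    (rna_sequence, mature_offset_in_window, window_locus, truncated_flag) on
    the hit strand.
    """
    chrom, start, end, strand = hit
    seq = genome[chrom]
    out = []
    for lo, hi in ((start - edge, end + flank), (start - flank, end + edge)):
        truncated = lo < 0 or hi > len(seq)
        lo_c, hi_c = max(lo, 0), min(hi, len(seq))
        window_dna = seq[lo_c:hi_c]
        if strand == "-":
            window_rna = revcomp(window_dna).replace("T", "U")
            mat_off = hi_c - end
        else:
            window_rna = window_dna.replace("T", "U")
            mat_off = start - lo_c
        out.append((window_rna, mat_off, (chrom, lo_c, hi_c, strand), truncated))
    # the two windows coincide for short chromosomes
    if out[0][2] == out[1][2]:
        out = out[:1]
    return out


_COMP = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def evaluate_candidate(
    window: str,
    mature: str,
    locus: tuple[str, int, int, str] = ("?", 0, 0, "+"),
    thresholds: HairpinThresholds = HairpinThresholds(),
    mature_offset: int | None = None,
    backend: str = "builtin",
    structure: SecondaryStructure | None = None,
) -> HairpinCandidate | Rejection:
    """Fold a window and test the mature tag against the stem-loop criteria.

    Returns an accepted :class:`HairpinCandidate` or a :class:`Rejection`
    carrying the first failed criterion.  Raises :class:`MatureNotInWindow`
    when the mature sequence does not occur in the window at all.
    """
    t = thresholds
    w = window.upper().replace("T", "U")
    m = mature.upper().replace("T", "U")
    if mature_offset is None:
        mature_offset = w.find(m)
        if mature_offset < 0:
            raise MatureNotInWindow(f"mature {mature!r} not found in window")
    elif w[mature_offset : mature_offset + len(m)] != m:
        raise MatureNotInWindow("mature does not match window at given offset")

    if not (t.mature_len_min <= len(m) <= t.mature_len_max):
        return Rejection("bad_mature_length", f"mature length {len(m)}")

    struct = structure if structure is not None else fold(w, backend=backend)
    pt = struct.pair_table()
    m0, m1 = mature_offset, mature_offset + len(m)  # half-open on window

    partners = [(i, pt[i]) for i in range(m0, m1) if pt[i] >= 0]
    if not partners:
        return Rejection("no_star", "mature entirely unpaired")
    # the star is the dominant duplex block: the longest run of mature
    # positions whose partners decrease strictly with bounded gaps (bulges);
    # short helix extensions into the loop or flanks form their own blocks
    # and their mature positions count as mismatches
    blocks: list[list[tuple[int, int]]] = [[partners[0]]]
    for i, p in partners[1:]:
        pp = blocks[-1][-1][1]
        if pp - (t.max_unpaired + 1) <= p < pp:
            blocks[-1].append((i, p))
        else:
            blocks.append([(i, p)])
    block = max(blocks, key=len)
    part_idx = [p for _, p in block]
    if any(m0 <= p < m1 for p in part_idx):
        return Rejection("not_hairpin", "mature pairs within itself")
    right = all(p >= m1 for p in part_idx)
    left = all(p < m0 for p in part_idx)
    if not (right or left):
        return Rejection("not_hairpin", "mature duplex straddles both sides")

    star_lo, star_hi = min(part_idx), max(part_idx) + 1
    n_mismatch = len(m) - len(block)  # mature positions outside the duplex block
    if n_mismatch > t.max_mismatch:
        return Rejection("too_many_mismatches", f"{n_mismatch} > {t.max_mismatch}")
    star_unpaired = sum(1 for i in range(star_lo, star_hi) if pt[i] < 0)
    if star_unpaired > t.max_unpaired:
        return Rejection("too_many_unpaired", f"{star_unpaired} > {t.max_unpaired}")
    # within its span the star must pair back exclusively into the mature:
    # an enclosed helix would be a loop/break inside the star
    for i in range(star_lo, star_hi):
        if pt[i] >= 0 and not (m0 <= pt[i] < m1):
            return Rejection("structural_break", "star pairs outside the mature")

    if right:
        arm = "5p"
        distance = star_lo - m1
        loop_span = (m1, star_lo)
    else:
        arm = "3p"
        distance = m0 - star_hi
        loop_span = (star_hi, m0)
    if not (t.min_distance <= distance <= t.max_distance):
        return Rejection("bad_distance", f"distance {distance}")

    # trim the precursor to the hairpin: from outermost of (mature, star)
    lo = min(m0, star_lo)
    hi = max(m1, star_hi)
    precursor = w[lo:hi]
    # re-balance the sub-structure: drop pairs crossing the precursor boundary
    sub_pt = [
        pt[i] - lo if pt[i] >= 0 and lo <= pt[i] < hi else -1 for i in range(lo, hi)
    ]
    sub_db = "".join(
        "(" if p > i else ")" if 0 <= p < i else "." for i, p in enumerate(sub_pt)
    )
    mfe = structure_energy(precursor, sub_db)
    if mfe > t.mfe_max:
        return Rejection("mfe_too_high", f"MFE {mfe:.1f} > {t.mfe_max}")
    sub_struct = SecondaryStructure(precursor, sub_db, mfe)
    try:
        mfe, amfe, mfei = compute_energies(sub_struct, precursor)
    except ValueError:
        return Rejection("mfei_too_low", "GC content zero, MFEI undefined")
    if abs(mfei) < t.mfei_floor:
        return Rejection("mfei_too_low", f"|MFEI| {abs(mfei):.3f} < {t.mfei_floor}")

    chrom, wlo, whi, strand = locus
    if strand == "-":
        g_lo, g_hi = whi - hi, whi - lo
    else:
        g_lo, g_hi = wlo + lo, wlo + hi
    return HairpinCandidate(
        precursor=precursor,
        locus=(chrom, g_lo, g_hi, strand),
        structure=sub_struct,
        mature_span=(m0 - lo, m1 - lo),
        star_span=(star_lo - lo, star_hi - lo),
        loop_span=(loop_span[0] - lo, loop_span[1] - lo),
        n_mismatch=n_mismatch,
        n_unpaired=star_unpaired,
        distance=distance,
        mfe=mfe,
        amfe=amfe,
        mfei=mfei,
        arm=arm,
        mature_seq=m,
    )


def discover(
    tags: Sequence,
    hits: dict[str, list[tuple[str, int, int, str]]],
    genome: dict[str, str],
    classes: dict[str, str] | None = None,
    thresholds: HairpinThresholds = HairpinThresholds(),
    flank: int = 250,
    backend: str = "builtin",
) -> tuple[list[HairpinCandidate], list[tuple[str, Rejection]]]:
    """Scan unannotated mapped tags for hairpin precursors.

    ``classes`` (tag sequence -> annotation class), when given, restricts the
    scan to tags classified "other".  Candidates from overlapping windows are
    deduplicated by (locus, mature), keeping the lowest-MFE precursor.
    """
    accepted: dict[tuple, HairpinCandidate] = {}
    rejections: list[tuple[str, Rejection]] = []
    for tag in tags:
        seq = tag.sequence if hasattr(tag, "sequence") else str(tag)
        if classes is not None and classes.get(seq) != "other":
            continue
        if not (thresholds.mature_len_min <= len(seq) <= thresholds.mature_len_max):
            continue
        for hit in hits.get(seq, []):
            for window, mat_off, wlocus, _trunc in extract_windows(hit, genome, flank=flank):
                try:
                    res = evaluate_candidate(
                        window, seq, wlocus, thresholds, mature_offset=mat_off, backend=backend
                    )
                except MatureNotInWindow:
                    continue
                if isinstance(res, Rejection):
                    rejections.append((seq, res))
                    continue
                key = (res.locus, res.mature_seq)
                prev = accepted.get(key)
                if prev is None or res.mfe < prev.mfe:
                    accepted[key] = res
    # collapse identical matures discovered at overlapping loci
    best: dict[str, HairpinCandidate] = {}
    for cand in accepted.values():
        prev = best.get(cand.mature_seq)
        if prev is None or cand.mfe < prev.mfe:
            best[cand.mature_seq] = cand
    return list(best.values()), rejections


def detect_star(
    candidates: Iterable[HairpinCandidate],
    tags: Sequence,
    genome_hits: dict[str, list[tuple[str, int, int, str]]] | None = None,
    shift: int = 2,
) -> list[HairpinCandidate]:
    """Annotate candidates with sequenced miRNA* support.

    A tag counts as the star when it matches the precursor's star span up to
    ``shift`` nt of end slack (the biogenesis 2-nt 3' overhang blurs exact
    ends in real data).
    """
    out = []
    for cand in candidates:
        star = cand.precursor[slice(*cand.star_span)]
        lo, hi = cand.star_span
        star_reads = 0
        star_tags = []
        for tag in tags:
            seq = tag.sequence if hasattr(tag, "sequence") else str(tag)
            rna = seq.upper().replace("T", "U")
            pos = cand.precursor.find(rna)
            if pos < 0:
                continue
            if abs(pos - lo) <= shift and abs(pos + len(rna) - hi) <= shift:
                counts = getattr(tag, "counts", (1,))
                star_reads += int(sum(counts))
                star_tags.append(seq)
        cand = replace_star(cand, star_reads, star_tags)
        out.append(cand)
    return out


def replace_star(cand: HairpinCandidate, reads: int, tags: list) -> HairpinCandidate:
    cand.star_reads = reads
    cand.star_tags = tags
    return cand
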