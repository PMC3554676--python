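"""Rule-based miRNA target prediction on transcript sense sequences.

A candidate site is an ungapped window of miRNA length on the mRNA, paired
antiparallel to the miRNA.  Per position (numbered 1..L from the miRNA 5'
end) the state is Watson-Crick match, G:U wobble (0.5 mismatch points, both
orientations), or mismatch (1 point).  A duplex is accepted iff

  1. total points <= 4.0
  2. no run of more than two adjacent full mismatches anywhere
  3. no two adjacent full mismatches within positions 2-12
  4. positions 10 and 11 are not mismatches
  5. points over positions 1-12 <= 2.5

G:U wobbles count toward the point totals (rules 1 and 5) but do not make a
position "adjacent-mismatch" for rules 2-4.  Plant miRNAs guide cleavage of
the target between the bases opposite positions 10 and 11.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

RULES = {
    1: "total mismatch points > 4 (G:U = 0.5)",
    2: "more than two adjacent mismatches",
    3: "adjacent mismatches in positions 2-12",
    4: "mismatch at position 10 or 11",
    5: "more than 2.5 mismatch points in positions 1-12",
}

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass
class TargetDuplex:
    mirna_id: str
    transcript_id: str
    site: tuple[int, int]  # 0-based half-open on transcript
    pairs: tuple[str, ...]  # per position 1..L from miRNA 5': match|GU|mismatch
    score: float
    score_1_12: float

    @property
    def cleavage_site(self) -> int:
        """Transcript coordinate of the base opposite miRNA position 10
        (cleavage occurs between this base and the next one 5'-ward)."""
        start, end = self.site
        return end - 10  # 0-based; antiparallel: miRNA pos k pairs site[end-k]

    def alignment(self) -> str:
        """Pipe/dot alignment string, miRNA 3'->5' under target 5'->3'."""
        marks = {"match": "|", "GU": "o", "mismatch": "."}
        return "".join(marks[p] for p in reversed(self.pairs))


@dataclass(frozen=True)
class DuplexRules:
    max_score: float = 4.0
    max_adjacent: int = 2  # longest allowed run of full mismatches
    seed_region: tuple[int, int] = (2, 12)  # no adjacent mismatches here
    no_mismatch_positions: tuple[int, ...] = (10, 11)
    max_score_1_12: float = 2.5


def _pair_state(mirna_base: str, target_base: str) -> str:
    duo = (mirna_base, target_base)
    if duo in _WC:
        return "match"
    if duo in _GU:
        return "GU"
    return "mismatch"


def score_duplex(
    mirna: str,
    site: str,
    rules: DuplexRules = DuplexRules(),
    mirna_id: str = "",
    transcript_id: str = "",
    site_start: int = 0,
) -> TargetDuplex | int:
    """Score one miRNA against an equal-length transcript sense window.

    Returns an accepted :class:`TargetDuplex`, or the integer id of the first
    violated rule.  Raises ValueError on unequal lengths.
    """
    m = mirna.upper().replace("T", "U")
    s = site.upper().replace("T", "U")
    if len(m) != len(s):
        raise ValueError(f"miRNA ({len(m)} nt) and site ({len(s)} nt) differ in length")
    L = len(m)
    # antiparallel: miRNA position k (1-based from 5') pairs site position L-k (0-based)
    pairs = tuple(_pair_state(m[k - 1], s[L - k]) for k in range(1, L + 1))
    pts = {"match": 0.0, "GU": 0.5, "mismatch": 1.0}
    score = sum(pts[p] for p in pairs)
    score_1_12 = sum(pts[p] for p in pairs[: min(12, L)])

    if score > rules.max_score:
        return 1
    run = 0
    for p in pairs:
        run = run + 1 if p == "mismatch" else 0
        if run > rules.max_adjacent:
            return 2
    lo, hi = rules.seed_region
    for k in range(lo, min(hi, L)):
        if pairs[k - 1] == "mismatch" and pairs[k] == "mismatch":
            return 3
    for k in rules.no_mismatch_positions:
        if k <= L and pairs[k - 1] == "mismatch":
            return 4
    if score_1_12 > rules.max_score_1_12:
        return 5
    return TargetDuplex(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site=(site_start, site_start + L),
        pairs=pairs,
        score=score,
        score_1_12=score_1_12,
    )


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    rules: DuplexRules = DuplexRules(),
) -> list[TargetDuplex]:
    """Exhaustive scan: every transcript window of miRNA length is scored.

    Accepted duplexes are deduplicated by (miRNA, transcript, site) and
    returned sorted by (miRNA id, transcript id, site start).
    """
    out: dict[tuple, TargetDuplex] = {}
    for mid, mseq in mirnas.items():
        L = len(mseq)
        for tid, tseq in transcripts.items():
            for start in range(0, len(tseq) - L + 1):
                res = score_duplex(
                    mseq,
                    tseq[start : start + L],
                    rules,
                    mirna_id=mid,
                    transcript_id=tid,
                    site_start=start,
                )
                if isinstance(res, TargetDuplex):
                    out[(mid, tid, start)] = res
    return [out[k] for k in sorted(out)]


def map_cleavage(duplex: TargetDuplex, observed_5p_end: int) -> str:
    """Classify an observed mRNA-fragment 5' end against the canonical
    cleavage point (between the bases opposite miRNA positions 10 and 11).

    Returns "canonical", "non-canonical", or "non-canonical (out of range)"
    when the coordinate falls outside the site +- 5 nt.
    """
    start, end = duplex.site
    if not (start - 5 <= observed_5p_end <= end + 5):
        return "non-canonical (out of range)"
    return "canonical" if observed_5p_end == duplex.cleavage_site else "non-canonical"
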