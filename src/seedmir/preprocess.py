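"""Raw-read accounting: quality screen, adapter handling, length/polyA
filters, and collapsing of clean inserts to unique tags with counts.

Reads failing the quality screen (any N, or mean Phred < 20) are excluded
up front; every surviving ("high-quality") read is assigned exactly one
terminal category:

  adaptor5_contaminants  5' adapter carried through into the read
  adaptor3_null          3' adapter never found
  insert_null            3' adapter at position 0 (empty insert)
  small_than_18nt        insert shorter than the minimum length
  polyA                  insert >= 90% adenine
  clean                  usable insert, returned for downstream analysis
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator

CATEGORIES = (
    "adaptor3_null",
    "insert_null",
    "adaptor5_contaminants",
    "small_than_18nt",
    "polyA",
    "clean",
)


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding at the printed precision (banker's rounding
    would drift on .5 boundaries)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TrimConfig:
    adapter3: str
    adapter5: str = ""
    match_len: int = 8  # adapter prefix length used for exact matching
    min_len: int = 18
    polya_frac: float = 0.90
    min_mean_q: float = 20.0


@dataclass
class SmallRNATag:
    """A unique insert sequence with per-library read counts."""

    sequence: str
    counts: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class LibraryStats:
    total_reads: int = 0
    high_quality: int = 0
    categories: dict = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    warning: str | None = None

    @property
    def clean_reads(self) -> int:
        return self.categories["clean"]

    def percentages(self) -> dict[str, float]:
        """Per-category percentages of high-quality reads, half-up to 2 dp."""
        if self.high_quality == 0:
            self.warning = "no high-quality reads; percentages reported as 0"
            return {c: 0.0 for c in CATEGORIES}
        return {
            c: round_half_up(100.0 * n / self.high_quality)
            for c, n in self.categories.items()
        }


def is_low_quality(seq: str, quals: list[int] | None, min_mean_q: float = 20.0) -> bool:
    if "N" in seq.upper():
        return True
    if quals:
        return sum(quals) / len(quals) < min_mean_q
    return False


def is_polya(insert: str, frac: float = 0.90) -> bool:
    return len(insert) > 0 and insert.upper().count("A") / len(insert) >= frac


def trim_read(read: str, cfg: TrimConfig) -> tuple[str | None, str]:
    """Categorize one high-quality read; return (insert or None, category).

    Matching is exact on a configurable-length adapter prefix (leftmost
    occurrence); the 5' adapter is only searched near the read start, where
    adapter-dimer chemistry deposits it.
    """
    read = read.upper()
    if not read:
        return None, "insert_null"
    a3 = cfg.adapter3.upper()[: cfg.match_len]
    if cfg.adapter5:
        a5 = cfg.adapter5.upper()[-cfg.match_len :]
        pos5 = read.find(a5)
        if 0 <= pos5 <= max(len(cfg.adapter5) - cfg.match_len, 0):
            return None, "adaptor5_contaminants"
    pos = read.find(a3)
    if pos < 0:
        return None, "adaptor3_null"
    if pos == 0:
        return None, "insert_null"
    insert = read[:pos]
    if len(insert) < cfg.min_len:
        return None, "small_than_18nt"
    if is_polya(insert, cfg.polya_frac):
        return None, "polyA"
    return insert, "clean"


def preprocess_library(
    reads: Iterable[tuple[str, list[int] | None]], cfg: TrimConfig
) -> tuple[list[str], LibraryStats]:
    """Run the quality screen and trimmer over one library.

    ``reads`` yields (sequence, phred-qualities-or-None) pairs; returns the
    clean inserts and the per-category accounting.
    """
    stats = LibraryStats()
    inserts: list[str] = []
    for seq, quals in reads:
        stats.total_reads += 1
        if is_low_quality(seq, quals, cfg.min_mean_q):
            continue
        stats.high_quality += 1
        insert, cat = trim_read(seq, cfg)
        stats.categories[cat] += 1
        if insert is not None:
            inserts.append(insert)
    return inserts, stats


def collapse(per_library_inserts: list[list[str]]) -> list[SmallRNATag]:
    """Collapse clean inserts to unique tags with per-library counts.

    Tags are returned sorted by total count (desc), then sequence, so output
    order is deterministic.
    """
    n_lib = len(per_library_inserts)
    counts: dict[str, list[int]] = {}
    for lib, inserts in enumerate(per_library_inserts):
        for ins in inserts:
            row = counts.setdefault(ins, [0] * n_lib)
            row[lib] += 1
    tags = [SmallRNATag(seq, tuple(c)) for seq, c in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def summarize_preprocessing(stats: LibraryStats) -> dict:
    """Table-style summary row set: counts plus percentages of high-quality."""
    pct = stats.percentages()
    rows = {
        "total_reads": (stats.total_reads, None),
        "high_quality": (stats.high_quality, 100.0 if stats.high_quality else 0.0),
    }
    for cat in CATEGORIES:
        label = "clean reads" if cat == "clean" else cat
        rows[label] = (stats.categories[cat], pct[cat])
    return rows


def fastq_reads(path) -> Iterator[tuple[str, list[int]]]:
    """Stream (sequence, phred) pairs from a FASTQ file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq), rec.letter_annotations["phred_quality"]
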