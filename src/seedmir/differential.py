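"""Two-library differential abundance for miRNA families and tags.

Each condition is represented by a single library (no replicates), so the
comparison is a count test between two proportions count/libsize.  The
default is Fisher's exact two-sided test on the 2x2 table
[[count_ds, libsize_ds - count_ds], [count_gs, libsize_gs - count_gs]];
an Audic-Claverie style posterior and a two-proportion normal approximation
are selectable alternatives.  Fold changes are raw-count ratios rounded
half-up to one decimal, matching how such tables are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .annotate import FamilyRecord
from .preprocess import round_half_up


def normalize_rpm(count: int, libsize: int) -> float:
    """Reads per million mapped reads."""
    if libsize <= 0:
        raise ValueError("library size must be positive")
    return 1e6 * count / libsize


def fold_change(count_ds: int, count_gs: int) -> float | None:
    """Raw-count DS/GS ratio, half-up to one decimal.

    Returns ``math.inf`` when count_gs is 0 and count_ds > 0, and ``None``
    (undefined) when both are zero.
    """
    if count_gs == 0:
        return None if count_ds == 0 else math.inf
    return round_half_up(count_ds / count_gs, 1)


def test_difference(
    count_ds: int,
    libsize_ds: int,
    count_gs: int,
    libsize_gs: int,
    method: str = "fisher",
) -> float:
    """P-value for a two-library difference in a tag/family proportion."""
    if count_ds > libsize_ds or count_gs > libsize_gs:
        raise ValueError("count exceeds library size")
    if libsize_ds <= 0 or libsize_gs <= 0:
        raise ValueError("library sizes must be positive")
    if method == "fisher":
        table = [
            [count_ds, libsize_ds - count_ds],
            [count_gs, libsize_gs - count_gs],
        ]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "audic-claverie":
        return _audic_claverie(count_ds, libsize_ds, count_gs, libsize_gs)
    if method == "normal":
        return _two_proportion(count_ds, libsize_ds, count_gs, libsize_gs)
    raise ValueError(f"unknown method: {method!r}")


def _audic_claverie(x: int, n1: int, y: int, n2: int) -> float:
    """Audic-Claverie tail probability: given x reads in library 1, the
    posterior predictive for y in library 2 is negative binomial with
    r = x + 1 and p = n1 / (n1 + n2); two-sided by doubling the smaller tail.
    """
    r = x + 1
    p = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, r, p)
    upper = stats.nbinom.sf(y - 1, r, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _two_proportion(x: int, n1: int, y: int, n2: int) -> float:
    p1, p2 = x / n1, y / n2
    pool = (x + y) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class FamilyAbundance:
    family: str
    count_ds: int
    count_gs: int
    libsize_ds: int
    libsize_gs: int
    rpm_ds: float
    rpm_gs: float
    ratio: float | None
    p_value: float
    significant: bool
    direction: str  # up | down | flat (in GS relative to DS)


def build_family_table(
    families: list[FamilyRecord],
    libsize_ds: int,
    libsize_gs: int,
    alpha: float = 0.01,
    method: str = "fisher",
    correction: str | None = None,
) -> list[FamilyAbundance]:
    """One differential-abundance row per family, sorted by family id.

    ``correction`` may be None (raw p-values, the default), "bonferroni", or
    "bh" (Benjamini-Hochberg); significance is flagged on the (possibly
    adjusted) p-value at ``alpha``.
    """
    rows = []
    pvals = []
    for fam in sorted(families, key=lambda f: _family_sort_key(f.family)):
        ds, gs = fam.counts[0], fam.counts[1]
        p = test_difference(ds, libsize_ds, gs, libsize_gs, method=method)
        pvals.append(p)
        rows.append((fam, ds, gs, p))
    if correction == "bonferroni":
        pvals = [min(1.0, p * len(pvals)) for p in pvals]
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests

        pvals = list(multipletests(pvals, method="fdr_bh")[1]) if pvals else []
    elif correction is not None:
        raise ValueError(f"unknown correction: {correction!r}")
    out = []
    for (fam, ds, gs, _), p in zip(rows, pvals):
        rpm_ds = normalize_rpm(ds, libsize_ds)
        rpm_gs = normalize_rpm(gs, libsize_gs)
        if rpm_gs > rpm_ds:
            direction = "up"
        elif rpm_gs < rpm_ds:
            direction = "down"
        else:
            direction = "flat"
        out.append(
            FamilyAbundance(
                family=fam.family,
                count_ds=ds,
                count_gs=gs,
                libsize_ds=libsize_ds,
                libsize_gs=libsize_gs,
                rpm_ds=rpm_ds,
                rpm_gs=rpm_gs,
                ratio=fold_change(ds, gs),
                p_value=p,
                significant=alpha > 0 and p <= alpha,
                direction=direction,
            )
        )
    return out


def _family_sort_key(name: str):
    import re

    m = re.search(r"(\d+)", name)
    return (0, int(m.group(1)), name) if m else (1, 0, name)
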