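"""Hypergeometric term enrichment of target gene sets.

For a term annotating K of N background genes, observing k annotated genes in
a target set of size n has upper-tail probability P[X >= k] with
X ~ Hypergeometric(N, K, n); p-values are Benjamini-Hochberg adjusted across
terms.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    term: str
    k: int  # target genes with the term
    K: int  # background genes with the term
    n: int  # target-set size
    N: int  # background size
    p_value: float
    p_adjusted: float


def enrich(
    target_genes: Iterable[str],
    background_genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment, one result per term with k >= 1.

    ``term_map`` maps gene -> terms.  Raises ValueError naming any target
    gene absent from the background.  Results are sorted by adjusted then raw
    p-value.
    """
    background = set(background_genes)
    target = set(target_genes)
    missing = target - background
    if missing:
        raise ValueError(f"target gene(s) not in background: {sorted(missing)}")
    N, n = len(background), len(target)
    term_bg: dict[str, set] = defaultdict(set)
    for gene, terms in term_map.items():
        if gene in background:
            for t in terms:
                term_bg[t].add(gene)
    rows = []
    for term, genes in sorted(term_bg.items()):
        k = len(genes & target)
        if k < 1:
            continue
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return []
    padj = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    out = [
        EnrichmentResult(term, k, K, n, N, p, float(pa))
        for (term, k, K, p), pa in zip(rows, padj)
    ]
    out.sort(key=lambda r: (r.p_adjusted, r.p_value, r.term))
    return out


def filter_by_abundance(
    normalized_counts: Mapping[str, float], min_reads: float = 50
) -> set[str]:
    """Keep miRNAs sequenced strictly more than ``min_reads`` times in the
    normalized libraries (the conventional >50-read cut for downstream
    functional analysis)."""
    return {mid for mid, c in normalized_counts.items() if c > min_reads}
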