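"""Co-binding overlap enrichment and pre-ranked weighted GSEA.

Overlap enrichment treats accessible regions as a finite universe: with N
accessible sites of which K overlap another factor's binding sites, drawing
the n accessible sites overlapped by the heterodimer and observing k in the
intersection has upper-tail probability

    P = sum_{j=k}^{min(n,K)} C(K,j) C(N-K, n-j) / C(N,n)

Gene set enrichment uses the pre-ranked weighted running-sum statistic.
Genes are ranked by pi = log2FC * (-log10 p); walking the ranked list, set
members add |pi|^p (normalized so hits sum to 1) and non-members subtract
1/(N - m). The enrichment score ES is the signed maximum deviation from
zero; significance comes from gene-label permutations, and NES divides ES
by the mean magnitude of same-sign permutation scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GeneAnnotation, PeakSet
from .genomic_distribution import nearest_tss
from .site_definition import CanonicalSiteSet

__all__ = [
    "OverlapTest",
    "EnrichmentResult",
    "hypergeometric_overlap",
    "rank_genes",
    "gsea_preranked",
    "nearest_gene_set",
]

P_VALUE_FLOOR = 1e-300


@dataclass
class OverlapTest:
    N: int           # universe size (accessible regions)
    K: int           # universe members overlapped by the other factor
    n: int           # universe members overlapped by the heterodimer
    k: int           # overlapped by both
    p_value: float   # hypergeometric upper tail P(X >= k)
    enrichment: float  # (k/n) / (K/N)


def hypergeometric_overlap(
    universe: PeakSet, factor: PeakSet, target: PeakSet, min_overlap: int = 1
) -> OverlapTest:
    """Hypergeometric test of co-binding within an accessible-region universe.

    Membership is >= min_overlap bp overlap of a universe region with the
    factor / target sets. ``target`` is the heterodimer site set (the draw);
    ``factor`` defines the successes.
    """
    f_trees = factor.trees()
    t_trees = target.trees()
    f_by, t_by = factor.by_chrom(), target.by_chrom()

    def member(iv, trees, by_chrom):
        tree = trees.get(iv.chrom)
        if tree is None:
            return False
        return any(
            iv.overlap(by_chrom[iv.chrom][h.data]) >= min_overlap
            for h in tree.overlap(iv.start, iv.end)
        )

    N = len(universe)
    in_f = np.array([member(iv, f_trees, f_by) for iv in universe])
    in_t = np.array([member(iv, t_trees, t_by) for iv in universe])
    K, n, k = int(in_f.sum()), int(in_t.sum()), int((in_f & in_t).sum())
    if K == 0:
        raise ValueError("no universe member overlaps the factor set")
    if n == 0:
        raise ValueError("no universe member overlaps the target set")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(N, K, n, k, min(p, 1.0), (k / n) / (K / N))


def rank_genes(
    table: pd.DataFrame,
    log2fc_col: str = "log2fc",
    pvalue_col: str = "pvalue",
    gene_col: str = "gene_id",
    p_floor: float = P_VALUE_FLOOR,
) -> pd.Series:
    """Rank genes by pi = log2FC * (-log10 p), descending.

    Returns a Series of pi scores indexed by gene_id, sorted descending with
    ties broken by gene_id. Zero p-values are clipped to ``p_floor``.
    """
    if table[gene_col].duplicated().any():
        raise ValueError("duplicate gene ids in ranked table")
    phi = table[log2fc_col].astype(float).values
    pv = np.clip(table[pvalue_col].astype(float).values, p_floor, 1.0)
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite fold changes")
    pi = phi * (-np.log10(pv))
    out = pd.Series(pi, index=pd.Index(table[gene_col].values, name="gene_id"))
    return out.sort_index().sort_values(ascending=False, kind="stable")


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_permutations: int
    running_sum: np.ndarray
    hit_positions: np.ndarray


def _es_from_positions(
    pos: np.ndarray, weights: np.ndarray, n_list: int
) -> float:
    """Signed maximum running-sum deviation from hit positions and weights.

    ``pos`` are 0-based, sorted hit indices; ``weights`` the corresponding
    normalized increments. The running sum's extrema occur just before or
    just after a hit, so only those 2m points need checking.
    """
    m = pos.size
    miss_pen = 1.0 / (n_list - m)
    cum = np.cumsum(weights)
    misses_before = pos - np.arange(m)
    at_hit = cum - misses_before * miss_pen
    before_hit = np.concatenate(([0.0], cum[:-1])) - misses_before * miss_pen
    hi = float(at_hit.max())
    lo = float(min(before_hit.min(), 0.0))
    return hi if hi >= -lo else lo


def gsea_preranked(
    ranked: pd.Series,
    gene_set: set[str] | frozenset[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Weighted pre-ranked gene set enrichment with gene-label permutations.

    ``ranked`` is the descending pi-score Series from :func:`rank_genes`.
    Nominal P = (1 + #{same-sign null |ES| >= |ES|}) / (n_perm + 1);
    NES = ES / mean |same-sign null ES|.
    """
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    n_list = genes.size
    in_set = np.isin(genes, list(gene_set))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if m >= n_list:
        raise ValueError("gene set covers the whole ranked list")
    w_all = np.abs(scores) ** weight

    def es_at(idx_sorted: np.ndarray) -> float:
        w = w_all[idx_sorted]
        tot = w.sum()
        if tot == 0:  # all-zero scores degenerate to the unweighted statistic
            w = np.ones_like(w)
            tot = w.sum()
        return _es_from_positions(idx_sorted, w / tot, n_list)

    hit_idx = np.flatnonzero(in_set)
    es = es_at(hit_idx)

    # observed running sum, for plotting
    steps = np.full(n_list, -1.0 / (n_list - m))
    w_obs = w_all[hit_idx]
    tot = w_obs.sum()
    steps[hit_idx] = (w_obs / tot) if tot > 0 else (1.0 / m)
    running = np.cumsum(steps)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = np.sort(rng.choice(n_list, size=m, replace=False))
        null[i] = es_at(idx)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    n_extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
    p = (1 + n_extreme) / (n_perm + 1)
    denom = float(np.mean(np.abs(same_sign))) if same_sign.size else float("nan")
    nes = es / denom if denom and np.isfinite(denom) else float("nan")
    return EnrichmentResult(float(es), float(nes), float(p), n_perm, running, hit_idx)


def nearest_gene_set(sites: CanonicalSiteSet, ann: GeneAnnotation) -> set[str]:
    """The deduplicated set of genes whose TSS is nearest to each site."""
    if len(sites.peaks) == 0:
        return set()
    dist = nearest_tss(sites.peaks, ann)
    return set(dist["gene_id"].tolist())
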