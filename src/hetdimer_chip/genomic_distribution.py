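"""TSS-distance profiles of binding-site sets and their comparison.

Each site is anchored at its summit and assigned the transcription start
site minimizing the absolute summit-TSS distance on the same chromosome.
The signed distance follows gene orientation: negative = upstream of the
TSS relative to the gene's strand. Profiles are binned frequency
distributions over symmetric log-spaced magnitude bins and compared with a
two-sample chi-squared test on the 2 x k count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GeneAnnotation, PeakSet, intersect

__all__ = [
    "DistanceProfile",
    "DEFAULT_BIN_EDGES",
    "nearest_tss",
    "distance_histogram",
    "compare_distributions",
    "accessible_motif_distribution",
    "stratify_by_conservation",
]

# Symmetric log-spaced magnitude bins (bp), upstream negative. The zero
# distance is folded into the first downstream bin [0, 1k).
DEFAULT_BIN_EDGES: tuple[float, ...] = (
    -np.inf, -1e5, -1e4, -1e3, 0.0, 1e3, 1e4, 1e5, np.inf
)


@dataclass
class DistanceProfile:
    distances: np.ndarray          # signed distances of the profiled sites
    bin_edges: np.ndarray          # len k+1, half-open [lo, hi) bins
    counts: np.ndarray
    proportions: np.ndarray
    n_sites: int


def nearest_tss(sites: PeakSet, ann: GeneAnnotation) -> pd.DataFrame:
    """Signed distance from each site summit to the nearest TSS.

    Returns a DataFrame (site, chrom, distance, gene_id, tie) for sites on
    chromosomes present in the annotation; sites on absent chromosomes are
    excluded with a warning. Equidistant TSS ties are broken toward the
    lexicographically smaller gene_id and flagged.
    """
    if len(ann) == 0:
        raise ValueError("empty annotation")
    by_chrom = {
        chrom: (
            sub["tss"].to_numpy(),
            sub["gene_id"].to_numpy(),
            sub["strand"].to_numpy(),
        )
        for chrom, sub in ann.by_chrom().items()
    }
    rows, skipped = [], 0
    for iv in sites:
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            skipped += 1
            continue
        pos, gene_ids, strands = entry
        summit = iv.summit_pos
        j = int(np.searchsorted(pos, summit))
        cand = [k for k in (j - 1, j) if 0 <= k < len(pos)]
        dists = {k: abs(summit - pos[k]) for k in cand}
        best_d = min(dists.values())
        winners = sorted(
            (gene_ids[k], k) for k in cand if dists[k] == best_d
        )
        gene, k_win = winners[0]
        signed = (summit - pos[k_win]) * (1 if strands[k_win] == "+" else -1)
        rows.append(
            {
                "site": iv.name,
                "chrom": iv.chrom,
                "distance": int(signed),
                "gene_id": gene,
                "tie": len(winners) > 1,
            }
        )
    if skipped:
        warnings.warn(f"{skipped} sites on chromosomes absent from annotation")
    return pd.DataFrame(rows, columns=["site", "chrom", "distance", "gene_id", "tie"])


def distance_histogram(
    distances: np.ndarray | Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> DistanceProfile:
    """Binned frequency distribution of signed TSS distances."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("no distances to profile")
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    idx = np.searchsorted(edges, distances, side="right") - 1
    idx = np.clip(idx, 0, len(counts) - 1)
    for i in idx:
        counts[i] += 1
    return DistanceProfile(
        distances=distances,
        bin_edges=edges,
        counts=counts,
        proportions=counts / counts.sum(),
        n_sites=int(distances.size),
    )


def _merge_sparse(table: np.ndarray) -> np.ndarray:
    """Merge bins pairwise from the tails until expected counts are adequate.

    Expected counts under homogeneity must be >= 5 in at least 80% of bins;
    tail bins are folded inwards (left tail first) until that holds or only
    two bins remain.
    """
    t = table.copy().astype(float)
    while t.shape[1] > 2:
        total = t.sum()
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
        if (expected >= 5).mean() >= 0.8:
            break
        left, right = expected[:, 0].min(), expected[:, -1].min()
        if left <= right:
            t[:, 1] += t[:, 0]
            t = t[:, 1:]
        else:
            t[:, -2] += t[:, -1]
            t = t[:, :-1]
    return t


def compare_distributions(
    profile_a: DistanceProfile,
    profile_b: DistanceProfile,
    merge_sparse: bool = True,
) -> tuple[float, int, float]:
    """Two-sample chi-squared test on the two profiles' count vectors.

    Bins with zero joint count are dropped; sparse tail bins are optionally
    merged so expected counts are adequate. Returns (statistic, df, P).
    """
    if not np.array_equal(profile_a.bin_edges, profile_b.bin_edges):
        raise ValueError("profiles use different bin schemes")
    table = np.vstack([profile_a.counts, profile_b.counts]).astype(float)
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0, 0, 1.0
    if merge_sparse:
        table = _merge_sparse(table)
    if np.array_equal(table[0], table[1]):
        return 0.0, table.shape[1] - 1, 1.0
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def accessible_motif_distribution(
    motifs: PeakSet,
    accessible: PeakSet,
    ann: GeneAnnotation,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> DistanceProfile:
    """TSS-distance profile of motif occurrences lying in open chromatin.

    Serves as the neutral baseline both isoforms' site profiles are compared
    against: where *could* the dimer bind, given motif and accessibility?
    """
    open_motifs = intersect(motifs, accessible, 1)
    if len(open_motifs) == 0:
        raise ValueError("no motifs overlap accessible regions")
    dist = nearest_tss(open_motifs, ann)
    return distance_histogram(dist["distance"].values, bin_edges)


def stratify_by_conservation(
    clusters: PeakSet,
    cell_counts: pd.Series,
    ann: GeneAnnotation,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> dict[int, DistanceProfile]:
    """One TSS-distance profile per conservation stratum (cells supporting).

    ``cell_counts`` maps cluster name -> number of supporting cell lines
    (the conservation_count output). Empty strata are skipped with a warning.
    """
    dist = nearest_tss(clusters, ann).set_index("site")
    out: dict[int, DistanceProfile] = {}
    for k in sorted(set(cell_counts.values), reverse=True):
        names = cell_counts.index[cell_counts == k]
        sub = dist.loc[dist.index.intersection(names), "distance"].values
        if sub.size == 0:
            warnings.warn(f"conservation stratum {k}: no sites, skipped")
            continue
        out[int(k)] = distance_histogram(sub, bin_edges)
    return out
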