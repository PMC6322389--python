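"""Heterodimer stoichiometry: alpha:beta signal ratios and their reproducibility.

A heterodimeric transcription factor binding DNA as an obligate 1:1 dimer
should show total alpha-subunit ChIP signal proportional to beta-subunit
signal at every site. Three views of this are computed:

- the correlation of total alpha (alpha1 + alpha2) with beta signal across
  sites (log scale);
- the per-site ratio r = total_alpha / beta and its distribution (log2
  histogram, median, mode, central fold-range);
- the reproducibility of per-site ratios between replicates. If apparent
  deviations from 1:1 are noise, the per-site log-ratio correlates poorly
  between independent replicates; genuine site-wise stoichiometry differences
  would reproduce.

All ratio work uses a pseudocount (default 0.1 CPM) added to numerator and
denominator, and log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .signal_quant import SiteSignalMatrix

__all__ = [
    "StoichiometryResult",
    "alpha_beta_correlation",
    "ratio_distribution",
    "ratio_reproducibility",
]

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class StoichiometryResult:
    ratios: np.ndarray                 # per-site replicate-averaged r
    log2_bin_edges: np.ndarray
    density: np.ndarray                # histogram, integrates to 1 over log2 r
    median: float
    mode_log2: float                   # centre of the modal log2 bin
    fold_range_central98: float        # 99th / 1st percentile of r


@dataclass
class CorrelationResult:
    total_alpha: np.ndarray
    beta: np.ndarray
    pearson_r: float
    p_value: float


@dataclass
class ReproducibilityResult:
    log2_ratio_rep1: np.ndarray
    log2_ratio_rep2: np.ndarray
    pearson_r: float
    slope: float
    noise_dominated: bool


def _columns(
    matrix: SiteSignalMatrix,
    alpha1: Sequence[str],
    alpha2: Sequence[str],
    beta: Sequence[str],
    units: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a1 = matrix.assay_mean(alpha1, units).values
    a2 = matrix.assay_mean(alpha2, units).values
    b = matrix.assay_mean(beta, units).values
    return a1, a2, b


def alpha_beta_correlation(
    matrix: SiteSignalMatrix,
    alpha1_cols: Sequence[str],
    alpha2_cols: Sequence[str],
    beta_cols: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    units: str = "cpm",
) -> CorrelationResult:
    """Pearson correlation of log10 total-alpha vs beta signal across sites."""
    a1, a2, b = _columns(matrix, alpha1_cols, alpha2_cols, beta_cols, units)
    if a1.size < 3:
        raise ValueError("need at least 3 sites for a correlation")
    total_alpha = a1 + a2
    r, p = stats.pearsonr(
        np.log10(total_alpha + pseudocount), np.log10(b + pseudocount)
    )
    return CorrelationResult(total_alpha, b, float(r), float(p))


def ratio_distribution(
    matrix: SiteSignalMatrix,
    alpha1_cols: Sequence[str],
    alpha2_cols: Sequence[str],
    beta_cols: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    bins: int = 50,
    units: str = "cpm",
) -> StoichiometryResult:
    """Per-site total-alpha : beta ratio and its log2 frequency distribution."""
    a1, a2, b = _columns(matrix, alpha1_cols, alpha2_cols, beta_cols, units)
    r = (a1 + a2 + pseudocount) / (b + pseudocount)
    log2r = np.log2(r)
    lo, hi = float(np.min(log2r)), float(np.max(log2r))
    if lo == hi:  # degenerate: all mass in one bin
        lo, hi = lo - 0.5, hi + 0.5
    density, edges = np.histogram(log2r, bins=bins, range=(lo, hi), density=True)
    mode_bin = int(np.argmax(density))
    mode_log2 = float((edges[mode_bin] + edges[mode_bin + 1]) / 2)
    q01, q99 = np.percentile(r, [1, 99])
    return StoichiometryResult(
        ratios=r,
        log2_bin_edges=edges,
        density=density,
        median=float(np.median(r)),
        mode_log2=mode_log2,
        fold_range_central98=float(q99 / q01),
    )


def ratio_reproducibility(
    matrix: SiteSignalMatrix,
    rep1_cols: tuple[Sequence[str], Sequence[str], Sequence[str]],
    rep2_cols: tuple[Sequence[str], Sequence[str], Sequence[str]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    noise_threshold: float = 0.2,
    units: str = "cpm",
) -> ReproducibilityResult:
    """Correlate the per-site log2 alpha:beta ratio between replicates.

    ``rep1_cols`` / ``rep2_cols`` each give (alpha1, alpha2, beta) column
    labels for that replicate. A correlation below ``noise_threshold`` flags
    the ratio spread as noise-dominated (apparent stoichiometry differences
    do not reproduce between independent experiments).
    """
    ratios = []
    for cols in (rep1_cols, rep2_cols):
        a1, a2, b = _columns(matrix, *cols, units)
        ratios.append(np.log2((a1 + a2 + pseudocount) / (b + pseudocount)))
    r1, r2 = ratios
    if r1.size < 3:
        raise ValueError("need at least 3 sites")
    if np.std(r1) == 0 or np.std(r2) == 0:
        corr, slope = 1.0 if np.array_equal(r1, r2) else 0.0, 0.0
    else:
        corr = float(stats.pearsonr(r1, r2)[0])
        slope = float(np.polyfit(r1, r2, 1)[0])
    return ReproducibilityResult(
        r1, r2, corr, slope, noise_dominated=bool(corr < noise_threshold)
    )
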