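"""Cross-condition binding dynamics and isoform-specificity analyses.

Covers: condition-vs-condition signal comparison over a site superset; the
tertile corroboration test (do sites whose alpha-subunit signal loads
progressively with stimulus severity show the same behaviour in the
beta-subunit signal, arguing biology rather than assay noise?);
isoform-ratio stability across conditions or cell lines; knockout contrasts
(does losing one alpha-isoform increase binding of the other?); site
classification by isoform specificity; and cross-cell-line conservation
counting.

Wilcoxon tests use the exact null distribution for small samples without
ties (both groups <= 25 for the rank-sum test, n <= 25 pairs for the
signed-rank test) and the normal approximation with tie and continuity
corrections otherwise, so P values are reproducible across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, PeakSet, cluster_intervals
from .signal_quant import SiteSignalMatrix
from .site_definition import CanonicalSiteSet

__all__ = [
    "ConditionComparison",
    "IsoformSpecificity",
    "ConservationResult",
    "rank_sum_test",
    "signed_rank_test",
    "compare_conditions",
    "tertile_corroboration",
    "isoform_ratio_stability",
    "knockout_contrast",
    "classify_specificity",
    "conservation_count",
]

EXACT_N_MAX = 25          # exact null when no ties and samples this small
TIE_ENUM_N_MAX = 12       # permutation enumeration with midranks despite ties


# ---------------------------------------------------------------------------
# Wilcoxon wrappers
# ---------------------------------------------------------------------------


def _tail_p(null: np.ndarray, obs: float, alternative: str) -> float:
    if alternative == "greater":
        return float(np.mean(null >= obs - 1e-12))
    if alternative == "less":
        return float(np.mean(null <= obs + 1e-12))
    hi = np.mean(null >= obs - 1e-12)
    lo = np.mean(null <= obs + 1e-12)
    return float(min(1.0, 2 * min(hi, lo)))


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    The exact null distribution is used for small samples (both groups <= 25
    without ties; direct enumeration of group assignments over midranks for
    tied samples of <= 12 per group); otherwise the normal approximation
    with tie and continuity corrections. Returns (U statistic for x, P).
    """
    import itertools

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    n1, n2 = len(x), len(y)
    if np.all(combined == combined[0]):
        return float(n1 * n2 / 2), 1.0
    if not has_ties and n1 <= EXACT_N_MAX and n2 <= EXACT_N_MAX:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return float(res.statistic), float(res.pvalue)
    if n1 <= TIE_ENUM_N_MAX and n2 <= TIE_ENUM_N_MAX:
        ranks = stats.rankdata(combined)
        obs = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2
        null = np.array([
            ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            for idx in itertools.combinations(range(n1 + n2), n1)
        ])
        return obs, _tail_p(null, obs, alternative)
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples x vs y.

    The exact null is used for n <= 25 pairs without tied magnitudes, and a
    full sign-flip enumeration over midranks for tied samples of n <= 12;
    the normal approximation with continuity correction otherwise. Zero
    differences are dropped (Wilcoxon's convention). Returns (W+, P).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    n = d.size
    mags = np.abs(d)
    has_ties = np.unique(mags).size < mags.size
    if not has_ties and n <= EXACT_N_MAX:
        res = stats.wilcoxon(d, alternative=alternative, method="exact")
        return float(res.statistic), float(res.pvalue)
    if n <= TIE_ENUM_N_MAX:
        ranks = stats.rankdata(mags)
        obs = float(ranks[d > 0].sum())
        patterns = (
            np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        ) & 1  # every sign assignment as a 0/1 matrix
        null = patterns @ ranks
        return obs, _tail_p(null, obs, alternative)
    res = stats.wilcoxon(d, alternative=alternative, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Condition comparison & tertile corroboration
# ---------------------------------------------------------------------------


@dataclass
class ConditionComparison:
    """Per-site signal in two conditions and the loading ratios q = B/A."""

    table: pd.DataFrame            # columns: <assay>_a, <assay>_b, q_<assay>
    pearson_log: dict[str, float]  # per-assay Pearson r on log10 signals
    mean_fold_change: dict[str, float]
    alpha_assay: str
    beta_assay: str


def compare_conditions(
    matrix_a: SiteSignalMatrix,
    matrix_b: SiteSignalMatrix,
    assay_cols: dict[str, Sequence[str]],
    pseudocount: float = 0.0,
    alpha_assay: str = "alpha_total",
    beta_assay: str = "beta",
    units: str = "cpm",
) -> ConditionComparison:
    """Pair per-site signal between two conditions quantified on one superset.

    ``assay_cols`` maps assay names (e.g. ``alpha_total``, ``beta``) to the
    replicate column labels averaged within each matrix. q is the per-site
    fold change of condition B over condition A; sites where q is not finite
    (zero signal in A with zero pseudocount) are dropped with a warning.
    """
    if len(matrix_a.cpm) == 0:
        raise ValueError("empty site superset")
    if not matrix_a.cpm.index.equals(matrix_b.cpm.index):
        raise ValueError("matrices must be quantified on the same superset")
    data: dict[str, np.ndarray] = {}
    pearson, fold = {}, {}
    for assay, cols in assay_cols.items():
        a = matrix_a.assay_mean(cols, units).values
        b = matrix_b.assay_mean(cols, units).values
        q = (b + pseudocount) / (a + pseudocount)
        data[f"{assay}_a"] = a
        data[f"{assay}_b"] = b
        data[f"q_{assay}"] = q
        ok = (a > 0) & (b > 0)
        if ok.sum() >= 3 and np.std(np.log10(a[ok])) > 0 and np.std(np.log10(b[ok])) > 0:
            pearson[assay] = float(
                stats.pearsonr(np.log10(a[ok]), np.log10(b[ok]))[0]
            )
        else:
            pearson[assay] = float("nan")
        finite = np.isfinite(q)
        fold[assay] = float(np.mean(q[finite])) if finite.any() else float("nan")
    table = pd.DataFrame(data, index=matrix_a.cpm.index)
    bad = ~np.isfinite(table.filter(like="q_")).all(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} sites with non-finite ratios")
        table = table[~bad]
    return ConditionComparison(table, pearson, fold, alpha_assay, beta_assay)


@dataclass
class TertileResult:
    p_value: float
    direction: int           # sign of median q_beta difference (upper - lower)
    corroborated: bool
    upper_idx: np.ndarray
    lower_idx: np.ndarray


def tertile_corroboration(
    cmp: ConditionComparison, alpha_level: float = 0.05
) -> TertileResult:
    """Test whether alpha-defined loading tertiles reproduce in the beta signal.

    Sites are ranked by the alpha loading ratio q(alpha) and split into three
    rank tertiles (sizes differing by at most 1, ties broken by site order).
    A two-sided rank-sum test compares q(beta) between the upper and lower
    tertiles; the corroboration flag requires significance and a positive
    direction (upper-alpha tertile also has higher beta ratio).
    """
    q_alpha = cmp.table[f"q_{cmp.alpha_assay}"].values
    q_beta = cmp.table[f"q_{cmp.beta_assay}"].values
    n = q_alpha.size
    if n < 9:
        raise ValueError("need at least 9 sites for tertiles")
    order = np.argsort(q_alpha, kind="stable")
    thirds = np.array_split(order, 3)
    lower, upper = thirds[0], thirds[2]
    if np.all(q_beta == q_beta[0]):
        return TertileResult(1.0, 0, False, upper, lower)
    _, p = rank_sum_test(q_beta[upper], q_beta[lower], alternative="two-sided")
    direction = int(np.sign(np.median(q_beta[upper]) - np.median(q_beta[lower])))
    return TertileResult(
        float(p), direction, bool(p < alpha_level and direction > 0), upper, lower
    )


# ---------------------------------------------------------------------------
# Isoform specificity
# ---------------------------------------------------------------------------


@dataclass
class IsoformSpecificity:
    s: pd.Series                  # per-site log2((alpha1+pc)/(alpha2+pc))
    classes: pd.Series            # isoform1-specific | isoform2-specific | shared
    threshold_log2: float


def classify_specificity(
    matrix: SiteSignalMatrix,
    alpha1_cols: Sequence[str],
    alpha2_cols: Sequence[str],
    threshold_log2: float = 1.0,
    pseudocount: float = 0.1,
    units: str = "cpm",
) -> IsoformSpecificity:
    """Classify sites by the log2 ratio of alpha1 to alpha2 signal.

    s >= threshold -> isoform1-specific; s <= -threshold -> isoform2-specific;
    otherwise shared. Antisymmetric: swapping the alpha columns swaps the two
    specific classes.
    """
    a1 = matrix.assay_mean(alpha1_cols, units)
    a2 = matrix.assay_mean(alpha2_cols, units)
    s = np.log2((a1 + pseudocount) / (a2 + pseudocount))
    classes = pd.Series("shared", index=s.index)
    classes[s >= threshold_log2] = "isoform1-specific"
    classes[s <= -threshold_log2] = "isoform2-specific"
    return IsoformSpecificity(s, classes, threshold_log2)


def isoform_ratio_stability(
    matrix_a: SiteSignalMatrix,
    matrix_b: SiteSignalMatrix,
    alpha1_cols: Sequence[str],
    alpha2_cols: Sequence[str],
    pseudocount: float = 0.1,
    units: str = "cpm",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Correlate the per-site isoform ratio s between two conditions or cells.

    Returns (s_a, s_b, Pearson r). Only sites present in both matrices are
    used, so the same call serves cross-condition (identical supersets) and
    cross-cell (shared clusters) comparisons.
    """
    common = matrix_a.cpm.index.intersection(matrix_b.cpm.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared sites")
    out = []
    for m in (matrix_a, matrix_b):
        a1 = m.assay_mean(alpha1_cols, units).loc[common].values
        a2 = m.assay_mean(alpha2_cols, units).loc[common].values
        out.append(np.log2((a1 + pseudocount) / (a2 + pseudocount)))
    s_a, s_b = out
    r = float(stats.pearsonr(s_a, s_b)[0])
    return s_a, s_b, r


# ---------------------------------------------------------------------------
# Knockout contrasts
# ---------------------------------------------------------------------------


def knockout_contrast(
    wt_matrix: SiteSignalMatrix,
    ko_matrix: SiteSignalMatrix,
    surviving_cols: Sequence[str],
    classes: IsoformSpecificity,
    pseudocount: float = 0.1,
    min_class_size: int = 5,
    units: str = "cpm",
) -> pd.DataFrame:
    """Paired WT-vs-KO contrast of the surviving isoform's signal per site class.

    For each specificity class, a paired two-sided signed-rank test on log2
    signal, the median paired log2 difference (KO - WT), and the one-sided P
    for an *increase* in the knockout. Classes with fewer than
    ``min_class_size`` sites are skipped with a warning.
    """
    if not wt_matrix.cpm.index.equals(ko_matrix.cpm.index):
        raise ValueError("WT and KO matrices must share the site index")
    wt = np.log2(wt_matrix.assay_mean(surviving_cols, units) + pseudocount)
    ko = np.log2(ko_matrix.assay_mean(surviving_cols, units) + pseudocount)
    rows = []
    for cls in ("isoform1-specific", "isoform2-specific", "shared"):
        mask = (classes.classes == cls).values
        if mask.sum() < min_class_size:
            warnings.warn(f"class {cls}: only {int(mask.sum())} sites, skipped")
            continue
        w, k = wt.values[mask], ko.values[mask]
        _, p_two = signed_rank_test(k, w, alternative="two-sided")
        _, p_inc = signed_rank_test(k, w, alternative="greater")
        rows.append(
            {
                "class": cls,
                "n": int(mask.sum()),
                "median_shift_log2": float(np.median(k - w)),
                "p_two_sided": p_two,
                "p_increase": p_inc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-cell conservation
# ---------------------------------------------------------------------------


@dataclass
class ConservationResult:
    clusters: PeakSet                       # one interval per cluster
    cell_counts: pd.Series                  # cluster name -> number of cells
    membership: pd.DataFrame                # cluster x cell boolean flags
    proportion_by_count: dict[int, float]   # fraction of clusters in >= k cells
    per_cell_shared_fraction: float         # mean fraction of a cell's sites in >=2-cell clusters


def conservation_count(
    sets: Sequence[CanonicalSiteSet],
    cell_labels: Sequence[str] | None = None,
    min_overlap: int = 1,
) -> ConservationResult:
    """Cluster canonical sites across cell lines and count supporting cells.

    Single-linkage clustering (>= min_overlap bp); each cluster records which
    cell lines contributed a site. ``proportion_by_count[k]`` is the fraction
    of clusters supported by at least k cells; ``per_cell_shared_fraction``
    is the average, over cells, of the fraction of that cell's sites falling
    in clusters supported by two or more cells (the per-repertoire sharing
    the generator's shared core produces).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 cell-line site sets")
    isoforms = {s.isoform for s in sets}
    if len(isoforms) != 1:
        raise ValueError(f"mixed isoform labels {sorted(isoforms)}")
    if cell_labels is None:
        cell_labels = [f"cell{i}" for i in range(len(sets))]
    tagged = [(iv, lab) for s, lab in zip(sets, cell_labels) for iv in s.peaks]
    ivs, rows = [], []
    for i, cluster in enumerate(cluster_intervals(tagged, min_overlap)):
        start = min(iv.start for iv, _ in cluster)
        end = max(iv.end for iv, _ in cluster)
        name = f"cc{i:06d}"
        summit = (end - start) // 2
        ivs.append(GenomicInterval(cluster[0][0].chrom, start, end, name=name,
                                   summit=summit))
        members = {lab for _, lab in cluster}
        rows.append({"cluster": name, **{lab: lab in members for lab in cell_labels}})
    membership = pd.DataFrame(rows).set_index("cluster")
    counts = membership.sum(axis=1)
    n_clusters = len(counts)
    prop = {
        k: float((counts >= k).mean()) for k in range(1, len(sets) + 1)
    }
    shared_clusters = membership.index[counts >= 2]
    per_cell = []
    for lab in cell_labels:
        mine = membership[lab]
        if mine.sum() == 0:
            continue
        per_cell.append(float(membership.loc[mine, lab].index.isin(shared_clusters).mean()))
    return ConservationResult(
        clusters=PeakSet(ivs),
        cell_counts=counts,
        membership=membership,
        proportion_by_count=prop,
        per_cell_shared_fraction=float(np.mean(per_cell)) if per_cell else 0.0,
    )
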