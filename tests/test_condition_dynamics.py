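import itertools

import numpy as np
import pandas as pd
import pytest

from hetdimer_chip import (
    CanonicalSiteSet,
    GenomicInterval,
    PeakSet,
    classify_specificity,
    compare_conditions,
    conservation_count,
    isoform_ratio_stability,
    knockout_contrast,
    rank_sum_test,
    signed_rank_test,
    tertile_corroboration,
)
from hetdimer_chip.signal_quant import SiteSignalMatrix


def matrix_from(cpm_dict):
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cpm_dict.items()})
    df.index = pd.Index([f"s{i}" for i in range(len(df))], name="site_id")
    return SiteSignalMatrix(PeakSet(), df, df.copy(), df.copy())


# ---------------------------------------------------------------------------
# Exact enumeration oracles for the Wilcoxon tests
# ---------------------------------------------------------------------------


def exact_rank_sum_p(x, y, alternative="two-sided"):
    """Enumerate all group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pooled.argsort().argsort() + 1.0
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2  # observed U for x
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    if alternative == "greater":
        return np.mean(us >= obs)
    if alternative == "less":
        return np.mean(us <= obs)
    return min(1.0, 2 * min(np.mean(us >= obs), np.mean(us <= obs)))


def exact_signed_rank_p(d, alternative="two-sided"):
    """Enumerate all 2^n sign assignments of the paired differences."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = np.abs(d).argsort().argsort() + 1.0
    obs = ranks[d > 0].sum()
    ws = np.array([
        ranks[list(signs)].sum() if signs else 0.0
        for r in range(len(d) + 1)
        for signs in itertools.combinations(range(len(d)), r)
    ])
    if alternative == "greater":
        return np.mean(ws >= obs)
    if alternative == "less":
        return np.mean(ws <= obs)
    return min(1.0, 2 * min(np.mean(ws >= obs), np.mean(ws <= obs)))


class TestWilcoxonWrappers:
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_rank_sum_matches_enumeration(self, rng, alternative):
        for _ in range(8):
            x = rng.normal(0, 1, int(rng.integers(3, 9)))
            y = rng.normal(0.5, 1, int(rng.integers(3, 9)))
            _, p = rank_sum_test(x, y, alternative)
            assert p == pytest.approx(exact_rank_sum_p(x, y, alternative), abs=1e-12)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_signed_rank_matches_enumeration(self, rng, alternative):
        for _ in range(8):
            n = int(rng.integers(5, 12))
            x = rng.normal(0.3, 1, n)
            y = rng.normal(0, 1, n)
            _, p = signed_rank_test(x, y, alternative)
            assert p == pytest.approx(
                exact_signed_rank_p(x - y, alternative), abs=1e-12
            )

    def test_constant_samples_give_p_one(self):
        assert rank_sum_test(np.ones(5), np.ones(5))[1] == 1.0
        assert signed_rank_test(np.ones(5), np.ones(5))[1] == 1.0


class TestCompareConditions:
    cols = {"alpha_total": ["a"], "beta": ["b"]}

    def test_doubled_signal_gives_fold_change_two_and_r_one(self, rng):
        a = rng.lognormal(2, 0.5, 50)
        b = rng.lognormal(2, 0.5, 50)
        mA = matrix_from({"a": a, "b": b})
        mB = matrix_from({"a": 2 * a, "b": 2 * b})
        cmp = compare_conditions(mA, mB, self.cols)
        assert cmp.mean_fold_change["alpha_total"] == pytest.approx(2.0)
        assert cmp.pearson_log["alpha_total"] == pytest.approx(1.0)

    def test_identical_matrices_give_unit_fold_change(self, rng):
        m = matrix_from({"a": rng.lognormal(2, 0.5, 20),
                         "b": rng.lognormal(2, 0.5, 20)})
        cmp = compare_conditions(m, m, self.cols)
        assert cmp.mean_fold_change["beta"] == pytest.approx(1.0)

    def test_empty_superset_is_an_error(self):
        m = matrix_from({"a": [], "b": []})
        with pytest.raises(ValueError):
            compare_conditions(m, m, self.cols)


class TestTertileCorroboration:
    cols = {"alpha_total": ["a"], "beta": ["b"]}

    def test_constant_beta_ratio_gives_p_one(self, rng):
        a = rng.lognormal(2, 0.5, 30)
        mA = matrix_from({"a": a, "b": np.full(30, 5.0)})
        mB = matrix_from({"a": a * rng.lognormal(0.5, 0.3, 30),
                          "b": np.full(30, 9.0)})
        res = tertile_corroboration(compare_conditions(mA, mB, self.cols))
        assert res.p_value == 1.0
        assert not res.corroborated

    def test_beta_ratio_tracking_alpha_is_maximally_significant(self, rng):
        n = 24
        q = rng.lognormal(0, 0.5, n)
        mA = matrix_from({"a": np.ones(n), "b": np.ones(n)})
        mB = matrix_from({"a": q, "b": q})  # q(beta) = q(alpha) exactly
        res = tertile_corroboration(compare_conditions(mA, mB, self.cols))
        # minimal attainable two-sided exact P for 8 vs 8
        assert res.p_value == pytest.approx(2 / 12870, rel=1e-9)
        assert res.corroborated

    def test_tertiles_differ_in_size_by_at_most_one(self, rng):
        for n in (9, 10, 11):
            a = rng.lognormal(0, 1, n)
            mA = matrix_from({"a": np.ones(n), "b": np.ones(n)})
            mB = matrix_from({"a": a, "b": rng.lognormal(0, 1, n)})
            res = tertile_corroboration(compare_conditions(mA, mB, self.cols))
            assert abs(len(res.upper_idx) - len(res.lower_idx)) <= 1

    def test_invariant_to_rescaling_either_condition(self, rng):
        n = 30
        mA = matrix_from({"a": rng.lognormal(2, 0.5, n), "b": rng.lognormal(2, 0.5, n)})
        mB = matrix_from({"a": rng.lognormal(2, 0.5, n), "b": rng.lognormal(2, 0.5, n)})
        res = tertile_corroboration(compare_conditions(mA, mB, self.cols))
        mB7 = matrix_from({"a": 7 * mB.cpm["a"].values, "b": 7 * mB.cpm["b"].values})
        res7 = tertile_corroboration(compare_conditions(mA, mB7, self.cols))
        assert res7.p_value == pytest.approx(res.p_value)
        assert np.array_equal(res7.upper_idx, res.upper_idx)


class TestClassifySpecificity:
    def test_balanced_signal_is_shared(self):
        m = matrix_from({"a1": [5.0], "a2": [5.0]})
        res = classify_specificity(m, ["a1"], ["a2"])
        assert res.classes.iloc[0] == "shared"

    def test_exclusive_alpha1_signal_is_isoform1_specific(self):
        m = matrix_from({"a1": [50.0], "a2": [0.0]})
        res = classify_specificity(m, ["a1"], ["a2"])
        assert res.classes.iloc[0] == "isoform1-specific"

    def test_zero_threshold_leaves_no_shared_class(self, rng):
        m = matrix_from({"a1": rng.lognormal(1, 1, 50), "a2": rng.lognormal(1, 1, 50)})
        res = classify_specificity(m, ["a1"], ["a2"], threshold_log2=0.0)
        assert (res.classes != "shared").all()

    def test_antisymmetric_under_column_swap(self, rng):
        m = matrix_from({"a1": rng.lognormal(1, 1, 100), "a2": rng.lognormal(1, 1, 100)})
        fwd = classify_specificity(m, ["a1"], ["a2"])
        rev = classify_specificity(m, ["a2"], ["a1"])
        swap = {"isoform1-specific": "isoform2-specific",
                "isoform2-specific": "isoform1-specific", "shared": "shared"}
        assert (rev.classes == fwd.classes.map(swap)).all()


class TestIsoformRatioStability:
    def test_scaled_copy_has_perfect_correlation(self, rng):
        a1 = rng.lognormal(2, 1, 50)
        a2 = rng.lognormal(2, 1, 50)
        mA = matrix_from({"a1": a1, "a2": a2})
        mB = matrix_from({"a1": 5 * a1, "a2": 5 * a2})
        _, _, r = isoform_ratio_stability(mA, mB, ["a1"], ["a2"], pseudocount=0.0)
        assert r == pytest.approx(1.0)

    def test_permuted_ratios_decorrelate(self, rng):
        n = 1000
        rs = []
        for _ in range(20):
            a1, a2 = rng.lognormal(2, 1, n), rng.lognormal(2, 1, n)
            perm = rng.permutation(n)
            mA = matrix_from({"a1": a1, "a2": a2})
            mB = matrix_from({"a1": a1[perm], "a2": a2[perm]})
            rs.append(isoform_ratio_stability(mA, mB, ["a1"], ["a2"])[2])
        assert np.mean(np.abs(rs)) < 0.15


class TestKnockoutContrast:
    def _classes(self, m, n):
        labels = pd.Series(
            ["isoform1-specific"] * n + ["isoform2-specific"] * n + ["shared"] * n,
            index=m.cpm.index,
        )
        s = pd.Series(0.0, index=m.cpm.index)
        from hetdimer_chip.condition_dynamics import IsoformSpecificity
        return IsoformSpecificity(s, labels, 1.0)

    def test_identical_wt_and_ko_give_zero_shift_and_p_one(self, rng):
        n = 10
        m = matrix_from({"a1": rng.lognormal(2, 1, 3 * n)})
        res = knockout_contrast(m, m, ["a1"], self._classes(m, n))
        assert (res["median_shift_log2"] == 0).all()
        assert (res["p_two_sided"] == 1.0).all()

    def test_doubled_ko_signal_yields_minimal_p(self, rng):
        n = 8
        wt = matrix_from({"a1": rng.lognormal(2, 1, 3 * n)})
        ko = matrix_from({"a1": 2 * wt.cpm["a1"].values})
        res = knockout_contrast(wt, ko, ["a1"], self._classes(wt, n), pseudocount=0.0)
        assert np.allclose(res["median_shift_log2"], 1.0)
        # minimal exact two-sided signed-rank P at n = 8 pairs
        assert res["p_two_sided"].iloc[0] == pytest.approx(2 / 2**8)
        assert (res["p_increase"] < 0.01).all()

    def test_small_classes_skipped_with_warning(self, rng):
        m = matrix_from({"a1": rng.lognormal(2, 1, 6)})
        classes = self._classes(m, 2)
        with pytest.warns(UserWarning, match="skipped"):
            res = knockout_contrast(m, m, ["a1"], classes)
        assert len(res) == 0


class TestConservationCount:
    def _set(self, starts, isoform="isoform1"):
        return CanonicalSiteSet(
            PeakSet([GenomicInterval("chr1", s, s + 100, name=f"x{s}")
                     for s in starts]),
            isoform=isoform,
        )

    def test_identical_repertoires_fully_shared(self):
        sets = [self._set([100, 500, 900]) for _ in range(3)]
        res = conservation_count(sets)
        assert res.proportion_by_count[3] == 1.0
        assert res.per_cell_shared_fraction == 1.0

    def test_disjoint_repertoires_share_nothing(self):
        res = conservation_count([self._set([100]), self._set([500])])
        assert res.proportion_by_count[2] == 0.0
        assert res.per_cell_shared_fraction == 0.0

    def test_partial_sharing_counts_cells_per_cluster(self):
        res = conservation_count(
            [self._set([100, 500]), self._set([120, 900])]  # 100/120 overlap
        )
        assert len(res.clusters) == 3
        assert sorted(res.cell_counts.values) == [1, 1, 2]


class TestSyntheticFoldChangeRecovery:
    def test_doubled_condition_multiplier_recovered(self):
        import hetdimer_chip as hc

        cfg = hc.SimConfig(
            genome_length=30_000_000, n_genes=600, n_sites_per_isoform=250,
            depth_per_assay=1e6, seed=26, condition_scales={"lo": 0.5, "hi": 1.0},
        )
        _, truth = hc.generate_sites(cfg, hc.generate_annotation(cfg))
        m_lo = hc.site_signal_matrix(cfg, truth, "lo")
        m_hi = hc.site_signal_matrix(cfg, truth, "hi")
        cols = {
            "alpha_total": ["alpha1_rep1", "alpha1_rep2",
                            "alpha2_rep1", "alpha2_rep2"],
            "beta": ["beta_rep1", "beta_rep2"],
        }
        cmp = compare_conditions(m_lo, m_hi, cols, pseudocount=0.1)
        assert 1.8 <= cmp.mean_fold_change["beta"] <= 2.2
        assert cmp.pearson_log["beta"] > 0.9
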