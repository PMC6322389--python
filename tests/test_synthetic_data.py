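import numpy as np
import pytest

from hetdimer_chip import (
    GenomicInterval,
    PeakSet,
    SignalTrack,
    SimConfig,
    call_peaks_standin,
    generate_annotation,
    generate_expression,
    generate_sites,
    simulate_coverage,
    simulate_site_counts,
    write_dataset,
)
from hetdimer_chip.synthetic_data import expected_site_reads


class TestConfigValidation:
    def test_proportions_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(shared_fraction=1.2)
        with pytest.raises(ValueError):
            SimConfig(progressive_fraction=-0.1)

    def test_empty_condition_scales_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(condition_scales={})


class TestGenerateAnnotation:
    def test_tss_within_genome_bounds(self):
        cfg = SimConfig(n_genes=100, genome_length=10_000_000)
        ann = generate_annotation(cfg)
        assert len(ann) == 100
        assert ann.table["tss"].between(0, cfg.genome_length - 1).all()

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_genes=50, genome_length=5_000_000, seed=3)
        a = generate_annotation(cfg)
        b = generate_annotation(cfg)
        assert a.table.equals(b.table)

    def test_zero_genes_gives_empty_annotation(self):
        assert len(generate_annotation(SimConfig(n_genes=0))) == 0

    def test_too_many_genes_for_genome_is_sizing_error(self):
        with pytest.raises(ValueError, match="too short"):
            generate_annotation(SimConfig(n_genes=10_000, genome_length=1_000_000))


class TestGenerateSites:
    def test_isoform1_sites_concentrate_near_tss(self):
        cfg = SimConfig(
            genome_length=60_000_000, n_genes=1200, n_sites_per_isoform=1000,
            shared_fraction=0.0, isoform1_proximal_sd=500, seed=5,
        )
        ann = generate_annotation(cfg)
        _, truth = generate_sites(cfg, ann)
        iso1 = truth.sites[truth.sites["category"] == "isoform1"]
        frac = (iso1["tss_distance"].abs() <= 2000).mean()
        assert frac >= 0.8

    def test_isoform2_sites_kept_out_of_the_proximal_window(self):
        cfg = SimConfig(seed=6)
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        iso2 = truth.sites[truth.sites["category"] == "isoform2"]
        assert (iso2["tss_distance"].abs() >= cfg.proximal_window).all()

    def test_no_shared_sites_means_only_extreme_mixing(self):
        cfg = SimConfig(shared_fraction=0.0, seed=7)
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        lo, hi = 1 - cfg.specific_mix, cfg.specific_mix
        assert not ((truth.sites["mix"] > lo) & (truth.sites["mix"] < hi)).any()

    def test_all_shared_when_fraction_is_one(self):
        cfg = SimConfig(shared_fraction=1.0, seed=8)
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        assert (truth.sites["category"] == "shared").all()

    def test_minimum_separation_enforced(self):
        cfg = SimConfig(seed=9)
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        centres = np.sort(truth.sites["start"].values + truth.sites["summit"].values)
        assert np.diff(centres).min() >= cfg.min_separation

    def test_infeasible_packing_is_sizing_error(self):
        cfg = SimConfig(
            genome_length=400_000, n_genes=10, n_sites_per_isoform=300, seed=10
        )
        with pytest.raises(ValueError):
            generate_sites(cfg, generate_annotation(cfg))


class TestSimulateCounts:
    def test_noise_free_alpha_beta_ratio_is_exact(self):
        cfg = SimConfig(alpha_beta_ratio=1.0, replicate_cv=0.0, seed=11)
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        a1 = expected_site_reads(cfg, truth, "alpha1", "severe")
        a2 = expected_site_reads(cfg, truth, "alpha2", "severe")
        b = expected_site_reads(cfg, truth, "beta", "severe")
        assert np.allclose((a1 + a2) / b, 1.0)

    def test_condition_multiplier_scales_expectations(self):
        cfg = SimConfig(seed=12, condition_scales={"lo": 0.5, "hi": 1.0})
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        lo = expected_site_reads(cfg, truth, "beta", "lo")
        hi = expected_site_reads(cfg, truth, "beta", "hi")
        assert np.allclose(hi / lo, 2.0)

    def test_doubling_depth_multiplier_doubles_observed_counts(self):
        # graded-loading recovery on sampled counts at >= 1e6 depth
        cfg = SimConfig(
            seed=13, depth_per_assay=2e6, replicate_cv=0.2,
            condition_scales={"lo": 0.5, "hi": 1.0},
        )
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        lo, _ = simulate_site_counts(cfg, truth, "beta", "lo", 1)
        hi, _ = simulate_site_counts(cfg, truth, "beta", "hi", 1)
        assert 1.9 <= hi.mean() / lo.mean() <= 2.1

    def test_unknown_labels_rejected(self):
        cfg = SimConfig(seed=14)
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        with pytest.raises(ValueError):
            simulate_site_counts(cfg, truth, "gamma", "severe", 1)
        with pytest.raises(ValueError):
            simulate_site_counts(cfg, truth, "alpha1", "anoxia", 1)

    def test_knockout_condition_zeroes_the_deleted_isoform(self):
        cfg = SimConfig(
            seed=15,
            condition_scales={"wt": 1.0, "ko1": {"global": 1.0, "alpha1": 0.0}},
        )
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        counts, _ = simulate_site_counts(cfg, truth, "alpha1", "ko1", 1)
        assert np.all(counts == 0)

    def test_zero_depth_gives_empty_track(self):
        cfg = SimConfig(seed=16, depth_per_assay=0)
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        track = simulate_coverage(cfg, truth, "alpha1", "severe", 1)
        assert track.total_mapped_reads == 0
        assert track.total_in_track() == 0


class TestCallPeaksStandin:
    def test_flat_zero_track_has_no_peaks(self):
        track = SignalTrack({}, 1e6)
        assert len(call_peaks_standin(track, min_count=1.0)) == 0

    def test_single_rectangular_pulse_gives_one_spanning_interval(self):
        dense = np.zeros(5000)
        dense[2000:2400] = 10.0
        track = SignalTrack.from_dense({"chr1": dense}, 1e6)
        peaks = call_peaks_standin(track, min_count=5.0, window=1)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (2000, 2400)

    def test_two_pulses_with_subthreshold_gap_stay_separate(self):
        dense = np.zeros(5000)
        dense[1000:1200] = 10.0
        dense[2000:2150] = 8.0
        track = SignalTrack.from_dense({"chr1": dense}, 1e6)
        peaks = call_peaks_standin(track, min_count=5.0, window=1)
        # run-length scan oracle on the raw vector
        above = dense >= 5.0
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(int))
        oracle = list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))
        assert [(p.start, p.end) for p in peaks] == oracle

    def test_summit_is_argmax_of_smoothed_signal(self):
        dense = np.zeros(3000)
        dense[1000:1200] = 5.0
        dense[1100] = 50.0
        track = SignalTrack.from_dense({"chr1": dense}, 1e6)
        peaks = call_peaks_standin(track, min_count=2.0, window=1)
        assert peaks[0].summit_pos == 1100

    def test_invalid_parameters_rejected(self):
        track = SignalTrack({}, 1e6)
        with pytest.raises(ValueError):
            call_peaks_standin(track, min_count=0)
        with pytest.raises(ValueError):
            call_peaks_standin(track, min_count=1.0, window=0)


class TestGenerateExpression:
    def test_noise_free_effect_is_exact(self):
        cfg = SimConfig(seed=17, effect_size=3.0, expression_null_sd=0.0)
        ann = generate_annotation(cfg)
        _, truth = generate_sites(cfg, ann)
        table, truth = generate_expression(cfg, truth, ann)
        merged = table.merge(truth.genes, on="gene_id")
        assert (merged.loc[merged["regulated"], "log2fc"] == 3.0).all()
        assert (merged.loc[~merged["regulated"], "log2fc"] == 0.0).all()

    def test_null_effect_makes_flags_unrecoverable(self):
        cfg = SimConfig(seed=18, effect_size=0.0, expression_null_sd=0.5)
        ann = generate_annotation(cfg)
        _, truth = generate_sites(cfg, ann)
        table, truth = generate_expression(cfg, truth, ann)
        merged = table.merge(truth.genes, on="gene_id")
        reg = merged.loc[merged["regulated"], "log2fc"]
        null = merged.loc[~merged["regulated"], "log2fc"]
        assert abs(reg.mean() - null.mean()) < 3 * merged["log2fc"].std()

    def test_pvalues_in_unit_interval(self):
        cfg = SimConfig(seed=19)
        ann = generate_annotation(cfg)
        _, truth = generate_sites(cfg, ann)
        table, _ = generate_expression(cfg, truth, ann)
        assert ((table["pvalue"] > 0) & (table["pvalue"] <= 1)).all()


class TestDeterminism:
    def test_identical_config_and_seed_give_byte_identical_files(self, tmp_path):
        cfg = SimConfig(
            genome_length=1_000_000, n_genes=30, n_sites_per_isoform=15,
            depth_per_assay=50_000, seed=20,
            condition_scales={"severe": 1.0},
        )
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        write_dataset(cfg, d1, replicates=1)
        write_dataset(cfg, d2, replicates=1)
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_streams_independent_of_added_assays(self):
        cfg = SimConfig(seed=21)
        _, truth = generate_sites(cfg, generate_annotation(cfg))
        a_before, _ = simulate_site_counts(cfg, truth, "alpha1", "severe", 1)
        # drawing another assay's counts must not perturb the first stream
        simulate_site_counts(cfg, truth, "beta", "severe", 1)
        a_after, _ = simulate_site_counts(cfg, truth, "alpha1", "severe", 1)
        assert np.array_equal(a_before, a_after)
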