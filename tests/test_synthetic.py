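"""Synthetic droplet data: generative structure, closed forms, determinism."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from hostquant.synthetic import (
    SimulationConfig,
    StudyDesign,
    simulate_dilution_series,
    simulate_longitudinal_study,
    simulate_preservation_timecourse,
    simulate_spikein_experiment,
    simulate_well,
)


def positive_fraction(well, threshold=3400.0):
    return float(np.mean(well.amplitudes > threshold))


class TestSimulateWell:
    def test_empty_reaction_has_no_positives(self, clean_cfg):
        well = simulate_well(0.0, clean_cfg, seed=4)
        assert positive_fraction(well, clean_cfg.neg_mean + 5 * clean_cfg.neg_sd) == 0.0

    def test_occupancy_matches_closed_form(self, clean_cfg):
        conc = 235.4
        well = simulate_well(conc, clean_cfg, seed=9)
        p = 1.0 - math.exp(-conc * clean_cfg.droplet_volume_nl / 1000.0)  # 0.1813
        n = well.accepted_count
        lo, hi = sps.binom.interval(0.99, n, p)
        assert lo <= positive_fraction(well) * n <= hi

    def test_seed_determinism_is_bit_identical(self):
        cfg = SimulationConfig()
        a = simulate_well(123.0, cfg, seed=42)
        b = simulate_well(123.0, cfg, seed=42)
        assert np.array_equal(a.amplitudes, b.amplitudes)
        c = simulate_well(123.0, cfg, seed=43)
        assert not np.array_equal(a.amplitudes, c.amplitudes)

    def test_accepted_count_tracks_accepted_fraction(self):
        cfg = SimulationConfig(n_droplets_generated=20_000, accepted_fraction=0.75)
        assert simulate_well(10.0, cfg, seed=0).accepted_count == 15_000

    def test_clean_amplitudes_stay_within_clusters(self, clean_cfg):
        well = simulate_well(500.0, clean_cfg, seed=5)
        near_neg = np.abs(well.amplitudes - clean_cfg.neg_mean) <= 5 * clean_cfg.neg_sd
        near_pos = np.abs(well.amplitudes - clean_cfg.pos_mean) <= 5 * clean_cfg.pos_sd
        assert np.all(near_neg | near_pos)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_well(-1.0, SimulationConfig(), seed=0)

    def test_positive_fraction_converges_to_poisson_occupancy(self):
        """1 - exp(-cV) at a million droplets, relative error < 1%."""
        cfg = SimulationConfig(
            n_droplets_generated=1_000_000, accepted_fraction=1.0,
            rain_fraction=0.0, false_positive_rate=0.0,
        )
        conc = 300.0
        well = simulate_well(conc, cfg, seed=17)
        expected = 1.0 - math.exp(-conc * cfg.droplet_volume_nl / 1000.0)
        assert positive_fraction(well) == pytest.approx(expected, rel=0.01)


class TestDilutionSeries:
    def test_default_fixture_mirrors_validated_range(self):
        wells, truth = simulate_dilution_series(120_440.0, seed=0)
        assert len(wells) == 15
        top = truth.theoretical_copies_per_reaction.max()
        bottom = truth.theoretical_copies_per_reaction.min()
        assert top == pytest.approx(120_440.0)
        assert bottom == pytest.approx(193.0, rel=0.01)

    def test_single_level_single_replicate(self):
        wells, truth = simulate_dilution_series(100.0, [1.0], 1, seed=0)
        assert len(wells) == 1
        assert truth.theoretical_copies_per_reaction.iloc[0] == 100.0

    def test_truth_monotone_in_dilution_factor(self):
        _, truth = simulate_dilution_series(50_000.0, [1.0, 2.0, 8.0, 64.0], 1, seed=0)
        assert truth.theoretical_copies_per_reaction.is_monotonic_decreasing

    def test_empty_dilution_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_dilution_series(100.0, [], 3, seed=0)


class TestSpikeInExperiment:
    def test_lossless_recovery_with_no_background(self, clean_cfg):
        """With true recovery 1 and no background, R ~ 100% at every level,
        within the Poisson counting noise of the arm sizes."""
        from hostquant.pipeline import estimate_spike_recovery, quantify_well
        from hostquant import RunConfig

        fx = simulate_spikein_experiment(
            true_recovery=1.0, background_acn=0.0, cfg=clean_cfg, seed=1
        )
        recov = estimate_spike_recovery(fx)
        config = RunConfig()
        for ge, r in recov.items():
            # counting SE of R from the per-well replicate spread of each arm
            spike = [quantify_well(w, config).copies_per_reaction for w in fx.with_spike[ge]]
            alone = [quantify_well(w, config).copies_per_reaction for w in fx.spike_alone[ge]]
            se_rel = math.sqrt(
                np.var(spike, ddof=1) / len(spike) / np.mean(spike) ** 2
                + np.var(alone, ddof=1) / len(alone) / np.mean(alone) ** 2
            )
            tol = max(2.0, 4.0 * 100.0 * se_rel)
            assert r == pytest.approx(100.0, abs=tol)

    def test_zero_recovery_leaves_spike_arm_at_background(self, clean_cfg):
        fx = simulate_spikein_experiment(true_recovery=0.0, cfg=clean_cfg, seed=2)
        truth = fx.truth.set_index("arm").true_copies_per_reaction
        buffer_truth = truth["buffer"]
        for arm, value in truth.items():
            if arm.startswith("spike-"):
                assert value == pytest.approx(buffer_truth)

    def test_arm_truths_follow_recovery_equation(self):
        fx = simulate_spikein_experiment(
            spike_ge_levels=[232_000.0], true_recovery=0.62, background_acn=1_500.0, seed=3
        )
        truth = fx.truth.set_index("arm").true_copies_per_reaction
        spike = truth["alone-232000GE"]
        assert truth["spike-232000GE"] == pytest.approx(1_500.0 + 0.62 * spike)

    def test_out_of_range_recovery_rejected(self):
        with pytest.raises(ValueError):
            simulate_spikein_experiment(true_recovery=1.5)


class TestLongitudinalStudy:
    def test_well_and_sample_counts(self):
        design = StudyDesign(subjects=("a", "b", "c"), timepoints=tuple(range(10)))
        study = simulate_longitudinal_study(design, seed=0)
        sample_wells = [w for w in study.wells if w.sample_id != "NTC"]
        ntc_wells = [w for w in study.wells if w.sample_id == "NTC"]
        assert len(sample_wells) == 3 * 10 * 2
        assert len(ntc_wells) == design.n_ntc_wells
        assert len(study.truth) == 30

    def test_noise_free_replicates_share_occupancy(self, clean_cfg):
        design = StudyDesign(
            subjects=("s",), timepoints=(0,), log_variation_sd=0.0, extraction_cv=0.0
        )
        study = simulate_longitudinal_study(design, clean_cfg, seed=6)
        reps = [w for w in study.wells if w.sample_id != "NTC"]
        assert len(reps) == 2
        conc = study.truth.true_copies_per_ul_reaction.iloc[0]
        p = 1.0 - math.exp(-conc * clean_cfg.droplet_volume_nl / 1000.0)
        for w in reps:
            lo, hi = sps.binom.interval(0.99, w.accepted_count, p)
            assert lo <= positive_fraction(w) * w.accepted_count <= hi

    def test_sample_sheet_round_trips_losslessly(self, tmp_path):
        from hostquant.io import read_sample_sheet, write_sample_sheet

        study = simulate_longitudinal_study(
            StudyDesign(subjects=("x",), timepoints=(0, 1)), seed=0
        )
        path = tmp_path / "sheet.csv"
        write_sample_sheet(study.samples, path)
        assert read_sample_sheet(path) == study.samples

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            simulate_longitudinal_study(StudyDesign(subjects=()), seed=0)


class TestPreservationTimecourse:
    def test_zero_decay_keeps_truth_at_baseline(self):
        study = simulate_preservation_timecourse(
            buffers=["EDTA"], decay_rate_per_hour={"EDTA": 0.0}, seed=0
        )
        values = study.truth.true_copies_per_ul_extract
        assert values.nunique() == 1

    def test_negative_rate_gives_monotone_growth(self):
        study = simulate_preservation_timecourse(
            buffers=["EDTA"], decay_rate_per_hour={"EDTA": -0.01}, seed=0
        )
        assert study.truth.sort_values("time_hours").true_copies_per_ul_extract.is_monotonic_increasing

    def test_decay_closed_form_at_96_hours(self):
        study = simulate_preservation_timecourse(
            buffers=["TEN2"], decay_rate_per_hour={"TEN2": 0.01}, seed=0
        )
        t = study.truth.set_index("time_hours").true_copies_per_ul_extract
        assert t[96.0] / t[0.0] == pytest.approx(math.exp(-0.96))

    def test_single_extraction_buffer_gets_one_well_per_timepoint(self):
        study = simulate_preservation_timecourse(buffers=["OMNI"], seed=0)
        per_sample = {}
        for w in study.wells:
            if w.sample_id != "NTC":
                per_sample[w.sample_id] = per_sample.get(w.sample_id, 0) + 1
        assert set(per_sample.values()) == {1}

    def test_missing_time_zero_rejected(self):
        with pytest.raises(ValueError):
            simulate_preservation_timecourse(timepoints_hours=[4.0, 24.0], seed=0)
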