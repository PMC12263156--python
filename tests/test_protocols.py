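"""Protocol contracts: tables, orderings, drug conditions, reproducibility."""

import numpy as np
import pytest

from navdissect.neuron_model import build_model
from navdissect import protocols as pr
from navdissect.protocols import StimulusProtocol


class TestStimulusProtocol:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol("voodoo")

    def test_nonincreasing_isi_ladder_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol("onboarding_recovery",
                             {"isi_ladder_s": [5.0, 2.0, 15.0]})


class TestBaselineTuner:
    def test_finds_amplitude_in_physiological_range(self, tuned_amp):
        assert 0.1 <= tuned_amp <= 0.6

    def test_tuned_amplitude_gives_target_spikes(self, model, tuned_amp):
        model.find_bias_current(-80.0)
        _, train = pr._first_ap_features(model, tuned_amp)
        assert 4 <= train["spike_count"] <= 6


class TestDensitySweep:
    def test_eleven_rows_full_grid(self, density_sweeps):
        s16, s12 = density_sweeps
        for s in (s16, s12):
            assert len(s) == 11
            assert s.scale.tolist() == pytest.approx(
                np.arange(1.0, -0.01, -0.1).tolist())

    def test_rows_retained_when_no_ap(self, density_sweeps):
        s16, _ = density_sweeps
        row = s16[s16.scale == 0.0].iloc[0]
        assert row.spike_count == 0 and np.isnan(row.threshold)

    def test_full_density_matches_single_baseline(self, model, tuned_amp,
                                                  density_sweeps):
        s16, s12 = density_sweeps
        model.find_bias_current(-80.0)
        feats, _ = pr._first_ap_features(model, tuned_amp)
        assert s16.threshold.iloc[0] == pytest.approx(feats[0].threshold, abs=1e-6)
        assert s16.threshold.iloc[0] == pytest.approx(s12.threshold.iloc[0], abs=1e-9)


class TestCrossoverSweep:
    def test_grid_is_80_rows_without_100_0(self, crossover_table):
        t = crossover_table
        assert len(t) == 80
        assert not ((t.nav12_pct == 100) & (t.nav16_pct == 0)).any()
        assert t.crossover_um.nunique() == 8

    def test_pure_nav16_hyperpolarized_vs_balanced(self, crossover_table):
        """At every crossover position the 0:100 condition has a more
        hyperpolarized threshold than the 50:50 condition."""
        for xc, sub in crossover_table.groupby("crossover_um"):
            thr_0_100 = sub[sub.nav16_pct == 100].threshold.iloc[0]
            thr_50_50 = sub[sub.nav16_pct == 50].threshold.iloc[0]
            assert thr_0_100 < thr_50_50, f"crossover {xc}"


class TestOnboardingRecovery:
    def test_no_drug_recovers_immediately(self, onboarding_results):
        t = onboarding_results["no_drug"]["table"]
        assert abs(t.delta_threshold.iloc[0]) < 0.5

    def test_sr_sr_with_drug_matches_no_drug(self, onboarding_results):
        a = onboarding_results["no_drug"]["summary"]
        b = onboarding_results["sr_sr"]["summary"]
        assert abs(a["delta_threshold"] - b["delta_threshold"]) < 0.5
        assert abs(a["delta_spike_count"] - b["delta_spike_count"]) < 1.0

    def test_nav16_block_depolarizes_threshold(self, onboarding_results):
        s = onboarding_results["block16"]["summary"]
        assert s["delta_threshold"] > 0.2

    def test_block_selectivity_in_model(self, onboarding_results):
        t = onboarding_results["block12"]["table"]
        assert t.blocked_nav12.iloc[0] > 0.85
        assert t.blocked_nav16.iloc[0] < 0.05


class TestExcitabilityParadox:
    def test_nav12_block_raises_output_with_depolarized_ahp(self, onboarding_results):
        s = onboarding_results["block12"]["summary"]
        assert s["delta_spike_count"] >= 0.0
        assert s["delta_last_ahp"] > 0.0
        assert abs(s["delta_threshold"]) < 1.0

    def test_nav16_block_lowers_output(self, onboarding_results):
        s = onboarding_results["block16"]["summary"]
        assert s["delta_spike_count"] <= 0.0


class TestNucleatedPatch:
    def test_baseline_normalization_and_recovery(self, model):
        df = pr.run_nucleated_patch(model, 0.0)
        base = df[df.phase == "baseline"]
        assert base.normalized_peak_current.mean() == pytest.approx(1.0, abs=1e-6)
        rec = df[df.phase == "recovery"]
        # drug-free: near-baseline recovery within 5 s of returning to -80
        early = rec[rec.pulse_time_s <= rec.pulse_time_s.min() + 5.0]
        assert early.normalized_peak_current.max() > 0.9

    def test_wildtype_drug_shows_no_recovery_within_25s(self, model):
        df = pr.run_nucleated_patch(model, 200.0, "YW", "YW")
        rec = df[df.phase == "recovery"]
        assert rec.normalized_peak_current.max() < 0.75

    def test_sr_sr_drug_recovers_like_control(self, model):
        df = pr.run_nucleated_patch(model, 200.0, "SR", "SR")
        rec = df[df.phase == "recovery"]
        assert rec.normalized_peak_current.iloc[1] > 0.9


class TestLongTrain:
    def test_first_bin_delta_is_zero_ish(self, long_train_results):
        """Bin 1 overlaps the normalization window; its delta is small."""
        t = long_train_results["no_drug"]
        assert abs(t.delta_threshold.iloc[0]) < 1.0

    def test_no_drug_firing_is_steady_after_first_second(self, long_train_results):
        t = long_train_results["no_drug"]
        late = t[t.bin_s >= 1.0]
        assert np.nanmax(np.abs(late.delta_inst_freq)) < 2.0
        assert np.nanmax(np.abs(late.delta_threshold)) < 1.0

    def test_sr_sr_matches_no_drug(self, long_train_results):
        a = long_train_results["no_drug"]
        b = long_train_results["sr_sr"]
        d = np.nanmax(np.abs(a.delta_threshold - b.delta_threshold))
        assert d < 0.5

    def test_wildtype_drug_drifts(self, long_train_results):
        """Use-dependent onboarding: threshold keeps depolarizing and peak
        dV/dt keeps falling across the 10 s train, unlike the stable
        drug-free control."""
        t = long_train_results["wt_drug"]
        ctrl = long_train_results["no_drug"]
        assert t.delta_threshold.iloc[-1] > ctrl.delta_threshold.iloc[-1] + 0.3
        assert t.delta_peak_dvdt.iloc[-1] < ctrl.delta_peak_dvdt.iloc[-1] - 50.0
        # drift is progressive, not a step
        assert t.delta_threshold.is_monotonic_increasing

    def test_zero_amplitude_rejected(self, model):
        with pytest.raises(ValueError):
            pr.run_long_train(model, 0.0, 10.0)


@pytest.fixture(scope="module")
def short_runs():
    """Two identical-seed seizure runs plus one other genotype, with
    shortened segments (the qualitative structure is preserved at 20 s)."""
    out = {}
    m = build_model()
    out["a"] = pr.run_seizure_protocol(m, 11, segment_s=20.0,
                                       n_recovery_segments=1)
    m2 = build_model()
    out["b"] = pr.run_seizure_protocol(m2, 11, segment_s=20.0,
                                       n_recovery_segments=1)
    m3 = build_model()
    out["blk16"] = pr.run_seizure_protocol(m3, 11, 200.0, "SR", "YW",
                                           segment_s=20.0,
                                           n_recovery_segments=1)
    return out


class TestSeizureProtocol:
    def test_same_seed_is_bit_identical(self, short_runs):
        assert short_runs["a"].equals(short_runs["b"])

    def test_seizure_raises_firing_in_both_genotypes(self, short_runs):
        for key in ("a", "blk16"):
            df = short_runs[key]
            assert (df[df.phase == "seizure"].rate_hz.mean()
                    > df[df.phase == "baseline"].rate_hz.mean())

    def test_control_threshold_returns_toward_baseline(self, short_runs):
        df = short_runs["a"]
        thr_base = np.nanmean(df[df.phase == "baseline"].threshold)
        thr_seiz = np.nanmean(df[df.phase == "seizure"].threshold)
        thr_rec = np.nanmean(df[df.phase == "recovery"].threshold)
        assert thr_seiz > thr_base
        assert abs(thr_rec - thr_base) < 0.5 * abs(thr_seiz - thr_base)
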