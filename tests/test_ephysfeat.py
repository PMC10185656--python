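"""Patch-clamp QC, spike detection, AP features and pattern classes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aisquant import ephysfeat as ef
from aisquant import synthgen as sg


def _sweepset(rs_start=6.0, rs_end=6.3, **kw):
    return ef.SweepSet(
        mode="current_clamp", fs=1000.0, sweeps=np.full((1, 100), -70.0),
        command_amplitudes=[10.0], rs_start=rs_start, rs_end=rs_end, **kw
    )


class TestQcGate:
    @pytest.mark.parametrize("rs0,rs1,rmp,expect_pass,expect_reason", [
        (10.0, 10.0, -60.0, True, None),       # Rs exactly at the bound
        (10.1, 10.1, -60.0, False, "rs"),      # Rs just over
        (12.0, 12.0, -60.0, False, "rs"),
        (8.0, 9.6, -60.0, True, None),         # drift exactly 20%
        (8.0, 9.68, -60.0, False, "delta_rs"),  # drift 21%
        (8.0, 10.0, -60.0, False, "delta_rs"),  # drift 25%
        (6.0, 6.6, -60.0, True, None),
        (8.0, 8.0, -35.1, True, None),         # just hyperpolarised enough
        (8.0, 8.0, -35.0, False, "rmp"),       # not more hyperpolarised
        (8.0, 8.0, -20.0, False, "rmp"),
    ])
    def test_truth_table(self, rs0, rs1, rmp, expect_pass, expect_reason):
        ok, reasons = ef.qc_gate(_sweepset(rs0, rs1), rmp=rmp)
        assert ok is expect_pass
        if expect_reason:
            assert expect_reason in reasons

    def test_missing_metadata_fails_with_reason(self):
        ss = ef.SweepSet(
            mode="current_clamp", fs=1000.0, sweeps=np.zeros((1, 10)),
            command_amplitudes=[10.0],
        )
        ok, reasons = ef.qc_gate(ss, rmp=None)
        assert not ok
        assert any(r.startswith("metadata_missing") for r in reasons)

    @settings(deadline=None, max_examples=30)
    @given(
        rs0=st.floats(1.0, 15.0), drift=st.floats(0.0, 0.5),
        rmp=st.floats(-90.0, -20.0), worsen=st.sampled_from(["rs", "drift", "rmp"]),
        delta=st.floats(0.1, 5.0),
    )
    def test_monotone_worsening_never_flips_fail_to_pass(
        self, rs0, drift, rmp, worsen, delta
    ):
        base = ef.qc_gate(_sweepset(rs0, rs0 * (1 + drift)), rmp=rmp)[0]
        if worsen == "rs":
            worse = ef.qc_gate(
                _sweepset(rs0 + delta, (rs0 + delta) * (1 + drift)), rmp=rmp
            )[0]
        elif worsen == "drift":
            worse = ef.qc_gate(
                _sweepset(rs0, rs0 * (1 + drift + delta / 5)), rmp=rmp
            )[0]
        else:
            worse = ef.qc_gate(
                _sweepset(rs0, rs0 * (1 + drift)), rmp=rmp + delta
            )[0]
        assert not (worse and not base)


class TestComputeRmp:
    def test_junction_subtraction(self):
        sig = np.full(31_000, -55.0)
        assert ef.compute_rmp(sig, 1000.0, 15.0) == -70.0

    def test_zero_junction_identity(self):
        sig = np.full(31_000, -60.0)
        assert ef.compute_rmp(sig, 1000.0, 0.0) == -60.0

    def test_zero_mean_noise_averages_out(self):
        t = np.arange(40_000) / 1000.0
        sig = -60.0 + 3.0 * np.sin(2 * np.pi * t)  # integer cycles
        assert ef.compute_rmp(sig, 1000.0, 15.0) == pytest.approx(-75.0, abs=1e-6)

    def test_short_window_raises(self):
        with pytest.raises(ValueError, match="30"):
            ef.compute_rmp(np.full(1000, -60.0), 1000.0)


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        assert len(ef.detect_spikes(np.full(5000, -70.0), 50_000.0)) == 0

    def test_subthreshold_depolarisation_empty(self):
        fs = 50_000.0
        t = np.arange(int(fs)) / fs
        v = -70.0 + 40.0 * (1 - np.exp(-t / 0.02))  # peaks at -30 mV
        assert len(ef.detect_spikes(v, fs)) == 0

    def test_template_spikes_recovered_at_known_times(self):
        gt = sg.generate_ephys_cell(sg.EphysParams(), "adaptive", 50)
        ss = sg.generate_sweeps(gt, noise_sd_mv=0.0)
        for sweep, truth in zip(ss.sweeps, gt.spike_times_per_sweep):
            times = ef.detect_spikes(sweep, ss.fs, ss.step_onset)
            assert len(times) == len(truth)
            if truth:
                assert np.abs(np.asarray(times) - np.asarray(truth)).max() \
                    <= 0.2e-3


class TestClassifyPattern:
    @pytest.mark.parametrize("spikes,expected", [
        ([[], [], []], "none"),
        ([[], [0.2], [0.15]], "one_spike"),
        ([[], [0.1, 0.15, 0.25, 0.45]], "adaptive"),
        ([[], [0.05, 0.25, 0.45, 0.65, 0.85]], "repetitive"),
    ])
    def test_direct_cases(self, spikes, expected):
        assert ef.classify_pattern(spikes, 1.0) == expected

    def test_generator_regimes_noiseless_all_correct(self):
        for regime in sg.REGIMES:
            for seed in range(70, 76):
                gt = sg.generate_ephys_cell(sg.EphysParams(), regime, seed)
                ss = sg.generate_sweeps(gt, noise_sd_mv=0.0)
                spikes = [
                    ef.detect_spikes(sw, ss.fs, ss.step_onset)
                    for sw in ss.sweeps
                ]
                assert ef.classify_pattern(spikes, ss.step_duration) == regime


class TestApFeatures:
    def test_rheobase_is_first_spiking_amplitude(self):
        gt = sg.generate_ephys_cell(sg.EphysParams(), "one_spike", 42)
        ss = sg.generate_sweeps(gt, noise_sd_mv=0.0)
        rec = ef.ap_features(ss)
        assert rec.rheobase == gt.true_rheobase

    def test_features_match_template_closed_forms(self):
        """Threshold/amplitude/half-width against the analytic template."""
        par = sg.EphysParams()
        tpl = par.template
        gt = sg.generate_ephys_cell(par, "one_spike", 42)
        ss = sg.generate_sweeps(gt, noise_sd_mv=0.0, params=par)
        rec = ef.ap_features(ss)
        counts = [len(s) for s in gt.spike_times_per_sweep]
        i0 = next(i for i, c in enumerate(counts) if c > 0)
        dv = par.input_resistance_gohm * ss.command_amplitudes[i0]
        onset_t = gt.spike_times_per_sweep[i0][0] - tpl.t_peak
        plateau = gt.true_rmp + dv * (1 - math.exp(-onset_t / par.tau_membrane))
        sample_ms = 1000.0 / ss.fs
        assert rec.peak_amplitude == pytest.approx(
            plateau + tpl.amplitude, abs=0.05
        )
        assert rec.threshold == pytest.approx(
            plateau + tpl.threshold_offset(), abs=0.3
        )
        assert rec.amplitude == pytest.approx(
            tpl.amplitude - tpl.threshold_offset(), abs=0.3
        )
        assert rec.half_width == pytest.approx(
            tpl.half_width() * 1000.0, abs=sample_ms
        )
        assert rec.delay == pytest.approx(
            (onset_t + tpl.onset_crossing()) * 1000.0, abs=2 * sample_ms
        )

    def test_max_frequency_is_max_count_over_duration(self):
        gt = sg.generate_ephys_cell(sg.EphysParams(), "repetitive", 13)
        ss = sg.generate_sweeps(gt, noise_sd_mv=0.0)
        rec = ef.ap_features(ss)
        expected = max(len(s) for s in gt.spike_times_per_sweep)
        assert rec.max_frequency == expected / ss.step_duration

    def test_no_spikes_gives_pattern_none_without_error(self):
        gt = sg.generate_ephys_cell(sg.EphysParams(), "none", 14)
        ss = sg.generate_sweeps(gt, noise_sd_mv=0.0)
        rec = ef.ap_features(ss)
        assert rec.pattern == "none"
        assert math.isnan(rec.threshold)
        assert math.isnan(rec.rheobase)


class TestVcFeatures:
    def test_density_worked_example(self):
        fs = 50_000.0
        n = int(0.24 * fs)
        sweep = np.zeros(n)
        i0 = int(0.02 * fs)
        sweep[i0 + 5] = -500.0  # Na transient
        sweep[int(0.2 * fs):] = 0.0
        ss = ef.SweepSet(
            mode="voltage_clamp", fs=fs, sweeps=sweep[None],
            command_amplitudes=[20.0], cm=50.0,
            step_duration=0.2, step_onset=0.02,
        )
        rec = ef.vc_features(ss)
        assert rec.na_peak_density == pytest.approx(-10.0)

    def test_generator_ratio_recovered(self):
        par = sg.EphysParams(
            na_peak=(-800.0, -800.0), k_low=(400.0, 400.0), cm=(40.0, 40.0)
        )
        gt = sg.generate_ephys_cell(par, "none", 15)
        ss = sg.generate_vc_sweeps(gt, noise_sd_pa=0.0)
        rec = ef.vc_features(ss)
        assert rec.na_peak_density == pytest.approx(-20.0, rel=0.02)
        assert rec.k_low_density == pytest.approx(10.0, rel=0.02)
        assert rec.na_k_ratio == pytest.approx(2.0, rel=0.03)

    def test_zero_k_current_reason_coded(self):
        ss = ef.SweepSet(
            mode="voltage_clamp", fs=1000.0, sweeps=np.zeros((1, 400)),
            command_amplitudes=[20.0], cm=40.0,
            step_duration=0.2, step_onset=0.02,
        )
        rec = ef.vc_features(ss)
        assert math.isnan(rec.na_k_ratio)
        assert rec.ratio_reason == "zero_k_current"

    def test_nonpositive_capacitance_raises(self):
        ss = ef.SweepSet(
            mode="voltage_clamp", fs=1000.0, sweeps=np.zeros((1, 400)),
            command_amplitudes=[20.0], cm=0.0,
        )
        with pytest.raises(ValueError, match="capacitance"):
            ef.vc_features(ss)


class TestSweepSetValidation:
    def test_non_increasing_amplitudes_rejected(self):
        with pytest.raises(ef.SweepFormatError):
            ef.SweepSet(
                mode="current_clamp", fs=1000.0, sweeps=np.zeros((2, 10)),
                command_amplitudes=[10.0, 10.0],
            )

    def test_missing_sidecar_raises(self, tmp_path):
        (tmp_path / "x.csv").write_text("time_s,sweep_00\n0,1\n")
        with pytest.raises(ef.SweepFormatError, match="sidecar"):
            ef.read_sweepset_csv(tmp_path / "x.csv")


def test_analyze_cell_end_to_end():
    par = sg.EphysParams()
    gt = sg.generate_ephys_cell(par, "adaptive", 16)
    ss = sg.generate_sweeps(gt)
    baseline = sg.generate_baseline(gt)
    rec = ef.analyze_cell(ss, baseline=baseline, baseline_fs=5000.0)
    assert rec.pattern == "adaptive"
    assert rec.qc_pass
    assert rec.rmp == pytest.approx(gt.true_rmp - 15.0, abs=0.1)
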