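"""Slice-stage tests: QC, passive properties, spike detection and
kinetics, pharmacological subtraction, synaptic events, and the
excitability phenotype of the synthetic membrane model."""

import math

import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import mannwhitneyu

from loomlab import ephys_slice as es
from loomlab.synthetic.patch import (
    CURRENT_STEPS_PA,
    MUTANT_CELL,
    PatchSimParams,
    WT_CELL,
    dtx_pair,
    gen_patch_cell,
)


class TestQC:
    def test_stable_recording_passes(self):
        ok, reasons = es.qc_recording([15.0, 16.0, 17.0], [-30.0, -32.0])
        assert ok and not reasons

    def test_high_access_resistance_fails(self):
        ok, reasons = es.qc_recording([21.0], [-30.0])
        assert not ok and "access resistance" in reasons[0]

    def test_access_change_ratio_fails(self):
        ok, reasons = es.qc_recording([15.0, 19.0], [-30.0])  # +26.7%
        assert not ok

    def test_holding_current_change_fails(self):
        ok, _ = es.qc_recording([15.0, 15.5], [-30.0, -40.0])  # +33%
        assert not ok

    def test_missing_series_unverifiable(self):
        ok, reasons = es.qc_recording(None, None)
        assert not ok and "unverifiable" in reasons[0]


class TestPassiveProperties:
    def test_reference_cell_tau_equals_rc(self, quiet_cell):
        props = es.passive_properties(quiet_cell)
        assert abs(props.r_in_gohm - 1.0) < 0.02
        assert abs(props.tau_ms - 50.0) < 2.0
        assert abs(props.c_m_pf - 50.0) < 2.0
        assert abs(props.rmp_mv + 70.0) < 0.5
        assert props.rheobase_pa == 20.0

    def test_cm_is_tau_over_rin(self, quiet_cell):
        props = es.passive_properties(quiet_cell)
        assert np.isclose(props.c_m_pf, props.tau_ms / props.r_in_gohm, rtol=1e-9)

    def test_random_cell_recovery_within_5_percent(self):
        rng = np.random.default_rng(0)
        for i in range(5):
            p = PatchSimParams(
                leak_ns=rng.uniform(0.6, 1.5),
                capacitance_pf=rng.uniform(35, 65),
                g_kv_ns=rng.choice([0.0, 3.0]),
                seed=10 + i,
            )
            ss = gen_patch_cell(p, "current_steps")
            props = es.passive_properties(ss)
            assert abs(props.r_in_gohm / ss.truth["r_in_gohm"] - 1) < 0.05
            assert abs(props.tau_ms / ss.truth["tau_ms"] - 1) < 0.05
            assert abs(props.c_m_pf / ss.truth["c_m_pf"] - 1) < 0.05


class TestSpikeDetection:
    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 1, 1e-4)
        times, _ = es.detect_action_potentials(t, np.full(t.size, -70.0))
        assert times.size == 0

    def test_noiseless_count_matches_truth(self, quiet_cell):
        for j in (3, 8, 14, 22):
            detected, _ = es.detect_action_potentials(
                quiet_cell.times, quiet_cell.sweeps[j]
            )
            assert detected.size == len(quiet_cell.truth["spike_times"][j])

    def test_high_gkv_cell_fires_less_at_120pa(self, quiet_cell):
        p = replace(MUTANT_CELL, noise_sd=0.0, seed=1)
        cc = gen_patch_cell(p, "current_steps")
        j = int(np.flatnonzero(CURRENT_STEPS_PA == 120.0)[0])
        n_wt, _ = es.detect_action_potentials(quiet_cell.times, quiet_cell.sweeps[j])
        n_mut, _ = es.detect_action_potentials(cc.times, cc.sweeps[j])
        assert n_mut.size < n_wt.size

    def test_low_sampling_rejected(self):
        t = np.arange(0, 1, 1e-3)
        with pytest.raises(ValueError):
            es.detect_action_potentials(t, np.zeros(t.size))


class TestFICurve:
    def test_sub_rheobase_steps_silent(self, quiet_cell):
        fi = es.fi_curve(quiet_cell)
        assert (fi["n_spikes"][fi["current_pa"] < 20.0] == 0).all()

    def test_noiseless_fi_monotone(self, quiet_cell):
        fi = es.fi_curve(quiet_cell)
        assert (np.diff(fi["n_spikes"]) >= 0).all()

    def test_rheobase_is_first_nonzero_step(self, quiet_cell):
        fi = es.fi_curve(quiet_cell)
        props = es.passive_properties(quiet_cell)
        first = fi["current_pa"][np.flatnonzero(fi["n_spikes"])[0]]
        assert props.rheobase_pa == first

    def test_genotype_pairs_diverge_only_at_high_currents(self):
        """Pairs differing only in g_kv: indistinguishable at <= 50 pA,
        separated at >= 120 pA after Bonferroni correction across steps
        (the multiple-comparison design used for F-I analyses)."""
        def cohort(preset, seed0, n=8):
            return np.array([
                es.fi_curve(
                    gen_patch_cell(replace(preset, seed=seed0 + i), "current_steps")
                )["n_spikes"]
                for i in range(n)
            ])

        wt = cohort(WT_CELL, 500)
        mut = cohort(MUTANT_CELL, 600)
        steps = CURRENT_STEPS_PA
        p_corr = []
        for i in range(steps.size):
            a, b = wt[:, i], mut[:, i]
            if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
                p = 1.0
            else:
                p = mannwhitneyu(a, b).pvalue
            p_corr.append(min(p * steps.size, 1.0))
        p_corr = np.asarray(p_corr)
        assert (p_corr[steps <= 50.0] >= 0.05).all()
        assert (p_corr[steps >= 120.0] < 0.05).all()


class TestAPKinetics:
    def test_triangular_spike_geometry(self):
        # symmetric triangular spike: width at half-peak = half the base
        fs = 50_000.0
        t = np.arange(0, 0.05, 1 / fs)
        v = np.full(t.size, -60.0)
        base_ms = 2.0
        i0 = 1000
        n_half = int(base_ms / 2 * 1e-3 * fs)
        up = np.linspace(-60.0, 40.0, n_half)
        v[i0 : i0 + n_half] = up
        v[i0 + n_half : i0 + 2 * n_half] = up[::-1]
        kin = es.ap_kinetics(t, v)
        assert kin.v_max_mv[0] == 40.0
        # dV/dt crosses 20 V/s immediately on the linear rise (slope 1e5
        # mV/s = 100 V/s), so threshold ~ base and width ~ base_ms/2
        assert abs(kin.width_ms[0] - base_ms / 2) < 0.15

    def test_peak_value_convention(self, quiet_cell):
        fi = es.fi_curve(quiet_cell)
        j = int(np.flatnonzero(fi["n_spikes"])[0])
        kin = es.ap_kinetics(quiet_cell.times, quiet_cell.sweeps[j])
        assert (kin.v_max_mv > 20.0).all()  # absolute peak, not amplitude
        assert (kin.threshold_mv < -20.0).all()
        assert (kin.width_ms > 0).all()
        assert (kin.ahp_mv > 0).all()

    def test_upstroke_dvdt_decreases_with_gkv(self):
        """The K+ conductance opposes the spike upstroke once its gate has
        charged, so the mean per-spike peak dV/dt at a strong step falls
        strictly with g_kv in the noiseless model."""
        j = int(np.flatnonzero(CURRENT_STEPS_PA == 120.0)[0])
        peaks = []
        for g in (0.0, 500.0, 1500.0):
            p = replace(MUTANT_CELL, g_kv_ns=g, noise_sd=0.0, seed=2)
            cc = gen_patch_cell(p, "current_steps")
            peaks.append(es.ap_kinetics(cc.times, cc.sweeps[j]).mean_peak_dvdt)
        assert peaks[0] > peaks[1] > peaks[2]

    def test_no_spikes_raises(self):
        t = np.arange(0, 0.1, 1e-4)
        with pytest.raises(ValueError):
            es.ap_kinetics(t, np.full(t.size, -70.0))


class TestDTXSubtraction:
    def test_identical_inputs_zero(self):
        p = PatchSimParams(g_kv_ns=4.0, seed=3)
        ss = gen_patch_cell(p, "voltage_steps")
        res = es.dtx_sensitive_current([ss], [ss], c_m_pf=50.0)
        assert np.all(res.subtracted == 0.0)

    def test_zero_conductance_identically_zero(self):
        base, post = dtx_pair(PatchSimParams(g_kv_ns=0.0, seed=4))
        res = es.dtx_sensitive_current([base], [post], c_m_pf=50.0)
        assert np.all(res.subtracted == 0.0)

    def test_boltzmann_iv_recovered_noiseless(self):
        p = PatchSimParams(g_kv_ns=4.0, seed=5)
        base, post = dtx_pair(p)
        res = es.dtx_sensitive_current([base], [post], c_m_pf=p.capacitance_pf)
        truth = base.truth["kv_iv_deflection"]
        mask = np.abs(truth) > 1.0
        rel = np.abs(res.max_deflection_pa - truth)[mask] / np.abs(truth)[mask]
        assert rel.max() < 0.05
        assert np.allclose(res.density_pa_pf, res.max_deflection_pa / 50.0)

    def test_linearity_in_conductance(self):
        b1, p1 = dtx_pair(PatchSimParams(g_kv_ns=4.0, seed=6))
        b2, p2 = dtx_pair(PatchSimParams(g_kv_ns=8.0, seed=6))
        r1 = es.dtx_sensitive_current([b1], [p1], 50.0)
        r2 = es.dtx_sensitive_current([b2], [p2], 50.0)
        assert np.allclose(r2.max_deflection_pa, 2.0 * r1.max_deflection_pa)

    def test_protocol_mismatch_rejected(self):
        b, p = dtx_pair(PatchSimParams(g_kv_ns=4.0, seed=7))
        b.commands = b.commands[:-1]
        with pytest.raises(ValueError):
            es.dtx_sensitive_current([b], [p], 50.0)


class TestSynapticEvents:
    def test_noise_only_false_positive_rate(self):
        p = PatchSimParams(epsc_rate_hz=1e-4, noise_sd=1.5, seed=8)
        gp = gen_patch_cell(p, "gap_free", dt_ms=0.1)
        ev = es.detect_sepscs(gp.times, gp.sweeps[0])
        assert ev.frequency_hz < 0.1

    def test_two_hz_train_recovered(self):
        p = PatchSimParams(epsc_rate_hz=2.0, noise_sd=1.5, seed=9)
        gp = gen_patch_cell(p, "gap_free", dt_ms=0.1)
        ev = es.detect_sepscs(gp.times, gp.sweeps[0])
        n_true = len(gp.truth["event_times"])
        assert abs(len(ev.times_s) - n_true) <= 2 * math.sqrt(n_true)

    def test_amplitudes_within_10_percent_at_high_snr(self):
        p = PatchSimParams(epsc_rate_hz=1.0, epsc_amp_pa=40.0, noise_sd=1.0,
                           seed=10)
        gp = gen_patch_cell(p, "gap_free", dt_ms=0.1)
        ev = es.detect_sepscs(gp.times, gp.sweeps[0])
        true_t = gp.truth["event_times"]
        true_a = gp.truth["event_amps"]
        matched = []
        for t_det, a_det in zip(ev.times_s, ev.amplitudes_pa):
            k = int(np.argmin(np.abs(true_t - t_det)))
            if abs(true_t[k] - t_det) < 0.01:
                matched.append(abs(a_det / true_a[k] - 1.0))
        assert len(matched) > 0.8 * len(true_t)
        assert np.median(matched) < 0.10


class TestEPSCTrain:
    def _train_trace(self, amps, fs=10_000.0):
        t = np.arange(0, 1.5, 1 / fs)
        x = np.zeros(t.size)
        pulses = 0.2 + np.arange(10) * 0.1
        for p, a in zip(pulses, amps):
            m = (t >= p + 0.002) & (t < p + 0.012)
            x[m] = -a
        return t, x, pulses

    def test_identical_responses_all_relative_one(self):
        t, x, pulses = self._train_trace([100.0] * 10)
        out = es.epsc_train_analysis(t, x, pulses)
        assert np.allclose(out["relative_amplitude"], 1.0)

    def test_geometric_depression(self):
        amps = [100.0 * 0.9**k for k in range(10)]
        t, x, pulses = self._train_trace(amps)
        out = es.epsc_train_analysis(t, x, pulses)
        assert np.isclose(out["relative_amplitude"][9], 0.9**9, rtol=1e-6)
        assert out["relative_amplitude"][0] == 1.0

    def test_overlapping_windows_rejected(self):
        t, x, pulses = self._train_trace([100.0] * 10)
        with pytest.raises(ValueError):
            es.epsc_train_analysis(t, x, pulses, window_s=0.2)


class TestBaselineClassification:
    def test_bimodal_cohort_split(self):
        labels = es.classify_baseline_activity(np.array([120.0, 123.0, 1.0, 0.9]))
        assert list(labels) == [
            "putative_inhibitory", "putative_inhibitory",
            "putative_excitatory", "putative_excitatory",
        ]

    def test_all_silent_low_class(self):
        with pytest.warns(UserWarning):
            labels = es.classify_baseline_activity(np.zeros(6))
        assert (labels == "putative_excitatory").all()

    def test_guard_threshold_keeps_tight_cohort_single(self):
        with pytest.warns(UserWarning):
            labels = es.classify_baseline_activity(np.array([1.0, 2.0, 3.0, 4.0]))
        assert (labels == "putative_excitatory").all()

    def test_synthetic_bimodal_exact(self):
        rng = np.random.default_rng(1)
        hi = rng.normal(120, 10, 6)
        lo = rng.normal(1.0, 0.3, 10)
        labels = es.classify_baseline_activity(np.concatenate([hi, lo]))
        assert (labels[:6] == "putative_inhibitory").all()
        assert (labels[6:] == "putative_excitatory").all()
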