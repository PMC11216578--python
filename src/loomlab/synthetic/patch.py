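"""Synthetic whole-cell recordings with a tunable DTX-sensitive K+ current.

The membrane model is an exponential integrate-and-fire neuron plus one
non-inactivating, Boltzmann-gated K+ conductance (the dendrotoxin-sensitive
component).  The regenerative exponential term is capped so the spike
upstroke has a finite, physiological peak dV/dt, and a fast fixed
repolarising conductance produces a complete waveform (overshoot, downswing
and after-hyperpolarisation) so spike-kinetics analyses have something real
to measure.  In this noiseless model the peak dV/dt decreases strictly with
the K+ conductance, mirroring the slowed spike dynamics that motivate the
pharmacological subtraction analysis.

Voltage-clamp sweeps return the ionic current at the clamped potential, so
subtracting a zero-conductance ("post-drug") set from a baseline set
recovers the Boltzmann-gated I–V curve exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "PatchSimParams",
    "SweepSet",
    "gen_patch_cell",
    "CURRENT_STEPS_PA",
    "VOLTAGE_STEPS_MV",
]

#: standard protocols: current steps −20..200 pA in 10 pA for 1 s;
#: voltage steps −80..50 mV in 10 mV from a −60 mV hold
CURRENT_STEPS_PA = np.arange(-20.0, 201.0, 10.0)
VOLTAGE_STEPS_MV = np.arange(-80.0, 51.0, 10.0)


@dataclass(frozen=True)
class PatchSimParams:
    """Ground-truth biophysical parameters of one synthetic cell."""

    leak_ns: float = 1.0  # leak conductance, nS (R_in ~ 1/leak GΩ)
    e_leak_mv: float = -70.0
    capacitance_pf: float = 50.0
    threshold_mv: float = -50.0  # EIF soft threshold V_T
    delta_t_mv: float = 3.0  # EIF sharpness
    reset_mv: float = -65.0
    refractory_ms: float = 2.0
    g_kv_ns: float = 0.0  # DTX-sensitive K+ conductance
    kv_half_mv: float = -25.0
    kv_slope_mv: float = 4.0
    kv_tau_ms: float = 20.0  # first-order activation time constant
    kv_exponent: int = 2  # gate cooperativity (conductance ~ n^exponent)
    e_k_mv: float = -90.0
    epsc_rate_hz: float = 2.0
    epsc_amp_pa: float = 25.0
    epsc_rise_ms: float = 1.5
    epsc_decay_ms: float = 10.0
    noise_sd: float = 0.0  # current noise, pA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")
        if self.g_kv_ns < 0:
            raise ValueError("g_kv must be >= 0")
        if self.epsc_decay_ms <= self.epsc_rise_ms:
            raise ValueError("epsc_decay must exceed epsc_rise")

    def kv_activation(self, v_mv) -> np.ndarray:
        """Steady-state Boltzmann activation of the K+ conductance."""
        v = np.asarray(v_mv, float)
        return 1.0 / (1.0 + np.exp(-(v - self.kv_half_mv) / self.kv_slope_mv))

    def kv_iv(self, v_mv) -> np.ndarray:
        """Ground-truth DTX-sensitive current (pA) at clamped potentials."""
        v = np.asarray(v_mv, float)
        n = self.kv_activation(v) ** self.kv_exponent
        return self.g_kv_ns * n * (v - self.e_k_mv)

    def _membrane_current(self, v: float, i_inj: float) -> float:
        arg = min((v - self.threshold_mv) / self.delta_t_mv, _EXP_CAP)
        i_exp = self.leak_ns * self.delta_t_mv * math.exp(arg)
        return (
            -self.leak_ns * (v - self.e_leak_mv)
            + i_exp
            - float(self.kv_iv(v))
            + i_inj
        )

    def steady_state_v(self, i_inj: float) -> float:
        """Subthreshold steady-state potential for an injected current (pA)."""
        lo, hi = -140.0, self.threshold_mv - 1.0
        if self._membrane_current(lo, i_inj) * self._membrane_current(hi, i_inj) > 0:
            return math.nan  # no subthreshold fixed point (suprathreshold I)
        return float(brentq(self._membrane_current, lo, hi, args=(i_inj,)))

    def passive_truth(self) -> dict:
        """Small-signal ground truth matching the measurement definitions.

        The true input resistance is the slope of the steady-state V–I
        relation over the hyperpolarising steps (−20, −10 pA vs rest), the
        true membrane time constant is R_in · C_m, and the RMP is the
        zero-current fixed point.  These include the subthreshold
        contribution of the K+ conductance.
        """
        rmp = self.steady_state_v(0.0)
        currents = np.array([-20.0, -10.0, 0.0])
        volts = np.array([self.steady_state_v(i) for i in currents])
        slope = float(np.polyfit(currents, volts, 1)[0])  # mV/pA = GΩ
        return {
            "rmp_mv": rmp,
            "r_in_gohm": slope,
            "tau_ms": slope * self.capacitance_pf,  # GΩ·pF = ms
            "c_m_pf": self.capacitance_pf,
        }


@dataclass
class SweepSet:
    """Ordered sweeps sharing one time base, with protocol metadata."""

    mode: str  # current_clamp | voltage_clamp | gap_free
    times: np.ndarray  # s
    sweeps: np.ndarray  # (n_sweeps, n_samples): mV (CC) or pA (VC/gap-free)
    commands: np.ndarray  # step amplitudes: pA (CC) or mV (VC)
    sampling_hz: float
    step_start_s: float = 0.2
    step_dur_s: float = 1.0
    hold_mv: float = -60.0
    truth: dict | None = None


#: genotype-like excitability presets.  The wild-type-like cell has no
#: DTX-sensitive conductance; the mutant-like cell carries a strongly
#: cooperative (cubic-gate) K+ conductance whose spike-driven activation
#: suppresses firing only at large current injections, leaving the
#: rheobase and low-current F-I region intact.
WT_CELL = PatchSimParams(noise_sd=40.0)
MUTANT_CELL = replace(WT_CELL, g_kv_ns=1500.0, kv_exponent=3)

_PHASE_SUB, _PHASE_REPOL = 0, 1
_EXP_CAP = 8.0  # cap on the EIF exponential argument
_V_PEAK_ON = 25.0  # mV: switch to repolarisation above this
_G_REPOL = 80.0  # nS: fast repolarising conductance


@njit(cache=False)
def _integrate_cc(
    i_inj, dt_ms, c_pf, g_l, e_l, v_t, d_t, v_reset, refr_ms,
    g_kv, v_half, k_slope, kv_tau, kv_exp, e_k, noise,
):  # pragma: no cover - numba kernel
    n = i_inj.size
    v = np.empty(n)
    vv = e_l
    nn = 1.0 / (1.0 + math.exp(-(vv - v_half) / k_slope))
    phase = _PHASE_SUB
    refr_left = 0.0
    spike_times = []
    for i in range(n):
        n_inf = 1.0 / (1.0 + math.exp(-(vv - v_half) / k_slope))
        nn += (n_inf - nn) / kv_tau * dt_ms
        i_kv = g_kv * nn**kv_exp * (vv - e_k)
        if phase == _PHASE_SUB:
            arg = (vv - v_t) / d_t
            if arg > _EXP_CAP:
                arg = _EXP_CAP
            i_exp = 0.0 if refr_left > 0 else g_l * d_t * math.exp(arg)
            dv = (-g_l * (vv - e_l) + i_exp - i_kv + i_inj[i] + noise[i]) / c_pf
            vv += dv * dt_ms
            if vv >= _V_PEAK_ON and refr_left <= 0:
                phase = _PHASE_REPOL
                spike_times.append(i * dt_ms)
            if refr_left > 0:
                refr_left -= dt_ms
        else:
            dv = (
                -g_l * (vv - e_l) - _G_REPOL * (vv - e_k) - i_kv + i_inj[i]
            ) / c_pf
            vv += dv * dt_ms
            if vv <= v_reset:
                vv = v_reset
                phase = _PHASE_SUB
                refr_left = refr_ms
        v[i] = vv
    return v, np.array(spike_times)


def _biexp_kernel(rise_ms: float, decay_ms: float, dt_ms: float) -> np.ndarray:
    t = np.arange(0.0, decay_ms * 6, dt_ms)
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    return k / k.max()


def gen_patch_cell(
    params: PatchSimParams,
    protocol: str = "current_steps",
    dt_ms: float = 0.05,
    gap_free_s: float = 60.0,
    pre_s: float = 0.2,
    post_s: float = 0.2,
) -> SweepSet:
    """Simulated sweep set for one protocol.

    ``current_steps`` integrates the membrane model over the −20..200 pA
    protocol; ``voltage_steps`` returns the steady ionic current of each
    clamped step (−80..50 mV from −60 mV hold); ``gap_free`` returns a
    −60 mV hold current trace with Poisson sEPSC events of bi-exponential
    shape.  Ground truth (spike times, K+ I–V curve, event times) is stored
    in ``SweepSet.truth``.
    """
    if dt_ms > 0.1:
        raise ValueError("timestep must be <= 0.1 ms for integration accuracy")
    rng = np.random.Generator(np.random.Philox(params.seed))
    fs = 1000.0 / dt_ms

    if protocol == "current_steps":
        n = int((pre_s + 1.0 + post_s) * 1000 / dt_ms)
        times = np.arange(n) * dt_ms / 1000.0
        on = int(pre_s * 1000 / dt_ms)
        off = int((pre_s + 1.0) * 1000 / dt_ms)
        sweeps = np.empty((CURRENT_STEPS_PA.size, n))
        all_spikes = []
        for j, amp in enumerate(CURRENT_STEPS_PA):
            i_inj = np.zeros(n)
            i_inj[on:off] = amp
            # diffusive current noise: noise_sd is the sd integrated over 1 ms
            noise = (
                rng.normal(0.0, params.noise_sd / math.sqrt(dt_ms), n)
                if params.noise_sd > 0
                else np.zeros(n)
            )
            v, st = _integrate_cc(
                i_inj, dt_ms, params.capacitance_pf, params.leak_ns,
                params.e_leak_mv, params.threshold_mv, params.delta_t_mv,
                params.reset_mv, params.refractory_ms, params.g_kv_ns,
                params.kv_half_mv, params.kv_slope_mv, params.kv_tau_ms,
                params.kv_exponent, params.e_k_mv, noise,
            )
            sweeps[j] = v
            all_spikes.append(np.asarray(st) / 1000.0)
        return SweepSet(
            mode="current_clamp",
            times=times,
            sweeps=sweeps,
            commands=CURRENT_STEPS_PA.copy(),
            sampling_hz=fs,
            step_start_s=pre_s,
            truth={
                "params": params,
                "spike_times": all_spikes,
                **params.passive_truth(),
            },
        )

    if protocol == "voltage_steps":
        n = int((pre_s + 1.0 + post_s) * 1000 / dt_ms)
        times = np.arange(n) * dt_ms / 1000.0
        on = int(pre_s * 1000 / dt_ms)
        off = int((pre_s + 1.0) * 1000 / dt_ms)
        hold = -60.0
        sweeps = np.empty((VOLTAGE_STEPS_MV.size, n))
        n_hold = float(params.kv_activation(hold))
        t_ms = np.arange(n) * dt_ms
        for j, v_step in enumerate(VOLTAGE_STEPS_MV):
            i_hold = params.leak_ns * (hold - params.e_leak_mv) + params.kv_iv(hold)
            n_inf = float(params.kv_activation(v_step))
            # first-order activation relaxation during the clamped step
            n_t = n_inf + (n_hold - n_inf) * np.exp(
                -(t_ms[on:off] - t_ms[on]) / params.kv_tau_ms
            )
            i_step = (
                params.leak_ns * (v_step - params.e_leak_mv)
                + params.g_kv_ns
                * n_t**params.kv_exponent
                * (v_step - params.e_k_mv)
            )
            trace = np.full(n, i_hold)
            trace[on:off] = i_step
            if params.noise_sd > 0:
                trace = trace + rng.normal(0.0, params.noise_sd, n)
            sweeps[j] = trace
        return SweepSet(
            mode="voltage_clamp",
            times=times,
            sweeps=sweeps,
            commands=VOLTAGE_STEPS_MV.copy(),
            sampling_hz=fs,
            step_start_s=pre_s,
            hold_mv=hold,
            truth={
                "params": params,
                # steady-state Boltzmann I-V of the K+ conductance
                "kv_iv": params.kv_iv(VOLTAGE_STEPS_MV),
                # max deflection during the step (activation relaxes from
                # the holding level, so steps below hold peak at onset)
                "kv_iv_deflection": params.g_kv_ns
                * np.maximum(params.kv_activation(VOLTAGE_STEPS_MV), n_hold)
                ** params.kv_exponent
                * (VOLTAGE_STEPS_MV - params.e_k_mv),
            },
        )

    if protocol == "gap_free":
        n = int(gap_free_s * 1000 / dt_ms)
        times = np.arange(n) * dt_ms / 1000.0
        n_events = rng.poisson(params.epsc_rate_hz * gap_free_s)
        event_times = np.sort(rng.uniform(0.0, gap_free_s, n_events))
        amps = rng.normal(params.epsc_amp_pa, params.epsc_amp_pa * 0.15, n_events)
        amps = np.maximum(amps, params.epsc_amp_pa * 0.4)
        impulse = np.zeros(n)
        for et, a in zip(event_times, amps):
            i = int(et * 1000 / dt_ms)
            if i < n:
                impulse[i] += a
        kern = _biexp_kernel(params.epsc_rise_ms, params.epsc_decay_ms, dt_ms)
        trace = -np.convolve(impulse, kern)[:n]  # inward events are negative
        if params.noise_sd > 0:
            trace = trace + rng.normal(0.0, params.noise_sd, n)
        return SweepSet(
            mode="gap_free",
            times=times,
            sweeps=trace[None, :],
            commands=np.array([-60.0]),
            sampling_hz=fs,
            truth={
                "params": params,
                "event_times": event_times,
                "event_amps": amps,
            },
        )

    raise ValueError(f"unknown protocol {protocol!r}")


def dtx_pair(params: PatchSimParams, **kwargs) -> tuple[SweepSet, SweepSet]:
    """Baseline and post-drug voltage-step sets (post-drug has g_kv = 0)."""
    baseline = gen_patch_cell(params, "voltage_steps", **kwargs)
    washed = gen_patch_cell(
        replace(params, g_kv_ns=0.0), "voltage_steps", **kwargs
    )
    return baseline, washed
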