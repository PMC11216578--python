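"""Whole-cell sweep analysis: passive properties, excitability, spike
kinetics, pharmacological subtraction, synaptic events and recording QC.

Definitions follow standard current-clamp practice: the resting membrane
potential is the pre-step baseline; the input resistance is the slope of
the steady-state voltage–current relation over hyperpolarising steps; the
membrane time constant comes from a single-exponential fit of the step
onset; C_m = τ/R_in; the rheobase is the first step current eliciting at
least one action potential.  The dendrotoxin-sensitive current is the
average post-drug voltage-step trace subtracted from the average baseline
trace, summarised as the maximal deflection in either direction per step
and normalised by C_m to a current density (pA/pF).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

__all__ = [
    "PassiveProperties",
    "APKinetics",
    "DTXResult",
    "SynapticEvents",
    "qc_recording",
    "passive_properties",
    "detect_action_potentials",
    "fi_curve",
    "ap_kinetics",
    "dtx_sensitive_current",
    "detect_sepscs",
    "epsc_train_analysis",
    "classify_baseline_activity",
]

#: spike detector: dV/dt crossing (V/s), confirmation level (mV), window (ms)
DVDT_THRESHOLD = 20.0
SPIKE_CONFIRM_MV = 0.0
SPIKE_CONFIRM_MS = 2.0
SPIKE_REFRACTORY_MS = 1.0


@dataclass
class PassiveProperties:
    rmp_mv: float
    r_in_gohm: float
    tau_ms: float
    c_m_pf: float
    rheobase_pa: float  # NaN when no step elicits a spike


@dataclass
class APKinetics:
    """Per-spike action-potential kinetics from the rheobase sweep."""

    v_max_mv: np.ndarray
    threshold_mv: np.ndarray
    width_ms: np.ndarray  # at half-peak (threshold-to-peak half height)
    ahp_mv: np.ndarray  # AHP amplitude below threshold
    rise_ms: np.ndarray  # 10-90% rise time
    decay_tau_ms: np.ndarray  # exponential repolarisation constant
    phase_v: list  # per-spike V trace for the phase plane
    phase_dvdt: list  # per-spike dV/dt (V/s)

    @property
    def peak_dvdt(self) -> float:
        return max(float(np.max(d)) for d in self.phase_dvdt)

    @property
    def mean_peak_dvdt(self) -> float:
        """Mean over spikes of the per-spike maximum dV/dt."""
        return float(np.mean([np.max(d) for d in self.phase_dvdt]))


@dataclass
class DTXResult:
    step_mv: np.ndarray
    baseline_mean: np.ndarray  # (n_steps, n_samples)
    post_mean: np.ndarray
    subtracted: np.ndarray
    max_deflection_pa: np.ndarray  # signed, max |.| in either direction
    density_pa_pf: np.ndarray


@dataclass
class SynapticEvents:
    times_s: np.ndarray
    amplitudes_pa: np.ndarray
    rise_ms: np.ndarray
    decay_ms: np.ndarray
    frequency_hz: float


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_recording(
    access_mohm: np.ndarray | None,
    holding_pa: np.ndarray | None,
    ra_limit: float = 20.0,
    change_limit: float = 0.20,
) -> tuple[bool, list[str]]:
    """Recording quality control.

    Fails when access resistance exceeds 20 MΩ at any checkpoint, or when
    access resistance or holding current changes by more than 20% relative
    to the first checkpoint.  Missing series fail as unverifiable.
    """
    reasons: list[str] = []
    if access_mohm is None or len(np.atleast_1d(access_mohm)) == 0:
        return False, ["unverifiable: no access-resistance series"]
    ra = np.asarray(access_mohm, float)
    if np.any(ra > ra_limit):
        reasons.append(f"access resistance exceeds {ra_limit:g} MOhm")
    if ra[0] > 0 and np.max(np.abs(ra - ra[0])) / ra[0] > change_limit:
        reasons.append("access resistance changed by more than 20%")
    if holding_pa is None or len(np.atleast_1d(holding_pa)) == 0:
        reasons.append("unverifiable: no holding-current series")
    else:
        hold = np.asarray(holding_pa, float)
        if abs(hold[0]) > 0 and np.max(np.abs(hold - hold[0])) / abs(hold[0]) > change_limit:
            reasons.append("holding current changed by more than 20%")
    return (len(reasons) == 0), reasons


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def detect_action_potentials(
    times_s: np.ndarray, v_mv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spike times and indices from a voltage sweep.

    A spike is an upward crossing of dV/dt >= 20 V/s followed by the
    voltage exceeding 0 mV within 2 ms, with a 1-ms refractory period.
    Returns ``(spike_times_s, onset_indices)`` where the onset index is
    the dV/dt-crossing sample (used as the threshold point).
    """
    t = np.asarray(times_s, float)
    v = np.asarray(v_mv, float)
    dt_s = t[1] - t[0]
    if 1.0 / dt_s < 10_000:
        raise ValueError("sampling rate must be >= 10 kHz for spike detection")
    dvdt = np.gradient(v, dt_s) / 1000.0  # V/s
    above = dvdt >= DVDT_THRESHOLD
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    confirm_n = int(SPIKE_CONFIRM_MS / 1000.0 / dt_s)
    refr_n = int(SPIKE_REFRACTORY_MS / 1000.0 / dt_s)
    onsets: list[int] = []
    last = -refr_n - 1
    for i in crossings:
        if i - last <= refr_n:
            continue
        seg = v[i : i + confirm_n + 1]
        if seg.size and seg.max() > SPIKE_CONFIRM_MV:
            onsets.append(int(i))
            last = i
    onsets_arr = np.asarray(onsets, int)
    return t[onsets_arr] if onsets_arr.size else np.empty(0), onsets_arr


# ---------------------------------------------------------------------------
# passive properties and F-I
# ---------------------------------------------------------------------------

def _exp_rise(t, v0, dv, tau):
    return v0 + dv * (1.0 - np.exp(-t / tau))


def passive_properties(sweep_set) -> PassiveProperties:
    """Passive membrane properties from a current-step sweep set.

    Uses the pre-step baseline for the RMP, the final 200 ms of the step
    for steady states, the −20/−10 pA steps plus rest for the R_in fit,
    a single-exponential fit of the first 300 ms of the −10 (or −20) pA
    step onset (excluding the first 2 ms) for τ, and spike detection for
    the rheobase.
    """
    t = sweep_set.times
    dt_s = t[1] - t[0]
    on = int(round(sweep_set.step_start_s / dt_s))
    off = on + int(round(sweep_set.step_dur_s / dt_s))
    steps = np.asarray(sweep_set.commands, float)
    sweeps = np.asarray(sweep_set.sweeps, float)

    hyper = steps < 0
    if hyper.sum() < 2:
        raise ValueError("need at least 2 hyperpolarising steps")

    rmp = float(sweeps[:, : max(on - 1, 1)].mean())
    ss_n = int(0.2 / dt_s)
    steady = sweeps[:, off - ss_n : off].mean(axis=1)

    fit_mask = hyper | (steps == 0)
    slope = float(np.polyfit(steps[fit_mask], steady[fit_mask], 1)[0])  # GΩ
    r_in = slope

    tau_ms = math.nan
    for target in (-10.0, -20.0):
        idx = np.flatnonzero(np.isclose(steps, target))
        if idx.size == 0:
            continue
        j = int(idx[0])
        i0 = on + int(0.002 / dt_s)
        i1 = on + int(0.3 / dt_s)
        tt = (t[i0:i1] - t[on]) * 1000.0  # ms
        vv = sweeps[j, i0:i1]
        try:
            p0 = (vv[0], vv[-1] - vv[0], 30.0)
            popt, _ = curve_fit(_exp_rise, tt, vv, p0=p0, maxfev=5000)
            if popt[2] > 0:
                tau_ms = float(popt[2])
                break
        except RuntimeError:
            continue

    c_m = tau_ms / r_in if (np.isfinite(tau_ms) and r_in > 0) else math.nan

    rheo = math.nan
    for j in np.argsort(steps):
        if steps[j] <= 0:
            continue
        st, _ = detect_action_potentials(t, sweeps[j])
        if st.size:
            rheo = float(steps[j])
            break
    return PassiveProperties(rmp, r_in, tau_ms, c_m, rheo)


def fi_curve(sweep_set) -> dict:
    """Spike count and mean rate per injected current step."""
    t = sweep_set.times
    counts = []
    for j in range(sweep_set.sweeps.shape[0]):
        st, _ = detect_action_potentials(t, sweep_set.sweeps[j])
        in_step = (
            (st >= sweep_set.step_start_s)
            & (st < sweep_set.step_start_s + sweep_set.step_dur_s)
        )
        counts.append(int(in_step.sum()))
    counts = np.asarray(counts)
    return {
        "current_pa": np.asarray(sweep_set.commands, float),
        "n_spikes": counts,
        "rate_hz": counts / sweep_set.step_dur_s,
    }


# ---------------------------------------------------------------------------
# spike kinetics and phase plane
# ---------------------------------------------------------------------------

def _exp_decay(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def ap_kinetics(
    times_s: np.ndarray,
    v_mv: np.ndarray,
    window_ms: tuple[float, float] = (-2.0, 5.0),
) -> APKinetics:
    """Spike kinetics and phase-plane traces from one sweep.

    The threshold is the voltage at the first dV/dt >= 20 V/s crossing;
    the width is measured at half height between threshold and peak; the
    AHP is the minimum within 10 ms after the peak, reported as depth
    below threshold; rise time is 10–90% threshold-to-peak; the decay
    constant is a single-exponential fit of the repolarisation.  Spikes
    with truncated waveform windows are excluded.
    """
    t = np.asarray(times_s, float)
    v = np.asarray(v_mv, float)
    dt_s = t[1] - t[0]
    _, onsets = detect_action_potentials(t, v)
    if onsets.size == 0:
        raise ValueError("no action potentials in the sweep")
    dvdt = np.gradient(v, dt_s) / 1000.0

    w0 = int(window_ms[0] / 1000.0 / dt_s)
    w1 = int(window_ms[1] / 1000.0 / dt_s)
    vmaxs, thrs, widths, ahps, rises, decays = [], [], [], [], [], []
    pv, pdv = [], []
    for i in onsets:
        if i + w0 < 0 or i + w1 >= v.size:
            continue
        seg = v[i + w0 : i + w1]
        seg_dv = dvdt[i + w0 : i + w1]
        thr = float(v[i])
        pk_rel = int(np.argmax(seg))
        pk = float(seg[pk_rel])
        half = thr + (pk - thr) / 2.0
        above = seg >= half
        lo = pk_rel
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = pk_rel
        while hi < seg.size - 1 and above[hi + 1]:
            hi += 1
        width = (hi - lo + 1) * dt_s * 1000.0

        post = seg[pk_rel:]
        ahp_depth = thr - float(post.min()) if post.size else math.nan

        lvl10 = thr + 0.1 * (pk - thr)
        lvl90 = thr + 0.9 * (pk - thr)
        upstroke = seg[: pk_rel + 1]
        i10 = int(np.argmax(upstroke >= lvl10))
        i90 = int(np.argmax(upstroke >= lvl90))
        rise = max(i90 - i10, 1) * dt_s * 1000.0

        tau_d = math.nan
        rep = post[: int(0.004 / dt_s)]
        if rep.size > 5:
            tt = np.arange(rep.size) * dt_s * 1000.0
            try:
                popt, _ = curve_fit(
                    _exp_decay, tt, rep, p0=(pk - rep[-1], 1.0, rep[-1]),
                    bounds=([-np.inf, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=2000,
                )
                if popt[1] > 0:
                    tau_d = float(popt[1])
            except RuntimeError:
                pass

        vmaxs.append(pk)
        thrs.append(thr)
        widths.append(width)
        ahps.append(ahp_depth)
        rises.append(rise)
        decays.append(tau_d)
        pv.append(seg)
        pdv.append(seg_dv)
    if not vmaxs:
        raise ValueError("all spike waveforms truncated")
    return APKinetics(
        np.asarray(vmaxs), np.asarray(thrs), np.asarray(widths),
        np.asarray(ahps), np.asarray(rises), np.asarray(decays), pv, pdv,
    )


# ---------------------------------------------------------------------------
# pharmacological subtraction
# ---------------------------------------------------------------------------

def dtx_sensitive_current(
    baseline_sets: list,
    post_sets: list,
    c_m_pf: float,
) -> DTXResult:
    """Drug-sensitive current by subtraction of averaged voltage-step sets.

    The 2–3 protocol repeats under each condition are averaged, the
    post-drug average is subtracted from the baseline average, and each
    step is summarised by its maximal deflection during the 1-s step in
    either direction (signed) and as a current density (pA/pF).
    """
    if isinstance(baseline_sets, (list, tuple)) is False:
        baseline_sets = [baseline_sets]
    if isinstance(post_sets, (list, tuple)) is False:
        post_sets = [post_sets]
    ref = baseline_sets[0]
    for s in list(baseline_sets) + list(post_sets):
        if not np.array_equal(s.commands, ref.commands) or s.sweeps.shape != ref.sweeps.shape:
            raise ValueError("voltage-step protocols do not match")
    base = np.mean([s.sweeps for s in baseline_sets], axis=0)
    post = np.mean([s.sweeps for s in post_sets], axis=0)
    sub = base - post

    dt_s = ref.times[1] - ref.times[0]
    on = int(round(ref.step_start_s / dt_s))
    off = on + int(round(ref.step_dur_s / dt_s))
    seg = sub[:, on:off]
    i_abs = np.argmax(np.abs(seg), axis=1)
    deflection = seg[np.arange(seg.shape[0]), i_abs]
    return DTXResult(
        step_mv=np.asarray(ref.commands, float),
        baseline_mean=base,
        post_mean=post,
        subtracted=sub,
        max_deflection_pa=deflection,
        density_pa_pf=deflection / c_m_pf,
    )


# ---------------------------------------------------------------------------
# synaptic events
# ---------------------------------------------------------------------------

def detect_sepscs(
    times_s: np.ndarray,
    current_pa: np.ndarray,
    rise_ms: float = 1.5,
    decay_ms: float = 10.0,
    threshold_sd: float = 3.0,
) -> SynapticEvents:
    """Spontaneous EPSC detection by matched bi-exponential template.

    The trace is correlated with a unit-peak bi-exponential kernel; local
    minima of the filtered trace below ``threshold_sd`` times the robust
    (MAD-based) baseline noise are events.  Per-event amplitude, 10–90%
    rise and single-exponential decay are measured on the raw trace.
    """
    t = np.asarray(times_s, float)
    x = np.asarray(current_pa, float)
    dt_s = t[1] - t[0]
    dt_ms = dt_s * 1000.0

    kt = np.arange(0.0, decay_ms * 5, dt_ms)
    kern = np.exp(-kt / decay_ms) - np.exp(-kt / rise_ms)
    kern /= kern.max()
    filt = fftconvolve(x, kern[::-1] / kern.sum(), mode="same")

    noise_sd = float(np.median(np.abs(x - np.median(x))) / 0.6745)
    thr = -threshold_sd * noise_sd + np.median(filt)

    below = filt < thr
    starts = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    min_sep = int((rise_ms + decay_ms) / dt_ms)
    ev_idx: list[int] = []
    last = -min_sep - 1
    for s in starts:
        e = s
        while e < filt.size - 1 and below[e + 1]:
            e += 1
        i_min = s + int(np.argmin(x[s : e + 1])) if e > s else s
        if i_min - last > min_sep:
            ev_idx.append(int(i_min))
            last = i_min
    if not ev_idx:
        return SynapticEvents(np.empty(0), np.empty(0), np.empty(0), np.empty(0), 0.0)

    base_n = max(int(2.0 / dt_ms), 1)
    amps, rises_out, decays_out, times_out = [], [], [], []
    for i in ev_idx:
        b0 = max(i - int((rise_ms * 4) / dt_ms) - base_n, 0)
        base = float(np.median(x[b0 : b0 + base_n]))
        amp = base - float(x[i])  # positive magnitude of the inward event
        lvl10, lvl90 = base - 0.1 * amp, base - 0.9 * amp
        j = i
        while j > b0 and x[j - 1] < lvl10:
            j -= 1
        k = j
        while k < i and x[k] > lvl90:
            k += 1
        rise = max(k - j, 1) * dt_ms
        rep = x[i : i + int(decay_ms * 4 / dt_ms)]
        tau = math.nan
        if rep.size > 5:
            tt = np.arange(rep.size) * dt_ms
            try:
                popt, _ = curve_fit(
                    _exp_decay, tt, rep - base, p0=(-amp, decay_ms, 0.0),
                    bounds=([-np.inf, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=2000,
                )
                if popt[1] > 0:
                    tau = float(popt[1])
            except RuntimeError:
                pass
        amps.append(amp)
        rises_out.append(rise)
        decays_out.append(tau)
        times_out.append(float(t[i]))
    duration = t[-1] - t[0]
    return SynapticEvents(
        np.asarray(times_out), np.asarray(amps), np.asarray(rises_out),
        np.asarray(decays_out), len(times_out) / duration,
    )


def epsc_train_analysis(
    times_s: np.ndarray,
    current_pa: np.ndarray,
    pulse_times_s: np.ndarray,
    window_s: float = 0.08,
) -> dict:
    """Per-pulse EPSC amplitudes for a 10-Hz optogenetic train.

    Measures the peak inward deflection (relative to the pre-train
    baseline) in a post-pulse window for each pulse and normalises to the
    first pulse.  Windows must not overlap.
    """
    pulses = np.asarray(pulse_times_s, float)
    if pulses.size > 1 and window_s > np.min(np.diff(pulses)):
        raise ValueError("pulse windows overlap at this rate")
    t = np.asarray(times_s, float)
    x = np.asarray(current_pa, float)
    base = float(np.median(x[t < pulses[0]])) if (t < pulses[0]).any() else float(
        np.median(x)
    )
    amps = []
    for p in pulses:
        m = (t >= p) & (t < p + window_s)
        amps.append(base - float(x[m].min()) if m.any() else math.nan)
    amps_arr = np.asarray(amps)
    rel = amps_arr / amps_arr[0] if amps_arr[0] != 0 else np.full_like(amps_arr, np.nan)
    return {"amplitude_pa": amps_arr, "relative_amplitude": rel}


# ---------------------------------------------------------------------------
# baseline-activity cell classification
# ---------------------------------------------------------------------------

def classify_baseline_activity(
    baseline_rates_hz: np.ndarray, guard_hz: float = 10.0
) -> np.ndarray:
    """Split cells into putative inhibitory (active) vs excitatory (quiet).

    A 1-D two-means split of baseline firing rates; the high-rate class is
    putative inhibitory.  If the two centroids differ by less than
    ``guard_hz`` the cohort is treated as a single low-rate class.
    Returns an array of ``"putative_inhibitory"`` / ``"putative_excitatory"``.
    """
    rates = np.asarray(baseline_rates_hz, float)
    labels = np.full(rates.size, "putative_excitatory", dtype=object)
    if rates.size < 2 or np.allclose(rates, rates[0]):
        if rates.size and np.ptp(rates) < guard_hz:
            warnings.warn("baseline rates unimodal; all cells assigned low class")
        return labels
    km = KMeans_1d(rates)
    hi = int(np.argmax(km["centers"]))
    if abs(km["centers"][1] - km["centers"][0]) < guard_hz:
        warnings.warn("baseline rates unimodal; all cells assigned low class")
        return labels
    labels[km["labels"] == hi] = "putative_inhibitory"
    return labels


def KMeans_1d(x: np.ndarray) -> dict:
    """Exact 1-D two-means via the best sorted split point."""
    order = np.argsort(x)
    xs = x[order]
    best_cost, best_i = np.inf, 1
    for i in range(1, xs.size):
        lo, hi = xs[:i], xs[i:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_i = cost, i
    labels = np.zeros(x.size, dtype=int)
    labels[order[best_i:]] = 1
    centers = np.array([xs[:best_i].mean(), xs[best_i:].mean()])
    return {"labels": labels, "centers": centers}
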