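"""Synthetic superior-colliculus units and flash-evoked laminar LFP.

Spiking is an inhomogeneous Poisson process whose rate is a rectified
linear–nonlinear function of the stimulus: a Gaussian spatial receptive
field for checkerboard white noise, von Mises direction tuning for drifting
gratings/bars, and a transient kernel for looms.  The flash LFP block is
built by double integration of a template current source density with a
source overlying a sink at a known inflection depth, so laminar alignment
can be validated by recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VisualUnitParams",
    "CheckerStimulus",
    "gen_checker_stimulus",
    "gen_visual_unit",
    "gen_flash_lfp",
    "LFPBlock",
]


@dataclass(frozen=True)
class VisualUnitParams:
    """Ground-truth parameters of one synthetic visual unit."""

    baseline_rate: float = 4.0  # Hz
    rf_center: tuple[int, int] = (20, 20)  # checker coordinates (row, col)
    rf_radius: float = 2.5  # checkers (Gaussian sigma)
    rf_polarity: str = "ON"
    rf_gain: float = 30.0  # Hz per unit filtered contrast
    tuning_kappa: float = 2.0
    pref_direction: float = 0.0  # deg
    loom_peak: float = 40.0  # Hz
    loom_latency: float = 0.3  # s
    loom_decay: float = 0.15  # s
    depth: float = 200.0  # µm below sSC surface
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.loom_peak < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.pref_direction < 360:
            raise ValueError("pref_direction must be in [0, 360)")
        if self.rf_polarity not in ("ON", "OFF"):
            raise ValueError("rf_polarity must be ON or OFF")


@dataclass
class CheckerStimulus:
    """Binary (+-1) checkerboard white-noise movie."""

    frames: np.ndarray  # (n_frames, H, W), values +-1
    frame_rate: float = 20.0

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.frame_rate


def gen_checker_stimulus(
    n_frames: int = 7200,
    grid: tuple[int, int] = (40, 40),
    frame_rate: float = 20.0,
    seed: int = 0,
) -> CheckerStimulus:
    rng = np.random.Generator(np.random.Philox(seed))
    frames = rng.integers(0, 2, size=(n_frames, *grid)).astype(np.float32) * 2 - 1
    return CheckerStimulus(frames=frames, frame_rate=frame_rate)


def _poisson_times(rate: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Spike times from a piecewise-constant rate via per-bin thinning."""
    counts = rng.poisson(np.maximum(rate, 0.0) * dt)
    times = np.repeat(np.arange(rate.size) * dt, counts)
    times = times + rng.uniform(0.0, dt, size=times.size)
    return np.sort(times)


def _gaussian_rf(params: VisualUnitParams, grid: tuple[int, int]) -> np.ndarray:
    r, c = np.mgrid[0 : grid[0], 0 : grid[1]]
    cy, cx = params.rf_center
    rf = np.exp(-((r - cy) ** 2 + (c - cx) ** 2) / (2 * params.rf_radius**2))
    if params.rf_polarity == "OFF":
        rf = -rf
    return rf


def gen_visual_unit(
    params: VisualUnitParams,
    stimulus: str = "checker",
    *,
    checker: CheckerStimulus | None = None,
    directions: np.ndarray | None = None,
    n_repeats: int = 3,
    trial_s: float = 2.0,
    loom_onsets: np.ndarray | None = None,
    duration: float = 60.0,
) -> dict:
    """Inhomogeneous-Poisson spike times for one stimulus protocol.

    ``stimulus`` is one of ``checker``, ``gratings``, ``loom``, ``grey``.
    For checker stimuli the rate is ``baseline + gain * relu(rf . frame)``;
    for gratings the per-direction rate follows von Mises tuning around the
    preferred direction; for looms the rate adds an alpha-like transient at
    each loom onset.  Returns a dict with ``spike_times`` plus
    protocol-specific fields, and the ground-truth parameters.
    """
    rng = np.random.Generator(np.random.Philox(params.seed))
    out: dict = {"params": params, "stimulus": stimulus}

    if stimulus == "checker":
        if checker is None:
            raise ValueError("checker stimulus required")
        rf = _gaussian_rf(params, checker.frames.shape[1:])
        rf = rf / np.abs(rf).sum()
        drive = np.tensordot(checker.frames, rf, axes=([1, 2], [0, 1]))
        rate = params.baseline_rate + params.rf_gain * np.maximum(drive * 50.0, 0.0)
        out["spike_times"] = _poisson_times(rate, 1.0 / checker.frame_rate, rng)
        out["rf_truth"] = rf
    elif stimulus == "gratings":
        if directions is None:
            directions = np.arange(0, 360, 45.0)
        dt = 0.005
        trains = {}
        kappa = params.tuning_kappa
        for d in directions:
            ang = math.radians(d - params.pref_direction)
            gain = math.exp(kappa * (math.cos(ang) - 1.0))
            rate_val = params.baseline_rate * (1.0 + 4.0 * gain)
            reps = []
            for _ in range(n_repeats):
                rate = np.full(int(trial_s / dt), rate_val)
                reps.append(_poisson_times(rate, dt, rng))
            trains[float(d)] = reps
        out["direction_trains"] = trains
        out["trial_s"] = trial_s
        # a 30-s baseline stretch at the spontaneous rate
        out["baseline_spikes"] = _poisson_times(
            np.full(int(30.0 / dt), params.baseline_rate), dt, rng
        )
        out["baseline_s"] = 30.0
    elif stimulus == "loom":
        if loom_onsets is None:
            loom_onsets = np.arange(10) * 20.0 + 30.0
        dt = 0.002
        n = int((loom_onsets.max() + 10.0) / dt)
        tt = np.arange(n) * dt
        rate = np.full(n, params.baseline_rate)
        for onset in loom_onsets:
            for i_loom in range(5):
                t0 = onset + i_loom * 0.75 + params.loom_latency
                tau = (tt - t0) / params.loom_decay
                mask = tau >= 0
                rate[mask] += params.loom_peak * np.exp(-tau[mask]) * np.minimum(
                    tau[mask] * 4.0, 1.0
                )
        out["spike_times"] = _poisson_times(rate, dt, rng)
        out["loom_onsets"] = np.asarray(loom_onsets, float)
    elif stimulus == "grey":
        dt = 0.005
        rate = np.full(int(duration / dt), params.baseline_rate)
        out["spike_times"] = _poisson_times(rate, dt, rng)
    else:
        raise ValueError(f"unknown stimulus kind {stimulus!r}")
    return out


@dataclass
class LFPBlock:
    """Flash-locked LFP repetitions on a laminar probe."""

    depths_um: np.ndarray  # (n_channels,), increasing downward
    lfp: np.ndarray  # (n_reps, n_channels, n_samples)
    times: np.ndarray  # (n_samples,), s relative to flash onset
    inflection_depth_um: float  # ground truth


def gen_flash_lfp(
    depth_grid: np.ndarray,
    inflection_depth: float,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_reps: int = 10,
    amplitude: float = 1.0,
    extent_um: float = 150.0,
) -> LFPBlock:
    """Flash-evoked LFP with a known source-over-sink CSD profile.

    The template CSD has a source (positive) of width ``extent_um``
    immediately above ``inflection_depth`` and an equal sink below it,
    active in the first ~80 ms after the flash.  The LFP is obtained by
    double spatial integration of the CSD (so the negative second spatial
    difference of the noiseless LFP recovers the template exactly), with
    independent Gaussian noise per repetition.  Swapping the sign of
    ``amplitude`` swaps source and sink (polarity-inverted profile).
    """
    depths = np.asarray(depth_grid, float)
    if depths.size < 5:
        raise ValueError("need at least 5 channels for a CSD")
    spacing = np.diff(depths)
    if not np.allclose(spacing, spacing[0]):
        raise ValueError("depth grid must be uniformly spaced")
    dz = float(spacing[0])
    if not depths[0] < inflection_depth < depths[-1]:
        raise ValueError("inflection depth outside the channel span")
    rng = np.random.Generator(np.random.Philox(seed))

    dt = 0.001
    times = np.arange(-0.05, 0.25, dt)
    kern = np.exp(-((times - 0.04) ** 2) / (2 * 0.02**2))
    kern[times < 0] = 0.0

    csd_profile = np.zeros_like(depths)
    above = (depths >= inflection_depth - extent_um) & (depths < inflection_depth)
    below = (depths > inflection_depth) & (depths <= inflection_depth + extent_um)
    csd_profile[above] = amplitude
    csd_profile[below] = -amplitude

    # phi'' = -CSD (unit conductivity): discrete double integration aligned
    # so the second-difference estimator recovers the template exactly
    first = -np.concatenate([[0.0], np.cumsum(csd_profile)[:-1]]) * dz
    phi = np.cumsum(first) * dz
    lfp0 = np.outer(phi, kern)[None, :, :]
    lfp = np.repeat(lfp0, n_reps, axis=0) + rng.normal(
        0.0, noise_sd, size=(n_reps, depths.size, times.size)
    )
    return LFPBlock(
        depths_um=depths, lfp=lfp, times=times, inflection_depth_um=inflection_depth
    )
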