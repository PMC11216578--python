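"""Laminar alignment and visual-response metrics for sorted SC units.

Covers the head-fixed recording analysis chain: current-source-density
laminar alignment (inflection depth between an overlying source and an
underlying sink), event-aligned PSTHs in 16.7 ms bins, a ZETA-style
time-locked responsiveness test, k-means clustering of response profiles
with Calinski–Harabasz model selection, spike-triggered-average receptive
fields with SNR / polarity / half-peak radius, direction selectivity
(DSI = (Dp − Dnp)/(Dp + Dnp)), loom-response metrics, frame-difference
motion classification and pupil-diameter estimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import EllipseModel
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "DepthProfile",
    "ReceptiveField",
    "DirectionTuning",
    "compute_csd",
    "assign_layer",
    "compute_psth",
    "zeta_test",
    "cluster_responses",
    "sta_receptive_field",
    "flag_responsive_rfs",
    "direction_selectivity",
    "dsi_from_tuning",
    "loom_response_metrics",
    "classify_motion",
    "pupil_diameter",
]

PSTH_BIN_S = 0.0167  # 16.7 ms, one stimulus frame at 60 Hz


# ---------------------------------------------------------------------------
# current source density and laminar alignment
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """CSD profile with the source-to-sink inflection depth.

    The superficial SC (sSC) spans [ID − 300 µm, ID + 100 µm] and the
    intermediate/deep SC (idSC) everything below ID + 100 µm, with depth
    increasing downward.
    """

    depths_um: np.ndarray
    csd: np.ndarray  # (n_channels, n_samples)
    times: np.ndarray
    inflection_depth_um: float  # NaN when undefined
    flagged: bool = False
    polarity_inverted: bool = False

    @property
    def ssc_bounds(self) -> tuple[float, float]:
        return (self.inflection_depth_um - 300.0, self.inflection_depth_um + 100.0)


def compute_csd(
    lfp_block,
    early_window_s: tuple[float, float] = (0.0, 0.1),
    smooth_channels: int = 0,
) -> DepthProfile:
    """CSD from a flash-locked LFP block and the laminar inflection depth.

    The CSD is the negative second spatial difference of the trial-averaged
    LFP with one-channel Vaknin-style edge padding (optionally smoothed
    across channels).  The inflection depth is the boundary between the
    strongest adjacent source-above/sink-below pair of the time-averaged
    CSD within the early post-flash window; a sink-above/source-below
    profile is flagged as polarity-inverted.
    """
    depths = np.asarray(lfp_block.depths_um, float)
    if depths.size < 5:
        raise ValueError("need at least 5 channels for a CSD")
    dz = float(depths[1] - depths[0])
    mean_lfp = np.asarray(lfp_block.lfp, float).mean(axis=0)
    padded = np.vstack([mean_lfp[0], mean_lfp, mean_lfp[-1]])
    csd = -(padded[2:] - 2 * padded[1:-1] + padded[:-2]) / dz**2
    if smooth_channels > 1:
        kern = np.ones(smooth_channels) / smooth_channels
        csd = np.apply_along_axis(lambda c: np.convolve(c, kern, mode="same"), 0, csd)

    times = np.asarray(lfp_block.times, float)
    win = (times >= early_window_s[0]) & (times < early_window_s[1])
    profile = csd[:, win].mean(axis=1)

    # strongest positive-to-negative transition walking down the probe;
    # edge channels carry Vaknin-padding artifacts and are excluded
    best, best_i = 0.0, -1
    inv_best, inv_i = 0.0, -1
    for i in range(1, profile.size - 2):
        if profile[i] > 0 and profile[i + 1] < 0:
            score = profile[i] - profile[i + 1]
            if score > best:
                best, best_i = score, i
        if profile[i] < 0 and profile[i + 1] > 0:
            score = profile[i + 1] - profile[i]
            if score > inv_best:
                inv_best, inv_i = score, i

    if best_i >= 0:
        boundary = 0.5 * (depths[best_i] + depths[best_i + 1])
        return DepthProfile(depths, csd, times, boundary)
    if inv_i >= 0:
        boundary = 0.5 * (depths[inv_i] + depths[inv_i + 1])
        return DepthProfile(
            depths, csd, times, boundary, flagged=True, polarity_inverted=True
        )
    return DepthProfile(depths, csd, times, math.nan, flagged=True)


def assign_layer(depth_um: float, inflection_depth_um: float) -> str:
    """Layer of a unit given its depth and the CSD inflection depth."""
    if not np.isfinite(inflection_depth_um):
        return "other"
    if inflection_depth_um - 300.0 <= depth_um <= inflection_depth_um + 100.0:
        return "sSC"
    if depth_um > inflection_depth_um + 100.0:
        return "idSC"
    return "other"


# ---------------------------------------------------------------------------
# PSTH and responsiveness
# ---------------------------------------------------------------------------

def compute_psth(
    spike_times: np.ndarray,
    events: np.ndarray,
    window_s: tuple[float, float] = (0.0, 1.0),
    bin_s: float = PSTH_BIN_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-aligned mean firing rate (Hz) in fixed-width bins.

    Returns ``(rates, bin_edges)`` where ``rates[i]`` is the average rate
    in ``[edges[i], edges[i+1])`` relative to the events.
    """
    events = np.asarray(events, float)
    if events.size == 0:
        raise ValueError("events must be non-empty")
    spikes = np.sort(np.asarray(spike_times, float))
    n_bins = max(int(round((window_s[1] - window_s[0]) / bin_s)), 1)
    edges = window_s[0] + np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for ev in events:
        rel = spikes[(spikes >= ev + edges[0]) & (spikes < ev + edges[-1])] - ev
        counts += np.histogram(rel, bins=edges)[0]
    return counts / (events.size * bin_s), edges


def _ecdf_deviation(rel_times: np.ndarray, duration: float) -> float:
    """Max |ECDF − uniform| of event-relative spike times on [0, duration)."""
    if rel_times.size == 0:
        return 0.0
    s = np.sort(rel_times) / duration
    n = s.size
    upper = np.arange(1, n + 1) / n - s
    lower = s - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def zeta_test(
    spike_times: np.ndarray,
    events: np.ndarray,
    duration: float,
    baseline_span: tuple[float, float] | None = None,
    n_resamples: int = 100,
    method: str = "jitter",
    seed: int = 0,
) -> float:
    """ZETA-style p-value for time-locked responsiveness.

    The statistic is the maximal absolute deviation of the normalised
    cumulative distribution of event-relative spike times from the uniform
    null over the response window ``[0, duration)``.  Significance comes
    from resampling: ``jitter`` draws surrogate event onsets uniformly over
    the baseline span; ``permutation`` circularly shifts the spike train.
    Units with no spikes anywhere return p = 1.
    """
    spikes = np.sort(np.asarray(spike_times, float))
    events = np.asarray(events, float)
    if spikes.size == 0 or events.size == 0:
        return 1.0
    if baseline_span is None:
        baseline_span = (max(events.min() - 30.0, 0.0), events.min())

    def stat_for(ev: np.ndarray, shift: float = 0.0) -> float:
        rel = []
        sp = spikes if shift == 0.0 else np.sort(
            (spikes + shift) % (spikes[-1] + 1e-9)
        )
        for e in ev:
            lo = np.searchsorted(sp, e)
            hi = np.searchsorted(sp, e + duration)
            rel.append(sp[lo:hi] - e)
        rel = np.concatenate(rel) if rel else np.empty(0)
        return _ecdf_deviation(rel, duration)

    obs = stat_for(events)
    rng = np.random.Generator(np.random.Philox(seed))
    null = np.empty(n_resamples)
    span_lo, span_hi = baseline_span
    span_hi = max(span_hi, span_lo + duration)
    for r in range(n_resamples):
        if method == "jitter":
            surrogate = rng.uniform(span_lo, span_hi - duration, size=events.size)
            null[r] = stat_for(np.sort(surrogate))
        elif method == "permutation":
            null[r] = stat_for(events, shift=rng.uniform(0.0, spikes[-1]))
        else:
            raise ValueError(f"unknown method {method!r}")
    return float((1 + np.sum(null >= obs)) / (n_resamples + 1))


# ---------------------------------------------------------------------------
# clustering of response profiles
# ---------------------------------------------------------------------------

def cluster_responses(
    responses: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    ch_tolerance: float = 0.10,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """K-means clustering with Calinski–Harabasz model selection.

    The number of clusters is the elbow of the CH index, operationalised as
    the smallest k whose CH score is within ``ch_tolerance`` of the maximum
    over the scanned range.  Degenerate input (all rows identical) gives a
    single cluster.
    """
    X = np.asarray(responses, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 units")
    if np.allclose(X, X[0]):
        return np.zeros(X.shape[0], dtype=int), 1
    k_max = min(k_range[1], X.shape[0] - 1)
    scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_range[0], k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        scores[k] = calinski_harabasz_score(X, km.labels_)
        labels_by_k[k] = km.labels_
    if not scores:
        return np.zeros(X.shape[0], dtype=int), 1
    best = max(scores.values())
    k_sel = min(k for k, s in scores.items() if s >= (1 - ch_tolerance) * best)
    return labels_by_k[k_sel], k_sel


# ---------------------------------------------------------------------------
# spike-triggered-average receptive fields
# ---------------------------------------------------------------------------

@dataclass
class ReceptiveField:
    """Spatiotemporal STA and its summary metrics."""

    sta: np.ndarray  # (n_lags, H, W) cropped to the centre
    center: tuple[int, int]  # (row, col) in stimulus coordinates
    snr_db: float
    polarity: str  # "ON" or "OFF"
    radius: float  # half-peak radius in checkers
    low_confidence: bool = False
    responsive: bool | None = None  # set relative to the sSC population


def sta_receptive_field(
    spike_times: np.ndarray,
    checker,
    lag_window_s: tuple[float, float] = (0.0, 0.25),
    crop: int = 160,
    min_spikes: int = 50,
) -> ReceptiveField:
    """Spike-triggered average from checkerboard white noise.

    The STA is accumulated per frame lag over the peri-spike window; the RF
    centre is the pixel with the highest variance across lags, the crop is
    centred on it (clipped to the stimulus), the SNR is
    ``10*log10(max_power/noise_power)`` with the noise power taken from a
    5-pixel border, the polarity is the sign of the centre pixel's mean
    across lags, and the radius is the half-peak width of the spatial
    profile at the best lag.
    """
    frames = checker.frames
    n_frames, H, W = frames.shape
    dt = 1.0 / checker.frame_rate
    spikes = np.asarray(spike_times, float)
    spikes = spikes[(spikes >= 0) & (spikes < n_frames * dt)]
    if spikes.size == 0:
        raise ValueError("no spikes within the stimulus span")
    low_conf = spikes.size < min_spikes

    n_lags = max(int(round((lag_window_s[1] - lag_window_s[0]) / dt)), 1)
    lag0 = int(round(lag_window_s[0] / dt))
    spike_frames = np.floor(spikes / dt).astype(int)
    sta = np.zeros((n_lags, H, W), dtype=np.float64)
    flat = frames.reshape(n_frames, -1)
    for li in range(n_lags):
        idx = spike_frames - (lag0 + li)
        idx = idx[idx >= 0]
        if idx.size == 0:
            continue
        counts = np.bincount(idx, minlength=n_frames).astype(np.float64)
        sta[li] = (counts @ flat).reshape(H, W) / max(idx.size, 1)

    var_map = sta.var(axis=0)
    cy, cx = np.unravel_index(int(np.argmax(var_map)), var_map.shape)

    half = crop // 2
    r0, r1 = max(cy - half, 0), min(cy + half + 1, H)
    c0, c1 = max(cx - half, 0), min(cx + half + 1, W)
    sta_crop = sta[:, r0:r1, c0:c1]

    center_trace = sta[:, cy, cx]
    best_lag = int(np.argmax(np.abs(center_trace)))
    spatial = sta[best_lag]
    max_power = float(spatial[cy, cx] ** 2)
    border = np.ones_like(spatial, dtype=bool)
    b = 5
    border[b:-b, b:-b] = False
    noise_power = float(spatial[border].var())
    snr_db = 10.0 * math.log10(max_power / noise_power) if noise_power > 0 else math.inf

    polarity = "ON" if center_trace.mean() >= 0 else "OFF"

    # half-peak radius along the centre row of the spatial profile
    prof = np.abs(spatial[cy, :])
    half_peak = prof[cx] / 2.0
    above = prof >= half_peak
    left = cx
    while left > 0 and above[left - 1]:
        left -= 1
    right = cx
    while right < W - 1 and above[right + 1]:
        right += 1
    radius = (right - left) / 2.0

    return ReceptiveField(
        sta=sta_crop,
        center=(int(cy), int(cx)),
        snr_db=snr_db,
        polarity=polarity,
        radius=radius,
        low_confidence=low_conf,
    )


def flag_responsive_rfs(rfs: list[ReceptiveField], percentile: float = 80.0) -> None:
    """Set the responsive flag relative to the population SNR percentile."""
    snrs = np.array([rf.snr_db for rf in rfs])
    thr = np.percentile(snrs, percentile)
    for rf in rfs:
        rf.responsive = bool(rf.snr_db >= thr)


# ---------------------------------------------------------------------------
# direction selectivity
# ---------------------------------------------------------------------------

@dataclass
class DirectionTuning:
    """Baseline-normalised direction tuning and DSI."""

    directions: np.ndarray  # deg
    responses: np.ndarray  # baseline-normalised mean rate per direction
    pref_direction: float
    d_p: float
    d_np: float
    dsi: float  # NaN when Dp + Dnp == 0
    ds: bool | None = None  # set relative to the sSC population


def dsi_from_tuning(responses: np.ndarray, directions: np.ndarray) -> DirectionTuning:
    """DSI from an already-normalised tuning vector."""
    responses = np.asarray(responses, float)
    directions = np.asarray(directions, float)
    i_pref = int(np.argmax(responses))
    pref = directions[i_pref]
    anti = (pref + 180.0) % 360.0
    i_anti = int(np.argmin(np.abs(((directions - anti) + 180) % 360 - 180)))
    d_p, d_np = float(responses[i_pref]), float(responses[i_anti])
    denom = d_p + d_np
    dsi = (d_p - d_np) / denom if denom > 0 else math.nan
    return DirectionTuning(directions, responses, float(pref), d_p, d_np, dsi)


def direction_selectivity(
    direction_trains: dict,
    trial_s: float,
    baseline_spikes: np.ndarray,
    baseline_s: float = 30.0,
) -> DirectionTuning:
    """Direction tuning from per-direction spike trains.

    For each direction the mean rate across repetitions is normalised to
    the baseline rate in the 30 s before stimulus onset; the preferred
    direction maximises the normalised response and the non-preferred
    direction is 180° away.  A zero denominator leaves the DSI undefined
    (NaN).
    """
    directions = np.array(sorted(direction_trains), float)
    if directions.size != 8:
        warnings.warn("expected 8 directions 45 deg apart")
    base_rate = len(baseline_spikes) / baseline_s
    resp = []
    for d in directions:
        reps = direction_trains[d]
        if len(reps) < 2:
            raise ValueError("need >=2 repetitions per direction")
        rates = [len(r) / trial_s for r in reps]
        m = float(np.mean(rates))
        resp.append(m / base_rate if base_rate > 0 else m)
    return dsi_from_tuning(np.asarray(resp), directions)


# ---------------------------------------------------------------------------
# loom responses
# ---------------------------------------------------------------------------

def loom_response_metrics(
    spike_times: np.ndarray,
    bout_onsets: np.ndarray,
    loom_s: float = 0.75,
    n_looms: int = 5,
    bin_s: float = PSTH_BIN_S,
) -> dict:
    """Mean/max rate, time-to-peak and per-loom adaptation for loom bouts.

    The mean rate is the average over the five looms of the mean firing
    rate within each loom window (averaged across repetitions); the max
    rate and time-to-peak are similarly per-loom and then averaged, with
    time-to-peak ties broken to the earliest bin.
    """
    spikes = np.sort(np.asarray(spike_times, float))
    onsets = np.asarray(bout_onsets, float)
    if onsets.size == 0:
        raise ValueError("need at least one loom bout")
    mean_rates, max_rates, t_peaks = [], [], []
    for i in range(n_looms):
        loom_events = onsets + i * loom_s
        psth, edges = compute_psth(spikes, loom_events, (0.0, loom_s), bin_s)
        mean_rates.append(float(psth.mean()))
        max_rates.append(float(psth.max()))
        t_peaks.append(float(edges[int(np.argmax(psth))] + bin_s / 2))
    any_spikes = any(m > 0 for m in mean_rates)
    return {
        "mean_rate": float(np.mean(mean_rates)),
        "max_rate": float(np.mean(max_rates)),
        "time_to_peak": float(np.mean(t_peaks)) if any_spikes else math.nan,
        "per_loom_rates": np.asarray(mean_rates),
        "defined": any_spikes,
    }


# ---------------------------------------------------------------------------
# behavioural gating: motion and pupil
# ---------------------------------------------------------------------------

def classify_motion(
    frame_energy: np.ndarray,
    repetition_frames: list[np.ndarray] | None = None,
    seed: int = 0,
) -> dict:
    """Two-class k-means split of frame-difference energy into moving/still.

    ``frame_energy`` is the per-frame sum of squared pixel differences
    between neighbouring frames.  The class with the higher mean is
    "moving".  When ``repetition_frames`` (frame indices per stimulus
    repetition) is given, a repetition is flagged as running when more than
    half of its frames are moving.
    """
    e = np.asarray(frame_energy, float).reshape(-1, 1)
    if e.size < 2:
        raise ValueError("need at least 2 frames")
    if np.allclose(e, e[0]):
        moving = np.zeros(e.size, dtype=bool)
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(e)
        hi = int(np.argmax(km.cluster_centers_.ravel()))
        moving = km.labels_ == hi
    out = {"moving": moving, "proportion_moving": float(moving.mean())}
    if repetition_frames is not None:
        out["running_repetitions"] = np.array(
            [bool(moving[np.asarray(idx, int)].mean() > 0.5) for idx in repetition_frames]
        )
    return out


def pupil_diameter(boundary_points: list[np.ndarray]) -> np.ndarray:
    """Pupil diameter per frame from boundary points via ellipse fitting.

    Fits a least-squares ellipse to >=5 boundary points per frame and
    returns the major-axis length (2·max semi-axis); frames with too few
    or degenerate (collinear) points give NaN.
    """
    diams = np.full(len(boundary_points), np.nan)
    for i, pts in enumerate(boundary_points):
        pts = np.asarray(pts, float)
        if pts.shape[0] < 5:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if hasattr(EllipseModel, "from_estimate"):
                model = EllipseModel.from_estimate(pts)
                if not model:
                    continue
                a, b = model.axis_lengths
            else:  # older scikit-image
                model = EllipseModel()
                if not model.estimate(pts) or model.params is None:
                    continue
                _, _, a, b, _ = model.params
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
            continue
        diams[i] = 2.0 * max(a, b)
    return diams
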