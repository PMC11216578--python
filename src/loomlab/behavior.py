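"""Quantification of looming-escape behaviour in the open arena.

Implements the arena-session analysis chain: speed smoothing, closed-loop
trigger emulation, escape classification and timing, immediate speed-change
(arrest vs escape) categorisation, shelter-exit / occupancy metrics,
positional covariates at stimulus onset and cohort aggregation.

Conventions
-----------
Coordinates are in cm with the origin at the arena centre.  Time is in
seconds from session start; all intervals are half-open ``[start, end)``.
The shelter is a square of side ``shelter_side`` centred on
``shelter_center``; the threat zone is the region beyond ``trigger_radius``
cm from the shelter centre.

An escape is a trial in which the animal returns to the shelter within 7 s
of stimulus onset and reaches at least 20 cm/s; the reaction time is the
time from stimulus onset to the maximum of the smoothed speed between onset
and shelter entry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "EscapeMetrics",
    "compute_speed",
    "emulate_closed_loop",
    "shelter_occupancy",
    "classify_escape",
    "immediate_speed_change",
    "detect_shelter_exits",
    "occupancy_metrics",
    "positional_covariates",
    "aggregate_cohort",
]

#: escape criteria (shelter return deadline s, minimum peak speed cm/s)
ESCAPE_RETURN_S = 7.0
ESCAPE_MIN_SPEED = 20.0
#: duration of a single loom (expansion + hold), s
LOOM_S = 0.75
N_LOOMS = 5


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and timing of the behavioural arena.

    Defaults follow the standard paradigm: 32-cm square arena, 9-cm shelter
    in a corner, 10-cm trigger radius with a 30-s refractory period, and
    7-/14-cm centre/edge radii for occupancy metrics.
    """

    arena_side: float = 32.0
    shelter_center: tuple[float, float] = (-11.5, -11.5)
    shelter_side: float = 9.0
    trigger_radius: float = 10.0
    refractory_s: float = 30.0
    center_radius: float = 7.0
    edge_radius: float = 14.0
    frame_rate: float = 60.0
    #: hysteresis dilation for "full body out" shelter exits, cm
    exit_dilation: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.center_radius < self.edge_radius < self.arena_side:
            raise ValueError("need 0 < center_radius < edge_radius < arena_side")
        if self.trigger_radius <= self.shelter_side / 2:
            raise ValueError("trigger_radius must exceed shelter_side/2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        half = self.arena_side / 2
        sx, sy = self.shelter_center
        if abs(sx) > half or abs(sy) > half:
            raise ValueError("shelter centre outside arena")

    @property
    def half_side(self) -> float:
        return self.arena_side / 2

    def in_shelter(self, x, y, dilation: float = 0.0) -> np.ndarray:
        """Boolean mask: is the point inside the (optionally dilated) shelter."""
        half = self.shelter_side / 2 + dilation
        sx, sy = self.shelter_center
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (np.abs(x - sx) <= half) & (np.abs(y - sy) <= half)

    def shelter_distance(self, x, y) -> np.ndarray:
        """Euclidean distance (cm) from the shelter centre."""
        sx, sy = self.shelter_center
        return np.hypot(np.asarray(x, float) - sx, np.asarray(y, float) - sy)


@dataclass
class EscapeMetrics:
    """Per-trial escape classification and timing."""

    is_escape: bool
    reaction_time: float  # s, NaN when not an escape
    max_escape_speed: float  # cm/s, NaN when not an escape
    looms_to_escape: str  # "1".."5", ">5" or "NR"
    shelter_entry: float  # s after onset, NaN if never returned
    valid: bool = True
    s_at: float = math.nan
    s_im: float = math.nan
    category: str = ""
    log_speed_ratio: float = math.nan
    directedness: float = math.nan


def compute_speed(
    trajectory: pd.DataFrame, window_ms: float = 83.0
) -> pd.DataFrame:
    """Smoothed locomotion speed from a tracked trajectory.

    The speed is the frame-to-frame displacement rate smoothed with a
    centred moving mean over ``window_ms`` (rounded to the nearest odd
    number of frames; 5 frames at 60 Hz).  Edges use shrinking windows.

    Parameters
    ----------
    trajectory
        DataFrame with columns ``time_s``, ``x_cm``, ``y_cm``.
    window_ms
        Width of the moving-mean window in milliseconds.

    Returns
    -------
    DataFrame with columns ``time_s`` and ``speed`` (cm/s), same length as
    the input.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 frames to compute speed")
    t = trajectory["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dx = np.diff(trajectory["x_cm"].to_numpy(dtype=float))
    dy = np.diff(trajectory["y_cm"].to_numpy(dtype=float))
    inst = np.hypot(dx, dy) / dt
    # assign the displacement rate to the later frame; frame 0 copies frame 1
    inst = np.concatenate([[inst[0]], inst])
    frame_s = float(np.median(dt))
    n_win = max(1, int(round(window_ms / 1000.0 / frame_s)))
    if n_win % 2 == 0:
        n_win += 1
    speed = (
        pd.Series(inst).rolling(n_win, center=True, min_periods=1).mean().to_numpy()
    )
    return pd.DataFrame({"time_s": t, "speed": speed})


def emulate_closed_loop(
    trajectory: pd.DataFrame, config: ArenaConfig
) -> pd.DataFrame:
    """Closed-loop stimulus log from a trajectory.

    A stimulus onset is recorded at each outward crossing of
    ``trigger_radius`` (distance from shelter centre) provided at least
    ``refractory_s`` seconds have passed since the previous onset.

    Returns a StimulusLog DataFrame with columns ``onset_s`` and
    ``trigger_index`` (frame index of the crossing).
    """
    x = trajectory["x_cm"].to_numpy(dtype=float)
    y = trajectory["y_cm"].to_numpy(dtype=float)
    t = trajectory["time_s"].to_numpy(dtype=float)
    half = config.half_side
    if np.any(np.abs(x) > half + 1e-9) or np.any(np.abs(y) > half + 1e-9):
        warnings.warn("trajectory outside arena bounds; clamping for distances")
        x = np.clip(x, -half, half)
        y = np.clip(y, -half, half)
    dist = config.shelter_distance(x, y)
    beyond = dist >= config.trigger_radius
    crossings = np.flatnonzero(beyond[1:] & ~beyond[:-1]) + 1
    onsets: list[float] = []
    idx: list[int] = []
    last = -np.inf
    for i in crossings:
        if t[i] - last >= config.refractory_s:
            onsets.append(t[i])
            idx.append(int(i))
            last = t[i]
    return pd.DataFrame({"onset_s": onsets, "trigger_index": idx})


def shelter_occupancy(trajectory: pd.DataFrame, config: ArenaConfig) -> np.ndarray:
    """Per-frame boolean: centroid inside the (undilated) shelter polygon."""
    return config.in_shelter(
        trajectory["x_cm"].to_numpy(float), trajectory["y_cm"].to_numpy(float)
    )


def _looms_label(reaction_time: float) -> str:
    if reaction_time > N_LOOMS * LOOM_S:
        return ">5"
    # half-open loom windows [(i-1)*0.75, i*0.75); boundary goes to later loom
    loom = int(math.floor(reaction_time / LOOM_S)) + 1
    return str(min(loom, N_LOOMS))


def classify_escape(
    onset_s: float,
    speed: pd.DataFrame,
    in_shelter: np.ndarray,
    config: ArenaConfig | None = None,
    trajectory: pd.DataFrame | None = None,
) -> EscapeMetrics:
    """Classify a single stimulated trial as escape / no-response.

    ``speed`` must cover the peristimulus window (−3 s to +10 s around
    onset).  The shelter-entry time is the first frame inside the shelter
    after onset; the reaction time is the time of the speed maximum in the
    half-open interval (onset, entry].  When ``trajectory`` is given, the
    escape directedness (path length / shortest distance to the shelter
    edge) is also computed.
    """
    config = config or ArenaConfig()
    t = speed["time_s"].to_numpy(float)
    v = speed["speed"].to_numpy(float)
    i0 = int(np.searchsorted(t, onset_s))
    if i0 >= len(t):
        raise ValueError("stimulus onset outside speed series")
    if in_shelter[max(i0 - 1, 0)] and in_shelter[i0]:
        return EscapeMetrics(False, math.nan, math.nan, "NR", math.nan, valid=False)

    after = np.flatnonzero(in_shelter[i0 + 1 :]) + i0 + 1
    entry_i = int(after[0]) if after.size else -1
    entry_s = t[entry_i] - onset_s if entry_i >= 0 else math.nan

    if entry_i > i0:
        seg = slice(i0 + 1, entry_i + 1)
    else:
        seg = slice(i0 + 1, int(np.searchsorted(t, onset_s + 10.0)))
    vmax_i = i0 + 1 + int(np.argmax(v[seg])) if v[seg].size else i0
    vmax = float(v[vmax_i])
    rt = float(t[vmax_i] - onset_s)

    is_escape = (
        entry_i >= 0 and entry_s <= ESCAPE_RETURN_S and vmax >= ESCAPE_MIN_SPEED
    )
    if not is_escape:
        return EscapeMetrics(False, math.nan, math.nan, "NR", entry_s)

    metrics = EscapeMetrics(True, rt, vmax, _looms_label(rt), entry_s)
    if trajectory is not None and entry_i > i0:
        x = trajectory["x_cm"].to_numpy(float)
        y = trajectory["y_cm"].to_numpy(float)
        path = float(
            np.sum(np.hypot(np.diff(x[i0 : entry_i + 1]), np.diff(y[i0 : entry_i + 1])))
        )
        shortest = float(
            config.shelter_distance(x[i0], y[i0]) - config.shelter_side / 2
        )
        if shortest > 0:
            metrics.directedness = max(path / shortest, 1.0)
    return metrics


def immediate_speed_change(
    trials: pd.DataFrame,
    speed_by_trial: dict | None = None,
) -> pd.DataFrame:
    """S_at / S_im categorisation of the immediate response to the stimulus.

    ``trials`` must contain ``s_at`` and ``s_im`` columns (mean speed over
    onset ±50 ms and onset +[300, 800) ms respectively) and a ``genotype``
    column.  Responses are categorised as ``increase`` / ``decrease`` /
    ``no_change`` depending on whether S_im is more than 1 SD above, more
    than 1 SD below, or within 1 SD of S_at, where the SD is that of the
    pooled S_at values of all trials of the same genotype.

    Returns the input with ``category`` and ``log_speed_ratio``
    (log10(S_im/S_at)) columns added.
    """
    out = trials.copy()
    out["category"] = ""
    out["log_speed_ratio"] = np.nan
    for geno, sub in out.groupby("genotype"):
        if len(sub) < 2:
            raise ValueError(f"need >=2 trials for genotype {geno!r} to define SD")
        sd = float(sub["s_at"].std(ddof=1))
        diff = sub["s_im"] - sub["s_at"]
        cat = np.where(diff > sd, "increase", np.where(diff < -sd, "decrease", "no_change"))
        out.loc[sub.index, "category"] = cat
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log10(sub["s_im"].to_numpy() / sub["s_at"].to_numpy())
        ratio[~np.isfinite(ratio)] = np.nan
        out.loc[sub.index, "log_speed_ratio"] = ratio
    return out


def window_speeds(
    onset_s: float, speed: pd.DataFrame
) -> tuple[float, float]:
    """Mean speed at onset (±50 ms) and immediately after (+300 to +800 ms)."""
    t = speed["time_s"].to_numpy(float)
    v = speed["speed"].to_numpy(float)
    at = (t >= onset_s - 0.05) & (t < onset_s + 0.05)
    im = (t >= onset_s + 0.3) & (t < onset_s + 0.8)
    s_at = float(v[at].mean()) if at.any() else math.nan
    s_im = float(v[im].mean()) if im.any() else math.nan
    return s_at, s_im


def detect_shelter_exits(
    trajectory: pd.DataFrame, config: ArenaConfig
) -> pd.DataFrame:
    """Shelter-exit episodes with a hysteresis rule.

    A "full body" exit is approximated by the centroid crossing the shelter
    boundary dilated by ``config.exit_dilation`` cm; the episode ends at
    re-entry into the undilated shelter.  Each exit is annotated with its
    maximum straight-line distance from the shelter centre, duration, and
    whether the threat zone (``trigger_radius``) was entered.
    """
    x = trajectory["x_cm"].to_numpy(float)
    y = trajectory["y_cm"].to_numpy(float)
    t = trajectory["time_s"].to_numpy(float)
    inside = config.in_shelter(x, y)
    outside_dilated = ~config.in_shelter(x, y, dilation=config.exit_dilation)
    dist = config.shelter_distance(x, y)

    rows = []
    out = False
    start = 0
    for i in range(len(t)):
        if not out and outside_dilated[i]:
            out, start = True, i
        elif out and inside[i]:
            seg = slice(start, i)
            rows.append(
                {
                    "exit_start_s": t[start],
                    "exit_end_s": t[i],
                    "duration_s": t[i] - t[start],
                    "max_distance_cm": float(dist[seg].max()),
                    "entered_threat_zone": bool(
                        (dist[seg] >= config.trigger_radius).any()
                    ),
                }
            )
            out = False
    exits = pd.DataFrame(
        rows,
        columns=[
            "exit_start_s",
            "exit_end_s",
            "duration_s",
            "max_distance_cm",
            "entered_threat_zone",
        ],
    )
    if len(exits) > 1:
        exits["interbout_interval_s"] = np.concatenate(
            [[np.nan], exits["exit_start_s"].to_numpy()[1:] - exits["exit_end_s"].to_numpy()[:-1]]
        )
    else:
        exits["interbout_interval_s"] = np.nan
    return exits


def occupancy_metrics(
    trajectory: pd.DataFrame, config: ArenaConfig, analysis_s: float = 600.0
) -> dict:
    """Occupancy percentages over the first ``analysis_s`` seconds.

    Percent of frames spent out of the shelter, inside the central disc
    (``center_radius`` from the arena centre) and outside the edge disc
    (``edge_radius``), plus mean/max smoothed speed.
    """
    t = trajectory["time_s"].to_numpy(float)
    if t[-1] - t[0] < analysis_s:
        warnings.warn("session shorter than the analysis window; using full span")
    mask = t < t[0] + analysis_s
    sub = trajectory.loc[mask]
    x = sub["x_cm"].to_numpy(float)
    y = sub["y_cm"].to_numpy(float)
    r_center = np.hypot(x, y)
    in_shelter = config.in_shelter(x, y)
    speed = compute_speed(sub)["speed"].to_numpy() if len(sub) > 1 else np.zeros(1)
    n = len(sub)
    return {
        "pct_time_out": 100.0 * float((~in_shelter).sum()) / n,
        "pct_time_center": 100.0 * float((r_center <= config.center_radius).sum()) / n,
        "pct_time_edge": 100.0 * float((r_center > config.edge_radius).sum()) / n,
        "mean_speed": float(speed.mean()),
        "max_speed": float(speed.max()),
    }


def positional_covariates(
    onset_s: float,
    trajectory: pd.DataFrame,
    config: ArenaConfig,
) -> dict:
    """Position, speed and heading covariates at the stimulus-onset frame.

    The heading angle is the angle at the back-paw midpoint B between the
    snout A and the shelter centre C, in degrees within [0, 180].  Missing
    snout/back columns leave the heading as NaN.
    """
    t = trajectory["time_s"].to_numpy(float)
    i = int(np.clip(np.searchsorted(t, onset_s), 0, len(t) - 1))
    row = trajectory.iloc[i]
    out = {
        "distance_to_shelter": float(
            config.shelter_distance(row["x_cm"], row["y_cm"])
        ),
        "speed_at_onset": math.nan,
        "heading_angle": math.nan,
    }
    if len(trajectory) > 1:
        out["speed_at_onset"] = float(compute_speed(trajectory)["speed"].iloc[i])
    cols = {"snout_x", "snout_y", "back_x", "back_y"}
    if cols.issubset(trajectory.columns) and not row[list(cols)].isna().any():
        b = np.array([row["back_x"], row["back_y"]], float)
        a = np.array([row["snout_x"], row["snout_y"]], float)
        c = np.asarray(config.shelter_center, float)
        u, w = a - b, c - b
        nu, nw = np.linalg.norm(u), np.linalg.norm(w)
        if nu > 0 and nw > 0:
            cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
            out["heading_angle"] = float(np.degrees(np.arccos(cosang)))
    return out


def aggregate_cohort(trial_metrics: pd.DataFrame) -> dict:
    """Cohort aggregation of per-trial metrics.

    ``trial_metrics`` needs columns ``animal``, ``genotype``, ``day``,
    ``is_escape``, ``reaction_time``, ``max_escape_speed`` and optionally
    ``n_exits`` / ``category``.  Behavioural metrics are the mean across
    escape trials for each animal, then averaged across animals within a
    genotype; animals with zero escapes are excluded from the
    reaction-time/vigour averages but retained in trial counts.

    Returns a dict with ``per_animal``, ``per_genotype``, ``per_day`` and a
    ``category_table`` contingency table (genotype x category) when
    categories are present.
    """
    df = trial_metrics.copy()
    esc = df[df["is_escape"].astype(bool)]
    per_animal = (
        esc.groupby(["genotype", "animal"])
        .agg(
            reaction_time=("reaction_time", "mean"),
            max_escape_speed=("max_escape_speed", "mean"),
            n_escapes=("is_escape", "size"),
        )
        .reset_index()
    )
    counts = (
        df.groupby(["genotype", "animal"])
        .agg(n_trials=("is_escape", "size"))
        .reset_index()
    )
    per_animal = counts.merge(per_animal, on=["genotype", "animal"], how="left")
    per_animal["n_escapes"] = per_animal["n_escapes"].fillna(0).astype(int)
    per_genotype = (
        per_animal.groupby("genotype")
        .agg(
            reaction_time=("reaction_time", "mean"),
            max_escape_speed=("max_escape_speed", "mean"),
            n_trials=("n_trials", "sum"),
        )
        .reset_index()
    )
    per_day = (
        esc.groupby(["genotype", "day"])
        .agg(reaction_time=("reaction_time", "mean"))
        .reset_index()
        if "day" in df.columns
        else pd.DataFrame()
    )
    out = {
        "per_animal": per_animal,
        "per_genotype": per_genotype,
        "per_day": per_day,
    }
    if "category" in df.columns and df["category"].astype(bool).any():
        out["category_table"] = pd.crosstab(df["genotype"], df["category"])
    return out
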