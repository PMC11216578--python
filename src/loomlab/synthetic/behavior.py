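"""Synthetic arena sessions with known ground truth.

The locomotion model is a four-state semi-Markov agent
(shelter / explore / arrest / escape):

* in the shelter the animal idles with small positional jitter;
* an exploration bout is a smooth out-and-back excursion towards a random
  target, with speed following a mean-reverting (Ornstein–Uhlenbeck,
  positive-clipped) process;
* crossing the trigger radius outward (with the 30-s refractory rule)
  triggers a looming bout.  The agent then either escapes — a short
  risk-assessment slowdown followed by a straight run to the shelter whose
  speed profile is a raised-cosine bump peaking at the drawn peak speed —
  or arrests (near-zero speed with residual jitter) and later walks back
  below the escape-speed criterion;
* escape occurs iff any of the five per-loom Bernoulli draws at
  ``escape_prob_per_loom`` succeeds; the escape latency (true time of
  maximum speed) is drawn from a shifted log-normal so the genotype's
  latency median is an exact generator input.

Every latent label, latency and peak speed is recorded, so the behaviour
stage can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..behavior import ArenaConfig, LOOM_S, N_LOOMS

__all__ = ["BehaviorSimParams", "BehaviorGroundTruth", "gen_ler_session"]


@dataclass(frozen=True)
class BehaviorSimParams:
    """Parameters of the synthetic arena session.

    Defaults emulate the standard paradigm: 32-cm arena, 9-cm corner
    shelter, 10-cm trigger radius, 60 Hz tracking, wild-type-like escape
    statistics (latency median 0.3 s, peak escape speed ~65 cm/s).
    """

    arena_side: float = 32.0
    shelter_center: tuple[float, float] = (-11.5, -11.5)
    shelter_side: float = 9.0
    trigger_radius: float = 10.0
    frame_rate: float = 60.0
    session_length: float = 540.0
    #: shifted log-normal escape latency: median (s), log-sd shape, shift (s)
    latency_median: float = 0.3
    latency_shape: float = 0.5
    latency_shift: float = 0.25
    escape_prob_per_loom: float = 0.9
    arrest_prob: float = 1.0
    peak_escape_speed: tuple[float, float] = (65.0, 8.0)  # mean, sd cm/s
    explore_speed_mean: float = 8.0
    explore_speed_relax_s: float = 0.5
    explore_speed_sd: float = 2.5
    exits_per_session: float = 12.0
    adaptation_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("escape_prob_per_loom", "arrest_prob"):
            p = getattr(self, name)
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not self.trigger_radius < self.arena_side / 2:
            raise ValueError("trigger_radius must be < arena_side/2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (np.isfinite(self.latency_median) and self.latency_median > 0):
            raise ValueError("latency median must be positive and finite")
        if self.latency_shift >= self.latency_median:
            raise ValueError("latency_shift must be below the latency median")
        half = self.arena_side / 2
        sx, sy = self.shelter_center
        if abs(sx) + self.shelter_side / 2 > half or abs(sy) + self.shelter_side / 2 > half:
            raise ValueError("shelter outside arena")
        if not all(np.isfinite(v) for v in (self.session_length, self.exits_per_session)):
            raise ValueError("non-finite parameter")

    def arena_config(self) -> ArenaConfig:
        return ArenaConfig(
            arena_side=self.arena_side,
            shelter_center=self.shelter_center,
            shelter_side=self.shelter_side,
            trigger_radius=self.trigger_radius,
            frame_rate=self.frame_rate,
        )


#: preset parameter sets for the two genotype-like study conditions
WT_PRESET = BehaviorSimParams()
MUTANT_PRESET = replace(
    WT_PRESET,
    latency_median=1.5,
    escape_prob_per_loom=0.45,
    peak_escape_speed=(50.0, 8.0),
    exits_per_session=24.0,
)


@dataclass
class BehaviorGroundTruth:
    """Latent labels of a generated session."""

    states: np.ndarray  # per-frame labels: shelter/explore/arrest/escape
    trials: pd.DataFrame  # onset_s, response, latency_s, peak_speed, loom
    exits: pd.DataFrame  # exit_start_s, exit_end_s, max_distance_cm, threat
    seed: int = 0


class _Agent:
    """Frame-stepping state machine used by :func:`gen_ler_session`."""

    def __init__(self, params: BehaviorSimParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.dt = 1.0 / params.frame_rate
        self.shelter = np.asarray(params.shelter_center, float)
        self.half = params.arena_side / 2
        self.pos = self.shelter.copy()
        self.speed = 0.0

    def _clip_arena(self, pos: np.ndarray) -> np.ndarray:
        m = self.half - 0.2
        return np.clip(pos, -m, m)

    def _ou_speed(self) -> float:
        p = self.p
        a = math.exp(-self.dt / p.explore_speed_relax_s)
        noise = p.explore_speed_sd * math.sqrt(1 - a * a)
        raw = (
            p.explore_speed_mean
            + a * (self.speed - p.explore_speed_mean)
            + noise * self.rng.standard_normal()
        )
        # clip to [0, mean + 3 sd]: exploration never mimics an escape sprint
        self.speed = min(max(raw, 0.0), p.explore_speed_mean + 3 * p.explore_speed_sd)
        return self.speed

    def step_towards(self, target: np.ndarray, speed: float) -> None:
        d = target - self.pos
        dist = float(np.hypot(*d))
        move = min(speed * self.dt, dist)
        if dist > 1e-9:
            self.pos = self._clip_arena(self.pos + d / dist * move)


def _draw_latency(p: BehaviorSimParams, rng: np.random.Generator) -> float:
    mu = math.log(p.latency_median - p.latency_shift)
    lat = p.latency_shift + rng.lognormal(mu, p.latency_shape)
    return float(min(lat, N_LOOMS * LOOM_S + 1.2))


def gen_ler_session(
    params: BehaviorSimParams,
    n_days: int = 1,
    stimulus_kind: str = "loom",
) -> tuple[pd.DataFrame, pd.DataFrame, BehaviorGroundTruth]:
    """Generate a tracked arena session with closed-loop stimulation.

    Returns ``(tracked_session, stimulus_log, ground_truth)``.  The tracked
    session has columns ``time_s, x_cm, y_cm, snout_x, snout_y, back_x,
    back_y, day``; the stimulus log has ``onset_s, trigger_index, kind``.
    Time is continuous across days (day d starts at ``d *
    session_length``).  Identical parameters and seed give bit-identical
    output.
    """
    if stimulus_kind not in ("loom", "laser"):
        raise ValueError(f"unknown stimulus kind {stimulus_kind!r}")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.Generator(np.random.Philox(params.seed))
    agent = _Agent(params, rng)
    dt = agent.dt
    refractory = 30.0

    times: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    states: list[str] = []
    headings: list[float] = []
    stim_rows: list[dict] = []
    trial_rows: list[dict] = []
    exit_rows: list[dict] = []

    last_stim = -math.inf
    frame = 0
    heading = 0.0

    def emit(state: str, t: float) -> None:
        nonlocal frame, heading
        times.append(t)
        xs.append(agent.pos[0])
        ys.append(agent.pos[1])
        states.append(state)
        headings.append(heading)
        frame += 1

    for day in range(n_days):
        t0_day = day * params.session_length
        t_end = t0_day + params.session_length
        exit_rate = params.exits_per_session * params.adaptation_factor**day
        dwell_mean = max(params.session_length / max(exit_rate, 0.5) * 0.55, 2.0)
        t = t0_day
        agent.pos = agent.shelter.copy()
        agent.speed = 0.0
        prev_beyond = False

        while t < t_end:
            # --- shelter dwell (gentle drift to centre, then jitter) ---
            dwell = rng.exponential(dwell_mean)
            n_dwell = max(int(dwell / dt), 1)
            for _ in range(n_dwell):
                if t >= t_end:
                    break
                if float(np.hypot(*(agent.pos - agent.shelter))) > 0.3:
                    agent.step_towards(agent.shelter, 3.0)
                else:
                    agent.pos = agent._clip_arena(
                        agent.pos
                        + 0.05 * (agent.shelter - agent.pos)
                        + rng.normal(0.0, 0.01, 2)
                    )
                emit("shelter", t)
                t += dt
            if t >= t_end:
                break

            # --- exploration bout ---
            d_max = rng.uniform(5.0, 0.92 * agent.half * math.sqrt(2))
            ang = rng.uniform(0, 2 * math.pi)
            target = agent._clip_arena(
                agent.shelter + d_max * np.array([math.cos(ang), math.sin(ang)])
            )
            exit_start = t
            max_dist = 0.0
            max_cheb = 0.0
            threat = False
            completed = False
            phase = "out"
            while t < t_end:
                goal = target if phase == "out" else agent.shelter
                sp = agent._ou_speed()
                agent.step_towards(goal, sp)
                vec = goal - agent.pos
                if np.hypot(*vec) > 1e-6:
                    heading = math.atan2(vec[1], vec[0])
                dist = float(np.hypot(*(agent.pos - agent.shelter)))
                max_dist = max(max_dist, dist)
                max_cheb = max(max_cheb, float(np.abs(agent.pos - agent.shelter).max()))
                threat = threat or dist >= params.trigger_radius
                emit("explore", t)
                t += dt
                beyond = dist >= params.trigger_radius
                trigger = (
                    beyond and not prev_beyond and t - dt - last_stim >= refractory
                )
                prev_beyond = beyond
                if trigger:
                    onset = times[-1]
                    last_stim = onset
                    stim_rows.append(
                        {
                            "onset_s": onset,
                            "trigger_index": frame - 1,
                            "kind": stimulus_kind,
                        }
                    )
                    t, _ = _respond(
                        agent, rng, params, onset, t, t_end, emit, trial_rows
                    )
                    prev_beyond = False
                    completed = _in_shelter(agent, params)
                    break
                if phase == "out" and float(np.hypot(*(agent.pos - goal))) < 0.5:
                    phase = "back"
                elif phase == "back" and _in_shelter(agent, params):
                    completed = True
                    break
            exit_rows.append(
                {
                    "exit_start_s": exit_start,
                    "exit_end_s": t,
                    "max_distance_cm": max_dist,
                    "entered_threat_zone": threat,
                    # did the centroid cross the +2 cm dilated shelter boundary
                    "full_exit": max_cheb > params.shelter_side / 2 + 2.0,
                    "completed": completed,
                }
            )
            agent.speed = 0.0

    tracked = pd.DataFrame(
        {
            "time_s": np.asarray(times),
            "x_cm": np.asarray(xs),
            "y_cm": np.asarray(ys),
        }
    )
    h = np.asarray(headings)
    tracked["snout_x"] = tracked["x_cm"] + 1.5 * np.cos(h)
    tracked["snout_y"] = tracked["y_cm"] + 1.5 * np.sin(h)
    tracked["back_x"] = tracked["x_cm"] - 1.5 * np.cos(h)
    tracked["back_y"] = tracked["y_cm"] - 1.5 * np.sin(h)
    tracked["day"] = (tracked["time_s"] // params.session_length).astype(int)
    stim_log = pd.DataFrame(stim_rows, columns=["onset_s", "trigger_index", "kind"])
    truth = BehaviorGroundTruth(
        states=np.asarray(states, dtype=object),
        trials=pd.DataFrame(
            trial_rows,
            columns=["onset_s", "response", "latency_s", "peak_speed", "loom"],
        ),
        exits=pd.DataFrame(
            exit_rows,
            columns=[
                "exit_start_s",
                "exit_end_s",
                "max_distance_cm",
                "entered_threat_zone",
                "full_exit",
                "completed",
            ],
        ),
        seed=params.seed,
    )
    return tracked, stim_log, truth


def _in_shelter(agent: _Agent, params: BehaviorSimParams) -> bool:
    half = params.shelter_side / 2
    d = np.abs(agent.pos - agent.shelter)
    return bool(d[0] <= half - 1.0 and d[1] <= half - 1.0)


def _respond(agent, rng, params, onset, t, t_end, emit, trial_rows):
    """Play out the response to a triggered loom bout; returns (t, ended)."""
    dt = agent.dt
    escapes = rng.random(N_LOOMS) < params.escape_prob_per_loom
    if escapes.any():
        latency = _draw_latency(params, rng)
        peak = max(
            float(rng.normal(*params.peak_escape_speed)), 25.0
        )
        d_start = float(np.hypot(*(agent.pos - agent.shelter)))
        width = 2.0 * d_start / peak
        delay = max(latency - width / 2.0, 2 * dt)
        t_peak = delay + width / 2.0  # true reaction time
        # risk-assessment slowdown during the hazard delay
        n_delay = int(round(delay / dt))
        for k in range(n_delay):
            if t >= t_end:
                break
            agent.pos = agent._clip_arena(agent.pos + rng.normal(0, 0.01, 2))
            emit("arrest", t)
            t += dt
        # raised-cosine escape run straight to the shelter
        n_run = int(round(width / dt))
        start_run = t
        for k in range(n_run):
            if t >= t_end:
                break
            tau = (k + 0.5) * dt
            sp = peak * 0.5 * (1 - math.cos(2 * math.pi * tau / width))
            agent.step_towards(agent.shelter, sp)
            emit("escape", t)
            t += dt
            if _in_shelter(agent, params) and tau > width / 2:
                break
        trial_rows.append(
            {
                "onset_s": onset,
                "response": "escape",
                "latency_s": t_peak,
                "peak_speed": peak,
                "loom": min(int(t_peak // LOOM_S) + 1, N_LOOMS + 1),
            }
        )
        return t, True
    if rng.random() < params.arrest_prob:
        arrest_dur = rng.uniform(2.0, 5.0)
        n_arr = int(round(arrest_dur / dt))
        for _ in range(n_arr):
            if t >= t_end:
                break
            agent.pos = agent._clip_arena(agent.pos + rng.normal(0, 0.01, 2))
            emit("arrest", t)
            t += dt
        # slow walk back, capped below the escape-speed criterion
        while t < t_end and not _in_shelter(agent, params):
            sp = min(agent._ou_speed(), 13.0)
            agent.step_towards(agent.shelter, sp)
            emit("arrest", t)
            t += dt
        trial_rows.append(
            {
                "onset_s": onset,
                "response": "arrest",
                "latency_s": math.nan,
                "peak_speed": math.nan,
                "loom": 0,
            }
        )
        return t, True
    trial_rows.append(
        {
            "onset_s": onset,
            "response": "ignore",
            "latency_s": math.nan,
            "peak_speed": math.nan,
            "loom": 0,
        }
    )
    return t, False
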