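"""Readers/writers for the on-disk formats and the pipeline driver.

Tracked sessions and stimulus logs are CSV; per-trial and per-unit metrics
are TSV; sweep sets use an HDF5 container (one dataset per sweep with
protocol attributes); peptidoform matrices are TSV.  Run configuration is
YAML, archived alongside outputs with a content hash.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SessionBundle",
    "save_session",
    "load_bundle",
    "save_sweep_set",
    "load_sweep_set",
    "load_config",
    "archive_config",
    "run_pipeline",
]

TRACKED_COLUMNS = ["time_s", "x_cm", "y_cm"]
STIM_COLUMNS = ["onset_s"]


@dataclass
class SessionBundle:
    tracked: pd.DataFrame
    stimuli: pd.DataFrame
    metadata: dict


def save_session(
    tracked: pd.DataFrame, stimuli: pd.DataFrame, metadata: dict, out_dir: Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracked.to_csv(out_dir / "tracked.csv", index=False)
    stimuli.to_csv(out_dir / "stimuli.csv", index=False)
    (out_dir / "metadata.json").write_text(json.dumps(metadata, indent=1))


def load_bundle(session_dir: Path) -> SessionBundle:
    """Load and validate a tracked session + stimulus log.

    Schema violations report the offending column; stimulus onsets outside
    the session time span are a hard error.
    """
    session_dir = Path(session_dir)
    tracked = pd.read_csv(session_dir / "tracked.csv")
    stimuli = pd.read_csv(session_dir / "stimuli.csv")
    meta_path = session_dir / "metadata.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    for col in TRACKED_COLUMNS:
        if col not in tracked.columns:
            raise ValueError(f"tracked.csv missing required column {col!r}")
    for col in STIM_COLUMNS:
        if col not in stimuli.columns:
            raise ValueError(f"stimuli.csv missing required column {col!r}")
    t = tracked["time_s"]
    if len(stimuli) and (
        (stimuli["onset_s"] < t.min()).any() or (stimuli["onset_s"] > t.max()).any()
    ):
        bad = stimuli.index[
            (stimuli["onset_s"] < t.min()) | (stimuli["onset_s"] > t.max())
        ].tolist()
        raise ValueError(f"stimulus onsets outside session span at rows {bad}")
    return SessionBundle(tracked, stimuli, metadata)


def save_sweep_set(sweep_set, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["mode"] = sweep_set.mode
        f.attrs["sampling_hz"] = sweep_set.sampling_hz
        f.attrs["step_start_s"] = sweep_set.step_start_s
        f.attrs["step_dur_s"] = sweep_set.step_dur_s
        f.attrs["hold_mv"] = sweep_set.hold_mv
        f.create_dataset("times", data=sweep_set.times)
        f.create_dataset("commands", data=sweep_set.commands)
        for i in range(sweep_set.sweeps.shape[0]):
            f.create_dataset(f"sweep_{i:03d}", data=sweep_set.sweeps[i])


def load_sweep_set(path: Path):
    from .synthetic.patch import SweepSet

    with h5py.File(path, "r") as f:
        names = sorted(k for k in f.keys() if k.startswith("sweep_"))
        sweeps = np.vstack([f[k][()] for k in names])
        return SweepSet(
            mode=str(f.attrs["mode"]),
            times=f["times"][()],
            sweeps=sweeps,
            commands=f["commands"][()],
            sampling_hz=float(f.attrs["sampling_hz"]),
            step_start_s=float(f.attrs["step_start_s"]),
            step_dur_s=float(f.attrs["step_dur_s"]),
            hold_mv=float(f.attrs["hold_mv"]),
        )


def load_config(path: Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in cfg.get("thresholds", {}).items():
        if not (isinstance(val, (int, float)) and val > 0):
            raise ValueError(f"threshold {key!r} must be positive")
    return cfg


def archive_config(cfg: dict, out_dir: Path) -> str:
    """Write the run config next to the outputs with a content hash."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    text = yaml.safe_dump(cfg, sort_keys=True)
    digest = hashlib.sha256(text.encode()).hexdigest()[:16]
    (out_dir / f"config_{digest}.yaml").write_text(text)
    return digest


def run_pipeline(config: dict, out_dir: Path) -> dict:
    """Simulate-and-analyse driver for the behaviour modality.

    Generates the configured synthetic sessions, runs the behavioural
    analysis chain, and writes per-trial and per-animal TSVs.  Exclusions
    are logged with reasons; reruns with the same seeds are deterministic.
    """
    from . import behavior as bhv
    from .synthetic.behavior import BehaviorSimParams, gen_ler_session

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    archive_config(config, out_dir)

    seed = int(config.get("seed", 0))
    n_animals = int(config.get("n_animals", 2))
    n_days = int(config.get("n_days", 1))
    presets = config.get("genotypes", {"wt": {}, "mut": {"latency_median": 1.5}})

    trial_rows = []
    exclusions = []
    for geno, overrides in presets.items():
        for a in range(n_animals):
            geno_tag = int(hashlib.sha256(geno.encode()).hexdigest()[:4], 16)
            params = BehaviorSimParams(
                **{**overrides, "seed": (seed + 1000 * a + geno_tag) % 2**31}
            )
            tracked, stim, _ = gen_ler_session(params, n_days=n_days)
            cfg = params.arena_config()
            speed = bhv.compute_speed(tracked)
            occupancy = bhv.shelter_occupancy(tracked, cfg)
            for _, row in stim.iterrows():
                m = bhv.classify_escape(row["onset_s"], speed, occupancy, cfg)
                if not m.valid:
                    exclusions.append(
                        {"genotype": geno, "animal": a, "onset_s": row["onset_s"],
                         "reason": "in shelter at onset"}
                    )
                    continue
                s_at, s_im = bhv.window_speeds(row["onset_s"], speed)
                trial_rows.append(
                    {
                        "genotype": geno,
                        "animal": f"{geno}{a}",
                        "day": int(row["onset_s"] // params.session_length),
                        "onset_s": row["onset_s"],
                        "is_escape": m.is_escape,
                        "reaction_time": m.reaction_time,
                        "max_escape_speed": m.max_escape_speed,
                        "looms_to_escape": m.looms_to_escape,
                        "s_at": s_at,
                        "s_im": s_im,
                    }
                )
    trials = pd.DataFrame(trial_rows)
    if len(trials):
        trials = bhv.immediate_speed_change(trials)
        agg = bhv.aggregate_cohort(trials)
        agg["per_animal"].to_csv(out_dir / "per_animal.tsv", sep="\t", index=False)
    trials.to_csv(out_dir / "per_trial.tsv", sep="\t", index=False)
    pd.DataFrame(exclusions).to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
    return {"n_trials": len(trials), "n_excluded": len(exclusions)}
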