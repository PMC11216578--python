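"""Synthetic peptidoform intensity matrices with known differential truth.

Log10 intensities are built additively: protein level + peptidoform offset
(ionisation efficiency) + per-sample loading offset + batch effect +
Gaussian noise, with missingness applied at random.  A configurable subset
of proteins carries a true log2 fold change between the two sample groups;
the truth table records every protein's effect so the quantification and
testing stages can be validated by false-discovery and power simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProteomeSimParams", "gen_peptidoform_matrix"]

LOG2_OVER_LOG10 = np.log10(2.0)


@dataclass(frozen=True)
class ProteomeSimParams:
    """Parameters of the synthetic peptidoform matrix."""

    n_proteins: int = 500
    peptidoforms_mean: float = 4.0  # mean of (1 + Poisson) peptidoforms/protein
    n_per_group: int = 6
    loading_sd: float = 0.15  # per-sample log10 offset sd
    n_batches: int = 2
    batch_sd: float = 0.1  # per-batch log10 offset sd
    frac_regulated: float = 0.0
    effect_log2: float = 1.0  # true |log2 FC| of regulated proteins
    noise_sd: float = 0.08  # residual log10 noise
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("group sizes must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")


def gen_peptidoform_matrix(
    params: ProteomeSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(matrix, truth)``.

    ``matrix`` is a wide peptidoform table: ``peptidoform_id``,
    ``protein_group``, ``is_unique``, then one log10-intensity column per
    sample (named ``<group>_<batch>_<replicate>``).  ``truth`` has one row
    per protein with its true log2 fold change, regulated flag, and the
    injected per-sample loading offsets stored in ``truth.attrs``.
    """
    rng = np.random.Generator(np.random.Philox(params.seed))
    n_samples = 2 * params.n_per_group
    groups = np.array(["ctrl"] * params.n_per_group + ["mut"] * params.n_per_group)
    batches = np.tile(
        np.arange(params.n_batches), n_samples // params.n_batches + 1
    )[:n_samples]
    sample_names = [
        f"{g}_b{b}_r{i}" for i, (g, b) in enumerate(zip(groups, batches))
    ]

    loading = rng.normal(0.0, params.loading_sd, n_samples)
    loading -= loading.mean()
    batch_fx = rng.normal(0.0, params.batch_sd, params.n_batches)
    batch_fx -= batch_fx.mean()

    n_reg = int(round(params.frac_regulated * params.n_proteins))
    effects = np.zeros(params.n_proteins)
    if n_reg:
        signs = rng.choice([-1.0, 1.0], n_reg)
        effects[:n_reg] = signs * params.effect_log2
        rng.shuffle(effects)

    rows = []
    data = []
    for p in range(params.n_proteins):
        level = rng.uniform(5.0, 9.0)  # log10 abundance
        n_pep = 1 + rng.poisson(params.peptidoforms_mean - 1)
        pep_offsets = rng.normal(0.0, 0.5, n_pep)
        for q in range(n_pep):
            base = level + pep_offsets[q]
            vals = (
                base
                + loading
                + batch_fx[batches]
                + np.where(groups == "mut", effects[p] * LOG2_OVER_LOG10, 0.0)
                + rng.normal(0.0, params.noise_sd, n_samples)
            )
            if params.missing_rate > 0:
                vals = np.where(
                    rng.random(n_samples) < params.missing_rate, np.nan, vals
                )
            rows.append(
                {
                    "peptidoform_id": f"P{p:04d}_pep{q}",
                    "protein_group": f"PROT{p:04d}",
                    "is_unique": True,
                }
            )
            data.append(vals)

    matrix = pd.DataFrame(rows)
    intensity = pd.DataFrame(np.vstack(data), columns=sample_names)
    matrix = pd.concat([matrix, intensity], axis=1)

    # drop all-missing peptidoforms (can occur at high missingness)
    value_cols = sample_names
    all_missing = matrix[value_cols].isna().all(axis=1)
    if all_missing.any():
        import warnings

        warnings.warn(f"dropped {int(all_missing.sum())} all-missing peptidoforms")
        matrix = matrix.loc[~all_missing].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "protein_group": [f"PROT{p:04d}" for p in range(params.n_proteins)],
            "log2_fc": effects,
            "regulated": effects != 0.0,
        }
    )
    truth.attrs["loading"] = loading
    truth.attrs["batch_effects"] = batch_fx
    truth.attrs["samples"] = sample_names
    truth.attrs["groups"] = groups
    truth.attrs["batches"] = batches
    return matrix, truth
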