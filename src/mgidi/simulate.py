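"""Synthetic randomized-complete-block factorial trials.

The generative model is the additive Gaussian RCBD model the downstream
analysis assumes:

    y_ijt = mu_t + tau_it + beta_jt + eps_ijt

with treatment effects tau ~ N(0, sd_tau), block effects beta ~
N(0, sd_beta) and residuals eps drawn jointly across traits from
N(0, D^(1/2) C D^(1/2)) where C is the residual trait-correlation matrix
and D the per-trait residual variances. One integer seed drives a single
``numpy.random.Generator``; identical seeds give identical tables.

``planted_best_scenario`` additionally shifts one chosen treatment by
``effect_size * residual_sd`` in the desired direction of every trait,
making it the true ideal — the recovery-test harness for the ranking
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import LongTable

__all__ = ["SimConfig", "simulate_trial", "planted_best_scenario"]


def _as_per_trait(x, n_traits: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n_traits,)).copy()
    if (arr < 0).any():
        raise ValueError(f"{name} must be non-negative")
    return arr


@dataclass
class SimConfig:
    """Configuration of one simulated RCBD factorial trial.

    Scalars given for per-trait fields are broadcast to all traits.
    Defaults emulate a generic agronomic trial: trait grand means of 100
    with unit treatment, block and residual standard deviations, and
    uncorrelated residuals.
    """

    n_treatments: int = 5
    n_blocks: int = 4
    n_traits: int = 3
    grand_means: float | np.ndarray = 100.0
    treatment_effect_sd: float | np.ndarray = 1.0
    block_effect_sd: float | np.ndarray = 1.0
    residual_sd: float | np.ndarray = 1.0
    trait_correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatments < 2:
            raise ValueError("need at least 2 treatments")
        if self.n_blocks < 1 or self.n_traits < 1:
            raise ValueError("n_blocks and n_traits must be positive")
        p = self.n_traits
        self.grand_means = np.broadcast_to(
            np.asarray(self.grand_means, dtype=float), (p,)
        ).copy()
        self.treatment_effect_sd = _as_per_trait(
            self.treatment_effect_sd, p, "treatment_effect_sd"
        )
        self.block_effect_sd = _as_per_trait(self.block_effect_sd, p, "block_effect_sd")
        self.residual_sd = _as_per_trait(self.residual_sd, p, "residual_sd")
        if (self.residual_sd <= 0).any():
            raise ValueError("residual_sd must be strictly positive")
        if self.trait_correlation is None:
            self.trait_correlation = np.eye(p)
        else:
            C = np.asarray(self.trait_correlation, dtype=float)
            if C.shape != (p, p):
                raise ValueError(f"trait_correlation must be {p}x{p}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("trait_correlation must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValueError("trait_correlation must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("trait_correlation must be positive semidefinite")
            self.trait_correlation = C

    @property
    def trait_names(self) -> list[str]:
        return [f"V{i + 1}" for i in range(self.n_traits)]

    def to_dict(self) -> dict:
        return {
            "n_treatments": self.n_treatments,
            "n_blocks": self.n_blocks,
            "n_traits": self.n_traits,
            "grand_means": np.asarray(self.grand_means).tolist(),
            "treatment_effect_sd": np.asarray(self.treatment_effect_sd).tolist(),
            "block_effect_sd": np.asarray(self.block_effect_sd).tolist(),
            "residual_sd": np.asarray(self.residual_sd).tolist(),
            "trait_correlation": np.asarray(self.trait_correlation).tolist(),
            "seed": self.seed,
        }


def _correlated_residuals(
    rng: np.random.Generator, n: int, config: SimConfig
) -> np.ndarray:
    # symmetric PSD square root of C, then per-trait scaling
    C = config.trait_correlation
    w, V = np.linalg.eigh(C)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    z = rng.standard_normal((n, config.n_traits))
    return (z @ root) * config.residual_sd


def simulate_trial(
    config: SimConfig, shift: np.ndarray | None = None
) -> LongTable:
    """Draw one RCBD trial from the additive Gaussian model.

    Parameters
    ----------
    config : SimConfig
    shift : ndarray (n_treatments, n_traits), optional
        Deterministic offsets added to the treatment effects
        (used by :func:`planted_best_scenario`).

    Returns
    -------
    LongTable with factors ``TRT`` and ``BLOCK`` and
    ``n_treatments * n_blocks`` records.
    """
    rng = np.random.default_rng(config.seed)
    g, b, p = config.n_treatments, config.n_blocks, config.n_traits
    tau = rng.standard_normal((g, p)) * config.treatment_effect_sd
    beta = rng.standard_normal((b, p)) * config.block_effect_sd
    eps = _correlated_residuals(rng, g * b, config).reshape(g, b, p)
    if shift is not None:
        tau = tau + np.asarray(shift, dtype=float)
    y = (
        config.grand_means[None, None, :]
        + tau[:, None, :]
        + beta[None, :, :]
        + eps
    )
    trt = np.repeat([f"T{i + 1}" for i in range(g)], b)
    blk = np.tile([f"B{j + 1}" for j in range(b)], g)
    df = pd.DataFrame({"TRT": trt, "BLOCK": blk})
    for t, name in enumerate(config.trait_names):
        df[name] = y[:, :, t].reshape(-1)
    return LongTable(
        data=df,
        factor_columns=["TRT", "BLOCK"],
        trait_columns=config.trait_names,
    )


def planted_best_scenario(
    config: SimConfig,
    best_index: int,
    directions: list[str],
    effect_size: float,
) -> LongTable:
    """Simulate a trial in which one treatment is the true ideal.

    Treatment ``best_index`` gets a shift of ``effect_size * residual_sd``
    toward the desired pole of every trait ("higher" → up, "lower" →
    down), so with a large effect it dominates in every trait
    simultaneously.
    """
    if not 0 <= best_index < config.n_treatments:
        raise ValueError("best_index out of range")
    if len(directions) != config.n_traits:
        raise ValueError("one direction per trait required")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    sign = np.array([1.0 if d == "higher" else -1.0 for d in directions])
    shift = np.zeros((config.n_treatments, config.n_traits))
    shift[best_index] = effect_size * config.residual_sd * sign
    return simulate_trial(config, shift=shift)
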