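"""Synthetic case-control fold-change data with a known sparse logistic signal.

Emulates the structure of a paired-design whole-blood transcriptomic study:
an n x p matrix of log2 case-minus-control fold changes (default 88 samples,
matching a small epidemiological case series, with the gene dimension scaled
down to 2000 for desk-scale work; full microarray widths are supported),
block-correlated genes (co-regulated genes move together, which is what
makes variable selection unstable), a sparse logistic signal on a known
support, and an outcome prevalence calibrated to a target (default 0.25,
the fraction of metastasized cancers among incident breast-cancer cases).

Fold changes are standard normal marginally: a log2 intensity ratio is
approximately continuous and centered, and the unit scale is a convention —
effect sizes are then per-standard-deviation log-odds.  Gene g in block b is

    sqrt(rho) * z_b + sqrt(1 - rho) * e_g,     z_b, e_g ~ N(0, 1) iid,

giving within-block correlation rho and zero across blocks.  Signal genes
are spread across distinct blocks where possible with alternating signs, so
the signature is not a single one-directional co-regulated clump.  The
intercept is calibrated by root-finding on a large auxiliary sample so the
population prevalence hits the target.

Everything is deterministic given the seed; the generated ground truth
(support, intercept, per-sample probabilities) is recorded for recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .preprocessing_io import FoldChangeMatrix, InputValidationError, OutcomeVector

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_matrix",
           "calibrate_intercept", "make_dataset"]

_AUX_DRAWS = 100_000
_PREVALENCE_TOL = 0.005


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    n: case-control pairs; p: genes; block_size/rho: correlation structure;
    n_signal/effect_size: sparse signal (|log-odds| per unit fold change);
    target_prevalence: population probability of the outcome.
    """

    n: int = 88
    p: int = 2000
    block_size: int = 10
    rho: float = 0.5
    n_signal: int = 10
    effect_size: float = 0.5
    target_prevalence: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal > self.p:
            raise InputValidationError("n_signal cannot exceed p")
        if not 0.0 <= self.rho < 1.0:
            raise InputValidationError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 <= self.target_prevalence <= 1.0:
            raise InputValidationError("target_prevalence must be in [0, 1]")
        if self.n < 1 or self.p < 1 or self.block_size < 1:
            raise InputValidationError("n, p and block_size must be positive")

    @property
    def n_blocks(self) -> int:
        return math.ceil(self.p / self.block_size)

    def block_of(self, gene_index: int) -> int:
        return gene_index // self.block_size


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated data plus the ground truth that produced it."""

    X: FoldChangeMatrix
    y: OutcomeVector
    true_support: tuple[tuple[str, int], ...]  # (gene_id, sign)
    true_intercept: float
    true_probabilities: np.ndarray
    config: SimulationConfig

    @property
    def true_support_ids(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.true_support)

    @property
    def realized_prevalence(self) -> float:
        return float(self.y.values.mean())

    def linear_predictor(self, X: FoldChangeMatrix) -> np.ndarray:
        """True-model linear predictor for any matrix on the same gene universe."""
        idx = {g: j for j, g in enumerate(X.gene_ids)}
        eta = np.full(X.n, self.true_intercept)
        for gene, sign in self.true_support:
            eta += sign * self.config.effect_size * X.values[:, idx[gene]]
        return eta

    def true_model_probabilities(self, X: FoldChangeMatrix) -> np.ndarray:
        return expit(self.linear_predictor(X))


def simulate_matrix(cfg: SimulationConfig, rng: np.random.Generator) -> FoldChangeMatrix:
    """Draw the block-correlated fold-change matrix (standard normal marginals)."""
    z = rng.standard_normal((cfg.n, cfg.n_blocks))
    e = rng.standard_normal((cfg.n, cfg.p))
    blocks = np.arange(cfg.p) // cfg.block_size
    values = math.sqrt(cfg.rho) * z[:, blocks] + math.sqrt(1.0 - cfg.rho) * e
    sample_ids = [f"pair{i:04d}" for i in range(cfg.n)]
    gene_ids = [f"gene{j:05d}" for j in range(cfg.p)]
    return FoldChangeMatrix(values, sample_ids, gene_ids)


def _support_indices(cfg: SimulationConfig) -> list[int]:
    # first gene of consecutive blocks, wrapping to second-of-block etc. when
    # there are more signal genes than blocks
    idx = []
    for s in range(cfg.n_signal):
        block = s % cfg.n_blocks
        offset = s // cfg.n_blocks
        j = block * cfg.block_size + offset
        idx.append(j if j < cfg.p else s)  # fallback for truncated last block
    return sorted(set(idx))[: cfg.n_signal] if len(set(idx)) >= cfg.n_signal else list(
        range(cfg.n_signal)
    )


def _signal_eta(cfg: SimulationConfig, support: list[int], signs: np.ndarray,
                rng: np.random.Generator, n_draws: int) -> np.ndarray:
    """Linear-predictor draws (without intercept) honoring block correlation
    among the support genes."""
    blocks = [cfg.block_of(j) for j in support]
    uniq = sorted(set(blocks))
    z = rng.standard_normal((n_draws, len(uniq)))
    zcol = {b: i for i, b in enumerate(uniq)}
    eta = np.zeros(n_draws)
    for (j, b, s) in zip(support, blocks, signs):
        xj = math.sqrt(cfg.rho) * z[:, zcol[b]] + math.sqrt(1.0 - cfg.rho) * \
            rng.standard_normal(n_draws)
        eta += s * cfg.effect_size * xj
    return eta


def calibrate_intercept(
    cfg: SimulationConfig,
    support: list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Intercept beta0 such that mean(expit(beta0 + eta)) hits the target
    prevalence, found by root-finding over a fixed auxiliary sample.

    With no signal this is the closed-form logit of the target prevalence.
    """
    target = cfg.target_prevalence
    if cfg.n_signal == 0 or cfg.effect_size == 0.0:
        if target in (0.0, 1.0):
            raise InputValidationError("degenerate target prevalence needs no model")
        return math.log(target / (1.0 - target))
    if support is None:
        support = _support_indices(cfg)
    signs = np.array([1 if i % 2 == 0 else -1 for i in range(len(support))])
    rng = rng or np.random.default_rng(cfg.seed)
    eta = _signal_eta(cfg, support, signs, rng, _AUX_DRAWS)

    def gap(b0: float) -> float:
        return float(expit(b0 + eta).mean()) - target

    b0 = brentq(gap, -40.0, 40.0, xtol=1e-10)
    if abs(gap(b0)) > _PREVALENCE_TOL:
        raise RuntimeError("intercept calibration failed to reach the target")
    return float(b0)


def make_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a full dataset: matrix, calibrated outcome model and draws."""
    root = np.random.SeedSequence(cfg.seed)
    rng_x, rng_aux, rng_y = (np.random.default_rng(s) for s in root.spawn(3))

    X = simulate_matrix(cfg, rng_x)
    support = _support_indices(cfg)
    signs = [1 if i % 2 == 0 else -1 for i in range(len(support))]
    b0 = calibrate_intercept(cfg, support, rng_aux)

    eta = np.full(cfg.n, b0)
    for j, s in zip(support, signs):
        eta += s * cfg.effect_size * X.values[:, j]
    probs = expit(eta)
    y = OutcomeVector(rng_y.binomial(1, probs), X.sample_ids)

    return SyntheticDataset(
        X=X,
        y=y,
        true_support=tuple((X.gene_ids[j], s) for j, s in zip(support, signs)),
        true_intercept=b0,
        true_probabilities=probs,
        config=cfg,
    )
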