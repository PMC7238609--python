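"""Evaluation statistics: Brier score, concordance probability, LOWESS
calibration curve, Jaccard set overlap and the expected-overlap count.

Brier score is the mean squared error between predicted probabilities and
the 0/1 outcome — a one-number calibration summary (lower is better; a
constant predictor at the prevalence p scores exactly p(1-p)).

Concordance (equivalently the area under the ROC curve) is the probability
that a randomly chosen positive is ranked above a randomly chosen negative
by the predictions, with ties counted one half — the Mann-Whitney U
convention.  A constant predictor scores exactly 0.5.

The calibration curve smooths the 0/1 outcome as a function of predicted
probability: under perfect calibration the smoothed proportion of events
equals the prediction, i.e. the curve is the diagonal.

The Jaccard index |S1 n S2| / |S1 u S2| measures the stability of gene
sets selected in different realizations of the modeling procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .preprocessing_io import InputValidationError, OutcomeVector

__all__ = [
    "CalibrationCurve",
    "brier_score",
    "concordance",
    "calibration_curve",
    "jaccard",
    "expected_overlap",
]

DEFAULT_SPAN = 2.0 / 3.0
DEFAULT_GRID_SIZE = 50
# Robustness iterations reweight by residual size; with 0/1 outcomes the
# minority class always has the larger residuals and gets suppressed, biasing
# the curve toward the majority, so the default is a plain (non-robust) fit.
DEFAULT_ROBUSTNESS_ITERATIONS = 0


def _as_outcome_array(y) -> np.ndarray:
    if isinstance(y, OutcomeVector):
        return y.values
    arr = np.asarray(y)
    if not np.isin(arr, (0, 1)).all():
        raise InputValidationError("outcome must be coded 0/1")
    return arr.astype(np.int64)


def _check_predictions(predicted, y) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    yv = _as_outcome_array(y)
    if p.shape != yv.shape:
        raise InputValidationError(
            f"predicted has length {p.shape}, outcome has length {yv.shape}"
        )
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise InputValidationError("predictions must lie in [0, 1]")
    return p, yv


def brier_score(predicted, y) -> float:
    """Mean squared difference between predicted probabilities and outcomes."""
    p, yv = _check_predictions(predicted, y)
    return float(np.mean((p - yv) ** 2))


def concordance(predicted, y) -> float:
    """Probability a random positive outranks a random negative; ties count 1/2.

    Computed from midranks, which is exactly (wins + ties/2) / (n+ * n-),
    the normalized Mann-Whitney U statistic.
    """
    p, yv = _check_predictions(predicted, y)
    n_pos = int(yv.sum())
    n_neg = len(yv) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InputValidationError("concordance needs both outcome classes")
    ranks = rankdata(p)
    u = ranks[yv == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class CalibrationCurve:
    """Smoothed event proportion (observed) over a grid of predicted values."""

    grid: np.ndarray
    observed: np.ndarray
    span: float = DEFAULT_SPAN

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        o = np.asarray(self.observed, dtype=float)
        if g.shape != o.shape:
            raise InputValidationError("grid and observed lengths differ")
        if len(g) and ((g < 0).any() or (g > 1).any() or (np.diff(g) < 0).any()):
            raise InputValidationError("grid must be increasing within [0, 1]")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "observed", np.clip(o, 0.0, 1.0))


def lowess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    xgrid: np.ndarray,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ROBUSTNESS_ITERATIONS,
) -> np.ndarray:
    """Locally weighted linear regression (tricube kernel) of y on x,
    evaluated at xgrid.  Degenerate x (zero range) yields the mean of y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) < 1e-12:
        return np.full(len(xgrid), y.mean())
    return _sm_lowess(y, x, frac=span, it=iterations, xvals=np.asarray(xgrid, float))


def calibration_curve(
    predicted,
    y,
    span: float = DEFAULT_SPAN,
    grid_size: int = DEFAULT_GRID_SIZE,
    iterations: int = DEFAULT_ROBUSTNESS_ITERATIONS,
    grid: np.ndarray | None = None,
) -> CalibrationCurve:
    """LOWESS calibration curve of the 0/1 outcome against predictions.

    Evaluated at ``grid_size`` evenly spaced points spanning the range of
    the predictions (or at an explicit ``grid``); values are clipped to
    [0, 1] since a smoothed proportion can leave the unit interval.
    """
    p, yv = _check_predictions(predicted, y)
    if len(p) < 10:
        raise InputValidationError(
            f"calibration needs at least 10 samples, got {len(p)}"
        )
    if not 0.0 < span <= 1.0:
        raise InputValidationError(f"span must be in (0, 1], got {span}")
    if grid is None:
        grid = np.linspace(p.min(), p.max(), grid_size)
    observed = lowess_smooth(p, yv.astype(float), grid, span, iterations)
    return CalibrationCurve(grid=np.asarray(grid, float), observed=observed, span=span)


def jaccard(s1, s2) -> float:
    """|S1 n S2| / |S1 u S2| for two gene sets; undefined when both are empty."""
    a = set(getattr(s1, "gene_ids", s1))
    b = set(getattr(s2, "gene_ids", s2))
    union = a | b
    if not union:
        raise InputValidationError("Jaccard index is undefined for two empty sets")
    return len(a & b) / len(union)


def expected_overlap(stability: float, set_size: int) -> int:
    """Expected overlap count implied by a mean pairwise Jaccard stability.

    Rounds stability * set_size half-to-even: a stability of 0.16 over a
    108-gene set implies an expected overlap of round(17.28) = 17 genes
    between two realizations of the selection.
    """
    if not 0.0 <= stability <= 1.0:
        raise InputValidationError(f"stability must be in [0, 1], got {stability}")
    if set_size < 0:
        raise InputValidationError(f"set_size must be nonnegative, got {set_size}")
    return int(round(stability * set_size))
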