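"""Simple-regression fitters: OLS, IRLS M-estimation, and LMS.

The M-estimate minimizes Σ ρ(rᵢ) over the line (α, β), solved by
iteratively reweighted least squares: at each pass the residuals of the
current line are turned into weights w(rᵢ/σ̂) and a weighted least-squares
line is refit, until the coefficients stop moving.  A converged fit is a
fixed point of the estimating equations Σ w(rᵢ)rᵢ = 0 and
Σ w(rᵢ)rᵢxᵢ = 0.

Residuals are standardized by a per-iteration robust scale
σ̂ = MAD/0.6745 by default (``scale="mad"``); ``scale="none"`` applies the
ψ-family to raw residuals, which only makes sense when the tuning constant
is already in response units.

Least median of squares (LMS) searches two-point elemental lines for the
one minimizing the median squared residual; it is the high-breakdown
baseline, not an M-estimator.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np

from .families import PsiFamily, TuningSpec, get_family

__all__ = [
    "RegressionData",
    "FitResult",
    "SubsetSSE",
    "DegenerateDesignError",
    "DegenerateWeightsError",
    "fit_ols",
    "fit_irls",
    "fit_lms",
    "flag_outliers",
    "subset_sse",
]

logger = logging.getLogger(__name__)

MAD_CONSISTENCY = 0.6745  # MAD of a standard normal


class DegenerateDesignError(ValueError):
    """Predictor is constant — the slope is unidentifiable."""


class DegenerateWeightsError(RuntimeError):
    """Every observation got (numerically) zero weight."""


@dataclass
class RegressionData:
    """Paired predictor/response vectors for one simple regression."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if self.x.size != self.y.size:
            raise ValueError(f"length mismatch: {self.x.size} x vs {self.y.size} y")
        if self.x.size < 3:
            raise ValueError("need at least 3 observations")
        if np.ptp(self.x) == 0:
            raise DegenerateDesignError("predictor is constant")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class FitResult:
    """A fitted line with its diagnostics.

    ``weights`` are relative weights w(r)/w(0) in [0, 1] at the final
    IRLS iterate (None for OLS/LMS).
    """

    intercept: float
    slope: float
    residuals: np.ndarray
    method: str
    weights: Optional[np.ndarray] = None
    n_iterations: int = 0
    converged: bool = True
    tuning: Optional[TuningSpec] = None
    scale: Optional[str] = None

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    @property
    def coefficients(self) -> tuple[float, float]:
        return (self.intercept, self.slope)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "intercept": self.intercept,
            "slope": self.slope,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "scale": self.scale,
            "tuning": None if self.tuning is None else {
                k: v for k, v in vars(self.tuning).items() if v is not None
            },
            "residuals": self.residuals.tolist(),
            "weights": None if self.weights is None else self.weights.tolist(),
        }


@dataclass
class SubsetSSE:
    """Sum of squared errors over all points and over a retained subset."""

    sse_all: float
    sse_retained: float
    retained: np.ndarray
    n_used: int


def _wls(x: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None) -> tuple[float, float]:
    """Closed-form (weighted) simple regression; exact normal equations."""
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    xb = (w * x).sum() / sw
    yb = (w * y).sum() / sw
    sxx = (w * (x - xb) ** 2).sum()
    if sxx <= 0:
        raise DegenerateDesignError("weighted predictor variance is zero")
    slope = (w * (x - xb) * (y - yb)).sum() / sxx
    return yb - slope * xb, slope


def _robust_scale(r: np.ndarray) -> float:
    return float(np.median(np.abs(r - np.median(r))) / MAD_CONSISTENCY)


def fit_ols(data: RegressionData) -> FitResult:
    """Ordinary least squares by the closed-form normal equations."""
    a, b = _wls(data.x, data.y)
    return FitResult(a, b, data.y - a - b * data.x, method="ols")


def fit_irls(
    data: RegressionData,
    family: Union[str, PsiFamily],
    tuning: Optional[TuningSpec] = None,
    *,
    start: Union[str, tuple[float, float]] = "ols",
    scale: str = "mad",
    max_iter: int = 200,
    tol: float = 1e-8,
) -> FitResult:
    """M-estimate of the line by iteratively reweighted least squares.

    Parameters
    ----------
    family : str or PsiFamily
        Registered ψ-family name or family object.
    tuning : TuningSpec, optional
        Tuning constants; the family default when omitted.
    start : {"ols", "lms", "huber"} or (intercept, slope)
        Starting line. Redescending ψ-functions have multiple IRLS fixed
        points; the start decides which basin is reached.
    scale : {"mad", "none"}
        Residual standardization before weighting. "mad" recomputes
        σ̂ = MAD/0.6745 each iteration.
    max_iter, tol
        Stop when the max coefficient change relative to the coefficient
        size drops below ``tol``. Non-convergence sets ``converged=False``
        and logs a warning; it is not an error.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if scale not in ("mad", "none"):
        raise ValueError(f"unknown scale strategy {scale!r}")
    fam = get_family(family) if isinstance(family, str) else family
    t = tuning if tuning is not None else fam.default_tuning

    if isinstance(start, str):
        if start == "ols":
            coef = fit_ols(data).coefficients
        elif start == "lms":
            coef = fit_lms(data).coefficients
        elif start == "huber":
            coef = fit_irls(data, "huber", start="ols", scale="mad").coefficients
        else:
            raise ValueError(f"unknown start strategy {start!r}")
    else:
        coef = (float(start[0]), float(start[1]))

    w0 = fam.weight_at_zero(t)
    x, y = data.x, data.y
    n_iter = 0
    converged = False
    w = np.ones_like(x)
    for n_iter in range(1, max_iter + 1):
        r = y - coef[0] - coef[1] * x
        if scale == "mad":
            s = _robust_scale(r)
            if s < 1e-12:  # exact fit of the majority; nothing left to reweight
                converged = True
                break
            rs = r / s
        else:
            rs = r
        w = np.asarray(fam.weight(rs, t), dtype=float)
        if not np.any(w > 1e-300):
            raise DegenerateWeightsError(
                f"all observations rejected by {fam.name} with k={t.k}; "
                "increase the tuning constant"
            )
        new = _wls(x, y, w)
        delta = max(
            abs(new[0] - coef[0]) / max(abs(new[0]), 1.0),
            abs(new[1] - coef[1]) / max(abs(new[1]), 1.0),
        )
        coef = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "IRLS (%s) did not converge in %d iterations", fam.name, max_iter
        )
        warnings.warn(f"IRLS ({fam.name}) did not converge in {max_iter} iterations")
    r = y - coef[0] - coef[1] * x
    return FitResult(
        coef[0], coef[1], r,
        method=f"irls:{fam.name}",
        weights=w / w0,
        n_iterations=n_iter,
        converged=converged,
        tuning=t,
        scale=scale,
    )


def fit_lms(data: RegressionData, n_subsets: int = 5000, seed: int = 0) -> FitResult:
    """Least median of squares over two-point elemental lines.

    All C(n,2) elemental lines are scanned when that count is at most
    ``n_subsets``; otherwise ``n_subsets`` random pairs are drawn with the
    given seed.  Candidates are enumerated in a canonical (x, y)-sorted
    order, so the result does not depend on observation order.  Ties keep
    the first candidate in that order.
    """
    if data.n < 4:
        raise ValueError("LMS needs at least 4 observations")
    x, y = data.x, data.y
    order = np.lexsort((y, x))  # canonical, permutation-invariant ordering
    xs, ys = x[order], y[order]
    n = data.n
    total = n * (n - 1) // 2
    if total <= n_subsets:
        pairs = combinations(range(n), 2)
    else:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, n, size=2 * n_subsets)
        jj = rng.integers(0, n, size=2 * n_subsets)
        keep = ii != jj
        pairs = list(zip(ii[keep][:n_subsets], jj[keep][:n_subsets]))
    best_obj = np.inf
    best = None
    for i, j in pairs:
        if xs[i] == xs[j]:
            continue
        slope = (ys[j] - ys[i]) / (xs[j] - xs[i])
        intercept = ys[i] - slope * xs[i]
        obj = np.median((ys - intercept - slope * xs) ** 2)
        if obj < best_obj:
            best_obj = obj
            best = (intercept, slope)
    if best is None:
        raise DegenerateDesignError("no elemental line with distinct x values")
    a, b = best
    return FitResult(a, b, y - a - b * x, method="lms")


def flag_outliers(
    fit: FitResult,
    *,
    weight_cutoff: float = 0.1,
    residual_cutoff: float = 2.5,
) -> np.ndarray:
    """Indices of observations a fit treats as outliers.

    Weight-bearing fits (IRLS): final relative weight below
    ``weight_cutoff``.  OLS/LMS: |residual| above ``residual_cutoff``
    times the robust scale 1.4826·MAD of the residuals.
    """
    if not (0.0 < weight_cutoff < 1.0):
        raise ValueError("weight_cutoff must lie in (0, 1)")
    if fit.weights is not None:
        return np.flatnonzero(fit.weights < weight_cutoff)
    r = fit.residuals
    s = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    if s < 1e-300:
        return np.flatnonzero(np.abs(r) > 0)
    return np.flatnonzero(np.abs(r) > residual_cutoff * s)


def subset_sse(
    data: RegressionData,
    fit: FitResult,
    retained: Sequence[int],
) -> SubsetSSE:
    """SSE of a fitted line over all points and over a retained subset."""
    retained = np.asarray(retained, dtype=int)
    if retained.size == 0:
        raise ValueError("retained set must not be empty")
    if retained.min() < 0 or retained.max() >= data.n:
        raise ValueError("retained indices out of range")
    r = data.y - fit.predict(data.x)
    return SubsetSSE(
        sse_all=float((r ** 2).sum()),
        sse_retained=float((r[retained] ** 2).sum()),
        retained=retained,
        n_used=int(retained.size),
    )
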