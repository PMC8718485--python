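"""Knee-point detection on ranked coefficient / importance curves.

The curve is the descending sequence of absolute model coefficients (or NN
first-layer importances) against rank.  The knee is located with the
differential-geometry curvature of a smoothed fit,

    kappa(x) = |f''(x)| / (1 + f'(x)^2)^(3/2),

evaluated at each interior rank of a cubic smoothing spline f fitted to the
(rank, value) points; the knee is the interior rank maximising kappa.
Both axes are min-max normalised to [0, 1] before smoothing: the value
normalisation makes the knee invariant to the overall coefficient scale,
and putting rank and value on a common scale is what places the maximal
curvature at the visual corner of an L-shaped curve (on raw axes the
curvature of a convex decay is maximised degenerately at its steep end).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .models import RegularizedFit

__all__ = [
    "CoefficientCurve",
    "KneeResult",
    "NoKneeError",
    "rank_coefficients",
    "find_knee",
    "select_above_knee",
    "discrete_curvature_knee",
]

_FLAT_TOL = 1e-12


class NoKneeError(ValueError):
    """Raised when the curve is flat or linear and has no knee."""


@dataclasses.dataclass(frozen=True)
class CoefficientCurve:
    """Descending |coefficient| (or importance) values with aligned names."""

    values: np.ndarray
    names: tuple[str, ...]
    source: str = "ridge"  # "ridge" | "nn_importance"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("curve values must be finite and nonnegative")
        if np.any(np.diff(v) > 0):
            raise ValueError("curve values must be non-increasing")
        if len(self.names) != v.size:
            raise ValueError("names and values lengths differ")
        object.__setattr__(self, "values", v)

    @property
    def is_flat(self) -> bool:
        return bool(np.ptp(self.values) <= _FLAT_TOL)


@dataclasses.dataclass(frozen=True)
class KneeResult:
    knee_rank: int  # 1-based rank into the curve
    curvature: np.ndarray  # per-rank kappa (NaN at the two boundary ranks)
    smoothing_bandwidth: float  # spline penalty; NaN when chosen by GCV internally


def rank_coefficients(fit: RegularizedFit, names=None,
                      source: str = "ridge") -> CoefficientCurve:
    """Sort |theta| descending into a CoefficientCurve (intercept excluded).

    Ties in |theta| are broken lexicographically by feature name so that the
    ranking is deterministic.
    """
    if not fit.converged:
        raise ValueError("cannot rank coefficients of a non-converged fit")
    if names is None:
        names = fit.feature_names
    if names is None:
        names = tuple(f"x{j}" for j in range(fit.theta.size))
    absval = np.abs(fit.theta)
    order = sorted(range(absval.size), key=lambda j: (-absval[j], str(names[j])))
    return CoefficientCurve(values=absval[list(order)],
                            names=tuple(str(names[j]) for j in order),
                            source=source)


def _smoothed_values(curve: CoefficientCurve):
    """Cubic smoothing spline (GCV-penalised) of the axis-normalised curve.

    Returns ``(x, spl)`` where x is the rank grid mapped onto [0, 1].
    """
    p = curve.values.size
    x = np.linspace(0.0, 1.0, p)
    rng = np.ptp(curve.values)
    y = (curve.values - curve.values.min()) / rng
    spl = make_smoothing_spline(x, y, lam=None)
    return x, spl


def _curvature_from(values_d1: np.ndarray, values_d2: np.ndarray) -> np.ndarray:
    return np.abs(values_d2) / np.power(1.0 + values_d1**2, 1.5)


def find_knee(curve: CoefficientCurve) -> KneeResult:
    """Locate the knee rank via spline curvature.

    Raises :class:`NoKneeError` on flat or (numerically) linear curves, where
    the maximal curvature falls below 1e-12.  Ties in curvature go to the
    smallest rank.
    """
    p = curve.values.size
    if p < 5:
        raise ValueError("curve must have at least 5 points")
    if curve.is_flat:
        raise NoKneeError("flat curve has no knee")
    x, spl = _smoothed_values(curve)
    d1 = spl.derivative(1)(x)
    d2 = spl.derivative(2)(x)
    kappa = _curvature_from(d1, d2)
    kappa[0] = np.nan
    kappa[-1] = np.nan
    interior = kappa[1:-1]
    if np.nanmax(interior) < _FLAT_TOL:
        raise NoKneeError("curve is linear: maximal curvature below 1e-12")
    knee_rank = int(np.argmax(interior)) + 2  # 1-based, interior starts at rank 2
    return KneeResult(knee_rank=knee_rank, curvature=kappa,
                      smoothing_bandwidth=float("nan"))


def discrete_curvature_knee(curve: CoefficientCurve) -> int:
    """Brute-force oracle: central-difference curvature on the smoothed values.

    Evaluates the same smoothing spline at integer ranks, forms discrete
    first/second central differences, and returns the interior rank with the
    largest discrete curvature.  Used to cross-check :func:`find_knee`.
    """
    p = curve.values.size
    if p < 5:
        raise ValueError("curve must have at least 5 points")
    if curve.is_flat:
        raise NoKneeError("flat curve has no knee")
    x, spl = _smoothed_values(curve)
    f = spl(x)
    h = x[1] - x[0]
    d1 = (f[2:] - f[:-2]) / (2.0 * h)
    d2 = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / h**2
    kappa = _curvature_from(d1, d2)
    if np.max(kappa) < _FLAT_TOL:
        raise NoKneeError("curve is linear: maximal curvature below 1e-12")
    return int(np.argmax(kappa)) + 2


def curve_to_frame(curve: CoefficientCurve, knee: KneeResult | None = None):
    """Rank/value/curvature table for plotting with any external tool."""
    import pandas as pd
    df = pd.DataFrame({"rank": np.arange(1, curve.values.size + 1),
                       "feature": list(curve.names),
                       "value": curve.values,
                       "source": curve.source})
    if knee is not None:
        df["curvature"] = knee.curvature
        df["above_knee"] = df["rank"] <= knee.knee_rank
    return df


def select_above_knee(curve: CoefficientCurve, knee: KneeResult) -> list[str]:
    """Features at ranks 1..knee_rank inclusive, in rank order (a prefix)."""
    if not (1 <= knee.knee_rank <= curve.values.size):
        raise ValueError("knee rank out of range for this curve")
    return list(curve.names[: knee.knee_rank])
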