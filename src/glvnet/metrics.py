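"""Ecological and growth-response summaries.

Pielou evenness (normalized Shannon entropy of a community's proportional
composition), log-fold knockdown ratios (logR) comparing a knockdown
condition against the equal-inoculum baseline, and four-parameter-logistic
EC50 fitting of metabolite growth-requirement curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .model import GLVModelError, Trajectory

__all__ = [
    "CompositionVector",
    "DoseResponseCurve",
    "composition",
    "pielou_evenness",
    "log_fold_ratio",
    "FourParamLogistic",
    "fit_sigmoid_ec50",
]


@dataclass
class CompositionVector:
    """Proportional composition of a community: p_i >= 0, sum(p) = 1."""

    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < 0):
            raise GLVModelError("proportions must be non-negative")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise GLVModelError("proportions must sum to 1")


def composition(abundances: Sequence[float]) -> CompositionVector:
    """Normalize an abundance vector to proportions."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise GLVModelError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise GLVModelError("cannot normalize an all-zero abundance vector")
    return CompositionVector(x / total)


def pielou_evenness(
    abundances: Union[Sequence[float], CompositionVector],
    num_species: Optional[int] = None,
) -> float:
    """Pielou's evenness index ``-sum(p_i ln p_i) / ln(S)`` in [0, 1].

    Inputs may be raw abundances (normalized internally) or proportions.
    ``num_species`` defaults to the vector length; zero proportions
    contribute 0 via the limit convention ``0 ln 0 = 0``.  1.0 means all
    species equally abundant; 0 means a single species dominates.
    """
    if isinstance(abundances, CompositionVector):
        p = abundances.proportions
    else:
        p = composition(abundances).proportions
    s = num_species if num_species is not None else p.size
    if s < 2:
        raise GLVModelError("evenness needs at least 2 species")
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))
    return h / np.log(s) + 0.0  # normalize -0.0 to 0.0


def _median_abundances(trajs: Sequence[Trajectory]) -> Trajectory:
    first = trajs[0]
    for t in trajs[1:]:
        if t.species != first.species or not np.array_equal(t.times, first.times):
            raise GLVModelError("replicates must share species and time grid")
    med = np.median(np.stack([t.abundances for t in trajs]), axis=0)
    return Trajectory(
        times=first.times, abundances=med, species=first.species,
        condition=first.condition, replicate=-1,
    )


def log_fold_ratio(
    knockdown: Union[Trajectory, Sequence[Trajectory]],
    baseline: Union[Trajectory, Sequence[Trajectory]],
    log_base: float = 10.0,
) -> np.ndarray:
    """Per-species logR series: ``log_b(x_kd(t) / x_base(t))``, shape (T, S).

    When lists of replicate trajectories are given, the replicate median is
    taken elementwise before forming the ratio.  Both sides must share the
    species ordering and time grid, and abundances must be strictly
    positive.
    """
    kd = _median_abundances(list(knockdown)) if not isinstance(knockdown, Trajectory) \
        else knockdown
    base = _median_abundances(list(baseline)) if not isinstance(baseline, Trajectory) \
        else baseline
    if kd.species != base.species:
        raise GLVModelError("species orderings differ between conditions")
    if not np.array_equal(kd.times, base.times):
        raise GLVModelError("time grids differ between conditions")
    if np.any(kd.abundances <= 0) or np.any(base.abundances <= 0):
        raise GLVModelError("logR requires strictly positive abundances")
    return np.log(kd.abundances / base.abundances) / np.log(log_base)


# ---------------------------------------------------------------------------
# Dose-response EC50 fitting
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseCurve:
    """Growth readout versus metabolite concentration (uM), with fitted
    four-parameter-logistic parameters after :func:`fit_sigmoid_ec50`."""

    concentrations: np.ndarray
    responses: np.ndarray
    bottom: Optional[float] = None
    top: Optional[float] = None
    ec50: Optional[float] = None
    hill_slope: Optional[float] = None
    residual_ss: Optional[float] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(self.concentrations <= 0):
            raise GLVModelError("concentrations must be > 0")
        if self.concentrations.shape != self.responses.shape:
            raise GLVModelError("concentrations/responses length mismatch")


def _four_pl(c, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic (variable-slope sigmoid) dose-response fit.

    Model: ``y = bottom + (top - bottom) / (1 + (ec50/c)**hill_slope)``;
    the fitted curve passes through ``(bottom+top)/2`` at ``c = ec50``.
    ``bottom`` is constrained to be >= 0.  Fitted attributes: ``bottom_``,
    ``top_``, ``ec50_`` (input concentration units), ``hill_slope_``,
    ``residual_ss_``.
    """

    def __init__(self, maxfev: int = 20000):
        self.maxfev = maxfev

    def fit(self, X: Sequence[float], y: Sequence[float]) -> "FourParamLogistic":
        c = np.asarray(X, dtype=float).ravel()
        r = np.asarray(y, dtype=float).ravel()
        if np.any(c <= 0):
            raise GLVModelError("concentrations must be > 0")
        if np.unique(c).size < 4:
            raise GLVModelError("need >= 4 distinct concentrations")
        span = r.max() - r.min()
        if span <= 1e-12 * max(abs(r).max(), 1.0):
            raise GLVModelError("flat response data: no transition to fit")
        # initial guesses: range endpoints, geometric-median half-response
        half = (r.max() + r.min()) / 2.0
        ec50_0 = float(np.exp(np.interp(half, np.sort(r), np.log(c)[np.argsort(r)])))
        p0 = [max(r.min(), 0.0), r.max(), ec50_0, 1.0]
        bounds = ([0.0, -np.inf, 1e-300, 1e-6], [np.inf, np.inf, np.inf, 50.0])
        try:
            popt, _ = curve_fit(
                _four_pl, c, r, p0=p0, bounds=bounds, maxfev=self.maxfev
            )
        except RuntimeError as exc:
            raise GLVModelError(f"EC50 fit did not converge: {exc}") from exc
        self.bottom_, self.top_, self.ec50_, self.hill_slope_ = map(float, popt)
        resid = r - _four_pl(c, *popt)
        self.residual_ss_ = float(resid @ resid)
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        c = np.asarray(X, dtype=float).ravel()
        return _four_pl(c, self.bottom_, self.top_, self.ec50_, self.hill_slope_)


def fit_sigmoid_ec50(
    curve: Union[DoseResponseCurve, Sequence[float]],
    responses: Optional[Sequence[float]] = None,
) -> DoseResponseCurve:
    """Least-squares 4PL fit; returns the curve with fitted parameters set.

    Accepts either a :class:`DoseResponseCurve` or separate concentration /
    response arrays.
    """
    if not isinstance(curve, DoseResponseCurve):
        curve = DoseResponseCurve(np.asarray(curve, dtype=float),
                                  np.asarray(responses, dtype=float))
    est = FourParamLogistic().fit(curve.concentrations, curve.responses)
    curve.bottom = est.bottom_
    curve.top = est.top_
    curve.ec50 = est.ec50_
    curve.hill_slope = est.hill_slope_
    curve.residual_ss = est.residual_ss_
    return curve
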