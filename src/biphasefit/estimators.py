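"""Scikit-learn style estimators for dose-response curve fitting.

Each estimator fits one of the three inhibition models to (concentration,
viability) data by minimizing the viability-scale RMSE, via bounded
`scipy.optimize.least_squares` (trust-region reflective) launched from a
deterministic multi-start lattice. Multi-start from fixed initial values makes
the fit reproducible; the result is the lowest-RMSE start, with ties broken
toward smaller Kd1, then smaller F1.

X is the concentration array in nM, shape (n,) or (n, 1); y is relative
viability. Fitted parameters carry a trailing underscore (`ic50_`, `f1_`,
`kd1_`, `kd2_`, ...) and `predict` returns model viability, so the estimators
compose with sklearn pipelines and scoring.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import (
    BiphasicParams,
    HillParams,
    MonophasicParams,
    eval_biphasic,
    eval_hill,
    eval_monophasic,
)

__all__ = ["MonophasicCurveFit", "HillCurveFit", "BiphasicCurveFit"]

#: ties in RMSE below this are broken by the (kd1, f1) convention
_TIE_TOL = 1e-9
#: a parameter within this relative distance of a box bound is flagged
_BOUND_RTOL = 1e-5


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be a 1-D array of concentrations (nM) or (n, 1)")
    y = np.asarray(y, dtype=float)
    if y.shape != X.shape:
        raise ValueError("X and y must have the same length")
    if np.any(X <= 0):
        raise ValueError("concentrations must be strictly positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("viability values must be finite")
    return X, y


def _near_bound(value: float, lo: float, hi: float) -> bool:
    span = hi - lo
    return abs(value - lo) <= _BOUND_RTOL * max(abs(lo), 1.0) or \
        abs(value - hi) <= _BOUND_RTOL * max(abs(hi), 1.0) or \
        (span > 0 and min(value - lo, hi - value) <= 1e-8 * span)


class _CurveFitBase(RegressorMixin, BaseEstimator):
    """Shared multi-start machinery; subclasses define the model."""

    def __init__(self, bounds_decades_below: float = 2.0,
                 bounds_decades_above: float = 2.0):
        self.bounds_decades_below = bounds_decades_below
        self.bounds_decades_above = bounds_decades_above

    # -- hooks -------------------------------------------------------------
    def _starts(self, X, y) -> np.ndarray:
        raise NotImplementedError

    def _theta_bounds(self, X) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def _inhibition_theta(self, d: np.ndarray, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _store(self, theta: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> None:
        raise NotImplementedError

    def _tie_key(self, theta: np.ndarray) -> tuple:
        return tuple(theta)

    def _start_groups(self, starts: np.ndarray):
        """Grouping key per start; the best start of every group is always
        polished (None = no grouping)."""
        return None

    #: polish at most this many starts (global best by initial RMSE, plus
    #: the best start of every group so no branch of the lattice is lost)
    _max_polish = 8

    def _select_starts(self, starts, rmse0) -> list[int]:
        order = np.argsort(rmse0, kind="stable")
        selected = list(order[: self._max_polish])
        groups = self._start_groups(starts)
        if groups is not None:
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                selected.append(idx[np.argmin(rmse0[idx])])
        return sorted(set(int(i) for i in selected))

    # -- fitting -----------------------------------------------------------
    def _grid_range(self, X) -> tuple[float, float]:
        gmin, gmax = float(np.min(X)), float(np.max(X))
        return (gmin / 10 ** self.bounds_decades_below,
                gmax * 10 ** self.bounds_decades_above)

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        if np.unique(X).size < 4:
            raise ValueError(
                f"need >= 4 distinct concentrations to fit, got {np.unique(X).size}"
            )
        lo, hi = self._theta_bounds(X)

        def residuals(theta):
            return y - (1.0 - self._inhibition_theta(X, theta))

        best = None  # (rmse, tie_key, theta, success)
        starts = np.clip(self._starts(X, y), lo, hi)
        rmse0 = np.array([float(np.sqrt(np.mean(residuals(t) ** 2)))
                          for t in starts])
        for i in self._select_starts(starts, rmse0):
            theta0 = starts[i]
            try:
                res = least_squares(residuals, theta0, bounds=(lo, hi),
                                    method="trf", x_scale=1.0,
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            r = float(np.sqrt(np.mean(res.fun ** 2)))
            cand = (r, self._tie_key(res.x), res.x, bool(res.success))
            if best is None or cand[0] < best[0] - _TIE_TOL or (
                    abs(cand[0] - best[0]) <= _TIE_TOL and cand[1] < best[1]):
                best = cand
        if best is None:
            raise RuntimeError("all optimizer starts failed")
        r, _, theta, success = best
        self.n_features_in_ = 1
        self.n_points_ = int(X.size)
        self.starts_tried_ = int(len(starts))
        self.converged_ = success
        self.rmse_ = r
        self._store(theta, lo, hi)
        return self

    def predict(self, X):
        """Model relative viability, 1 - I(d), at concentrations X (nM)."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        d = X[:, 0] if X.ndim == 2 else X
        return 1.0 - self._inhibition_theta(d, self._theta_)


class MonophasicCurveFit(_CurveFitBase):
    """Single-target fit V = 1 - D/(D + IC50), the classical IC50 model.

    Fitted attributes: `ic50_` (nM), `rmse_`, `at_bound_`, `converged_`,
    `n_points_`, `starts_tried_`, `params_`.
    """

    def __init__(self, n_starts: int = 8, bounds_decades_below: float = 2.0,
                 bounds_decades_above: float = 2.0):
        super().__init__(bounds_decades_below, bounds_decades_above)
        self.n_starts = n_starts

    def _theta_bounds(self, X):
        lo, hi = self._grid_range(X)
        return np.array([np.log10(lo)]), np.array([np.log10(hi)])

    def _starts(self, X, y):
        lo, hi = self._grid_range(X)
        return np.log10(np.geomspace(lo, hi, self.n_starts))[:, None]

    def _inhibition_theta(self, d, theta):
        return eval_monophasic(d, 10.0 ** theta[0])

    def _store(self, theta, lo, hi):
        self.ic50_ = float(10.0 ** theta[0])
        self.at_bound_ = frozenset(
            {"ic50"} if _near_bound(theta[0], lo[0], hi[0]) else ())
        self.params_ = MonophasicParams(self.ic50_)
        self._theta_ = theta


class HillCurveFit(_CurveFitBase):
    """Modified Hill fit V = 1 - Imax * D^n / (IC50*^n + D^n), with I0 = 0.

    Bounds: Imax in (0, 1.2], n in [0.05, 10], IC50* spanning the tested
    grid plus the configured decades. Fitted attributes: `i_max_`,
    `ic50_star_` (nM), `n_` (Hill coefficient), plus the shared ones.
    """

    def __init__(self, i_max_max: float = 1.2, n_bounds: tuple = (0.05, 10.0),
                 bounds_decades_below: float = 2.0,
                 bounds_decades_above: float = 2.0):
        super().__init__(bounds_decades_below, bounds_decades_above)
        self.i_max_max = i_max_max
        self.n_bounds = n_bounds

    def _theta_bounds(self, X):
        lo, hi = self._grid_range(X)
        return (np.array([1e-6, np.log10(lo), self.n_bounds[0]]),
                np.array([self.i_max_max, np.log10(hi), self.n_bounds[1]]))

    def _starts(self, X, y):
        blo, bhi = self._grid_range(X)
        # span the full bound range so degenerate ridges (flat data pushing
        # i_max to its floor and ic50 to its ceiling) are reachable
        ic50s = np.log10(np.geomspace(blo, bhi, 5))
        starts = [(imax, lic, n)
                  for imax in (0.05, 0.5, 1.0)
                  for lic in ic50s
                  for n in (0.3, 1.0, 3.0)]
        return np.array(starts)

    def _inhibition_theta(self, d, theta):
        return eval_hill(d, theta[0], 10.0 ** theta[1], theta[2])

    def _start_groups(self, starts):
        return starts[:, 0]  # keep the best start per i_max branch

    def _store(self, theta, lo, hi):
        self.i_max_ = float(theta[0])
        self.ic50_star_ = float(10.0 ** theta[1])
        self.n_ = float(theta[2])
        names = ("i_max", "ic50_star", "n")
        self.at_bound_ = frozenset(
            nm for nm, t, l, h in zip(names, theta, lo, hi) if _near_bound(t, l, h))
        self.params_ = HillParams(max(self.i_max_, 1e-12), self.ic50_star_, self.n_)
        self._theta_ = theta

    def _tie_key(self, theta):
        return (theta[1], theta[0], theta[2])


class BiphasicCurveFit(_CurveFitBase):
    """Two-site fit V = 1 - F1*D/(D+Kd1) - (1-F1)*D/(D+Kd2).

    F1 is the target-specific fraction of viability with affinity Kd1; the
    remainder F2 = 1 - F1 responds only through the off-target phase Kd2.
    Phase 1 is defined as the high-affinity phase (kd1 <= kd2), resolving
    the label-switching symmetry. Kd1 bounds span the tested grid plus two
    decades either side; the Kd2 upper bound extends six decades above the
    grid so that largely-resistant plateaus (Kd2 > 1000 uM) are representable.
    Bound hits are flagged in `at_bound_`, not errors.

    Fitted attributes: `f1_`, `kd1_`, `kd2_` (nM), `f2_`, plus the shared
    `rmse_`, `at_bound_`, `converged_`, `n_points_`, `starts_tried_`.
    """

    def __init__(self, f1_starts: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
                 kd_starts_per_axis: int = 4,
                 bounds_decades_below: float = 2.0,
                 bounds_decades_above: float = 2.0,
                 kd2_decades_above: float = 6.0):
        super().__init__(bounds_decades_below, bounds_decades_above)
        self.f1_starts = f1_starts
        self.kd_starts_per_axis = kd_starts_per_axis
        self.kd2_decades_above = kd2_decades_above

    def _theta_bounds(self, X):
        lo, hi = self._grid_range(X)
        kd2_hi = float(np.max(X)) * 10 ** self.kd2_decades_above
        return (np.array([0.0, np.log10(lo), np.log10(lo)]),
                np.array([1.0, np.log10(hi), np.log10(kd2_hi)]))

    def _starts(self, X, y):
        gmin, gmax = float(np.min(X)), float(np.max(X))
        k = self.kd_starts_per_axis
        kd1s = np.log10(np.geomspace(gmin, gmax, k))
        kd2s = np.log10(np.geomspace(gmin * 10, gmax * 10 ** (self.kd2_decades_above - 2), k))
        starts = [(f1, l1, l2)
                  for f1 in self.f1_starts
                  for l1 in kd1s
                  for l2 in kd2s
                  if l2 >= l1]
        return np.array(starts)

    def _inhibition_theta(self, d, theta):
        return eval_biphasic(d, theta[0], 10.0 ** theta[1], 10.0 ** theta[2])

    def _start_groups(self, starts):
        # always polish the best start of every f1 branch, so the f1 = 1
        # (monophasic-limit) branch survives prefiltering and degenerate
        # single-phase curves resolve to F1 = 100% via the tie-break
        return starts[:, 0]

    def _tie_key(self, theta):
        # Among RMSE ties, prefer the largest target-specific fraction, then
        # the smallest kd1, then the smallest kd2 (canonical orientation).
        # When kd1 ~ kd2 the model degenerates to monophasic and f1 is
        # unidentified; this rule lands the degenerate mass in phase 1, so a
        # noiseless single-target curve reports F1 = 1 (the monophasic limit).
        f1, l1, l2 = theta
        if l1 > l2:
            f1, l1, l2 = 1.0 - f1, l2, l1
        return (-f1, l1, l2)

    def _store(self, theta, lo, hi):
        f1, lkd1, lkd2 = float(theta[0]), float(theta[1]), float(theta[2])
        at = set()
        if _near_bound(f1, lo[0], hi[0]):
            at.add("f1")
        if _near_bound(lkd1, lo[1], hi[1]):
            at.add("kd1")
        if _near_bound(lkd2, lo[2], hi[2]):
            at.add("kd2")
        if lkd1 > lkd2:  # relabel so phase 1 is the high-affinity phase
            f1, lkd1, lkd2 = 1.0 - f1, lkd2, lkd1
            at = {{"kd1": "kd2", "kd2": "kd1"}.get(nm, nm) for nm in at}
        self.f1_ = f1
        self.f2_ = 1.0 - f1
        self.kd1_ = float(10.0 ** lkd1)
        self.kd2_ = float(10.0 ** lkd2)
        self.at_bound_ = frozenset(at)
        self.params_ = BiphasicParams(self.f1_, self.kd1_, self.kd2_)
        self._theta_ = np.array([f1, lkd1, lkd2])
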