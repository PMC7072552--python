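"""Dose-response model equations and their closed-form inversions.

Three nested models of relative inhibition I as a function of drug
concentration D (nM):

* monophasic (single-target binding):  I = D / (D + IC50)
* modified Hill:                       I = Imax * D^n / (IC50*^n + D^n)
* biphasic (two-site):                 I = F1*D/(D+Kd1) + (1-F1)*D/(D+Kd2)

The biphasic model splits the response into a high-affinity target-specific
phase (fraction F1, affinity Kd1) and a low-affinity off-target phase
(fraction F2 = 1 - F1, affinity Kd2). The Hill intercept I0 is fixed at zero:
there is no inhibition at zero dose. The monophasic model is the F1 = 1 (or
Kd1 = Kd2) limit of the biphasic model and the Imax = 1, n = 1 limit of the
Hill model.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

__all__ = [
    "MonophasicParams",
    "HillParams",
    "BiphasicParams",
    "ModelParams",
    "UnattainableInhibitionError",
    "eval_monophasic",
    "eval_hill",
    "eval_biphasic",
    "eval_model",
    "analytic_icx",
    "rmse",
    "KD2_RESISTANT_NM",
]

#: Kd2 above this (1000 µM) is displayed as "> 1000 µM" (largely resistant).
KD2_RESISTANT_NM = 1e6


class UnattainableInhibitionError(ValueError):
    """Requested inhibition level exceeds what the model can reach."""


@dataclass(frozen=True)
class MonophasicParams:
    ic50: float  # nM

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError(f"ic50 must be > 0, got {self.ic50}")


@dataclass(frozen=True)
class HillParams:
    i_max: float
    ic50_star: float  # nM
    n: float

    def __post_init__(self) -> None:
        if not 0 < self.i_max <= 1.2:
            raise ValueError(f"i_max must be in (0, 1.2], got {self.i_max}")
        if not self.ic50_star > 0:
            raise ValueError(f"ic50_star must be > 0, got {self.ic50_star}")
        if not self.n > 0:
            raise ValueError(f"Hill coefficient must be > 0, got {self.n}")


@dataclass(frozen=True)
class BiphasicParams:
    """Biphasic two-site parameters; phase 1 is the high-affinity phase.

    The ordering convention kd1 <= kd2 is enforced by relabeling (the model
    is symmetric under (f1, kd1) <-> (1-f1, kd2)).
    """

    f1: float
    kd1: float  # nM
    kd2: float  # nM

    def __post_init__(self) -> None:
        if not 0 <= self.f1 <= 1:
            raise ValueError(f"f1 must be in [0, 1], got {self.f1}")
        if not (self.kd1 > 0 and self.kd2 > 0):
            raise ValueError("kd1 and kd2 must be > 0")
        if self.kd1 > self.kd2:
            object.__setattr__(self, "f1", 1.0 - self.f1)
            kd1, kd2 = self.kd2, self.kd1
            object.__setattr__(self, "kd1", kd1)
            object.__setattr__(self, "kd2", kd2)

    @property
    def f2(self) -> float:
        return 1.0 - self.f1

    @property
    def kd2_resistant(self) -> bool:
        return self.kd2 > KD2_RESISTANT_NM


ModelParams = Union[MonophasicParams, HillParams, BiphasicParams]


def eval_monophasic(d, ic50: float):
    """Single-target inhibition I = D/(D + IC50); in [0, 1), I(0) = 0."""
    d = np.asarray(d, dtype=float)
    out = d / (d + ic50)
    return out if out.ndim else float(out)


def eval_hill(d, i_max: float, ic50_star: float, n: float):
    """Modified Hill inhibition I = Imax * D^n / (IC50*^n + D^n), I0 = 0."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        # compute in log space to avoid overflow for extreme n
        ratio = np.where(d > 0, (d / ic50_star) ** n, 0.0)
    out = i_max * ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def eval_biphasic(d, f1: float, kd1: float, kd2: float):
    """Two-site inhibition I = F1*D/(D+Kd1) + (1-F1)*D/(D+Kd2)."""
    d = np.asarray(d, dtype=float)
    out = f1 * d / (d + kd1) + (1.0 - f1) * d / (d + kd2)
    return out if out.ndim else float(out)


def eval_model(d, params: ModelParams):
    """Evaluate inhibition at dose(s) `d` for any of the three models."""
    if isinstance(params, MonophasicParams):
        return eval_monophasic(d, params.ic50)
    if isinstance(params, HillParams):
        return eval_hill(d, params.i_max, params.ic50_star, params.n)
    if isinstance(params, BiphasicParams):
        return eval_biphasic(d, params.f1, params.kd1, params.kd2)
    raise TypeError(f"unsupported params type {type(params).__name__}")


def _icx_monophasic(x: float, ic50: float) -> float:
    return x * ic50 / (1.0 - x)


def _icx_hill(x: float, i_max: float, ic50_star: float, n: float) -> float:
    if x >= i_max:
        raise UnattainableInhibitionError(
            f"inhibition level {x} is not attainable: Hill model saturates at {i_max}"
        )
    return ic50_star * (x / (i_max - x)) ** (1.0 / n)


def _icx_biphasic(x: float, f1: float, kd1: float, kd2: float) -> float:
    # Clearing denominators in F1*D/(D+Kd1) + (1-F1)*D/(D+Kd2) = x gives
    # (1-x) D^2 + [F1*Kd2 + (1-F1)*Kd1 - x (Kd1 + Kd2)] D - x Kd1 Kd2 = 0.
    # The constant term is negative, so exactly one root is positive.
    a = 1.0 - x
    b = f1 * kd2 + (1.0 - f1) * kd1 - x * (kd1 + kd2)
    c = -x * kd1 * kd2
    disc = b * b - 4.0 * a * c
    return (-b + np.sqrt(disc)) / (2.0 * a)


def analytic_icx(params: ModelParams, x: float) -> float:
    """Concentration (nM) at which the model reaches inhibition level `x`.

    Closed-form inversion of each model. Raises
    :class:`UnattainableInhibitionError` when `x` is at or above the model's
    supremum (1 for monophasic/biphasic, Imax for Hill).
    """
    if not 0 < x < 1:
        raise UnattainableInhibitionError(
            f"inhibition level must be in (0, 1), got {x}"
        )
    if isinstance(params, MonophasicParams):
        return _icx_monophasic(x, params.ic50)
    if isinstance(params, HillParams):
        return _icx_hill(x, params.i_max, params.ic50_star, params.n)
    if isinstance(params, BiphasicParams):
        return _icx_biphasic(x, params.f1, params.kd1, params.kd2)
    raise TypeError(f"unsupported params type {type(params).__name__}")


def rmse(curve, predict_inhibition: Callable[[np.ndarray], np.ndarray],
         use_replicate_means: bool = False) -> float:
    """Root mean square error between observed and model viability.

    Computed on the viability scale, V = 1 - I, over all replicate points by
    default (equivalently the inhibition-scale RMSE).
    """
    if use_replicate_means:
        conc, via = curve.replicate_means()
    else:
        conc, via = curve.conc_nM, curve.viability
    if conc.size == 0:
        raise ValueError("cannot compute RMSE of an empty curve")
    predicted_viability = 1.0 - np.asarray(predict_inhibition(conc), dtype=float)
    return float(np.sqrt(np.mean((via - predicted_viability) ** 2)))
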