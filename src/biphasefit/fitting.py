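"""Curve-level fitting interface and model comparison.

Thin wrappers that run the sklearn-style estimators on a
:class:`~biphasefit.curve.DoseResponseCurve` and package the results, plus
the monophasic-vs-biphasic RMSE comparison used to decide whether a response
is adequately described by single-target binding.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .curve import DoseResponseCurve
from .estimators import BiphasicCurveFit, HillCurveFit, MonophasicCurveFit
from .models import BiphasicParams, HillParams, ModelParams, MonophasicParams

__all__ = ["FitResult", "ModelComparison", "fit_monophasic", "fit_hill",
           "fit_biphasic", "compare_models"]


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one model to one curve by RMSE minimization."""

    model_kind: str  # monophasic | hill | biphasic
    params: ModelParams
    rmse: float
    n_points: int
    at_bound: frozenset[str]
    starts_tried: int
    converged: bool

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass(frozen=True)
class ModelComparison:
    """All three fits plus the preferred model by the RMSE-ratio rule."""

    monophasic: FitResult
    hill: FitResult
    biphasic: FitResult
    preferred: str
    rmse_ratio: float  # monophasic rmse / biphasic rmse
    ratio_threshold: float = 2.0

    @property
    def fits(self) -> dict[str, FitResult]:
        return {"monophasic": self.monophasic, "hill": self.hill,
                "biphasic": self.biphasic}


def _xy(curve: DoseResponseCurve, config: AnalysisConfig):
    if config.use_replicate_means:
        return curve.replicate_means()
    return curve.conc_nM, curve.viability


def _result(kind: str, est, params: ModelParams) -> FitResult:
    return FitResult(kind, params, est.rmse_, est.n_points_, est.at_bound_,
                     est.starts_tried_, est.converged_)


def fit_monophasic(curve: DoseResponseCurve,
                   config: AnalysisConfig | None = None) -> FitResult:
    """Best-RMSE single-target IC50 fit."""
    config = config or AnalysisConfig()
    curve.require_fittable()
    X, y = _xy(curve, config)
    est = MonophasicCurveFit().fit(X, y)
    return _result("monophasic", est, MonophasicParams(est.ic50_))


def fit_hill(curve: DoseResponseCurve,
             config: AnalysisConfig | None = None) -> FitResult:
    """Best-RMSE modified-Hill fit (Imax, IC50*, n varied; I0 = 0)."""
    config = config or AnalysisConfig()
    curve.require_fittable()
    X, y = _xy(curve, config)
    est = HillCurveFit().fit(X, y)
    return _result("hill", est, est.params_)


def fit_biphasic(curve: DoseResponseCurve,
                 config: AnalysisConfig | None = None) -> FitResult:
    """Best-RMSE two-site biphasic fit (F1, Kd1, Kd2 varied; F2 = 1 - F1)."""
    config = config or AnalysisConfig()
    curve.require_fittable()
    X, y = _xy(curve, config)
    est = BiphasicCurveFit(
        f1_starts=config.f1_starts,
        kd_starts_per_axis=config.kd_starts_per_axis,
    ).fit(X, y)
    return _result("biphasic", est, BiphasicParams(est.f1_, est.kd1_, est.kd2_))


def compare_models(curve: DoseResponseCurve,
                   config: AnalysisConfig | None = None) -> ModelComparison:
    """Fit all three models and prefer biphasic only when it clearly wins.

    The biphasic model nests the monophasic one, so its RMSE is never worse;
    it is preferred when RMSE(mono)/RMSE(biphasic) exceeds
    ``config.rmse_ratio_threshold`` (default 2). The Hill fit is reported
    descriptively and never preferred by default.
    """
    config = config or AnalysisConfig()
    mono = fit_monophasic(curve, config)
    hill = fit_hill(curve, config)
    bi = fit_biphasic(curve, config)
    # below this both fits are exact to numerical precision; ratio is a tie
    exact = 1e-9
    if mono.rmse < exact:
        ratio = 1.0
    elif bi.rmse < exact:
        ratio = np.inf
    else:
        ratio = mono.rmse / bi.rmse
    preferred = "biphasic" if ratio > config.rmse_ratio_threshold else "monophasic"
    return ModelComparison(mono, hill, bi, preferred, float(ratio),
                           config.rmse_ratio_threshold)
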