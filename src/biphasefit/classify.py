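"""Screen normalization, QC filtering, and four-way response classification.

A screening response to a targeted agent falls into one of four categories:

* LV — low viability at every dose (drug-independent; typically suspension
  lines that read low in the assay);
* NI — no inhibition over the tested range;
* MP — monophasic response: the target-specific fraction F1 of the biphasic
  fit is at or above 0.85, so single-target binding describes the curve;
* BP — biphasic response: dose-dependent inhibition with F1 below 0.85,
  the signature of multi-driver dependence.

Raw plate readings are normalized to controls; when a low-dose reading
exceeds the control (a growth uptick), the highest reading replaces the
control so relative viability is anchored at 1.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .curve import DoseResponseCurve
from .fitting import FitResult, compare_models, fit_biphasic, fit_monophasic
from .models import KD2_RESISTANT_NM

__all__ = ["ResponseCategory", "QCRejection", "BatchReport",
           "normalize_viability", "qc_filter", "classify_response",
           "batch_analyze"]

CATEGORIES = ("LV", "NI", "MP", "BP")


@dataclass(frozen=True)
class ResponseCategory:
    """Classification label plus the evidence it rests on."""

    label: str  # LV | NI | MP | BP
    mean_viability: float
    viability_range: float
    max_inhibition: float
    monophasic: FitResult | None = None
    biphasic: FitResult | None = None
    f1: float | None = None
    kd2_unreliable: bool = False  # top dose < 10*kd1: second phase unobserved
    rmse_ratio: float | None = None  # monophasic rmse / biphasic rmse

    def __post_init__(self) -> None:
        if self.label not in CATEGORIES:
            raise ValueError(f"unknown category {self.label!r}")


@dataclass(frozen=True)
class QCRejection:
    curve: DoseResponseCurve
    reason: str  # high-rmse | non-monotone-jump


@dataclass
class BatchReport:
    table: pd.DataFrame
    tally: Counter
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    rejected: list[QCRejection] = field(default_factory=list)


def normalize_viability(table: pd.DataFrame) -> list[DoseResponseCurve]:
    """Normalize raw readings to relative viability, one curve per series.

    Expects long-format columns ``cell_line, drug, conc_nM, raw`` and either
    an ``is_control`` boolean column or a separate ``control`` column carrying
    the control reading. Per cell line x drug: relative viability =
    raw / control; if any treated reading exceeds the control, the maximum
    reading is used as the control instead, so viability is 1 at that point.
    """
    required = {"cell_line", "drug", "conc_nM", "raw"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"raw viability table missing columns {sorted(missing)}")
    curves = []
    for (cell, drug), grp in table.groupby(["cell_line", "drug"], sort=True):
        if "is_control" in grp.columns:
            ctrl_rows = grp[grp["is_control"].astype(bool)]
            treated = grp[~grp["is_control"].astype(bool)]
            if ctrl_rows.empty:
                raise ValueError(f"no control reading for {cell}/{drug}")
            control = float(ctrl_rows["raw"].mean())
        elif "control" in grp.columns:
            treated = grp
            control = float(grp["control"].iloc[0])
            if not np.isfinite(control):
                raise ValueError(f"no control reading for {cell}/{drug}")
        else:
            raise ValueError(
                f"no control information (is_control or control column) for {cell}/{drug}")
        readings = treated["raw"].to_numpy(dtype=float)
        if readings.size and float(np.max(readings)) > control:
            control = float(np.max(readings))
        rep = treated["replicate"].to_numpy() if "replicate" in treated.columns \
            else np.zeros(len(treated), dtype=int)
        curves.append(DoseResponseCurve(
            str(cell), str(drug),
            treated["conc_nM"].to_numpy(dtype=float),
            readings / control,
            rep,
            metadata={"control_used": control},
        ))
    return curves


def _max_step_increase(curve: DoseResponseCurve) -> float:
    _, means = curve.replicate_means()
    if means.size < 2:
        return 0.0
    return float(np.max(np.diff(means)))


def qc_filter(curves: Iterable[DoseResponseCurve],
              config: AnalysisConfig | None = None,
              ) -> tuple[list[DoseResponseCurve], list[QCRejection]]:
    """Drop scattered curves; every rejection carries a reason code.

    A curve is rejected when the best of the three model fits still leaves
    RMSE above ``qc_rmse_threshold`` (reason ``high-rmse``) or when relative
    viability jumps up by more than ``qc_jump_threshold`` between adjacent
    doses (reason ``non-monotone-jump``).
    """
    config = config or AnalysisConfig()
    kept, rejected = [], []
    for curve in curves:
        if _max_step_increase(curve) > config.qc_jump_threshold:
            rejected.append(QCRejection(curve, "non-monotone-jump"))
            continue
        cmp = compare_models(curve, config)
        best = min(f.rmse for f in cmp.fits.values())
        if best > config.qc_rmse_threshold:
            rejected.append(QCRejection(curve, "high-rmse"))
            continue
        kept.append(curve)
    return kept, rejected


def classify_response(curve: DoseResponseCurve,
                      config: AnalysisConfig | None = None) -> ResponseCategory:
    """Assign one of LV / NI / MP / BP to a normalized, QC-passed curve.

    Decision order: LV when mean viability is below ``lv_threshold`` and the
    dose-mean range is below ``lv_range`` (flat and low, i.e. not
    drug-driven); else NI when the maximum inhibition stays below
    ``ni_threshold``; else MP when the response is effectively single-target
    -- either the fitted biphasic F1 is at or above ``f1_mp_threshold``, or
    the monophasic fit is not clearly beaten by the biphasic one
    (RMSE(mono)/RMSE(biphasic) <= ``rmse_ratio_threshold``). The ratio guard
    matters because on a noisy single-target curve the extra biphasic
    parameters only absorb noise, collapsing the phases (kd1 ~ kd2) or
    parking a near-zero-weight phase at a bound, either of which leaves F1
    unidentified; MP cells are precisely those that fit both equations
    similarly well. Else BP.
    """
    config = config or AnalysisConfig()
    _, means = curve.replicate_means()
    mean_v = float(np.mean(means))
    rng = float(np.max(means) - np.min(means))
    max_inhib = float(1.0 - np.min(means))
    if mean_v < config.lv_threshold and rng < config.lv_range:
        return ResponseCategory("LV", mean_v, rng, max_inhib)
    if max_inhib < config.ni_threshold:
        return ResponseCategory("NI", mean_v, rng, max_inhib)
    mono = fit_monophasic(curve, config)
    bi = fit_biphasic(curve, config)
    f1 = bi.params.f1
    kd2_unreliable = float(np.max(curve.conc_nM)) < 10.0 * bi.params.kd1
    if mono.rmse < 1e-9:  # both exact: single-target to numerical precision
        ratio = 1.0
    elif bi.rmse < 1e-9:
        ratio = float(np.inf)
    else:
        ratio = mono.rmse / bi.rmse
    effectively_mono = ratio <= config.rmse_ratio_threshold
    label = "MP" if (f1 >= config.f1_mp_threshold or effectively_mono) else "BP"
    return ResponseCategory(label, mean_v, rng, max_inhib, mono, bi, f1,
                            kd2_unreliable, ratio)


def _kd_display(value_nM: float, at_bound: bool) -> str:
    if value_nM > KD2_RESISTANT_NM:
        return "> 1000 uM"
    if at_bound:
        return f"> {value_nM / 1e3:.4g} uM"
    return f"{value_nM:.4g} nM"


def batch_analyze(data: pd.DataFrame | Iterable[DoseResponseCurve],
                  config: AnalysisConfig | None = None,
                  apply_qc: bool = True) -> BatchReport:
    """Classify every curve in a screen and tally the categories.

    Accepts either a raw viability table (normalized here; duplicate
    cell line x drug rows merge as replicates) or pre-normalized curves.
    Per-curve errors are collected, not fatal.
    """
    config = config or AnalysisConfig()
    if isinstance(data, pd.DataFrame):
        curves = normalize_viability(data)
    else:
        curves = list(data)
    rejected: list[QCRejection] = []
    if apply_qc:
        curves, rejected = qc_filter(curves, config)
    rows, errors = [], []
    tally: Counter = Counter()
    for curve in curves:
        try:
            cat = classify_response(curve, config)
        except Exception as exc:  # pragma: no cover - defensive
            errors.append((curve.cell_line, curve.drug, str(exc)))
            continue
        tally[cat.label] += 1
        row: dict[str, Any] = {
            "cell_line": curve.cell_line,
            "drug": curve.drug,
            "category": cat.label,
            "mean_viability": cat.mean_viability,
            "max_inhibition": cat.max_inhibition,
        }
        if cat.biphasic is not None:
            bp, mono = cat.biphasic, cat.monophasic
            row.update({
                "f1": bp.params.f1,
                "kd1_nM": bp.params.kd1,
                "kd2_nM": bp.params.kd2,
                "kd2_display": _kd_display(bp.params.kd2,
                                           "kd2" in bp.at_bound or cat.kd2_unreliable),
                "kd2_unreliable": cat.kd2_unreliable,
                "ic50_nM": mono.params.ic50,
                "rmse_monophasic": mono.rmse,
                "rmse_biphasic": bp.rmse,
            })
        rows.append(row)
    columns = ["cell_line", "drug", "category", "mean_viability",
               "max_inhibition", "f1", "kd1_nM", "kd2_nM", "kd2_display",
               "kd2_unreliable", "ic50_nM", "rmse_monophasic", "rmse_biphasic"]
    table = pd.DataFrame(rows, columns=columns) if rows else \
        pd.DataFrame(columns=columns)
    return BatchReport(table, tally, errors, rejected)
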