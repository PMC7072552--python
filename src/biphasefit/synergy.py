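"""Combination synergy analysis via the dose reduction index (DRI).

The DRI at inhibition level x measures how many fold the drug doses can be
reduced by combining two drugs at a 1:1 ratio:

    DRI = ICx_a * ICx_b / (ICx_ab * (ICx_a + ICx_b))

where ICx_a and ICx_b are the single-agent concentrations reaching x
inhibition and ICx_ab is the total combined dose reaching the same level.
This aggregate form is symmetric in the two drugs and invariant to unit
rescaling. ICx levels are read off the measured curves by log-linear
interpolation of replicate-mean inhibition (the reproducible analogue of
reading them manually from a graph), or from the fitted biphasic model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import AnalysisConfig
from .curve import DoseResponseCurve
from .fitting import fit_biphasic
from .models import UnattainableInhibitionError, analytic_icx

__all__ = ["CombinationDataset", "ICxEstimate", "DRIRow", "DRIReport",
           "estimate_icx", "compute_dri", "dri_table"]


@dataclass
class CombinationDataset:
    """Single-agent curves for drugs A and B plus their 1:1 combination.

    The combination curve's dose axis is the total combined drug (each drug
    contributes half of every dose).
    """

    curve_a: DoseResponseCurve
    curve_b: DoseResponseCurve
    curve_ab: DoseResponseCurve

    def __post_init__(self) -> None:
        lines = {self.curve_a.cell_line, self.curve_b.cell_line,
                 self.curve_ab.cell_line}
        if len(lines) != 1:
            raise ValueError(
                f"combination curves must share a cell line, got {sorted(lines)}")


@dataclass(frozen=True)
class ICxEstimate:
    """Concentration reaching inhibition level x, or flagged unattainable."""

    x: float
    conc_nM: float | None
    method: str  # interpolated | from_fit
    attainable: bool

    def __post_init__(self) -> None:
        if not 0 < self.x < 1:
            raise ValueError(f"inhibition level must be in (0, 1), got {self.x}")
        if self.attainable and not (self.conc_nM is not None and self.conc_nM > 0):
            raise ValueError("attainable estimate requires a positive concentration")


@dataclass(frozen=True)
class DRIRow:
    level: float
    icx_a: ICxEstimate
    icx_b: ICxEstimate
    icx_ab: ICxEstimate
    dri: float | None  # None mirrors the NC (not calculated) convention

    @property
    def attainable(self) -> bool:
        return self.dri is not None


@dataclass(frozen=True)
class DRIReport:
    rows: tuple[DRIRow, ...]
    method: str

    def __iter__(self):
        return iter(self.rows)

    def as_dict(self) -> dict:
        def icx(e: ICxEstimate):
            return {"conc_nM": e.conc_nM, "attainable": e.attainable}

        return {
            "method": self.method,
            "levels": [
                {"level": r.level, "icx_a": icx(r.icx_a), "icx_b": icx(r.icx_b),
                 "icx_ab": icx(r.icx_ab), "dri": r.dri}
                for r in self.rows
            ],
        }


def estimate_icx(curve: DoseResponseCurve, x: float,
                 method: str = "interpolated",
                 config: AnalysisConfig | None = None) -> ICxEstimate:
    """Estimate the concentration producing x fractional inhibition.

    method="interpolated": linear interpolation of replicate-mean inhibition
    against log10(concentration) between the bracketing measured points.
    method="from_fit": closed-form ICx on the best biphasic fit.

    A level above the maximum observed inhibition is flagged
    ``attainable=False`` rather than raising.
    """
    if not 0 < x < 1:
        raise ValueError(f"inhibition level must be in (0, 1), got {x}")
    conc, via = curve.replicate_means()
    inhib = 1.0 - via
    if float(np.max(inhib)) < x:
        return ICxEstimate(x, None, method, attainable=False)
    if method == "interpolated":
        if inhib[0] >= x:
            # already past the level at the lowest tested dose
            return ICxEstimate(x, float(conc[0]), method, attainable=True)
        # first upward crossing walking from low dose
        idx = int(np.argmax(inhib >= x))
        i0, i1 = inhib[idx - 1], inhib[idx]
        l0, l1 = np.log10(conc[idx - 1]), np.log10(conc[idx])
        frac = (x - i0) / (i1 - i0)
        return ICxEstimate(x, float(10.0 ** (l0 + frac * (l1 - l0))), method, True)
    if method == "from_fit":
        fit = fit_biphasic(curve, config)
        try:
            d = analytic_icx(fit.params, x)
        except UnattainableInhibitionError:
            return ICxEstimate(x, None, method, attainable=False)
        return ICxEstimate(x, float(d), method, attainable=True)
    raise ValueError(f"unknown ICx method {method!r}")


def compute_dri(icx_a: float, icx_b: float, icx_ab: float) -> float:
    """Aggregate dose reduction index ICa*ICb / (ICab*(ICa+ICb)).

    All three concentrations must be positive and share a unit; the result
    is a unit-free fold value, symmetric in the two single agents.
    """
    for name, v in (("icx_a", icx_a), ("icx_b", icx_b), ("icx_ab", icx_ab)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return icx_a * icx_b / (icx_ab * (icx_a + icx_b))


def dri_table(combo: CombinationDataset,
              levels: Sequence[float] | None = None,
              method: str | None = None,
              config: AnalysisConfig | None = None) -> DRIReport:
    """DRI at each requested inhibition level for a 1:1 combination.

    Levels that one or more curves never reach are reported with
    ``dri=None`` (the NC, not-calculated, convention).
    """
    config = config or AnalysisConfig()
    levels = tuple(levels) if levels is not None else config.dri_levels
    method = method or config.icx_method
    rows = []
    for x in levels:
        ea = estimate_icx(combo.curve_a, x, method, config)
        eb = estimate_icx(combo.curve_b, x, method, config)
        eab = estimate_icx(combo.curve_ab, x, method, config)
        if ea.attainable and eb.attainable and eab.attainable:
            dri = compute_dri(ea.conc_nM, eb.conc_nM, eab.conc_nM)
        else:
            dri = None
        rows.append(DRIRow(x, ea, eb, eab, dri))
    return DRIReport(tuple(rows), method)
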