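"""Dose-response data containers and concentration unit handling.

Concentrations are stored internally in nanomolar (nM). Micromolar and molar
inputs are converted at the boundary; conversions are exact powers of ten.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

__all__ = ["Concentration", "DoseResponseCurve", "to_nM", "UNIT_TO_NM"]

#: Exact power-of-ten factors to the canonical nanomolar unit.
UNIT_TO_NM: dict[str, float] = {
    "nM": 1.0,
    "nm": 1.0,
    "uM": 1e3,
    "um": 1e3,
    "µM": 1e3,  # µM
    "µm": 1e3,
    "mM": 1e6,
    "M": 1e9,
}


def to_nM(value: float, unit: str = "nM") -> float:
    """Convert a concentration to nanomolar.

    Parameters
    ----------
    value : float
        Non-negative concentration in `unit`.
    unit : str
        One of nM, uM (µM), mM, M.
    """
    try:
        factor = UNIT_TO_NM[unit.strip()]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None
    if value < 0:
        raise ValueError(f"negative concentration: {value} {unit}")
    return float(value) * factor


@dataclass(frozen=True)
class Concentration:
    """A drug concentration, canonically in nM.

    The original unit is retained for reporting; arithmetic happens on `.nM`.
    """

    nM: float
    original_unit: str = "nM"

    def __post_init__(self) -> None:
        if not np.isfinite(self.nM) or self.nM < 0:
            raise ValueError(f"concentration must be finite and >= 0, got {self.nM}")

    @classmethod
    def of(cls, value: float, unit: str = "nM") -> "Concentration":
        return cls(to_nM(value, unit), original_unit=unit)

    @property
    def uM(self) -> float:
        return self.nM / 1e3

    def __float__(self) -> float:
        return self.nM


def _as_nM(value: "Concentration | float") -> float:
    return float(value)


@dataclass
class DoseResponseCurve:
    """One cell line x drug viability series with replicates.

    Points are stored as parallel arrays sorted by ascending concentration
    (nM). `viability` is relative viability (1.0 = untreated control); values
    slightly above 1 are permitted as-is, normalization is upstream.
    """

    cell_line: str
    drug: str
    conc_nM: np.ndarray
    viability: np.ndarray
    replicate_id: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.conc_nM.ndim != 1 or self.viability.shape != self.conc_nM.shape:
            raise ValueError("conc_nM and viability must be 1-D arrays of equal length")
        if self.conc_nM.size == 0:
            raise ValueError("empty dose-response curve")
        if np.any(self.conc_nM <= 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability values must be finite")
        if self.replicate_id is None:
            self.replicate_id = np.zeros(self.conc_nM.size, dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id)
            if self.replicate_id.shape != self.conc_nM.shape:
                raise ValueError("replicate_id must match conc_nM in length")
        order = np.lexsort((self.replicate_id, self.conc_nM))
        self.conc_nM = self.conc_nM[order]
        self.viability = self.viability[order]
        self.replicate_id = self.replicate_id[order]

    @classmethod
    def from_points(
        cls,
        cell_line: str,
        drug: str,
        points: Iterable[tuple[float, float] | tuple[float, float, Any]],
        unit: str = "nM",
        **metadata: Any,
    ) -> "DoseResponseCurve":
        """Build a curve from (concentration, viability[, replicate]) tuples."""
        pts = list(points)
        conc = np.array([to_nM(p[0], unit) for p in pts])
        via = np.array([p[1] for p in pts], dtype=float)
        rep = np.array([p[2] if len(p) > 2 else 0 for p in pts])
        return cls(cell_line, drug, conc, via, rep, metadata=dict(metadata))

    @property
    def n_points(self) -> int:
        return int(self.conc_nM.size)

    @property
    def n_distinct_concentrations(self) -> int:
        return int(np.unique(self.conc_nM).size)

    def replicate_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean viability per distinct concentration, sorted ascending."""
        concs, inverse = np.unique(self.conc_nM, return_inverse=True)
        means = np.bincount(inverse, weights=self.viability) / np.bincount(inverse)
        return concs, means

    def inhibition(self) -> np.ndarray:
        """Observed relative inhibition, 1 - viability, per point."""
        return 1.0 - self.viability

    def require_fittable(self, min_distinct: int = 4) -> None:
        if self.n_distinct_concentrations < min_distinct:
            raise ValueError(
                f"curve {self.cell_line}/{self.drug}: need >= {min_distinct} distinct "
                f"concentrations to fit, got {self.n_distinct_concentrations}"
            )

    def scaled(self, factor: float) -> "DoseResponseCurve":
        """Return a copy with all concentrations multiplied by `factor`."""
        return DoseResponseCurve(
            self.cell_line,
            self.drug,
            self.conc_nM * factor,
            self.viability.copy(),
            self.replicate_id.copy(),
            metadata=dict(self.metadata),
        )
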