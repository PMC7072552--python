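"""Seeded synthetic dose-response and combination data generators.

The generators emulate the two canonical assay layouts:

* the 16-point 2x dilution series from 0.6 nM to ~20 uM used for manual
  viability assays (triplicate wells), and
* the 9-point GDSC-style 2x series from 5 nM to 1.28 uM (one well per dose).

Viability is the model value 1 - I(d) plus additive Gaussian noise per
replicate, truncated at a -0.05 floor. All generators are pure functions of
their spec including the seed, so datasets are bit-reproducible.

The combination generator composes independent cell-viability fractions:
drug A alone inhibits the fraction it targets (f_a plus any shared fraction)
with affinity kd_a and the remainder only through its off-target phase, so
each single-agent curve is biphasic; in the 1:1 combination each drug is
applied at half the total dose and survival multiplies across the
independent fractions. This generative construction is for testing the
analysis pipeline, not a biological claim.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .curve import DoseResponseCurve
from .models import (
    BiphasicParams,
    HillParams,
    ModelParams,
    MonophasicParams,
    eval_model,
)
from .synergy import CombinationDataset

__all__ = ["SIXTEEN_POINT_GRID", "GDSC_NINE_POINT_GRID", "SimSpec",
           "ComboSimSpec", "simulate_curve", "simulate_combination",
           "fixture_panel"]

#: 16 concentrations, 2x dilution, 0.6 nM .. 19.66 uM (nM)
SIXTEEN_POINT_GRID = 0.6 * 2.0 ** np.arange(16)
#: 9 concentrations, 2x dilution, 5 nM .. 1.28 uM (nM)
GDSC_NINE_POINT_GRID = 5.0 * 2.0 ** np.arange(9)

_GRIDS = {
    "sixteen_point": SIXTEEN_POINT_GRID,
    "gdsc_nine_point": GDSC_NINE_POINT_GRID,
}

#: viability readings are truncated below at this floor
VIABILITY_FLOOR = -0.05


def _resolve_grid(grid) -> np.ndarray:
    if isinstance(grid, str):
        try:
            return _GRIDS[grid].copy()
        except KeyError:
            raise ValueError(
                f"unknown grid {grid!r}; use one of {sorted(_GRIDS)}") from None
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size == 0 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
        raise ValueError("custom grid must be strictly increasing and positive")
    return g


@dataclass(frozen=True)
class SimSpec:
    """Specification for one synthetic dose-response curve."""

    truth: ModelParams
    grid: str | Sequence[float] = "sixteen_point"
    noise_sd: float = 0.05
    replicates: int = 3
    seed: int = 0
    cell_line: str = "SYN-1"
    drug: str = "drugX"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        _resolve_grid(self.grid)


def simulate_curve(spec: SimSpec) -> DoseResponseCurve:
    """Generate viability = 1 - I_truth(d) + N(0, noise_sd) per replicate."""
    grid = _resolve_grid(spec.grid)
    rng = np.random.default_rng(spec.seed)
    inhib = np.asarray(eval_model(grid, spec.truth), dtype=float)
    conc = np.tile(grid, spec.replicates)
    rep = np.repeat(np.arange(spec.replicates), grid.size)
    via = 1.0 - np.tile(inhib, spec.replicates)
    if spec.noise_sd > 0:
        via = via + rng.normal(0.0, spec.noise_sd, size=via.size)
    via = np.maximum(via, VIABILITY_FLOOR)
    return DoseResponseCurve(spec.cell_line, spec.drug, conc, via, rep,
                             metadata={"truth": spec.truth, "seed": spec.seed,
                                       "noise_sd": spec.noise_sd})


@dataclass(frozen=True)
class ComboSimSpec:
    """Two-drug 1:1 combination over independent viability fractions.

    f_a / f_b are the fractions driven only by drug A's / B's target,
    f_shared is driven by both, f_resistant by neither; they must sum to 1.
    kd2_a / kd2_b are the off-target affinities applying to fractions a drug
    does not target.
    """

    f_a: float
    f_b: float
    f_shared: float = 0.0
    f_resistant: float = 0.0
    kd_a: float = 20.0  # nM
    kd_b: float = 50.0  # nM
    kd2_a: float = 5e4  # nM
    kd2_b: float = 5e4  # nM
    grid: str | Sequence[float] = "sixteen_point"
    noise_sd: float = 0.05
    replicates: int = 3
    seed: int = 0
    cell_line: str = "SYN-1"

    def __post_init__(self) -> None:
        fracs = (self.f_a, self.f_b, self.f_shared, self.f_resistant)
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
        if self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("invalid noise_sd or replicates")


def _survival(d: np.ndarray, kd: float) -> np.ndarray:
    return kd / (d + kd)


def combination_viability(spec: ComboSimSpec, total_dose: np.ndarray,
                          arm: str) -> np.ndarray:
    """Noise-free viability for arm 'a', 'b' or 'ab' of the combination model.

    Single-agent arms see the full dose; in the 'ab' arm each drug is applied
    at half the total dose and survival multiplies across fractions.
    """
    d = np.asarray(total_dose, dtype=float)
    if arm == "a":
        on, off = _survival(d, spec.kd_a), _survival(d, spec.kd2_a)
        return (spec.f_a + spec.f_shared) * on + (spec.f_b + spec.f_resistant) * off
    if arm == "b":
        on, off = _survival(d, spec.kd_b), _survival(d, spec.kd2_b)
        return (spec.f_b + spec.f_shared) * on + (spec.f_a + spec.f_resistant) * off
    if arm == "ab":
        da = db = d / 2.0
        on_a, off_a = _survival(da, spec.kd_a), _survival(da, spec.kd2_a)
        on_b, off_b = _survival(db, spec.kd_b), _survival(db, spec.kd2_b)
        return (spec.f_a * on_a * off_b
                + spec.f_b * on_b * off_a
                + spec.f_shared * on_a * on_b
                + spec.f_resistant * off_a * off_b)
    raise ValueError(f"unknown arm {arm!r}")


def simulate_combination(spec: ComboSimSpec) -> CombinationDataset:
    """Generate aligned drug-A, drug-B and 1:1 combination curves."""
    grid = _resolve_grid(spec.grid)
    rng = np.random.default_rng(spec.seed)
    curves = {}
    for arm, drug in (("a", "drugA"), ("b", "drugB"), ("ab", "drugA+drugB")):
        via0 = combination_viability(spec, grid, arm)
        conc = np.tile(grid, spec.replicates)
        rep = np.repeat(np.arange(spec.replicates), grid.size)
        via = np.tile(via0, spec.replicates)
        if spec.noise_sd > 0:
            via = via + rng.normal(0.0, spec.noise_sd, size=via.size)
        via = np.maximum(via, VIABILITY_FLOOR)
        curves[arm] = DoseResponseCurve(spec.cell_line, drug, conc, via, rep,
                                        metadata={"arm": arm, "seed": spec.seed})
    return CombinationDataset(curves["a"], curves["b"], curves["ab"])


def fixture_panel(seed: int = 0, n_per_category: int = 5,
                  noise_sd: float = 0.03,
                  grid: str = "gdsc_nine_point",
                  ) -> list[tuple[str, DoseResponseCurve]]:
    """Deterministic labeled panel of LV / NI / MP / BP / scattered curves.

    Ground-truth parameters are drawn well away from the classification
    thresholds so that label recovery failures indicate analysis defects,
    not borderline draws. The 'scattered' curves are white noise around
    mid-range viability and exist to exercise QC rejection.
    """
    rng = np.random.default_rng(seed)
    g = _resolve_grid(grid)
    top = float(g[-1])
    panel: list[tuple[str, DoseResponseCurve]] = []
    idx = 0
    for k in range(n_per_category):
        # LV: flat, low viability (baseline well below the 0.35 threshold)
        base = rng.uniform(0.10, 0.22)
        conc = np.tile(g, 3)
        rep = np.repeat(np.arange(3), g.size)
        via = np.maximum(base + rng.normal(0, min(noise_sd, 0.02), conc.size),
                         VIABILITY_FLOOR)
        panel.append(("LV", DoseResponseCurve(f"LV-{k}", "dasatinib", conc, via,
                                              rep, metadata={"label": "LV"})))
        # NI: flat near full viability (max inhibition well below 0.20)
        truth_ni = BiphasicParams(1.0, kd1=top * 200, kd2=top * 2000)
        panel.append(("NI", simulate_curve(SimSpec(
            truth_ni, grid, noise_sd, 3, seed=int(rng.integers(2 ** 31)),
            cell_line=f"NI-{k}", drug="dasatinib"))))
        # MP: near-pure single-target response, IC50 inside the grid
        ic50 = float(rng.uniform(g[1], g[4]))
        truth_mp = MonophasicParams(ic50)
        panel.append(("MP", simulate_curve(SimSpec(
            truth_mp, grid, noise_sd, 3, seed=int(rng.integers(2 ** 31)),
            cell_line=f"MP-{k}", drug="dasatinib"))))
        # BP: F1 clearly below 0.85, Kd1 inside the grid, distant Kd2
        f1 = float(rng.uniform(0.40, 0.70))
        kd1 = float(rng.uniform(g[1], g[3]))
        truth_bp = BiphasicParams(f1, kd1, kd2=top * 100)
        panel.append(("BP", simulate_curve(SimSpec(
            truth_bp, grid, noise_sd, 3, seed=int(rng.integers(2 ** 31)),
            cell_line=f"BP-{k}", drug="dasatinib"))))
        # scattered: white noise around 0.7, should fail QC
        via_s = np.maximum(rng.normal(0.7, 0.30, conc.size), VIABILITY_FLOOR)
        panel.append(("scattered", DoseResponseCurve(
            f"SC-{k}", "dasatinib", conc, via_s, rep,
            metadata={"label": "scattered"})))
        idx += 1
    return panel
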