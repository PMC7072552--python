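"""Normalization, QC filtering, and LV/NI/MP/BP classification."""
import numpy as np
import pandas as pd
import pytest

from biphasefit import (AnalysisConfig, BiphasicParams, DoseResponseCurve,
                        MonophasicParams, SimSpec, batch_analyze,
                        classify_response, normalize_viability, qc_filter,
                        simulate_curve)
from biphasefit.simulate import GDSC_NINE_POINT_GRID


def raw_table(readings, control=1.0, cell="A", drug="dasatinib"):
    conc = GDSC_NINE_POINT_GRID[:len(readings)]
    return pd.DataFrame({
        "cell_line": cell, "drug": drug, "conc_nM": conc,
        "raw": readings, "control": control,
    })


# -- normalization -----------------------------------------------------------

def test_raw_equal_to_control_gives_unit_viability():
    curves = normalize_viability(raw_table([1.0, 1.0, 1.0]))
    np.testing.assert_allclose(curves[0].viability, 1.0)


def test_uptick_renormalizes_by_highest_reading():
    """A low-dose reading above the control becomes the new control."""
    curves = normalize_viability(raw_table([1.10, 0.8, 0.4], control=1.0))
    np.testing.assert_allclose(curves[0].viability,
                               [1.0, 0.8 / 1.10, 0.4 / 1.10], rtol=1e-12)
    assert curves[0].metadata["control_used"] == pytest.approx(1.10)


def test_all_below_control_plain_division():
    curves = normalize_viability(raw_table([0.9, 0.6, 0.3], control=1.2))
    np.testing.assert_allclose(curves[0].viability, [0.75, 0.5, 0.25])


def test_normalization_is_scale_free():
    t = raw_table([1.10, 0.8, 0.4], control=1.0)
    t2 = t.copy()
    t2[["raw", "control"]] *= 2.0
    np.testing.assert_allclose(normalize_viability(t)[0].viability,
                               normalize_viability(t2)[0].viability)


def test_missing_control_names_series():
    t = raw_table([1.0, 0.5, 0.2], control=np.nan, cell="HT-29")
    with pytest.raises(ValueError, match="HT-29"):
        normalize_viability(t)


def test_is_control_rows_dialect():
    t = pd.DataFrame({
        "cell_line": "A", "drug": "d",
        "conc_nM": [0.0, 5.0, 10.0, 20.0],
        "raw": [2.0, 1.8, 1.0, 0.5],
        "is_control": [True, False, False, False],
    })
    curves = normalize_viability(t)
    np.testing.assert_allclose(curves[0].viability, [0.9, 0.5, 0.25])


# -- QC ----------------------------------------------------------------------

def test_clean_model_curve_is_kept():
    curve = simulate_curve(SimSpec(BiphasicParams(0.5, 30.0, 1e5),
                                   "gdsc_nine_point", 0.0, 1))
    kept, rejected = qc_filter([curve])
    assert kept and not rejected


def test_large_upward_jump_rejected():
    curve = simulate_curve(SimSpec(MonophasicParams(50.0), "gdsc_nine_point",
                                   0.0, 1))
    via = curve.viability.copy()
    via[4] = via[5] - 0.5  # carve a 0.5 upward step between doses 4 -> 5
    bad = DoseResponseCurve(curve.cell_line, curve.drug, curve.conc_nM, via)
    kept, rejected = qc_filter([bad])
    assert not kept
    assert rejected[0].reason == "non-monotone-jump"


def test_white_noise_curves_rejected():
    """Pure scatter around 0.7 (sd 0.25) fails QC in >= 18 of 20 seeds."""
    n_rejected = 0
    grid = GDSC_NINE_POINT_GRID
    for seed in range(20):
        rng = np.random.default_rng(seed)
        via = rng.normal(0.7, 0.25, grid.size)
        curve = DoseResponseCurve(f"W{seed}", "d", grid, via)
        _, rejected = qc_filter([curve])
        n_rejected += bool(rejected)
    assert n_rejected >= 18


# -- classification ----------------------------------------------------------

def test_monophasic_curve_classified_mp():
    curve = simulate_curve(SimSpec(MonophasicParams(40.0), "gdsc_nine_point",
                                   0.0, 1))
    cat = classify_response(curve)
    assert cat.label == "MP"
    assert cat.f1 == pytest.approx(1.0, abs=0.01)


def test_flat_full_viability_classified_ni():
    grid = GDSC_NINE_POINT_GRID
    curve = DoseResponseCurve("A", "d", grid, np.full(grid.size, 0.99))
    assert classify_response(curve).label == "NI"


def test_low_flat_viability_classified_lv():
    grid = GDSC_NINE_POINT_GRID
    curve = DoseResponseCurve("A", "d", grid, np.full(grid.size, 0.2))
    assert classify_response(curve).label == "LV"


def test_biphasic_curve_classified_bp_with_kd2_flag():
    curve = simulate_curve(SimSpec(BiphasicParams(0.5, 30.0, 1e5),
                                   "gdsc_nine_point", 0.0, 1))
    cat = classify_response(curve)
    assert cat.label == "BP"
    assert cat.f1 == pytest.approx(0.5, abs=0.05)
    # top dose 1.28 uM << 10 * Kd2 region: second phase unobserved
    assert cat.kd2_unreliable or cat.biphasic.params.kd2 > 1e4


def test_noiseless_category_recovery_away_from_thresholds():
    """Noiseless curves generated well clear of every threshold recover
    their generating category."""
    grid = GDSC_NINE_POINT_GRID
    rng = np.random.default_rng(2024)
    n_ok, n_tot = 0, 0
    for _ in range(8):
        # MP: pure single-target, IC50 mid-grid
        ic50 = float(rng.uniform(grid[1], grid[4]))
        mp = simulate_curve(SimSpec(MonophasicParams(ic50), "gdsc_nine_point",
                                    0.0, 1))
        # BP: F1 well below 0.85, Kd1 mid-grid, remote Kd2
        bp = simulate_curve(SimSpec(
            BiphasicParams(float(rng.uniform(0.4, 0.7)),
                           float(rng.uniform(grid[1], grid[3])), 1e6),
            "gdsc_nine_point", 0.0, 1))
        lv = DoseResponseCurve("A", "d", grid,
                               np.full(grid.size, rng.uniform(0.1, 0.25)))
        ni = DoseResponseCurve("A", "d", grid,
                               np.full(grid.size, rng.uniform(0.95, 1.0)))
        for want, curve in (("MP", mp), ("BP", bp), ("LV", lv), ("NI", ni)):
            n_tot += 1
            n_ok += classify_response(curve).label == want
    assert n_ok / n_tot >= 0.95


def test_labels_exhaustive_and_exclusive():
    for seed in range(6):
        rng = np.random.default_rng(seed)
        truth = BiphasicParams(rng.uniform(0, 1), 10 ** rng.uniform(0.5, 3),
                               10 ** rng.uniform(3, 6))
        curve = simulate_curve(SimSpec(truth, "gdsc_nine_point", 0.05, 1,
                                       seed=seed))
        assert classify_response(curve).label in {"LV", "NI", "MP", "BP"}


# -- batch -------------------------------------------------------------------

def test_batch_tally_on_known_panel():
    curves = []
    grid = GDSC_NINE_POINT_GRID
    for k in range(5):
        curves.append(DoseResponseCurve(f"LV{k}", "d", grid,
                                        np.full(grid.size, 0.15 + 0.01 * k)))
        curves.append(DoseResponseCurve(f"NI{k}", "d", grid,
                                        np.full(grid.size, 1.0 - 0.01 * k)))
        curves.append(simulate_curve(SimSpec(
            MonophasicParams(30.0 + 5 * k), "gdsc_nine_point", 0.0, 1,
            cell_line=f"MP{k}")))
        curves.append(simulate_curve(SimSpec(
            BiphasicParams(0.5, 30.0, 1e5), "gdsc_nine_point", 0.0, 1,
            cell_line=f"BP{k}")))
    report = batch_analyze(curves)
    assert dict(report.tally) == {"LV": 5, "NI": 5, "MP": 5, "BP": 5}
    assert len(report.table) == 20
    assert not report.errors


def test_batch_empty_table():
    empty = pd.DataFrame(columns=["cell_line", "drug", "conc_nM", "raw",
                                  "control"])
    report = batch_analyze(empty)
    assert report.table.empty
    assert not report.tally


def test_duplicate_rows_merge_as_replicates():
    t = pd.concat([raw_table([1.0, 0.7, 0.4]), raw_table([0.9, 0.6, 0.3])])
    curves = normalize_viability(t)
    assert len(curves) == 1
    assert curves[0].n_points == 6
    assert curves[0].n_distinct_concentrations == 3
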