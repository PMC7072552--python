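"""Multi-start RMSE fitting of the three models and model comparison."""
import numpy as np
import pytest

from biphasefit import (AnalysisConfig, BiphasicCurveFit, BiphasicParams,
                        DoseResponseCurve, HillParams, MonophasicParams,
                        SimSpec, compare_models, eval_biphasic,
                        eval_monophasic, fit_biphasic, fit_hill,
                        fit_monophasic, rmse, simulate_curve)


def noiseless(truth, grid="sixteen_point"):
    return simulate_curve(SimSpec(truth, grid, noise_sd=0.0, replicates=1))


def random_curve(seed):
    """Random noisy curve from a random biphasic truth (shared test helper)."""
    rng = np.random.default_rng(seed)
    truth = BiphasicParams(
        f1=rng.uniform(0, 1),
        kd1=10.0 ** rng.uniform(0, 3.5),
        kd2=10.0 ** rng.uniform(2, 6.5),
    )
    return simulate_curve(SimSpec(truth, "gdsc_nine_point",
                                  noise_sd=rng.uniform(0, 0.1), replicates=1,
                                  seed=seed))


def brute_force_biphasic_rmse(curve, n=50):
    """Dense lattice search oracle: best RMSE over a (f1, kd1, kd2) grid."""
    gmin, gmax = curve.conc_nM.min(), curve.conc_nM.max()
    f1 = np.linspace(0, 1, n)
    kd1 = np.geomspace(gmin / 100, gmax * 100, n)
    kd2 = np.geomspace(gmin / 100, gmax * 1e6, n)
    d = curve.conc_nM
    a1 = d / (d + kd1[:, None])          # (n, m)
    a2 = d / (d + kd2[:, None])          # (n, m)
    best = np.inf
    y = curve.viability
    for f in f1:
        inhib = f * a1[:, None, :] + (1 - f) * a2[None, :, :]  # (n, n, m)
        r = np.sqrt(np.mean((y - (1 - inhib)) ** 2, axis=-1))
        best = min(best, float(r.min()))
    return best


# -- monophasic --------------------------------------------------------------

def test_monophasic_self_consistency():
    fit = fit_monophasic(noiseless(MonophasicParams(100.0)))
    assert fit.params.ic50 == pytest.approx(100.0, rel=1e-6)
    assert fit.rmse == pytest.approx(0.0, abs=1e-9)
    assert fit.converged


def test_monophasic_recovers_equivalent_hill_data():
    fit = fit_monophasic(noiseless(HillParams(1.0, 250.0, 1.0)))
    assert fit.params.ic50 == pytest.approx(250.0, rel=1e-6)


def test_monophasic_floor_on_biphasic_data():
    """Single-target model cannot describe a half-resistant response."""
    curve = noiseless(BiphasicParams(0.5, 10.0, 1e5))
    fit = fit_monophasic(curve)
    # dense 1-D grid oracle for the best achievable monophasic RMSE
    grid = np.geomspace(curve.conc_nM.min() / 100, curve.conc_nM.max() * 100,
                        4000)
    oracle = min(rmse(curve, lambda d, k=k: eval_monophasic(d, k))
                 for k in grid)
    assert fit.rmse == pytest.approx(oracle, abs=1e-6)
    assert fit.rmse > 0.05


def test_too_few_points_raises():
    c = DoseResponseCurve("x", "y", np.array([1.0, 2.0, 4.0]),
                          np.array([1.0, 0.8, 0.5]))
    with pytest.raises(ValueError, match="distinct"):
        fit_monophasic(c)


# -- Hill --------------------------------------------------------------------

def test_hill_recovers_monophasic_truth():
    fit = fit_hill(noiseless(MonophasicParams(100.0)))
    assert fit.params.i_max == pytest.approx(1.0, abs=1e-4)
    assert fit.params.n == pytest.approx(1.0, abs=1e-4)
    assert fit.params.ic50_star == pytest.approx(100.0, rel=1e-3)


def test_hill_recovers_shallow_curve():
    """Shallow Hill slope (n = 0.34) and partial Imax are recovered to 1%."""
    fit = fit_hill(noiseless(HillParams(0.8, 500.0, 0.34)))
    assert fit.params.i_max == pytest.approx(0.8, rel=0.01)
    assert fit.params.ic50_star == pytest.approx(500.0, rel=0.01)
    assert fit.params.n == pytest.approx(0.34, rel=0.01)


def test_hill_flags_degenerate_flat_data():
    """Constant full viability has no inhibition signal: the fit runs into a
    parameter bound (i_max floor or ic50* ceiling, the same flat ridge) and
    flags it rather than erroring."""
    c = DoseResponseCurve("x", "y", 0.6 * 2.0 ** np.arange(8), np.ones(8))
    fit = fit_hill(c)
    assert fit.at_bound  # degenerate ridge hit a box bound
    assert fit.converged
    assert fit.rmse == pytest.approx(0.0, abs=1e-6)


# -- biphasic ----------------------------------------------------------------

def test_biphasic_monophasic_limit_165():
    """Noiseless IC50 = 165 nM curve yields F1 = 100%, Kd1 = 165 nM."""
    fit = fit_biphasic(noiseless(MonophasicParams(165.0)))
    assert fit.params.f1 == pytest.approx(1.0, abs=0.005)
    assert fit.params.kd1 == pytest.approx(165.0, rel=0.01)


def test_biphasic_recovers_two_site_truth():
    fit = fit_biphasic(noiseless(BiphasicParams(0.57, 19.8, 1e6)))
    assert fit.params.f1 == pytest.approx(0.57, rel=0.01)
    assert fit.params.f2 == pytest.approx(0.43, rel=0.02)
    assert fit.params.kd1 == pytest.approx(19.8, rel=0.01)
    assert fit.params.kd2 == pytest.approx(1e6, rel=0.01)


def test_biphasic_noisy_f1_recovery_small():
    """Median F1 error under sd = 0.05 noise stays below 0.05 (10 seeds)."""
    errs = []
    for seed in range(10):
        truth = BiphasicParams(0.6, 50.0, 2e5)
        curve = simulate_curve(SimSpec(truth, "sixteen_point", 0.05, 3, seed))
        errs.append(abs(fit_biphasic(curve).params.f1 - truth.f1))
    assert np.median(errs) < 0.05


def test_biphasic_optimizer_matches_lattice_oracle():
    for seed in (1, 2, 3):
        curve = random_curve(seed)
        fit = fit_biphasic(curve)
        assert fit.rmse <= brute_force_biphasic_rmse(curve) + 1e-4


def test_fit_determinism():
    curve = random_curve(7)
    a, b = fit_biphasic(curve), fit_biphasic(curve)
    assert a.params == b.params
    assert a.rmse == b.rmse


def test_scale_equivariance():
    """Multiplying concentrations by c scales the Kds by c, F1 unchanged."""
    curve = random_curve(11)
    a = fit_biphasic(curve)
    b = fit_biphasic(curve.scaled(1000.0))
    assert b.params.kd1 == pytest.approx(a.params.kd1 * 1000.0, rel=1e-6)
    assert b.params.kd2 == pytest.approx(a.params.kd2 * 1000.0, rel=1e-6)
    assert b.params.f1 == pytest.approx(a.params.f1, abs=1e-8)
    assert b.rmse == pytest.approx(a.rmse, rel=1e-9)


# -- estimator surface -------------------------------------------------------

def test_sklearn_estimator_api():
    from sklearn.base import clone
    curve = noiseless(BiphasicParams(0.5, 30.0, 1e5))
    est = BiphasicCurveFit()
    est2 = clone(est)
    est2.fit(curve.conc_nM, curve.viability)
    assert 0 <= est2.f1_ <= 1
    pred = est2.predict(curve.conc_nM[:, None])
    assert pred.shape == curve.viability.shape
    # R^2 of a near-perfect fit
    assert est2.score(curve.conc_nM[:, None], curve.viability) > 0.999
    assert set(est.get_params()) == set(est2.get_params())


# -- comparison --------------------------------------------------------------

def test_compare_prefers_monophasic_on_monophasic_data():
    cmp = compare_models(noiseless(MonophasicParams(100.0)))
    assert cmp.preferred == "monophasic"
    assert cmp.rmse_ratio == pytest.approx(1.0)


def test_compare_prefers_biphasic_on_two_site_data():
    cmp = compare_models(noiseless(BiphasicParams(0.5, 10.0, 1e5)))
    assert cmp.preferred == "biphasic"
    assert cmp.rmse_ratio > 2


@pytest.mark.parametrize("seed", range(8))
def test_nesting_property(seed):
    """Biphasic and Hill nest the monophasic model, so never fit worse."""
    curve = random_curve(seed + 100)
    mono = fit_monophasic(curve).rmse
    assert fit_biphasic(curve).rmse <= mono + 1e-9
    assert fit_hill(curve).rmse <= mono + 1e-9
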