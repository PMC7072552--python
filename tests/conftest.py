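import numpy as np
import pytest

from biphasefit import (AnalysisConfig, BiphasicParams, MonophasicParams,
                        SimSpec, simulate_curve)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def noiseless_mono_165():
    """Noiseless single-target curve, IC50 = 165 nM, 16-point grid."""
    return simulate_curve(SimSpec(MonophasicParams(165.0), "sixteen_point",
                                  noise_sd=0.0, replicates=1))


@pytest.fixture
def noiseless_biphasic_hg6():
    """Noiseless two-site curve: F1 = 0.57, Kd1 = 19.8 nM, Kd2 = 1 mM."""
    return simulate_curve(SimSpec(BiphasicParams(0.57, 19.8, 1e6),
                                  "sixteen_point", noise_sd=0.0, replicates=1))


def bisect_icx(inhibition_fn, x, lo=1e-9, hi=1e15, tol=1e-12):
    """Independent bisection root-finder for I(d) = x (test oracle)."""
    from scipy.optimize import brentq
    return brentq(lambda d: inhibition_fn(d) - x, lo, hi, xtol=tol, rtol=1e-14)
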