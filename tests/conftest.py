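import numpy as np
import pytest

import chitkin as ck


@pytest.fixture(scope="session")
def four_mu_plate():
    """Simulated wild-type 4MU-chitobioside plate at the reference study
    conditions (kcat 1.5/s, Km 33 µM, 5% noise), with standards."""
    spec = ck.reference_four_mu_spec(seed=7)
    curves, truth = ck.make_plate({"WT": spec})
    standards = ck.make_standards(spec, [0, 5, 10, 20, 30, 40, 50, 60, 80, 100])
    return spec, curves, standards, truth


@pytest.fixture(scope="session")
def four_mu_result(four_mu_plate):
    spec, curves, standards, truth = four_mu_plate
    config = ck.default_config("four_mu")
    (result,) = ck.run_assay(curves, config, standards=standards)
    return result


@pytest.fixture(scope="session")
def chito_plate():
    """Simulated wild-type chitO plate (kcat 1.0/s, Km 0.032 % w/v, drifting
    enzyme-free background, 5% noise), with standards."""
    spec = ck.reference_chito_spec(seed=11)
    curves, truth = ck.make_plate({"WT": spec})
    standards = ck.make_standards(spec, [0, 2, 5, 10, 15, 20, 25, 30])
    return spec, curves, standards, truth


@pytest.fixture(scope="session")
def chito_result(chito_plate):
    spec, curves, standards, truth = chito_plate
    config = ck.default_config("chito")
    (result,) = ck.run_assay(curves, config, standards=standards)
    return result


def single_exp_curve(A=100.0, k1=0.01, B=5.0, duration=3600.0, interval=60.0,
                     noise_sd=0.0, seed=0, **meta):
    """Exact relaxation-model curve, optionally with Gaussian noise."""
    t = np.arange(0.0, duration + interval / 2, interval)
    s = A * (-np.expm1(-k1 * t)) + B
    if noise_sd > 0:
        s = s + np.random.default_rng(seed).normal(0, noise_sd, t.shape)
    return ck.ProgressCurve(times=t, signals=s, **meta)
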