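import warnings

import pytest

from rootscale.fixtures import load_fixtures
from rootscale.simulator import AxisParameters


@pytest.fixture(scope="session")
def records():
    return load_fixtures()


@pytest.fixture(scope="session")
def experiment_report():
    """One full three-scenario reproduction run, shared across tests."""
    from rootscale.pipeline import reproduce_experiment

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reproduce_experiment(seed=0)


def tap_params(r=1.0, gf="linear", ln=0.5, nob=1000, sigma=0.0, **kw):
    return AxisParameters(
        order=0, r=r, gf=gf, interbranch=ln, nob=nob, sigma_flex=sigma, **kw
    )


def lateral_params(r=0.8, gf="linear", ln=0.5, nob=1000, sigma=0.0, theta=1.05):
    return AxisParameters(
        order=1, r=r, gf=gf, interbranch=ln, nob=nob, sigma_flex=sigma, theta=theta
    )


def stub_params(r=0.8, gf="linear"):
    return AxisParameters(
        order=2, r=r, gf=gf, apical_zone=0.0, basal_zone=0.5, interbranch=0.0,
        nob=1, theta=1.57, sigma_flex=0.0,
    )
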