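"""Shared fixtures: formulas, analytes, and small fast run geometries."""

import pytest

from osmoquant.chem import parse_formula
from osmoquant.simulate import AnalyteDef, NoiseModel, RunSettings


@pytest.fixture(scope="session")
def cysteinolic():
    """Neutral cysteinolic acid, C3H9NO4S."""
    return parse_formula("C3H9NO4S")


@pytest.fixture(scope="session")
def fast_settings():
    """A short 3-min run geometry that keeps unit tests quick."""
    return RunSettings(length_min=3.0, scan_interval_s=0.5)


@pytest.fixture(scope="session")
def cys_analyte(cysteinolic):
    return AnalyteDef("cysteinolic acid", cysteinolic, rt_min=1.5,
                      response_factor=1.27e7)


@pytest.fixture(scope="session")
def betaine_analyte():
    return AnalyteDef("glycine betaine", parse_formula("C5H11NO2"),
                      rt_min=2.2, response_factor=1.59e8)


@pytest.fixture(scope="session")
def no_noise():
    return NoiseModel.none()
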