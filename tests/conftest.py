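import numpy as np
import pytest

from tbm import TBMParameters, table1_fixture


@pytest.fixture(scope="session")
def usa_both_2001() -> TBMParameters:
    return table1_fixture("usa-2001-both").params


@pytest.fixture(scope="session")
def usa_males_2001() -> TBMParameters:
    return table1_fixture("usa-2001-males").params


@pytest.fixture(scope="session")
def wide_params() -> TBMParameters:
    """A broad-support parameter set: the curve spans most of ages 10-84,
    convenient for experiments that need signal across many age groups."""
    return TBMParameters(
        apex_constant=40.0,
        threshold=3.0,
        maturation_rate=0.05,
        middle_age=47.0,
        quiescent_drive=0.002,
        exponent=9,
    )


def random_valid_parameters(rng: np.random.Generator) -> TBMParameters:
    """Draw one random valid parameter set over realistic ranges."""
    return TBMParameters(
        apex_constant=float(rng.uniform(10.0, 500.0)),
        threshold=float(rng.uniform(2.0, 30.0)),
        maturation_rate=float(rng.uniform(0.05, 0.35)),
        middle_age=float(rng.uniform(40.0, 50.0)),
        quiescent_drive=float(rng.uniform(-0.002, 0.006)),
        exponent=int(rng.choice([7, 9, 11])),
    )
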