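import numpy as np
import pytest

from eliqrisk.distributions import DistributionSpec


@pytest.fixture(scope="session")
def nicotine_spec():
    """Printed nicotine concentration risk function (mg/ml)."""
    return DistributionSpec("normal", (11.023, 13.134), truncation=(0.0, None), unit="mg/ml")


@pytest.fixture(scope="session")
def glycerol_spec():
    return DistributionSpec(
        "weibull_shifted", (1.8104, 44.812), shift=-2.8327, truncation=(0.0, None), unit="g/100g"
    )


@pytest.fixture(scope="session")
def propanediol_spec():
    return DistributionSpec(
        "triangular", (-18.939, 91.8, 100.45), truncation=(0.0, None), unit="g/100g"
    )


@pytest.fixture(scope="session")
def ethylene_glycol_spec():
    return DistributionSpec(
        "loglogistic", (-0.40204, 5.15, 1.8215), truncation=(0.0, None), unit="g/100g"
    )


@pytest.fixture(scope="session")
def thujone_vector():
    """Two detects (183, 178 mg/L) among 54 samples, non-detects as zero."""
    return np.array([0.0] * 52 + [183.0, 178.0])


@pytest.fixture(scope="session")
def factor_specs():
    """Daily amount, vaporization %, bodyweight risk functions."""
    return {
        "liquid_amount_per_day": DistributionSpec(
            "normal_from_quantiles", (0.25, 3, 0.75, 5), truncation=(0.0, None)
        ),
        "vaporization_percentage": DistributionSpec(
            "uniform", (6, 81), truncation=(0.0, None)
        ),
        "bodyweight": DistributionSpec("normal", (73.9, 12), truncation=(0.0, None)),
    }
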