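import warnings

import numpy as np
import pytest

import habresp as hr


@pytest.fixture(autouse=True)
def _quiet_re_warnings():
    # single-year scenarios legitimately drop the year intercept
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="random intercept for 'year'")
        yield


@pytest.fixture(scope="session")
def type2_scenario():
    """40 animals, one focal category with a type-II truth (a=0.3, b=0.05)."""
    return hr.SimScenario(
        n_individuals=20,
        n_months=8,
        fixes_per_month=50,
        categories=("meadow", "old_mixed"),
        reference_category="old_mixed",
        seed=1,
    )


@pytest.fixture(scope="session")
def type2_truth():
    return hr.TruthCurve("meadow", "II", 0.3, 0.05)


@pytest.fixture(scope="session")
def type2_pairwise(type2_scenario, type2_truth):
    telemetry, _ = hr.generate_telemetry(type2_scenario, [type2_truth])
    availability = hr.generate_availability_vectors(type2_scenario)
    data, _ = hr.build_pairwise_dataset(telemetry, availability, "meadow", "old_mixed")
    return data


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
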