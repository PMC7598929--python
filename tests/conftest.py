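import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import equigr as eg
from equigr.equilibrium import baseline_reference
from equigr.scenarios import ScenarioSpec, knockout_catalog, run_scenario

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return eg.fixture_table1()


@pytest.fixture(scope="session")
def ref(params):
    return baseline_reference(params)


@pytest.fixture(scope="session")
def severe_elastin(params, ref):
    """Severe localized elastic-fiber-integrity lesion (fully converged)."""
    spec = ScenarioSpec(insult="elastin_integrity", severity="severe")
    return run_scenario(spec, params, ref=ref)


@pytest.fixture(scope="session")
def catalog_results(params, ref):
    """All axisymmetric catalog scenarios, run once and shared."""
    out = {}
    for spec in knockout_catalog():
        if spec.geometry == "asymmetric":
            continue
        out[spec] = run_scenario(spec, params, ref=ref)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
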