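import numpy as np
import pytest

from lynchcea.markov import CohortEngine
from lynchcea.model import evaluate_all
from lynchcea.parameters import ParameterSet, load_parameters


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return load_parameters()


@pytest.fixture(scope="session")
def base_results(params):
    """Deterministic base-case totals for all six strategies (shared cache)."""
    return evaluate_all(params, engine=CohortEngine(params))


def modify(params: ParameterSet, fn) -> ParameterSet:
    """Rebuild a ParameterSet after applying ``fn`` to its dict form."""
    tree = params.to_dict()
    fn(tree)
    return ParameterSet.from_dict(tree)


def zero_all_risks(tree: dict) -> None:
    """No mortality, no cancer incidence: useful for closed-form checks."""
    epi = tree["epidemiology"]
    for sex in epi["life_table_per_1000py"]:
        epi["life_table_per_1000py"][sex] = {0.0: 0.0, 100.0: 0.0}
    for g in epi["crc_incidence_ls_surveilled_per_1000py"]:
        epi["crc_incidence_ls_surveilled_per_1000py"][g] = {0.0: 0.0, 100.0: 0.0}
    epi["crc_incidence_general_per_1000py_by_age"] = {0.0: 0.0, 100.0: 0.0}
    epi["ec_mortality_rate_ls_per_1000py"] = 0.0
    epi["ec_mortality_sporadic_per_1000py_by_age"] = {0.0: 0.0, 100.0: 0.0}
    for k in epi["crc_mortality_per_1000py_by_age"]:
        epi["crc_mortality_per_1000py_by_age"][k] = {0.0: 0.0, 100.0: 0.0}


def flat_utilities(tree: dict, value: float = 1.0) -> None:
    for sex in tree["utilities"]["baseline_by_age"]:
        tree["utilities"]["baseline_by_age"][sex] = {0.0: value, 100.0: value}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
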