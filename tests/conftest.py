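import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from utilicit import datasets


@pytest.fixture(scope="session")
def catalog():
    return datasets.load_default_catalog()


@pytest.fixture(scope="session")
def reference_summary():
    return datasets.load_reference_summary()


@pytest.fixture(scope="session")
def sg_means(reference_summary):
    block = reference_summary[reference_summary["method"] == "SG"]
    return dict(zip(block["state_id"], block["mean"]))


@pytest.fixture(scope="session")
def rs_means(reference_summary):
    block = reference_summary[reference_summary["method"] == "RS"]
    return dict(zip(block["state_id"], block["mean"]))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A small simulated study (5 respondents) shared across tests."""
    from utilicit.pipeline import RunConfig, simulate_repository

    config = RunConfig(seed=7, n_respondents=5)
    catalog, respondents, records = simulate_repository(config)
    return catalog, respondents, records
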