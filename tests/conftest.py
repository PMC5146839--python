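import pytest

from gonadrisk import ModelConfig, load_cohort_counts
from gonadrisk.data_ingest import CountTable, SexClass
from gonadrisk.pipeline import disease_seed, fit_disease


@pytest.fixture(scope="session")
def cohort_tables():
    return load_cohort_counts()


@pytest.fixture(scope="session")
def cohort_fits(cohort_tables):
    """Default-protocol fits (4 chains, 20k/5k/thin 20) of every cohort disease.

    Shared across convergence, shrinkage and reproduction tests so the
    twelve full fits run once per session.
    """
    fits = {}
    for i, (disease, table) in enumerate(cohort_tables.items()):
        fits[disease] = fit_disease(table, ModelConfig(), disease_seed(1, i))
    return fits


@pytest.fixture
def toy_two_class():
    """Small two-class table with a tractable quadrature posterior."""
    return CountTable(
        "TOY", {SexClass.F: 3, SexClass.NF: 5}, {SexClass.F: 20, SexClass.NF: 25}
    )


@pytest.fixture
def fast_config():
    """Short protocol for tests that only need a rough posterior."""
    return ModelConfig(n_chains=2, n_total=1600, n_warmup=400, thin=2, master_seed=11)
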