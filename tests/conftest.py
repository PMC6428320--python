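import warnings

import pytest

from foramtax.pipeline import run_synthetic_survey
from foramtax.synthetic_data import SimulationConfig, simulate_reference_set


@pytest.fixture(scope="session")
def default_survey():
    """One fully processed synthetic survey shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_synthetic_survey(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def reference_sim():
    """Reference-side simulation only (records, metadata, truth)."""
    return simulate_reference_set(SimulationConfig(seed=11))


@pytest.fixture()
def tiny_config():
    """2 clades x 2 morphospecies x 1 lineage x 1 genotype x 2 basegroups
    x 2 basetypes: exactly 16 truth basetypes."""
    return SimulationConfig(
        seed=3,
        n_clades=2,
        n_morphospecies_per_clade=2,
        n_lineages_per_morphospecies=1,
        n_genotypes_per_lineage=1,
        n_basegroups_per_genotype=2,
        n_basetypes_per_basegroup=2,
        singleton_error_rate=0.0,
    )
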