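import pytest

from chemoprofile.fixtures import FixtureConfig, generate_all, generate_library
from chemoprofile.standardization import compute_zscores, orient_records


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic study: 60 compounds x 8 targets, planted module of 5."""
    config = FixtureConfig(
        n_compounds=60, n_targets=8, module_size=5, n_annotation_terms=10, seed=11
    )
    bundle = generate_all(config)
    orient_records(bundle.records)
    return bundle


@pytest.fixture(scope="session")
def medium_bundle():
    """Default study conditions: 200 compounds x 20 targets."""
    bundle = generate_all(FixtureConfig(seed=1))
    orient_records(bundle.records)
    return bundle


@pytest.fixture(scope="session")
def standardized_bundle(medium_bundle):
    records, stats = compute_zscores(medium_bundle.records)
    return medium_bundle, records, stats


@pytest.fixture(scope="session")
def background_library():
    """Library large enough for SEA background fitting (10x max set size)."""
    return generate_library(FixtureConfig(n_compounds=640))
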