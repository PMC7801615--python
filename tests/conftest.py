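import pytest

from compdecon import (
    SimulationConfig,
    make_profiles,
    normalize_reference,
    qc_filter_cells,
    simulate_paired_bulk,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 6 types, 40 cells/type, 6 subject pairs."""
    return SimulationConfig(
        n_genes=240,
        markers_per_type=20,
        cells_per_type=40,
        n_subjects=6,
        n_left=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_reference_cpm(small_reference):
    ref, truth = small_reference
    return normalize_reference(qc_filter_cells(ref, min_genes=20)), truth


@pytest.fixture(scope="session")
def small_bulk(small_config):
    profiles, markers = make_profiles(small_config)
    return simulate_paired_bulk(small_config, profiles, markers=markers)


@pytest.fixture(scope="session")
def marker_signature(small_config):
    """Noise-free basis: expected CPM of the true marker genes."""
    profiles, markers = make_profiles(small_config)
    rel = profiles / profiles.sum(axis=0)
    genes = sorted(set().union(*markers.values()))
    return rel.loc[genes] * 1e6, markers
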