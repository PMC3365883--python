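import pytest

from coidiet import identify, synthetic_data as sd


@pytest.fixture(scope="session")
def easy_fixture():
    """Small simulated study in the easy regime: tight species clusters,
    well-separated species, dark taxa with referenced congeners."""
    config = sd.SimConfig(
        seed=11,
        n_orders=2,
        families_per_order=2,
        genera_per_family=2,
        species_per_genus=3,
        haplotypes_per_species=2,
        n_queries=60,
        dark_taxon_fraction=0.2,
        cannibal_fraction=0.1,
    )
    return sd.simulate_fixture(config)


@pytest.fixture(scope="session")
def easy_assignments(easy_fixture):
    assignments, report = identify.identify_batch(
        easy_fixture.queries, easy_fixture.references, easy_fixture.ref_taxonomy
    )
    return assignments, report
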