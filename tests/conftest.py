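import numpy as np
import pytest

from squashgs import markers, simpop


@pytest.fixture(scope="session")
def small_map():
    return simpop.GeneticMap.uniform(5, 40, 100.0)


@pytest.fixture(scope="session")
def f2_pop(small_map):
    founders = simpop.make_founders(small_map.n_markers, small_map)
    return simpop.make_f2_population(founders, 200, small_map, simpop.child_rng(11, 0))


@pytest.fixture(scope="session")
def f2_kinship(f2_pop):
    return markers.vanraden_grm(f2_pop.dosage_matrix().astype(float), ids=f2_pop.ids)


@pytest.fixture(scope="session")
def sim_trait_data(small_map, f2_pop):
    """One simulated trait with known architecture on the shared F2 population."""
    arch = simpop.assign_architecture(
        small_map, [0.25], [0.55], rng=simpop.child_rng(11, 1), sites=("S1", "S2"),
        trait_names=["brix"],
    )
    records = simpop.simulate_records(f2_pop, arch, simpop.child_rng(11, 2),
                                      n_fruit_range=(4, 6))
    return arch, records


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from squashgs.cli import generate_fixtures

    outdir = tmp_path_factory.mktemp("fixtures")
    generate_fixtures(outdir, seed=0)
    return outdir
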