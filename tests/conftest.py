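import numpy as np
import pytest
from hypothesis import settings

from pinmap.fixtures import FixtureSpec, make_structure
from pinmap.regions import classify_regions

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def slab():
    """Two-slab complex with exact interface/surface ground truth."""
    return make_structure(FixtureSpec("two_slab_complex", 32, 2.0, seed=0))


@pytest.fixture(scope="session")
def slab_labels(slab):
    model, _ = slab
    return classify_regions(model)


@pytest.fixture(scope="session")
def globule():
    return make_structure(FixtureSpec("globule", 27, 2.0, seed=1))


@pytest.fixture(scope="session")
def helix_dimer():
    return make_structure(FixtureSpec("helix_dimer", 40, 2.0, seed=2))


@pytest.fixture(scope="session")
def all_fixture_models(slab, globule, helix_dimer):
    sphere, sphere_truth = make_structure(FixtureSpec("sphere_pair", 2, 2.0, seed=3))
    return {
        "two_slab_complex": slab,
        "globule": globule,
        "helix_dimer": helix_dimer,
        "sphere_pair": (sphere, sphere_truth),
    }


@pytest.fixture()
def atoms_of():
    """Flatten a StructureModel into (coords, radii) arrays for oracles."""

    def _extract(model, chains=None):
        coords, radii = [], []
        for cid, residues in model.chains.items():
            if chains is not None and cid not in chains:
                continue
            for r in residues:
                for a in r.atoms:
                    coords.append(a.coord)
                    radii.append(a.radius)
        return np.asarray(coords), np.asarray(radii)

    return _extract


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    from pinmap.pipeline import simulate

    path = tmp_path_factory.mktemp("demo")
    simulate(path, seed=17)
    return path
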