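import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from profilecad.io import RunConfig, Selection
from profilecad.pipeline import analyze_population
from profilecad.synthetic import (PhenotypeSpec, make_scene, mutant_phenotype,
                                  render_channels, wt_phenotype)

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None,
                          suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def scene49():
    """A 49-cell confluent monolayer scene, 512x512."""
    return make_scene(49, (512, 512), 0.2, seed=1)


@pytest.fixture(scope="session")
def wt_noiseless(scene49):
    """Noiseless wild-type-like rendering of the shared scene."""
    return render_channels(scene49, PhenotypeSpec(noise_model="none"))


def _pair_selections(scene):
    return [Selection("pair", "s", scene.cells[i].nucleus_center, scene.cells[j].nucleus_center)
            for i, j in scene.adjacency_pairs()]


def _run_population(seed, phenotype, name):
    scene = make_scene(49, (512, 512), 0.2, seed=seed)
    nuclear, protein = render_channels(scene, phenotype)
    result = analyze_population(name, nuclear, protein, _pair_selections(scene), RunConfig(),
                                denoise_gain=phenotype.photon_scale, do_rd=False)
    return scene, result


@pytest.fixture(scope="session")
def wt_study():
    """Wild-type-like population: Poisson noise, 120 internuclear pairs."""
    return _run_population(1, wt_phenotype(), "WT")


@pytest.fixture(scope="session")
def mutant_study():
    """Mutant-like population (reduced membrane + perinuclear peak at 0.8)."""
    return _run_population(2, mutant_phenotype(), "mutant")


def membrane_crossing_fractions(scene):
    """Ground-truth membrane crossing fraction along each pair's IN segment."""
    lab = scene.label_map()
    fractions = []
    for i, j in scene.adjacency_pairs():
        c1 = np.array(scene.cells[i].nucleus_center)
        c2 = np.array(scene.cells[j].nucleus_center)
        ts = np.linspace(0, 1, 400)
        pts = np.outer(1 - ts, c1) + np.outer(ts, c2)
        labs = lab[np.round(pts[:, 0]).astype(int), np.round(pts[:, 1]).astype(int)]
        changed = np.where(labs != labs[0])[0]
        if changed.size:
            fractions.append(ts[changed[0]])
    return np.array(fractions)
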