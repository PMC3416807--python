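import numpy as np
import pytest

from alemeta.ale import AleParams, ale_map, build_null, threshold_map
from alemeta.corpus_io import FociExperiment, Focus
from alemeta.synthetic import default_mask, generate_hub_scenario


@pytest.fixture(scope="session")
def grid32():
    """Default analysis grid: 32^3 voxels of 2 mm, centered on 0."""
    return default_mask()


@pytest.fixture()
def grid16():
    """Small grid for fast unit tests (spans +/-15 mm)."""
    return default_mask(16)


@pytest.fixture()
def grid_1mm():
    """Odd-sized 1 mm grid so that (0,0,0) is a voxel center."""
    return default_mask(31, voxel_size=1.0)


def make_experiment(exp_id, foci, study_id=None, domains=frozenset()):
    return FociExperiment(
        experiment_id=exp_id,
        study_id=study_id or exp_id,
        foci=[Focus(*f) for f in foci],
        domain_labels=set(domains),
    )


@pytest.fixture()
def sleuth_file(tmp_path):
    text = (
        "// Study: smith2001\n"
        "// Experiment: smith2001-1\n"
        "// Domain: pain, attention\n"
        "-2\t4\t6\n"
        "10\t-8\t2\n"
        "0\t0\t12\n"
        "\n"
        "// Study: jones2005\n"
        "// Experiment: jones2005-1\n"
        "// Domain: pain\n"
        "4\t4\t-6\n"
        "-10\t2\t0\n"
        "\n"
    )
    path = tmp_path / "foci.txt"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def hub_run(grid32):
    """Full planted-hub study: 8 networks through the ALE chain.

    Session-scoped because the permutation nulls dominate the suite's
    runtime; every consumer treats the result as read-only.
    """
    networks = generate_hub_scenario(seed=1)
    thresholded = {}
    ale_maps = {}
    for i, net in enumerate(networks):
        params = AleParams(n_permutations=200, seed=100 + i)
        amap = ale_map(net.experiments, params, grid32)
        null = build_null(net.experiments, params, grid32)
        thresholded[net.name] = threshold_map(amap, null, params)
        ale_maps[net.name] = amap
    return {
        "grid": grid32,
        "networks": networks,
        "ale_maps": ale_maps,
        "thresholded": thresholded,
    }
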