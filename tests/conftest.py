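import numpy as np
import pytest
from hypothesis import settings

from deeptms.phantom import build_layered_sphere_phantom, labels_to_sigma, load_tissue_table
from deeptms.pipeline import load_config, run_simulation

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tissue_table():
    return load_tissue_table()


@pytest.fixture(scope="session")
def phantom_2mm():
    """Default layered-sphere head phantom at 2 mm."""
    return build_layered_sphere_phantom()


@pytest.fixture(scope="session")
def sigma_2mm(phantom_2mm, tissue_table):
    return labels_to_sigma(phantom_2mm, tissue_table)


@pytest.fixture(scope="session")
def four_coil_run(tmp_path_factory):
    """Full pipeline on the 2 mm phantom: Halo, double-cone, Fo8, HDA, HFA.

    5 kA at 2.5 kHz; 64 polygon segments per winding keep the Biot-Savart
    stage light while staying well inside the sub-0.1% discretization regime
    needed for V50 comparisons.
    """
    outdir = tmp_path_factory.mktemp("four_coil_run")
    cfg = load_config(
        {
            "volume": {"phantom": {"spacing": 0.002}},
            "stimulus": {"current": 5000.0, "frequency": 2500.0},
            "n_segments": 64,
            "coils": [
                {"name": "halo", "type": "halo", "placement": "halo-ring", "offset": 0.097},
                {"name": "dc", "type": "double_cone", "placement": "vertex-offset", "offset": 0.010},
                {"name": "fo8", "type": "figure_of_eight", "placement": "vertex-offset", "offset": 0.010},
                {"name": "hda", "combine": ["halo", "dc"]},
                {"name": "hfa", "combine": ["halo", "fo8"]},
            ],
            "outputs": {"directory": str(outdir), "write_fields": False},
        }
    )
    return run_simulation(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
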