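import numpy as np
import pytest

from nanokymo import kymo, synthdata


@pytest.fixture(scope="session")
def imaging_stack():
    """50 linear monomers under the standard imaging condition."""
    cfg = synthdata.SimConfig(seed=1)
    stack, truths = synthdata.simulate_kymograph_stack(cfg, 50)
    return cfg, stack, truths


@pytest.fixture(scope="session")
def imaging_summaries(imaging_stack):
    """Analyzed summaries of the imaging fixture, keyed by channel row."""
    _cfg, stack, truths = imaging_stack
    boxes = kymo.detect_molecules(stack)
    summaries = {}
    for box in boxes:
        km = kymo.build_kymograph(stack, box)
        edges = kymo.extract_edges(km)
        summaries[box.row] = kymo.summarize_molecule(km, edges, molecule_id=box.row)
    return summaries


@pytest.fixture(scope="session")
def photodamage_stack():
    """60 monomers under continuous illumination with nicking enabled."""
    cfg = synthdata.SimConfig.photodamage(seed=4)
    stack, truths = synthdata.simulate_kymograph_stack(cfg, 60)
    return cfg, stack, truths


@pytest.fixture
def boxcar_kymo():
    """Noiseless 50-px boxcar kymograph: plateau 200 over background 10."""
    n_pos, n_frames = 80, 6
    mat = np.full((n_pos, n_frames), 10.0)
    mat[15:65, :] = 210.0
    return kymo.Kymograph(matrix=mat, channel_index=0, origin=(0, 0),
                          pixel_size=100.0, frame_interval=0.1)
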