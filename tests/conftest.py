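import numpy as np
import pytest

from dynstalk.sm.tracking import Track
from dynstalk.synth import generate_structure_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def identity_pair():
    """13-body synthetic pair with all transforms identity."""
    return generate_structure_pair(atoms_per_subdomain=10, seed=7)


def dataset_to_tracks(dataset):
    """Convert a SyntheticMotilityDataset into linkable Track objects."""
    tracks = []
    for tr in dataset.tracks:
        frames = np.rint(tr.t / dataset.frame_interval).astype(int)
        tracks.append(Track(track_id=tr.track_id, frames=frames,
                            t=tr.t, x=tr.x, y=tr.y))
    return tracks
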