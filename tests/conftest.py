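import numpy as np
import pytest

from scmem.model import BeadLabels, Trajectory


def make_trajectory(coords, box=(10.0, 10.0, 10.0), times=None, species=None,
                    bead_names=None, molecule_index=None, unwrapped=False):
    """Small helper assembling a Trajectory from raw coordinate arrays."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n_frames, n_beads, _ = coords.shape
    if times is None:
        times = np.arange(n_frames, dtype=float)
    if species is None:
        species = ["X"] * n_beads
    if bead_names is None:
        bead_names = ["B"] * n_beads
    if molecule_index is None:
        molecule_index = np.arange(1, n_beads + 1)
    labels = BeadLabels(np.array(species, dtype=object),
                        np.asarray(molecule_index),
                        np.array(bead_names, dtype=object))
    boxes = np.repeat(np.asarray(box, dtype=float)[None, :], n_frames, axis=0)
    return Trajectory(np.asarray(times, dtype=float), boxes, coords, labels,
                      unwrapped=unwrapped)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
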