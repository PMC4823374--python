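import numpy as np
import pytest

from vemseg.phantom import PhantomSpec, generate, make_training_scribbles
from vemseg.volumes import LabelVolume


@pytest.fixture(scope="session")
def default_phantom():
    """The reference phantom used by the heavier integration tests."""
    return generate(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def small_phantom():
    """A cheap phantom for smoke tests."""
    spec = PhantomSpec(
        shape=(48, 48, 12), n_mitochondria=1, n_synapses=1,
        mito_radius_range=(8.0, 10.0), sheet_radius_range=(10.0, 14.0),
        n_membranes=1, seed=3,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def half_slice_scribbles(default_phantom):
    """Scribbles restricted to the first half of the slices."""
    _, gt = default_phantom
    full = make_training_scribbles(gt, fraction=0.1, seed=1)
    half = gt.shape[2] // 2
    labels = full.labels.copy()
    labels[:, :, half:] = 0
    return LabelVolume(labels, full.label_table)


def random_probmap(shape, n_labels, rng, label_ids=None, concentration=1.0):
    """A random, normalized probability map for CRF tests."""
    from vemseg.classifier import ProbabilityMap

    raw = rng.dirichlet(np.full(n_labels, concentration), size=shape)
    ids = tuple(label_ids) if label_ids is not None else tuple(range(1, n_labels + 1))
    return ProbabilityMap(
        probs=raw, label_ids=ids, label_table={i: f"label_{i}" for i in ids}
    )
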