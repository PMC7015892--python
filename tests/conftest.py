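import numpy as np
import pytest

from cmrqc.features import segmap_from_labels
from cmrqc.synthetic.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Defect-free default phantom: 10 slices spanning the full LV axis."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def shifted_phantom():
    """Phantom with known per-slice in-plane shifts and mild truncation."""
    shifts = np.random.default_rng(42).uniform(-4.0, 4.0, size=(10, 2))
    spec = PhantomSpec(per_slice_shift=shifts, apical_truncation=4.0,
                       basal_truncation=6.0, seed=42)
    return generate_phantom(spec)


def truth_segs(stack, truth):
    """Ground-truth SegMaps for the SA stack of a generated phantom."""
    return [segmap_from_labels(m) for m in truth.sa_masks]


def truth_la_segs(la_views, truth):
    return [segmap_from_labels(truth.la_masks[v.view_label]) for v in la_views]
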