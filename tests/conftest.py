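import numpy as np
import pytest

from snoutnet.scenes import SceneSpec, generate_dataset
from snoutnet.types import BBox, ImageRecord


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """20 rendered scenes shared by I/O and split tests."""
    spec = SceneSpec(canvas_size=64, n_faces=1, animal_pool=12)
    records, manifest = generate_dataset(20, spec, seed=5)
    return records, manifest


def make_record(class_id=0, animal_id="pigA", size=8, box=None, n_boxes=1,
                seed=0):
    """Tiny handmade record for split/IO logic tests (no rendering)."""
    rng = np.random.default_rng(seed)
    pixels = rng.random((size, size, 3)).astype(np.float32)
    box = box or BBox(0.5, 0.5, 0.4, 0.4)
    anns = [(class_id, box)] * n_boxes
    return ImageRecord(pixels=pixels, animal_id=animal_id, annotations=anns)
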