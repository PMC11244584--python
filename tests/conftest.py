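import numpy as np
import pytest

from safi.data import SceneSpec, generate_scene
from safi.train import Sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_samples(n, image_size=160, seed0=500, n_objects=2,
                 object_scale=(0.12, 0.22), occlusion=(0.0, 0.0)):
    samples = []
    for i in range(n):
        spec = SceneSpec.random(seed=seed0 + i, n_objects=n_objects,
                                image_size=(image_size, image_size),
                                object_scale=object_scale,
                                occlusion_range=occlusion)
        img, boxes = generate_scene(spec)
        samples.append(Sample(img, boxes))
    return samples


@pytest.fixture(scope="session")
def tiny_samples():
    return make_samples(4, image_size=160)


def random_box_pair(rng, span=100.0):
    """A random valid (pred, target) box pair with varied overlap."""
    from safi.losses import BoundingBox, BoxPair

    def box():
        x1, y1 = rng.uniform(0, span, 2)
        w, h = rng.uniform(0.5, span / 2, 2)
        return BoundingBox(0, x1, y1, x1 + w, y1 + h)

    return BoxPair(pred=box(), target=box())
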