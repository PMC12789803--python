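import numpy as np
import pytest

from urimod import synth
from urimod.geometry import CoordinateSet


@pytest.fixture(scope="session")
def simple_hairpin():
    """Noiseless 2-bp stem + 7-nt loop hairpin with manifest."""
    spec = synth.GeneratorSpec(entry_id="HPX", loop_sequence="UUCAAAG")
    return synth.build_hairpin(spec)


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """Small labelled corpus on disk (modified/, library/, manifest)."""
    out = tmp_path_factory.mktemp("study")
    plan = synth.default_study_plan(seed=11)
    manifests = synth.generate_dataset(plan, out)
    return out, manifests, plan


def random_coordinate_set(rng, n, label_prefix="a"):
    labels = tuple((label_prefix, i, "X") for i in range(n))
    return CoordinateSet(labels, rng.normal(size=(n, 3)) * 5.0)


def random_rotation(rng):
    """Proper random rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
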