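import numpy as np
import pytest

from canalkit.synthetic import (
    AnnotatorModel,
    PhantomSpec,
    SystemModel,
    generate_cohort,
    generate_ground_truth,
    simulate_system_volume,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_curve(rng, n=None, scale=20.0):
    """Random smooth-ish polyline with distinct consecutive points."""
    n = n or int(rng.integers(3, 40))
    steps = rng.normal(0.0, 1.0, size=(n, 3))
    pts = np.cumsum(steps, axis=0) * scale / n
    # enforce distinct consecutive points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    pts = pts[np.concatenate([[True], seg > 1e-9])]
    if pts.shape[0] < 2:
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    return pts


@pytest.fixture(scope="session")
def clean_phantom():
    """Defect-free two-canal phantom volume plus its ground truth."""
    spec = PhantomSpec()
    left, right = generate_ground_truth(spec, 7)
    model = SystemModel(boundary_flip_prob=0.0, gap_rate=0.0, spurious_rate=0.0)
    vol = simulate_system_volume((left, right), model, spec.grid_spec(), 7)
    return spec, left, right, vol


@pytest.fixture(scope="session")
def small_cohort():
    """Six-scan curve-mode cohort shared across pipeline-level tests."""
    return generate_cohort(6, seed=42, system_mode="curve")
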