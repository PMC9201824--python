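import numpy as np
import pytest

from cropnav import synthetic


@pytest.fixture
def clean_params() -> synthetic.FieldSceneParams:
    """Three clean vertical bands: no jaggedness, weeds or shade."""
    return synthetic.FieldSceneParams(
        image_height=512,
        image_width=512,
        n_rows=3,
        row_spacing=120,
        row_width=30,
        row_angle=0.0,
        jaggedness=0.0,
        weed_density=0.0,
        shade_fraction=0.0,
    )


@pytest.fixture
def small_clean_params(clean_params) -> synthetic.FieldSceneParams:
    """Same geometry scaled to a 64x64 canvas for fast network tests."""
    return clean_params.with_(
        image_height=64, image_width=64, row_spacing=18, row_width=8
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def finite_difference_gradient(f, tensor, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar-valued function of one tensor."""
    grad = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = tensor.data[idx]
        tensor.data[idx] = orig + eps
        hi = float(f().data)
        tensor.data[idx] = orig - eps
        lo = float(f().data)
        tensor.data[idx] = orig
        grad[idx] = (hi - lo) / (2.0 * eps)
    return grad
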