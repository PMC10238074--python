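import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Standard small lesion-free phantom volume + ground truth (session-cached)."""
    from retnav.phantom import generate_retina_volume, small_params

    params = small_params(seed=7)
    vol, truth = generate_retina_volume(params)
    return params, vol, truth


@pytest.fixture(scope="session")
def averaged_phantom(small_phantom):
    from retnav.oct_processing import average_repeats

    params, vol, truth = small_phantom
    return params, average_repeats(vol), truth


@pytest.fixture(scope="session")
def benchmark_dataset():
    from retnav.benchmarks import make_benchmark_dataset

    return make_benchmark_dataset(n_volumes=8, seed=3)


@pytest.fixture(scope="session")
def quadratic_calibration():
    """Calibration model fitted to an exact quadratic scan distortion."""
    import numpy as np

    from retnav.calibration import fit_voltage_map

    cx = np.zeros((3, 3))
    cy = np.zeros((3, 3))
    cx[1, 0], cx[2, 0], cx[1, 1] = 95.0, 4.0, 1.5
    cy[0, 1], cy[0, 2], cy[1, 1] = 95.0, 4.0, -1.5
    v = np.linspace(-1, 1, 7)
    vv = np.stack(np.meshgrid(v, v, indexing="xy"), axis=-1).reshape(-1, 2)
    from numpy.polynomial import polynomial as npoly

    pos = np.stack(
        [npoly.polyval2d(vv[:, 0], vv[:, 1], cx), npoly.polyval2d(vv[:, 0], vv[:, 1], cy)],
        axis=-1,
    )
    model = fit_voltage_map(vv, pos, degree=2)
    return model, (cx, cy), vv, pos
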