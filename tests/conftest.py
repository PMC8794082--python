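import numpy as np
import pytest

from navmix import DirectionalDataset


def unit_rows(z: np.ndarray) -> np.ndarray:
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return z / np.linalg.norm(z, axis=1, keepdims=True)


def make_directional(x: np.ndarray) -> DirectionalDataset:
    x = unit_rows(x)
    return DirectionalDataset(
        x=x,
        variant_ids=[f"v{i}" for i in range(x.shape[0])],
        trait_names=[f"t{j}" for j in range(x.shape[1])],
    )


def sample_vmf3(mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact vMF sampler on the 2-sphere (m=3) via the inverse-CDF of the
    cosine w = mu'x: w = 1 + log(u + (1-u)exp(-2k))/k, azimuth uniform."""
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), w])
    # rotate north pole to mu
    mu = np.asarray(mu, dtype=float)
    pole = np.array([0.0, 0.0, 1.0])
    v = np.cross(pole, mu)
    c = float(pole @ mu)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return local @ R.T


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def two_cluster_data(rng):
    """Two tight antipodal groups on the circle plus ids."""
    base = np.array([1.0, 0.0])
    angles = rng.normal(0.0, 0.05, size=40)
    pts = np.column_stack([np.cos(angles), np.sin(angles)])
    pts[20:] *= -1.0
    return make_directional(pts)
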