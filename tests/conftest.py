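import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


def make_ar1(n, phi, rng, noise_sd=1.0):
    """Stationary AR(1) draw, standardized."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, noise_sd / np.sqrt(1.0 - phi**2))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0.0, noise_sd)
    return (x - x.mean()) / x.std()


def make_logistic(n, rng, r=3.8):
    """Chaotic logistic-map trajectory, standardized."""
    x = rng.uniform(0.2, 0.8)
    for _ in range(100):
        x = r * x * (1.0 - x)
    out = np.empty(n)
    for i in range(n):
        x = r * x * (1.0 - x)
        out[i] = x
    return (out - out.mean()) / out.std()


def coupled_logistic(n, byx, rng, bxy=0.0, rx=3.8, ry=3.5):
    """Bidirectionally couplable logistic maps; with bxy=0 the x map is
    autonomous and drives y with strength byx.  Returns (x, y) standardized."""
    x, y = rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8)
    for _ in range(100):
        x, y = x * (rx - rx * x - bxy * y), y * (ry - ry * y - byx * x)
    xs, ys = np.empty(n), np.empty(n)
    for i in range(n):
        x, y = x * (rx - rx * x - bxy * y), y * (ry - ry * y - byx * x)
        xs[i], ys[i] = x, y
    xs = (xs - xs.mean()) / xs.std()
    ys = (ys - ys.mean()) / ys.std()
    return xs, ys
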