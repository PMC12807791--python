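import numpy as np
import pytest

from rhsp import LSNRModel, PhantomSpec, ScanProfile, simulate_scan


@pytest.fixture(scope="session")
def default_scan():
    """One simulated freehand acquisition at default phantom conditions.

    2 mm spheres at 20% volume fraction, -40 dB contrast, 62 frames over
    3 cm (interframe ~= d/4), 0.14 mm pixels.  Shared across tests; the
    analysis path is deterministic so reuse is safe.
    """
    spec = PhantomSpec(phantom_size_cm=(2.2, 1.2, 3.1))
    profile = ScanProfile(n_frames=62, coverage_cm=3.0, speed_jitter=0.0, seed=1)
    volume, truth = simulate_scan(spec, profile, seed=1)
    return volume, truth, spec


@pytest.fixture(scope="session")
def default_fit(default_scan):
    """Full pipeline results on the default simulated acquisition."""
    volume, truth, spec = default_scan
    return LSNRModel(volume).fit()


def make_ball_mask(shape, center, radius):
    """Boolean mask of a digital ball (inclusive radius)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2
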