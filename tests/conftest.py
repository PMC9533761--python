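import numpy as np
import pytest

from shanift import ShannonGrid, InCoefficients, simulate_profile, sphere_shannon_In

SPHERE_R = 25.0
SPHERE_D = 50.0

# Table-style reference values for the solid sphere of radius 25
SPHERE_RG = np.sqrt(3.0 / 5.0) * SPHERE_R          # 19.3649...
SPHERE_RAVG = 36.0 * SPHERE_R / 35.0               # 25.7142...
SPHERE_VP = 4.0 * np.pi * SPHERE_R**3 / 3.0        # 65449.8...
SPHERE_LC = 1.5 * SPHERE_R                         # 37.5
SPHERE_VC = SPHERE_VP / (2.0 * np.pi * SPHERE_LC)  # 277.777...


@pytest.fixture(scope="session")
def sphere_coeffs_200():
    """Analytic sphere Shannon intensities, 200 channels, R = 25."""
    return sphere_shannon_In(SPHERE_R, 200)


@pytest.fixture(scope="session")
def sphere_coeffs_large():
    """Analytic sphere Shannon intensities at oracle scale (1e5 channels)."""
    return sphere_shannon_In(SPHERE_R, 100_000)


@pytest.fixture()
def noisy_profile():
    """Default simulation scenario: R=25, 8 channels, 500 pts, 2% noise."""
    return simulate_profile(seed=1)


def random_coeffs(rng, n_total=8, D=50.0, scale=1.0):
    """Random coefficient vector (zero covariance) on a D-grid."""
    grid = ShannonGrid(D=D, q_max=(n_total + 0.5) * np.pi / D)
    vals = scale * rng.standard_normal(n_total)
    return InCoefficients(values=vals, covariance=None, grid=grid)
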