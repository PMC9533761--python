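"""Analytic solid-sphere oracle and seeded synthetic-profile generator.

The solid sphere of radius R is one of the few shapes with closed-form
scattering: the normalised intensity is the squared form factor

    I(q) = I0_scale * [ 3 (sin(qR) - qR cos(qR)) / (qR)^3 ]^2,

its pair distribution function is P(r) proportional to r^2 gamma(r) with the
sphere correlation function gamma(r) = 1 - 3r/(4R) + r^3/(16 R^3) on
[0, 2R], and the Shannon intensities on the natural grid D = 2R reduce to

    I_n = I0_scale * 9 * (2/(n pi))^6     (n odd)
    I_n = I0_scale * 9 * (2/(n pi))^4     (n even),

independent of R.  These exact values anchor every parameter estimator in
the package; the generator adds seeded Gaussian noise to emulate a
measured beamline profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InCoefficients, ShannonGrid
from .fitting import ScatteringProfile

__all__ = [
    "SphereModel",
    "sphere_intensity",
    "sphere_shannon_In",
    "sphere_pr",
    "simulate_profile",
    "DEFAULT_R",
    "DEFAULT_QMAX",
    "DEFAULT_NQ",
    "DEFAULT_NOISE",
]

# Default simulation scenario: sphere of radius 25 (length units), data out
# to the eighth Shannon point q_max = 8*pi/(2R), 500 points, 2% noise.
DEFAULT_R = 25.0
DEFAULT_QMAX = 8.0 * np.pi / 50.0
DEFAULT_NQ = 500
DEFAULT_NOISE = 0.02

#: fraction of I(0) added to the noise amplitude as a floor, so sigma does
#: not vanish at the form-factor minima
NOISE_FLOOR = 0.01


@dataclass(frozen=True)
class SphereModel:
    """Solid sphere of radius R with forward scattering I0_scale."""

    R: float
    I0_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.R) and self.R > 0):
            raise ValueError(f"R must be finite and > 0, got {self.R}")

    @property
    def D(self) -> float:
        return 2.0 * self.R

    def intensity(self, q) -> np.ndarray:
        return sphere_intensity(self.R, q, self.I0_scale)

    def pr(self, r) -> np.ndarray:
        return sphere_pr(self.R, r, self.I0_scale)

    def shannon_In(self, n_total: int) -> InCoefficients:
        return sphere_shannon_In(self.R, n_total, self.I0_scale)


def sphere_intensity(R: float, q, I0_scale: float = 1.0):
    """Normalised sphere scattering intensity; I(0) = I0_scale.

    q = 0 (and tiny qR) handled by the series limit of the form factor.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    x = q * R
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    amp = np.where(
        small,
        1.0 - x**2 / 10.0,  # series of 3(sin x - x cos x)/x^3
        3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3,
    )
    out = I0_scale * amp**2
    return out if out.ndim else float(out)


def sphere_shannon_In(R: float, n_total: int, I0_scale: float = 1.0) -> InCoefficients:
    """Exact Shannon intensities of a sphere on the grid D = 2R.

    Uses the closed forms 9 (2/(n pi))^6 (odd n) and 9 (2/(n pi))^4 (even
    n), which are free of the sin/cos cancellation of the form factor at
    large n.  Covariance is zero (analytic values).
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    D = 2.0 * R
    grid = ShannonGrid(D=D, q_max=(n_total + 0.5) * np.pi / D, extension=1)
    assert grid.n_total == n_total
    n = grid.n.astype(float)
    values = I0_scale * np.where(
        grid.n % 2 == 1,
        9.0 * (2.0 / (n * np.pi)) ** 6,
        9.0 * (2.0 / (n * np.pi)) ** 4,
    )
    return InCoefficients(values=values, covariance=None, grid=grid)


def sphere_pr(R: float, r, I0_scale: float = 1.0):
    """Closed-form sphere pair distribution on [0, 2R].

    P(r) = I0_scale * 3 r^2 gamma(r) / (4 pi R^3), normalised so that
    4 pi * integral P dr = I(0), matching the package's Fourier
    convention.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 2.0 * R * (1 + 1e-12)):
        raise ValueError("r must lie in [0, 2R]")
    x = np.clip(r / R, 0.0, 2.0)
    gamma = 1.0 - 0.75 * x + x**3 / 16.0
    out = I0_scale * 3.0 * r**2 * gamma / (4.0 * np.pi * R**3)
    return out if out.ndim else float(out)


def simulate_profile(
    R: float = DEFAULT_R,
    q_max: float = DEFAULT_QMAX,
    n_q: int = DEFAULT_NQ,
    noise_frac: float = DEFAULT_NOISE,
    seed: int = 0,
    I0_scale: float = 1.0,
) -> ScatteringProfile:
    """Simulated noisy sphere profile on an even grid over (0, q_max].

    The reported uncertainty is sigma(q) = noise_frac * (I(q) + 0.01*I(0))
    — proportional noise with a floor so the error bars stay meaningful at
    the deep form-factor minima — and the observed intensities are
    I_e = I + sigma * eps with eps ~ N(0, 1) drawn from a generator seeded
    with ``seed`` (bit-for-bit reproducible).
    """
    if n_q < 50:
        raise ValueError("n_q must be >= 50")
    if not noise_frac > 0:
        raise ValueError("noise_frac must be > 0")
    rng = np.random.default_rng(seed)
    q = np.linspace(q_max / n_q, q_max, n_q)
    I_true = sphere_intensity(R, q, I0_scale)
    sigma = noise_frac * (I_true + NOISE_FLOOR * I0_scale)
    I_e = I_true + sigma * rng.standard_normal(n_q)
    return ScatteringProfile(q=q, I=I_e, sigma=sigma)
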