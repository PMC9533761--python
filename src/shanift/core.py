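"""Shannon-channel basis functions and curve evaluation.

A particle of maximum dimension ``D`` has a band-limited scattering
intensity that is fully determined by its values at the Shannon points
``q_n = n*pi/D``.  Writing ``I_n = I(q_n)``, the whole reciprocal-space
curve is the cardinal series

    I(q) = sum_n I_n * B_n(q),

with

    B_n(q) = 2 * (-1)**(n+1) * (n*pi)**2 * sin(qD) / (qD * ((n*pi)**2 - (qD)**2)),

and the real-space pair distribution function is the matching sine series

    P(r) = sum_n I_n * S_n(r),      S_n(r) = n*r / (2*D**2) * sin(n*pi*r/D),

normalised so that ``I(q) = 4*pi * integral_0^D P(r) * sinc(q*r) dr``.
``B_n`` interpolates (``B_n(q_m) = delta_nm``) and has the finite limit
``B_n(0) = 2*(-1)**(n+1)``, which yields the forward-scattering identity
``I(0) = 2 * sum_n (-1)**(n+1) * I_n``.

Uncertainties on the evaluated curves follow from the covariance matrix of
the coefficients by the usual quadratic form (``var = b^T C b`` with ``b``
the basis vector at the evaluation point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShannonGrid",
    "InCoefficients",
    "basis_b",
    "basis_s",
    "basis_matrix",
    "basis_matrix_real",
    "evaluate_intensity",
    "evaluate_pr",
    "default_r_grid",
]

#: number of points of the default real-space output grid on [0, D]
DEFAULT_NR = 501


@dataclass(frozen=True)
class ShannonGrid:
    """Index set of Shannon channels for a particle of maximum dimension D.

    Parameters
    ----------
    D :
        Maximum particle dimension, in the length unit reciprocal to q.
    q_max :
        Largest momentum transfer covered by the data.
    extension :
        Multiple of ``n_max`` carried as floating channels beyond the
        measured band (1 = no extension, 3 = the default when the
        regularised fit frees the channels above ``q_max``).
    """

    D: float
    q_max: float
    extension: int = 1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.D) and self.D > 0):
            raise ValueError(f"D must be finite and > 0, got {self.D}")
        if not (np.isfinite(self.q_max) and self.q_max > 0):
            raise ValueError(f"q_max must be finite and > 0, got {self.q_max}")
        if self.extension < 1:
            raise ValueError("extension multiple must be >= 1")
        if self.n_max < 1:
            raise ValueError(
                f"q_max*D/pi = {self.q_max * self.D / np.pi:.3g} < 1: no Shannon "
                "channel fits in the measured q range; increase D or q_max"
            )

    @property
    def n_max(self) -> int:
        """Number of channels inside the measured band, int(q_max*D/pi)."""
        return int(self.q_max * self.D / np.pi)

    @property
    def n_total(self) -> int:
        """Number of coefficients actually carried."""
        return self.extension * self.n_max

    @property
    def n(self) -> np.ndarray:
        """Channel indices 1..n_total."""
        return np.arange(1, self.n_total + 1)

    @property
    def q_n(self) -> np.ndarray:
        """Shannon point positions n*pi/D."""
        return self.n * np.pi / self.D


@dataclass
class InCoefficients:
    """Fitted (or analytic) Shannon intensities with their covariance.

    ``covariance=None`` means exactly zero (analytic values), stored
    sparsely so oracle computations can carry 1e5 channels.
    """

    values: np.ndarray
    covariance: "np.ndarray | None"
    grid: ShannonGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.grid.n_total
        if self.values.shape != (m,):
            raise ValueError(f"expected {m} coefficients, got {self.values.shape}")
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=float)
            if self.covariance.shape != (m, m):
                raise ValueError(f"covariance must be {m}x{m}, got {self.covariance.shape}")
            if not np.allclose(self.covariance, self.covariance.T,
                               atol=1e-8 * max(1.0, np.abs(self.covariance).max())):
                raise ValueError("covariance matrix must be symmetric")

    @property
    def n_total(self) -> int:
        return self.grid.n_total


def _check_nqd(n, q, D) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(n)
    q = np.asarray(q, dtype=float)
    if not np.all(n >= 1):
        raise ValueError("channel index n must be >= 1")
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite q")
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    if not (np.isfinite(D) and D > 0):
        raise ValueError("D must be finite and > 0")
    return n, q


def basis_b(n, q, D: float):
    """Reciprocal-space Shannon basis function B_n(q) for dimension D.

    Evaluated through two algebraically equivalent forms, each regular on
    its half of the axis, so the removable singularities at ``qD = 0`` and
    ``qD = n*pi`` are computed exactly rather than by series expansion:

    * ``qD < n*pi/2``:   ``2*(-1)**(n+1)*(n*pi)**2 * sinc(qD) / ((n*pi)**2-(qD)**2)``
    * ``qD >= n*pi/2``:  ``2*(n*pi)**2 * sinc(qD - n*pi) / (qD*(qD + n*pi))``

    (``sinc(x) = sin(x)/x``).  Broadcasts over ``n`` and ``q``.
    """
    n, q = _check_nqd(n, q, D)
    u = q * D
    npi = n * np.pi
    u, npi, n_b = np.broadcast_arrays(np.asarray(u, dtype=float), npi, n)
    sgn = np.where(n_b % 2 == 1, 1.0, -1.0)
    low = u < npi / 2
    den_a = np.where(low, npi**2 - u**2, 1.0)
    den_b = np.where(low, 1.0, u * (u + npi))
    # np.sinc is sin(pi x)/(pi x)
    out = np.where(
        low,
        2.0 * sgn * npi**2 * np.sinc(u / np.pi) / den_a,
        2.0 * npi**2 * np.sinc((u - npi) / np.pi) / den_b,
    )
    return out if out.ndim else float(out)


def basis_s(n, r, D: float):
    """Real-space Shannon basis function S_n(r) = n*r/(2 D^2) * sin(n pi r / D).

    Defined on 0 <= r <= D; vanishes at both ends. Broadcasts over n and r.
    """
    n = np.asarray(n)
    r = np.asarray(r, dtype=float)
    if not np.all(n >= 1):
        raise ValueError("channel index n must be >= 1")
    if not (np.isfinite(D) and D > 0):
        raise ValueError("D must be finite and > 0")
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite r")
    if np.any(r < 0) or np.any(r > D * (1 + 1e-12)):
        raise ValueError("r must lie in [0, D]")
    out = n * r / (2.0 * D**2) * np.sin(n * np.pi * r / D)
    # the sine vanishes identically at the support ends; make that exact
    out = np.where((r == 0.0) | (r == D), 0.0, out)
    return out if out.ndim else float(out)


def basis_matrix(q, grid: ShannonGrid) -> np.ndarray:
    """Matrix of B_n(q_i): shape (len(q), n_total)."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    return basis_b(grid.n[None, :], q[:, None], grid.D)


def basis_matrix_real(r, grid: ShannonGrid) -> np.ndarray:
    """Matrix of S_n(r_i): shape (len(r), n_total)."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    return basis_s(grid.n[None, :], r[:, None], grid.D)


def _evaluate(coeffs: InCoefficients, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = design @ coeffs.values
    if coeffs.covariance is None:
        return y, np.zeros_like(y)
    var = np.einsum("ij,jk,ik->i", design, coeffs.covariance, design)
    return y, np.sqrt(np.clip(var, 0.0, None))


def evaluate_intensity(coeffs: InCoefficients, q_out) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct I(q) = sum I_n B_n(q) with 1-sigma propagated errors."""
    B = basis_matrix(q_out, coeffs.grid)
    return _evaluate(coeffs, B)


def evaluate_pr(coeffs: InCoefficients, r_out) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct P(r) = sum I_n S_n(r) with 1-sigma propagated errors."""
    S = basis_matrix_real(r_out, coeffs.grid)
    return _evaluate(coeffs, S)


def default_r_grid(D: float, n_points: int = DEFAULT_NR) -> np.ndarray:
    """Evenly spaced real-space output grid on [0, D]."""
    return np.linspace(0.0, D, n_points)
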