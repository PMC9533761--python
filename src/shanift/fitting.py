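"""Regularized weighted least-squares estimation of Shannon intensities.

The coefficients I_n are obtained by minimising

    T = chi2_unreduced + alpha * S,          S = integral_0^D [P''(r)]^2 dr,

where the smoothness penalty S is an exact quadratic form ``I^T M I`` in
the coefficients (the second-derivative cross integrals of the sine-series
basis have closed forms, assembled in :func:`regularizer_matrix`).  The
minimiser solves the normal equations

    (A^T W A + alpha M) I = A^T W I_e,       W = diag(1/sigma_i^2),

and reports the coefficient covariance C = (A^T W A + alpha M)^{-1}.

Channels above the measured band (n_max < n <= 3 n_max) may be carried as
floating unknowns when alpha > 0: the data do not constrain them directly,
but the smoothness penalty does, which removes the implicit bias of pinning
them to zero.  With alpha = 0 those channels are entirely unconstrained, so
the fit silently falls back to n_total = n_max in that case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .core import InCoefficients, ShannonGrid, basis_matrix
from .errors import IllPosedError, ProfileError

__all__ = [
    "ScatteringProfile",
    "ShannonFit",
    "design_matrix",
    "regularizer_matrix",
    "fit_In",
    "chi2",
]

#: condition-number threshold beyond which the normal matrix is solved by
#: an eigenvalue-clipped pseudo-inverse instead of a Cholesky factorization
COND_LIMIT = 1e12

#: minimum number of data points required inside the trim window
MIN_POINTS = 10


@dataclass
class ScatteringProfile:
    """Experimental (q, I, sigma) profile with an inclusive trim window.

    ``first``/``last`` are indices into the stored arrays delimiting the
    window that is actually fit (``last`` is inclusive; None means the
    final point).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    first: int = 0
    last: Optional[int] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape) or self.q.ndim != 1:
            raise ProfileError("q, I and sigma must be 1-d arrays of equal length")
        if not np.all(np.isfinite(self.q)) or not np.all(np.isfinite(self.I)) or not np.all(np.isfinite(self.sigma)):
            raise ProfileError("profile contains non-finite values")
        if np.any(self.q <= 0):
            raise ProfileError("q values must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ProfileError("q values must be strictly increasing")
        bad = np.flatnonzero(self.sigma <= 0)
        if bad.size:
            raise ProfileError(f"non-positive sigma at rows {bad.tolist()[:10]}")
        if self.last is None:
            self.last = len(self.q) - 1
        if not (0 <= self.first <= self.last < len(self.q)):
            raise ProfileError(f"invalid trim window [{self.first}, {self.last}]")

    def __len__(self) -> int:
        return len(self.q)

    @property
    def window(self) -> slice:
        return slice(self.first, self.last + 1)

    @property
    def q_win(self) -> np.ndarray:
        return self.q[self.window]

    @property
    def I_win(self) -> np.ndarray:
        return self.I[self.window]

    @property
    def sigma_win(self) -> np.ndarray:
        return self.sigma[self.window]

    @property
    def q_max(self) -> float:
        return float(self.q_win[-1])

    def trimmed(self, first: int = 0, last: Optional[int] = None) -> "ScatteringProfile":
        """Copy of the profile with a new trim window."""
        return ScatteringProfile(self.q, self.I, self.sigma, first=first, last=last)

    def restricted(self, q_hi: float) -> "ScatteringProfile":
        """Copy keeping only points with q <= q_hi (window reset)."""
        keep = self.q_win <= q_hi
        if keep.sum() < 2:
            raise ProfileError(f"q <= {q_hi:g} keeps fewer than 2 points")
        return ScatteringProfile(self.q_win[keep], self.I_win[keep], self.sigma_win[keep])


@dataclass
class ShannonFit:
    """Result of a regularized Shannon-channel fit."""

    coeffs: InCoefficients
    alpha: float
    D: float
    chi2: float
    regularizer_value: float
    condition_fallback: bool = False

    @property
    def n_max(self) -> int:
        return self.coeffs.grid.n_max

    @property
    def n_total(self) -> int:
        return self.coeffs.grid.n_total


def design_matrix(profile: ScatteringProfile, grid: ShannonGrid) -> np.ndarray:
    """Rows of Shannon basis values B_n(q_i) over the trim window."""
    if grid.n_max < 1:
        raise IllPosedError("no Shannon channel in range: increase D or q_max")
    return basis_matrix(profile.q_win, grid)


def regularizer_matrix(grid: ShannonGrid) -> np.ndarray:
    """Exact quadratic form of the smoothness penalty S = int [P''(r)]^2 dr.

    With S_n(r) = n r/(2 D^2) sin(n pi r/D), the cross integrals
    ``M_mn = int_0^D S_m'' S_n'' dr`` evaluate in closed form to

        M_nn = n^4 pi^2 (11/4 + n^2 pi^2 / 6) / (4 D^5)
        M_mn = (-1)^(m+n) m^2 n^2 pi^2 / (2 D^5) * (1 + 2 m^2 n^2/(m^2-n^2)^2)

    (m != n).  The matrix is symmetric positive definite and has units of
    1/length^5, so ``alpha`` carries units of length^5 relative to chi2.
    """
    n = grid.n.astype(float)
    D = grid.D
    m2 = n[:, None] ** 2
    n2 = n[None, :] ** 2
    sgn = (-1.0) ** (n[:, None] + n[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        off = sgn * m2 * n2 * np.pi**2 / (2 * D**5) * (1 + 2 * m2 * n2 / (m2 - n2) ** 2)
    diag = n**4 * np.pi**2 * (11.0 / 4.0 + n**2 * np.pi**2 / 6.0) / (4 * D**5)
    M = off
    np.fill_diagonal(M, diag)
    return M


def _solve_normal(H: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Solve H x = rhs and return (x, H^-1, used_fallback).

    Prefers a Cholesky factorization; falls back to an eigenvalue-clipped
    pseudo-inverse when H is numerically singular or its condition number
    exceeds COND_LIMIT (typical for floating extension channels at tiny
    alpha).
    """
    w = scipy.linalg.eigvalsh(H)
    ill = w[0] <= 0 or (w[-1] / w[0]) > COND_LIMIT
    if not ill:
        try:
            cf = scipy.linalg.cho_factor(H)
            cov = scipy.linalg.cho_solve(cf, np.eye(H.shape[0]))
            return cov @ rhs, cov, False
        except scipy.linalg.LinAlgError:
            pass
    if w[-1] <= 0:
        raise IllPosedError("normal matrix is not positive semi-definite")
    cov = scipy.linalg.pinvh(H, atol=w[-1] / COND_LIMIT)
    return cov @ rhs, cov, True


def fit_In(
    profile: ScatteringProfile,
    D: float,
    alpha: float = 0.0,
    extend: bool = True,
) -> ShannonFit:
    """Fit Shannon intensities I_n to a profile at fixed D and alpha.

    Parameters
    ----------
    profile :
        Data to fit (trim window respected).
    D :
        Maximum particle dimension; must exceed pi/q_max so that at least
        one Shannon channel lies inside the data.
    alpha :
        Regularization weight (>= 0) multiplying the P'' smoothness
        penalty.
    extend :
        Carry floating channels up to 3*n_max beyond the measured band.
        Ignored (with a warning) when alpha = 0, where those channels
        would be entirely unconstrained.
    """
    if not (np.isfinite(alpha) and alpha >= 0):
        raise ValueError(f"alpha must be finite and >= 0, got {alpha}")
    npts = len(profile.q_win)
    if npts < MIN_POINTS:
        raise ProfileError(f"need at least {MIN_POINTS} points in the trim window, got {npts}")
    if extend and alpha == 0.0:
        warnings.warn(
            "alpha = 0 leaves extension channels unconstrained; "
            "fitting n_total = n_max instead",
            stacklevel=2,
        )
        extend = False
    grid = ShannonGrid(D=D, q_max=profile.q_max, extension=3 if extend else 1)
    A = design_matrix(profile, grid)
    if npts <= grid.n_max:
        raise ProfileError(
            f"{npts} data points cannot determine {grid.n_max} channels"
        )
    w = 1.0 / profile.sigma_win**2
    AtW = A.T * w
    H = AtW @ A
    M = regularizer_matrix(grid)
    if alpha > 0:
        H = H + alpha * M
    values, cov, fallback = _solve_normal(H, AtW @ profile.I_win)
    coeffs = InCoefficients(values=values, covariance=0.5 * (cov + cov.T), grid=grid)
    resid = (profile.I_win - A @ values) / profile.sigma_win
    chi2_red = float(resid @ resid) / (npts - grid.n_max)
    s_val = float(values @ M @ values)
    return ShannonFit(
        coeffs=coeffs,
        alpha=alpha,
        D=D,
        chi2=chi2_red,
        regularizer_value=s_val,
        condition_fallback=fallback,
    )


def chi2(profile: ScatteringProfile, fit: ShannonFit) -> float:
    """Reduced chi-square of a fit against a profile.

    Sigma-weighted squared residuals over the trim window, divided by
    N_points - n_max (extension channels are penalty-constrained and are
    not counted as free parameters).
    """
    npts = len(profile.q_win)
    if npts <= fit.n_max:
        raise ProfileError(f"{npts} points <= {fit.n_max} channels: dof would be <= 0")
    I_c, _ = _model_on(profile, fit)
    resid = (profile.I_win - I_c) / profile.sigma_win
    return float(resid @ resid) / (npts - fit.n_max)


def _model_on(profile: ScatteringProfile, fit: ShannonFit):
    from .core import evaluate_intensity

    return evaluate_intensity(fit.coeffs, profile.q_win)
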