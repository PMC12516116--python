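"""Semi-non-parametric (SNP) latent densities h(z) = P_L(z)^2 phi(z).

The latent trait density is a squared polynomial of degree L (0, 1 or 2)
times the standard normal density.  The polynomial coefficients are not
free: they are parameterized by L spherical angles ``phi`` so that
``integral h(z) dz = 1`` holds identically.  L = 0 is the standard normal;
L = 1 adds bimodal and mildly skewed shapes; L = 2 adds trimodal and
strongly skewed shapes.  Setting every angle to pi/2 collapses the density
back to the standard normal, which is what makes the SNP family a nested
extension of the normal-latent 2PL model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "SNPShape",
    "LatentMoments",
    "coefficients_from_phi",
    "coefficient_derivatives",
    "snp_pdf",
    "snp_moments",
    "moment_derivatives",
    "density_grid",
    "rescale_to_standard_metric",
]

# E[Z^k] for Z ~ N(0,1), k = 0..6; enough for variance of a degree-2 shape.
_GAUSS_MOMENTS = np.array([1.0, 0.0, 1.0, 0.0, 3.0, 0.0, 15.0])

_HALF_PI = np.pi / 2.0


@dataclass(frozen=True)
class SNPShape:
    """Degree and angles of an SNP density.

    Parameters
    ----------
    L : int
        Polynomial degree, one of 0, 1, 2.
    phi : sequence of float
        ``L`` angles, each in the half-open interval (-pi/2, pi/2].
        An angle of exactly -pi/2 is equivalent to +pi/2 (the squared
        polynomial is unchanged) and is normalized to +pi/2.
    """

    L: int
    phi: tuple = field(default=())

    def __post_init__(self):
        if self.L not in (0, 1, 2):
            raise ValueError(f"polynomial degree L must be 0, 1 or 2, got {self.L}")
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float)).ravel()
        if phi.size != self.L:
            raise ValueError(f"expected {self.L} angles, got {phi.size}")
        if np.any(phi < -_HALF_PI) or np.any(phi > _HALF_PI):
            raise ValueError("each angle must lie in (-pi/2, pi/2]")
        # -pi/2 gives the same density as +pi/2; keep a unique representative
        phi = np.where(phi == -_HALF_PI, _HALF_PI, phi)
        object.__setattr__(self, "phi", tuple(phi.tolist()))

    @property
    def is_normal(self) -> bool:
        """True when the density reduces exactly to the standard normal."""
        return self.L == 0 or all(p == _HALF_PI for p in self.phi)


@dataclass(frozen=True)
class LatentMoments:
    mean: float
    variance: float

    def __post_init__(self):
        if not np.isfinite(self.mean) or not np.isfinite(self.variance):
            raise FloatingPointError("non-finite latent moments")
        if self.variance <= 0:
            raise ValueError("latent variance must be strictly positive")


def coefficients_from_phi(shape: SNPShape) -> np.ndarray:
    """Polynomial coefficients (a_0, ..., a_L) implied by the angles.

    For L=1: a0 = sin(phi1), a1 = cos(phi1).
    For L=2: a1 = cos(phi1) sin(phi2), a2 = cos(phi1) cos(phi2) / sqrt(2),
    a0 = sin(phi1) - a2.  With these maps a' G a = 1 identically, where G is
    the Hankel matrix of standard-normal moments, so h integrates to one.
    """
    if shape.L == 0:
        return np.array([1.0])
    if shape.is_normal:
        # exact unit coefficient vector at phi = pi/2 (cos(pi/2) is only
        # ~6e-17 in floating point, which would leak into the moments)
        out = np.zeros(shape.L + 1)
        out[0] = 1.0
        return out
    phi = np.asarray(shape.phi)
    if shape.L == 1:
        return np.array([np.sin(phi[0]), np.cos(phi[0])])
    s1, c1 = np.sin(phi[0]), np.cos(phi[0])
    s2, c2 = np.sin(phi[1]), np.cos(phi[1])
    a2 = c1 * c2 / np.sqrt(2.0)
    return np.array([s1 - a2, c1 * s2, a2])


def coefficient_derivatives(shape: SNPShape) -> np.ndarray:
    """Jacobian d a / d phi, with shape (L, L+1); empty for L = 0."""
    if shape.L == 0:
        return np.zeros((0, 1))
    phi = np.asarray(shape.phi)
    if shape.L == 1:
        return np.array([[np.cos(phi[0]), -np.sin(phi[0])]])
    s1, c1 = np.sin(phi[0]), np.cos(phi[0])
    s2, c2 = np.sin(phi[1]), np.cos(phi[1])
    r = 1.0 / np.sqrt(2.0)
    da2_d1 = -r * s1 * c2
    da2_d2 = -r * c1 * s2
    return np.array(
        [
            [c1 - da2_d1, -s1 * s2, da2_d1],
            [-da2_d2, c1 * c2, da2_d2],
        ]
    )


def polynomial_values(z, shape: SNPShape) -> np.ndarray:
    """P_L(z) evaluated elementwise."""
    a = coefficients_from_phi(shape)
    z = np.asarray(z, dtype=float)
    out = np.full_like(z, a[0], dtype=float)
    if shape.L >= 1:
        out = out + a[1] * z
    if shape.L >= 2:
        out = out + a[2] * z * z
    return out


def snp_pdf(z, shape: SNPShape) -> np.ndarray:
    """Density h(z) = P_L(z)^2 phi(z); nonnegative, integrates to one."""
    z = np.asarray(z, dtype=float)
    return polynomial_values(z, shape) ** 2 * norm.pdf(z)


def _moment_matrix(offset: int, L: int) -> np.ndarray:
    """(L+1)x(L+1) matrix with entry (l, m) = E[Z^(l+m+offset)], Z~N(0,1)."""
    idx = np.add.outer(np.arange(L + 1), np.arange(L + 1)) + offset
    return _GAUSS_MOMENTS[idx]


def snp_moments(shape: SNPShape) -> LatentMoments:
    """Exact mean and variance of h via Gaussian moment identities.

    E(Z) = a' M1 a and E(Z^2) = a' M2 a where (Mk)_{lm} = E[N(0,1)^(l+m+k)].
    """
    a = coefficients_from_phi(shape)
    mean = a @ _moment_matrix(1, shape.L) @ a
    ez2 = a @ _moment_matrix(2, shape.L) @ a
    return LatentMoments(mean=float(mean), variance=float(ez2 - mean**2))


def moment_derivatives(shape: SNPShape):
    """(dE/dphi, dV/dphi), each a length-L vector."""
    a = coefficients_from_phi(shape)
    da = coefficient_derivatives(shape)  # (L, L+1)
    m1 = _moment_matrix(1, shape.L)
    m2 = _moment_matrix(2, shape.L)
    mean = a @ m1 @ a
    d_mean = 2.0 * da @ (m1 @ a)
    d_ez2 = 2.0 * da @ (m2 @ a)
    return d_mean, d_ez2 - 2.0 * mean * d_mean


def density_grid(shape: SNPShape, lo: float = -5.0, hi: float = 5.0,
                 num: int = 201) -> np.ndarray:
    """(z, h(z)) grid, suitable for CSV export or plotting."""
    z = np.linspace(lo, hi, num)
    return np.column_stack([z, snp_pdf(z, shape)])


def rescale_to_standard_metric(intercepts_raw, slopes_raw, shape: SNPShape):
    """Re-express raw item parameters for a standardized latent variable.

    If the fitted latent density has mean E and variance V, the model with
    item curve ``logit = a0 + a1 * x`` and ``x ~ h`` is observationally
    identical to one with a zero-mean unit-variance latent variable ``z``
    and parameters ``a0 + a1 E`` (intercept) and ``a1 sqrt(V)`` (slope).
    """
    mom = snp_moments(shape)
    a0 = np.asarray(intercepts_raw, dtype=float)
    a1 = np.asarray(slopes_raw, dtype=float)
    return a0 + a1 * mom.mean, a1 * np.sqrt(mom.variance)
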