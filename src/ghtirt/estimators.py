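"""Estimators for the 2PL model: pairwise likelihood and SNP maximum likelihood.

Two scikit-learn style estimators:

``PairwiseIRT2PL``
    Maximizes the pairwise (composite) likelihood of the normal-latent 2PL
    model.  Consistent under normality but not fully efficient, with a
    sandwich covariance A^-1 B A^-1.

``SNPIRT2PL``
    Maximizes the marginal likelihood of the 2PL model with an SNP latent
    density of degree L (quasi-ML when the true density is outside the
    family).  The optimization runs on the raw metric, where the item
    parameters are calibrated to the fitted (unstandardized) latent
    density; the optimum is then rescaled to the standard-normal metric
    and the per-person scores and Hessians are expressed on that metric
    through the Jacobian of the rescaling map, so everything downstream is
    directly comparable with the pairwise estimates.

Both expose per-person score matrices at the optimum; ``observed_sandwich``
and ``cross_matrix`` assemble the robust-covariance ingredients from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .likelihood import QuadratureRule, gauss_hermite_rule, pairwise_loglik, snp_full_loglik
from .snp import SNPShape, moment_derivatives, snp_moments

__all__ = [
    "PairwiseIRT2PL",
    "SNPIRT2PL",
    "SandwichSet",
    "observed_sandwich",
    "cross_matrix",
    "phi_start_grid",
]

_HALF_PI = np.pi / 2.0
_PHI_LO = -_HALF_PI + 1e-6  # open lower boundary; -pi/2 duplicates +pi/2


def _wrap_phi(phi):
    """Map angles into (-pi/2, pi/2]; the density is pi-periodic in each
    angle, so finite-difference steps across the boundary stay valid."""
    phi = np.mod(np.asarray(phi, dtype=float) + _HALF_PI, np.pi) - _HALF_PI
    return tuple(np.where(phi == -_HALF_PI, _HALF_PI, phi).tolist())


def validate_responses(X) -> np.ndarray:
    """Check a binary response matrix (n persons x p items, entries 0/1)."""
    X = check_array(X, dtype=float, ensure_min_features=2)
    bad = ~np.isin(X, (0.0, 1.0))
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"responses must be 0/1; found {X[i, j]!r} at row {i}, column {j}"
        )
    return X


def _start_values(X):
    """Marginal-logit intercepts and unit slopes."""
    pbar = np.clip(X.mean(axis=0), 1e-3, 1 - 1e-3)
    return np.concatenate([logit(pbar), np.ones(X.shape[1])])


def phi_start_grid(n_starts: int = 10, spacing: float = 0.1) -> np.ndarray:
    """Deterministic phi1 starting values.

    The candidate sequence is spaced ``spacing`` apart across (-pi/2, pi/2];
    ``n_starts`` evenly-indexed members are selected, so the starts cover
    the whole domain reproducibly.
    """
    grid = np.arange(-1.5, _HALF_PI - 1e-9, spacing)
    grid = np.append(grid, _HALF_PI)
    idx = np.unique(np.round(np.linspace(0, grid.size - 1, n_starts)).astype(int))
    return grid[idx]


class PairwiseIRT2PL(BaseEstimator):
    """Pairwise maximum-likelihood estimator of the normal-latent 2PL model.

    Parameters
    ----------
    n_quad : int
        Gauss-Hermite nodes for the bivariate margins.
    gtol, maxiter : float, int
        L-BFGS-B stopping controls (gradient tolerance on the per-person
        scale).

    Attributes
    ----------
    intercepts_, slopes_ : (p,) item parameters on the standard-normal metric.
    theta_ : (2p,) concatenated (intercepts, slopes).
    loglik_ : total pairwise log-likelihood at the optimum.
    loglik_per_person_ : (n,) per-person contributions.
    score_matrix_ : (n, 2p) per-person gradients at the optimum.
    converged_ : bool.
    """

    method = "PL"

    def __init__(self, n_quad: int = 49, gtol: float = 1e-6, maxiter: int = 500):
        self.n_quad = n_quad
        self.gtol = gtol
        self.maxiter = maxiter

    def _rule(self) -> QuadratureRule:
        return gauss_hermite_rule(self.n_quad)

    def total_gradient(self, X, theta):
        """Gradient of the total pairwise log-likelihood at theta."""
        p = X.shape[1]
        _, S = pairwise_loglik(X, theta[:p], theta[p:], self._rule(), return_scores=True)
        return S.sum(axis=0)

    def fit(self, X, y=None):
        X = validate_responses(X)
        n, p = X.shape
        rule = self._rule()

        def negloglik(theta):
            total, S = pairwise_loglik(X, theta[:p], theta[p:2 * p], rule, return_scores=True)
            return -total / n, -S.sum(axis=0) / n

        res = minimize(negloglik, _start_values(X), jac=True, method="L-BFGS-B",
                       options={"maxiter": self.maxiter, "gtol": self.gtol, "ftol": 1e-12})
        theta = res.x
        total, S, li = pairwise_loglik(X, theta[:p], theta[p:], rule,
                                       return_scores=True, return_per_person=True)
        self.n_features_in_ = p
        self.n_persons_ = n
        self.intercepts_ = theta[:p].copy()
        self.slopes_ = theta[p:].copy()
        self.theta_ = theta.copy()
        self.loglik_ = total
        self.loglik_per_person_ = li
        self.score_matrix_ = S
        self.converged_ = bool(res.success) and np.max(np.abs(S.sum(axis=0))) / n < 1e-3
        self.n_iter_ = int(res.nit)
        return self

    def score(self, X, y=None) -> float:
        """Mean per-person pairwise log-likelihood on X."""
        check_is_fitted(self)
        X = validate_responses(X)
        return pairwise_loglik(X, self.intercepts_, self.slopes_, self._rule()) / X.shape[0]


class SNPIRT2PL(BaseEstimator):
    """(Quasi-)ML estimator of the 2PL model with an SNP latent density.

    Parameters
    ----------
    L : int
        SNP polynomial degree (0, 1 or 2).  L = 0 is plain normal-latent ML.
    n_quad : int
        Gauss-Hermite nodes.
    n_phi_starts : int
        Number of phi1 starts for L = 1 (selected from a 0.1-spaced grid;
        the best-likelihood fit is kept).
    phi_starts : sequence or None
        Explicit phi starting vector(s); default for L = 2 is (0.7, 1.0),
        a skew-normal-like shape.
    item_starts : array or None
        Starting (intercepts, slopes); default is an internal L = 0 ML fit
        for L >= 1 and marginal logits for L = 0.

    Attributes
    ----------
    intercepts_, slopes_ : item parameters on the standard-normal metric.
    intercepts_raw_, slopes_raw_ : parameters on the fitted latent metric.
    phi_ : (L,) fitted angles; shape_ : the fitted ``SNPShape``.
    theta_ : (2p+L,) standard-metric parameter vector (a0, a1, phi).
    latent_mean_, latent_variance_ : moments of the fitted latent density.
    loglik_, loglik_per_person_, score_matrix_, converged_, n_starts_used_.
    """

    method = "ML"

    def __init__(self, L: int = 1, n_quad: int = 49, n_phi_starts: int = 10,
                 phi_starts=None, item_starts=None, gtol: float = 1e-5,
                 ftol: float = 2.2e-9, maxiter: int = 500):
        self.L = L
        self.n_quad = n_quad
        self.n_phi_starts = n_phi_starts
        self.phi_starts = phi_starts
        self.item_starts = item_starts
        self.gtol = gtol
        self.ftol = ftol
        self.maxiter = maxiter

    def _rule(self) -> QuadratureRule:
        return gauss_hermite_rule(self.n_quad)

    # -- standard-metric parameterization ---------------------------------
    # eta = (a0_std, a1_std, phi); raw slopes a1 = a1_std / sqrt(V(phi)),
    # raw intercepts a0 = a0_std - a1 * E(phi).

    def _raw_params(self, eta, p):
        if self.L == 0:
            return eta[:p], eta[p:2 * p], SNPShape(0)
        shape = SNPShape(self.L, _wrap_phi(eta[2 * p:]))
        mom = snp_moments(shape)
        a1_raw = eta[p:2 * p] / np.sqrt(mom.variance)
        a0_raw = eta[:p] - a1_raw * mom.mean
        return a0_raw, a1_raw, shape

    def _jacobian(self, eta, p):
        """J[b, a] = d theta_raw_b / d eta_a, shape (2p+L, 2p+L)."""
        dim = 2 * p + self.L
        J = np.eye(dim)
        if self.L == 0:
            return J
        shape = SNPShape(self.L, _wrap_phi(eta[2 * p:]))
        mom = snp_moments(shape)
        dE, dV = moment_derivatives(shape)
        s = np.sqrt(mom.variance)
        m = mom.mean
        a1_std = eta[p:2 * p]
        d_inv_s = -dV / (2.0 * s**3)           # d(1/s)/dphi
        d_m_over_s = dE / s + m * d_inv_s       # d(m/s)/dphi
        idx0, idx1 = np.arange(p), np.arange(p, 2 * p)
        J[idx0, idx1] = -m / s
        J[idx1, idx1] = 1.0 / s
        for l in range(self.L):
            col = 2 * p + l
            J[idx0, col] = -a1_std * d_m_over_s[l]
            J[idx1, col] = a1_std * d_inv_s[l]
        return J

    def _loglik_scores(self, X, eta):
        """(per-person loglik, per-person scores on the standard metric)."""
        p = X.shape[1]
        a0, a1, shape = self._raw_params(eta, p)
        ll, S_raw = snp_full_loglik(X, a0, a1, shape, self._rule(), return_scores=True)
        return ll, S_raw @ self._jacobian(eta, p)

    def total_gradient(self, X, eta):
        _, S = self._loglik_scores(X, eta)
        return S.sum(axis=0)

    def _to_standard(self, theta_raw, p):
        """Map a raw parameter vector to the standard metric."""
        if self.L == 0:
            return theta_raw.copy()
        shape = SNPShape(self.L, _wrap_phi(theta_raw[2 * p:]))
        mom = snp_moments(shape)
        a0 = theta_raw[:p] + theta_raw[p:2 * p] * mom.mean
        a1 = theta_raw[p:2 * p] * np.sqrt(mom.variance)
        return np.concatenate([a0, a1, theta_raw[2 * p:]])

    # ----------------------------------------------------------------------

    def _optimize(self, X, theta0):
        """Maximize the likelihood over the raw parameterization.

        The optimization runs on the raw metric (item parameters calibrated
        to the unstandardized SNP density), from the prescribed starting
        values; the optimum is rescaled afterwards.
        """
        n, p = X.shape

        def negloglik(theta):
            if self.L == 0:
                shape = SNPShape(0)
            else:
                shape = SNPShape(self.L, _wrap_phi(theta[2 * p:]))
            ll, S = snp_full_loglik(X, theta[:p], theta[p:2 * p], shape,
                                    self._rule(), return_scores=True)
            return -ll.sum() / n, -S.sum(axis=0) / n

        bounds = [(None, None)] * (2 * p) + [(_PHI_LO, _HALF_PI)] * self.L
        return minimize(negloglik, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": self.maxiter, "gtol": self.gtol,
                                 "ftol": self.ftol})

    def _starting_points(self, X):
        if self.item_starts is not None:
            items = np.asarray(self.item_starts, dtype=float).ravel()
        elif self.L == 0:
            items = _start_values(X)
        else:
            base = SNPIRT2PL(L=0, n_quad=self.n_quad, gtol=self.gtol,
                             ftol=self.ftol, maxiter=self.maxiter).fit(X)
            items = base.theta_
        if self.L == 0:
            return [items]
        if self.phi_starts is not None:
            phis = np.atleast_2d(np.asarray(self.phi_starts, dtype=float))
        elif self.L == 1:
            phis = phi_start_grid(self.n_phi_starts)[:, None]
        else:
            # skew-normal-like starts of varying strength; phi2 -> -phi2
            # mirrors the density (z -> -z), so both orientations are
            # tried, plus the normal corner as a guard
            phis = np.array([[0.7, 1.0], [0.7, -1.0], [1.2, 0.7], [1.2, -0.7],
                             [0.2, 1.2], [0.2, -1.2], [_HALF_PI, _HALF_PI]])
        phis = np.clip(phis, _PHI_LO, _HALF_PI)
        return [np.concatenate([items, phi]) for phi in phis]

    def fit(self, X, y=None):
        if self.L not in (0, 1, 2):
            raise ValueError("L must be 0, 1 or 2")
        X = validate_responses(X)
        n, p = X.shape

        best, n_ok = None, 0
        for theta0 in self._starting_points(X):
            res = self._optimize(X, theta0)
            if not np.isfinite(res.fun):
                continue
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise FloatingPointError("all optimization starts failed")

        eta = self._to_standard(best.x, p)
        ll, S = self._loglik_scores(X, eta)
        a0_raw, a1_raw, shape = self._raw_params(eta, p)
        mom = snp_moments(shape)
        self.n_features_in_ = p
        self.n_persons_ = n
        self.intercepts_ = eta[:p].copy()
        self.slopes_ = eta[p:2 * p].copy()
        self.phi_ = eta[2 * p:].copy()
        self.shape_ = shape
        self.theta_ = eta.copy()
        self.intercepts_raw_ = np.asarray(a0_raw)
        self.slopes_raw_ = np.asarray(a1_raw)
        self.latent_mean_ = mom.mean
        self.latent_variance_ = mom.variance
        self.loglik_ = float(ll.sum())
        self.loglik_per_person_ = ll
        self.score_matrix_ = S
        at_boundary = self.L > 0 and np.any(np.abs(np.abs(self.phi_) - _HALF_PI) < 1e-6)
        grad_ok = np.max(np.abs(S.sum(axis=0))) / n < 1e-3
        self.converged_ = bool(best.success) and (grad_ok or at_boundary)
        self.n_starts_used_ = n_ok
        self.n_iter_ = int(best.nit)
        return self

    def score(self, X, y=None) -> float:
        """Mean per-person marginal log-likelihood on X."""
        check_is_fitted(self)
        X = validate_responses(X)
        a0, a1, shape = self._raw_params(self.theta_, X.shape[1])
        return float(snp_full_loglik(X, a0, a1, shape, self._rule()).mean())


@dataclass(frozen=True)
class SandwichSet:
    """Observed sandwich ingredients: A = -sum of per-person Hessians
    (positive definite near an interior maximum), B = sum of per-person
    score outer products."""

    A: np.ndarray
    B: np.ndarray


def _numeric_hessian(grad_fn, theta, step: float = 1e-5) -> np.ndarray:
    """Symmetrized central-difference Jacobian of a gradient function."""
    theta = np.asarray(theta, dtype=float)
    dim = theta.size
    H = np.empty((dim, dim))
    for i in range(dim):
        h = step * max(1.0, abs(theta[i]))
        e = np.zeros(dim)
        e[i] = h
        H[i] = (grad_fn(theta + e) - grad_fn(theta - e)) / (2.0 * h)
    return 0.5 * (H + H.T)


def observed_sandwich(fit, X, step: float = 1e-5) -> SandwichSet:
    """Observed A and B matrices for a fitted estimator on its data.

    A is the negative Hessian of the total (pairwise or full) log-likelihood,
    obtained by central finite differences of the analytic gradient; B is the
    cross-product of the stored per-person scores.
    """
    check_is_fitted(fit)
    if not fit.converged_:
        raise ValueError("sandwich matrices require a converged fit")
    X = validate_responses(X)
    A = -_numeric_hessian(lambda th: fit.total_gradient(X, th), fit.theta_, step=step)
    if not np.all(np.isfinite(A)):
        raise FloatingPointError("non-finite Hessian")
    B = fit.score_matrix_.T @ fit.score_matrix_
    return SandwichSet(A=A, B=B)


def cross_matrix(fit_pl, fit_ml) -> np.ndarray:
    """R-hat: summed outer products of PL scores with ML scores,
    (2p) x (2p+L).  Both fits must be on the same persons in the same order."""
    check_is_fitted(fit_pl)
    check_is_fitted(fit_ml)
    if fit_pl.score_matrix_.shape[0] != fit_ml.score_matrix_.shape[0]:
        raise ValueError("fits refer to different numbers of persons")
    return fit_pl.score_matrix_.T @ fit_ml.score_matrix_
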