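"""2PL log-likelihood building blocks.

Two likelihoods are needed: the full-pattern marginal likelihood of a 2PL
model under an SNP latent density (used for ML estimation), and the
pairwise likelihood summing log bivariate margins over all item pairs
under the standard-normal density (used for the composite-likelihood
estimator).  Both are evaluated on a Gauss-Hermite grid with the normal
kernel absorbed into the weights, and both expose analytic per-person
score matrices because the robust (sandwich) covariances are built from
per-observation gradients.

Parameter vectors are ordered as (intercepts_1..p, slopes_1..p[, phi]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, log_expit, logsumexp

from .snp import SNPShape, coefficient_derivatives, polynomial_values

__all__ = [
    "QuadratureRule",
    "gauss_hermite_rule",
    "response_probability",
    "snp_full_loglik",
    "pattern_loglik_snp",
    "pairwise_loglik",
]

_TINY = 1e-300


@dataclass(frozen=True)
class QuadratureRule:
    """Discrete approximation of integration against phi(z) dz.

    ``sum(weights * f(nodes))`` approximates ``E[f(Z)]`` for Z ~ N(0,1);
    the weights therefore sum to one.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if self.nodes.shape != self.weights.shape or self.nodes.ndim != 1:
            raise ValueError("nodes and weights must be matching 1-d arrays")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")


def gauss_hermite_rule(n: int = 49) -> QuadratureRule:
    """Gauss-Hermite rule after the change of variable z = sqrt(2) x."""
    x, w = hermgauss(n)
    return QuadratureRule(nodes=np.sqrt(2.0) * x, weights=w / np.sqrt(np.pi))


def response_probability(intercept, slope, z):
    """P(y=1 | z) of the 2PL item curve, overflow-safe."""
    return expit(np.asarray(intercept, float) + np.asarray(slope, float) * np.asarray(z, float))


def _item_logprobs(intercepts, slopes, nodes):
    """log pi and log(1-pi), each (p, Q)."""
    eta = np.add.outer(np.asarray(intercepts, float), np.zeros_like(nodes))
    eta += np.outer(np.asarray(slopes, float), nodes)
    return log_expit(eta), log_expit(-eta)


def snp_full_loglik(Y, intercepts, slopes, shape: SNPShape, rule: QuadratureRule,
                    return_scores: bool = False):
    """Per-person marginal log-likelihood under an SNP latent density.

    l_i = log sum_q w_q P_L(z_q)^2 prod_j pi_j(z_q)^{y_ij} (1-pi_j)^{1-y_ij}

    with the quadrature weights absorbing phi(z).  When ``return_scores``
    is set, also returns the (n, 2p+L) matrix of per-person gradients on
    the *raw* parameter metric (intercepts, slopes, phi).
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    z, w = rule.nodes, rule.weights
    logpi, log1mpi = _item_logprobs(intercepts, slopes, z)

    pol = polynomial_values(z, shape)
    c = pol**2
    with np.errstate(divide="ignore"):
        logwc = np.log(w) + np.log(np.maximum(c, _TINY))

    # log prod_j A_j^{y_j}: one matmul pair, (n, Q)
    logB = Y @ logpi + (1.0 - Y) @ log1mpi
    logA = logB + logwc
    ll = logsumexp(logA, axis=1)
    if not return_scores:
        return ll

    pi = np.exp(logpi)
    with np.errstate(invalid="ignore"):
        r = np.exp(logA - ll[:, None])  # posterior node weights, rows sum to 1
    s_a0 = Y - r @ pi.T
    rz = r @ z
    s_a1 = Y * rz[:, None] - r @ (pi * z).T
    if shape.L == 0:
        return ll, np.hstack([s_a0, s_a1])
    # phi-scores via d c / d phi = 2 P_L(z) dP_L/dphi, avoiding division by P_L
    da = coefficient_derivatives(shape)  # (L, L+1)
    zpow = np.vander(z, shape.L + 1, increasing=True).T  # (L+1, Q)
    dc = 2.0 * pol * (da @ zpow)  # (L, Q)
    t = np.exp(logB + np.log(w) - ll[:, None])
    s_phi = t @ dc.T
    return ll, np.hstack([s_a0, s_a1, s_phi])


def pattern_loglik_snp(row, intercepts, slopes, shape: SNPShape, rule: QuadratureRule) -> float:
    """Log-likelihood of a single response pattern (convenience wrapper)."""
    ll = snp_full_loglik(np.atleast_2d(row), intercepts, slopes, shape, rule)
    value = float(ll[0])
    if not np.isfinite(value):
        raise FloatingPointError("response pattern has zero probability at every node")
    return value


def _bivariate_cell_probs(intercepts, slopes, rule: QuadratureRule):
    """All 2x2 bivariate margins under the standard-normal latent density.

    Returns (P11, P10, P01, P00), each (p, p); entry (j, k) is the
    probability of the cell for the ordered pair (item j, item k).
    """
    logpi, log1mpi = _item_logprobs(intercepts, slopes, rule.nodes)
    pi = np.exp(logpi)
    w = rule.weights
    m1 = pi @ w
    m11 = (pi * w) @ pi.T
    p11 = m11
    p10 = m1[:, None] - m11
    p01 = m1[None, :] - m11
    p00 = 1.0 - m1[:, None] - m1[None, :] + m11
    return p11, p10, p01, p00


def pairwise_loglik(Y, intercepts, slopes, rule: QuadratureRule,
                    return_scores: bool = False, return_per_person: bool = False):
    """Pairwise log-likelihood: sum over unordered item pairs of log
    bivariate margins, with the latent density fixed at N(0,1).

    Returns the total; optionally the (n, 2p) per-person score matrix
    and/or the length-n vector of per-person contributions.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    z, w = rule.nodes, rule.weights
    logpi, log1mpi = _item_logprobs(intercepts, slopes, z)
    pi = np.exp(logpi)

    P11, P10, P01, P00 = _bivariate_cell_probs(intercepts, slopes, rule)
    P = [[np.maximum(P00, _TINY), np.maximum(P01, _TINY)],
         [np.maximum(P10, _TINY), np.maximum(P11, _TINY)]]
    logP = [[np.log(P[a][b]) for b in (0, 1)] for a in (0, 1)]

    N11 = Y.T @ Y
    N10 = Y.T @ (1.0 - Y)
    N01 = N10.T
    N00 = n - N11 - N10 - N01
    Ncell = [[N00, N01], [N10, N11]]

    upper = np.triu(np.ones((p, p)), k=1)
    total = 0.0
    for a in (0, 1):
        for b in (0, 1):
            total += float(np.sum(Ncell[a][b] * logP[a][b] * upper))

    if not (return_scores or return_per_person):
        return total

    out = [total]
    offdiag = 1.0 - np.eye(p)

    if return_scores:
        # dP_{ab}(j,k)/d a0_j = (-1)^{1-a} * sum_q w u_j(q) A_k^b(q)
        u = pi * (1.0 - pi)
        C1 = (u * w) @ pi.T          # C1[j,k] = sum_q w u_j pi_k
        C0 = (u * w) @ (1.0 - pi).T
        V1 = (u * (z * w)) @ pi.T
        V0 = (u * (z * w)) @ (1.0 - pi).T
        S = np.zeros((n, 2 * p))
        for j in range(p):
            for a in (0, 1):
                mask = Y[:, j] == a
                if not np.any(mask):
                    continue
                sign = 1.0 if a == 1 else -1.0
                # vectors over partner item k (entry j zeroed)
                g1 = sign * C1[j] / P[a][1][j]
                g0 = sign * C0[j] / P[a][0][j]
                h1 = sign * V1[j] / P[a][1][j]
                h0 = sign * V0[j] / P[a][0][j]
                for g in (g1, g0, h1, h0):
                    g[j] = 0.0
                Ysub = Y[mask]
                S[mask, j] = Ysub @ (g1 - g0) + g0.sum()
                S[mask, p + j] = Ysub @ (h1 - h0) + h0.sum()
        out.append(S)

    if return_per_person:
        li = np.zeros(n)
        for j in range(p):
            for a in (0, 1):
                mask = Y[:, j] == a
                if not np.any(mask):
                    continue
                l1 = logP[a][1][j].copy()
                l0 = logP[a][0][j].copy()
                l1[j] = 0.0
                l0[j] = 0.0
                li[mask] += Y[mask] @ (l1 - l0) + l0.sum()
        li *= 0.5  # ordered pairs counted each unordered pair twice
        out.append(li)

    return tuple(out)
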