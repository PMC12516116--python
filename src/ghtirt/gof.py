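"""Reference tests and model-selection criteria.

Comparison statistics for the normal-latent 2PL model: the nested
likelihood-ratio test against the SNP-latent model, the summed-score
Pearson statistic (observed vs. model-implied total-score distribution),
the limited-information M2 statistic on univariate and bivariate margins,
and the AIC/BIC/Hannan-Quinn information criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from sklearn.utils.validation import check_is_fitted

from .estimators import validate_responses
from .likelihood import QuadratureRule, _item_logprobs, gauss_hermite_rule
from .snp import SNPShape, coefficient_derivatives, polynomial_values

__all__ = [
    "TestResult",
    "ICSet",
    "lr_test",
    "summed_score_distribution",
    "xbar2_test",
    "m2_test",
    "information_criteria",
]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    dof: float
    p_value: float

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclass(frozen=True)
class ICSet:
    aic: float
    bic: float
    hq: float
    k: int
    n: int


def lr_test(fit_ml_L, fit_ml_0) -> TestResult:
    """Likelihood-ratio test of the SNP_L model against the normal-latent
    model (both full-ML fits on the same data); chi-square with L dof."""
    check_is_fitted(fit_ml_L)
    check_is_fitted(fit_ml_0)
    if getattr(fit_ml_0, "method", None) != "ML" or getattr(fit_ml_L, "method", None) != "ML":
        raise ValueError("the LR test requires full-ML fits of both models")
    dof = fit_ml_L.L - fit_ml_0.L
    if dof < 1:
        raise ValueError("the first fit must have the larger polynomial degree")
    stat = 2.0 * (fit_ml_L.loglik_ - fit_ml_0.loglik_)
    if stat < -1e-6:
        raise FloatingPointError(
            f"negative LR statistic {stat:.3g}: the larger model is under-optimized"
        )
    stat = max(stat, 0.0)
    return TestResult(f"LR{dof}", float(stat), float(dof), float(chi2.sf(stat, dof)))


def summed_score_distribution(intercepts, slopes, shape: SNPShape,
                              rule: QuadratureRule | None = None) -> np.ndarray:
    """Model-implied distribution of the total score (0..p).

    Lord-Wingersky recursion over the quadrature grid: at each node the
    score distribution given z is built item by item, then mixed over the
    latent density.
    """
    if rule is None:
        rule = gauss_hermite_rule()
    logpi, log1mpi = _item_logprobs(intercepts, slopes, rule.nodes)
    pi, q = np.exp(logpi), np.exp(log1mpi)
    p, Q = pi.shape
    dist = np.zeros((p + 1, Q))
    dist[0] = 1.0
    for j in range(p):
        dist[1:j + 2] = dist[1:j + 2] * q[j] + dist[:j + 1] * pi[j]
        dist[0] *= q[j]
    w = rule.weights * polynomial_values(rule.nodes, shape) ** 2
    return dist @ w


def xbar2_test(X, fit) -> TestResult:
    """Summed-score Pearson statistic n sum_s (pbar_s - pibar_s)^2 / pibar_s,
    referred to chi-square with p - 2 dof."""
    check_is_fitted(fit)
    X = validate_responses(X)
    n, p = X.shape
    if p < 3:
        raise ValueError("the summed-score test needs p >= 3 items (dof = p - 2)")
    scores = X.sum(axis=1).astype(int)
    observed = np.bincount(scores, minlength=p + 1) / n
    implied = summed_score_distribution(fit.intercepts_raw_, fit.slopes_raw_,
                                        fit.shape_, fit._rule())
    if np.any((implied <= 0) & (observed > 0)):
        raise ZeroDivisionError("model assigns zero probability to an observed score")
    stat = float(n * np.sum((observed - implied) ** 2 / implied))
    dof = p - 2
    return TestResult("Xbar2", stat, float(dof), float(chi2.sf(stat, dof)))


def _margin_sets(p: int) -> np.ndarray:
    """Indicator matrix of the univariate then bivariate (j<k) margins."""
    sets = np.zeros((p + p * (p - 1) // 2, p))
    sets[np.arange(p), np.arange(p)] = 1.0
    row = p
    for j in range(p):
        for k in range(j + 1, p):
            sets[row, j] = sets[row, k] = 1.0
            row += 1
    return sets


def _margin_model(fit, p):
    """Model-implied margin machinery shared by M2 pieces.

    Returns (sets, pi_margins, Delta) where Delta is the Jacobian of the
    margin probabilities in the fit's standard-metric parameters.
    """
    rule = fit._rule()
    z, w = rule.nodes, rule.weights
    logpi, _ = _item_logprobs(fit.intercepts_raw_, fit.slopes_raw_, z)
    pi = np.exp(logpi)
    shape = fit.shape_
    pol = polynomial_values(z, shape)
    wc = w * pol**2

    sets = _margin_sets(p)
    prod = np.exp(sets @ logpi)          # (n_margins, Q): prod of pi over the set
    margins = prod @ wc

    # d margin / d raw intercept_j: integral of prod * (1 - pi_j) over set members
    n_m = sets.shape[0]
    d_a0 = (sets[:, :, None] * (prod[:, None, :] * (1.0 - pi)[None, :, :]))  # (n_m, p, Q)
    Delta_a0 = d_a0 @ wc
    Delta_a1 = d_a0 @ (wc * z)
    blocks = [Delta_a0, Delta_a1]
    if shape.L > 0:
        da = coefficient_derivatives(shape)
        zpow = np.vander(z, shape.L + 1, increasing=True).T
        dwc = w * 2.0 * pol * (da @ zpow)  # (L, Q)
        blocks.append(prod @ dwc.T)
    Delta_raw = np.hstack([b.reshape(n_m, -1) for b in blocks])
    # chain rule to the standard metric
    if hasattr(fit, "_jacobian"):
        Delta = Delta_raw @ fit._jacobian(fit.theta_, p)
    else:
        Delta = Delta_raw
    return sets, margins, Delta, prod, wc


def m2_test(X, fit) -> TestResult:
    """Limited-information overall fit statistic M2 = n e2' U2 e2.

    e2 stacks the univariate and bivariate residuals (observed minus
    model-implied margins); U2 = Xi^-1 - Xi^-1 D (D' Xi^-1 D)^-1 D' Xi^-1
    with Xi the multinomial covariance of the margin proportions and D the
    Jacobian of the margins in the item parameters.  Chi-square with
    p(p+1)/2 - k dof, k the number of fitted parameters.
    """
    check_is_fitted(fit)
    X = validate_responses(X)
    n, p = X.shape
    sets, margins, Delta, prod, wc = _margin_model(fit, p)
    n_m = sets.shape[0]

    # observed margins: mean of products of item indicators over each set
    obs = np.empty(n_m)
    obs[:p] = X.mean(axis=0)
    idx = p
    cross = (X.T @ X) / n
    for j in range(p):
        for k in range(j + 1, p):
            obs[idx] = cross[j, k]
            idx += 1
    e2 = obs - margins

    # Xi[r, s] = P(all items in S_r U S_s are 1) - pi_r pi_s
    union = np.minimum(sets[:, None, :] + sets[None, :, :], 1.0)
    logpi_items, _ = _item_logprobs(fit.intercepts_raw_, fit.slopes_raw_,
                                    fit._rule().nodes)
    # chunk the (n_m, n_m, Q) intermediate to keep memory flat for large p
    Xi = np.empty((n_m, n_m))
    for r0 in range(0, n_m, 64):
        r1 = min(r0 + 64, n_m)
        joint = np.exp(union[r0:r1] @ logpi_items) @ wc  # (chunk, n_m)
        Xi[r0:r1] = joint - margins[r0:r1, None] * margins[None, :]
    Xi = 0.5 * (Xi + Xi.T)

    if np.linalg.matrix_rank(Delta) < Delta.shape[1]:
        raise np.linalg.LinAlgError("margin Jacobian is rank deficient (unidentified fit)")
    Xi_inv = np.linalg.inv(Xi)
    W = Xi_inv @ Delta
    U2 = Xi_inv - W @ np.linalg.solve(Delta.T @ W, W.T)
    stat = float(n * e2 @ U2 @ e2)
    dof = n_m - Delta.shape[1]
    return TestResult("M2", stat, float(dof), float(chi2.sf(stat, dof)))


def information_criteria(fit) -> ICSet:
    """AIC, BIC and Hannan-Quinn for a full-ML fit; k = 2p + L."""
    check_is_fitted(fit)
    if getattr(fit, "method", None) != "ML":
        raise ValueError("information criteria require a full-ML fit")
    n = fit.n_persons_
    k = 2 * fit.n_features_in_ + fit.L
    m2ll = -2.0 * fit.loglik_
    return ICSet(
        aic=m2ll + 2.0 * k,
        bic=m2ll + k * np.log(n),
        hq=m2ll + 2.0 * k * np.log(np.log(n)),
        k=k,
        n=n,
    )
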