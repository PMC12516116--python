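"""Generalized Hausman test for latent-trait non-normality.

The test contrasts two estimators of the 2PL item parameters that are both
consistent when the latent trait is standard normal: the pairwise-likelihood
estimator of the normal-latent model and the (rescaled) ML estimator of the
SNP-latent model.  Under non-normality only the SNP estimator remains
consistent, so the difference vector drifts away from zero.

Two statistics are provided: the full quadratic form GH = d' S^-1 d
(asymptotically chi-square with 2p dof) and the simplified GHT = d'd, whose
null distribution is a weighted sum of chi-squares with weights equal to the
eigenvalues of S.  GHT is referred to a moment-matched a*chi2_b distribution
with a = sum(lam^2)/sum(lam) and b = (sum(lam))^2/sum(lam^2).

The difference vector and S are kept on matched (unnormalized, summed over
persons) scales, so no explicit n factor appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .estimators import SandwichSet, cross_matrix, observed_sandwich

__all__ = ["HausmanResult", "difference_covariance", "ght_test", "gh_test_full"]

_EIG_RTOL = 1e-10


@dataclass(frozen=True)
class HausmanResult:
    """Outcome of the generalized Hausman test."""

    statistic: float          # GHT = d'd
    diff: np.ndarray          # (2p,) rescaled ML minus PL item parameters
    S_hat: np.ndarray         # (2p, 2p) difference covariance
    eigenvalues: np.ndarray   # retained positive eigenvalues, length d
    d: int                    # retained rank
    n_discarded: int          # eigenvalues dropped (negative or ~0)
    a: float                  # moment-matching scale
    b: float                  # moment-matching dof
    p_value: float
    critical_values: dict = field(default_factory=dict)  # alpha -> a*chi2_b quantile
    gh_statistic: float | None = None   # full form d' S^-1 d, if computed
    gh_p_value: float | None = None     # chi2_{2p} tail, if computed

    def reject(self, alpha: float = 0.05) -> bool:
        if alpha not in self.critical_values:
            raise KeyError(f"no critical value computed for alpha={alpha}")
        return self.statistic >= self.critical_values[alpha]


def _inv(M: np.ndarray, name: str) -> np.ndarray:
    try:
        cond = np.linalg.cond(M)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(f"matrix {name} is numerically singular")
    return np.linalg.inv(M)


def difference_covariance(sand_pl: SandwichSet, sand_ml: SandwichSet,
                          R: np.ndarray, n_items: int) -> np.ndarray:
    """Estimated covariance of the estimator difference.

    S = Atf Bml Atf' + Apl^-1 Bpl Apl^-1' - Atf R' Apl^-1' - Apl^-1 R Atf',
    where Atf is the inverse ML-model A-matrix with its last L rows removed
    (keeping the item-parameter block) and R is the PL x ML score
    cross-product.  Symmetric by construction; symmetrized numerically.
    """
    p2 = 2 * n_items
    A_pl_inv = _inv(sand_pl.A, "A(PL)")
    A_ml_inv = _inv(sand_ml.A, "A(ML)")
    Atf = A_ml_inv[:p2, :]  # delete the last L rows
    term_ml = Atf @ sand_ml.B @ Atf.T
    term_pl = A_pl_inv @ sand_pl.B @ A_pl_inv.T
    cross = Atf @ R.T @ A_pl_inv.T
    S = term_ml + term_pl - cross - cross.T
    return 0.5 * (S + S.T)


def _moment_match(eigenvalues: np.ndarray):
    lam_sum = eigenvalues.sum()
    lam_sq = (eigenvalues**2).sum()
    return lam_sq / lam_sum, lam_sum**2 / lam_sq


def ght_test(fit_pl, fit_ml, X, alpha_levels=(0.05, 0.01),
             sand_pl: SandwichSet | None = None,
             sand_ml: SandwichSet | None = None) -> HausmanResult:
    """Simplified generalized Hausman test (no inversion of S).

    GHT is the squared norm of the difference between the SNP-model ML item
    parameters (on the standard-normal metric) and the pairwise-likelihood
    estimates; its null distribution is approximated by a*chi2_b with (a, b)
    moment-matched to the retained eigenvalues of the difference covariance.
    """
    p = fit_pl.n_features_in_
    diff = np.concatenate([fit_ml.intercepts_ - fit_pl.intercepts_,
                           fit_ml.slopes_ - fit_pl.slopes_])
    ght = float(diff @ diff)

    if sand_pl is None:
        sand_pl = observed_sandwich(fit_pl, X)
    if sand_ml is None:
        sand_ml = observed_sandwich(fit_ml, X)
    R = cross_matrix(fit_pl, fit_ml)
    S = difference_covariance(sand_pl, sand_ml, R, p)

    lam = np.linalg.eigvalsh(S)
    keep = lam > _EIG_RTOL * np.max(np.abs(lam))
    retained = lam[keep]
    if retained.size == 0:
        raise np.linalg.LinAlgError("all eigenvalues of S were discarded")
    a, b = _moment_match(retained)
    p_value = float(chi2.sf(ght / a, b))
    crit = {alpha: float(a * chi2.ppf(1.0 - alpha, b)) for alpha in alpha_levels}
    return HausmanResult(
        statistic=ght, diff=diff, S_hat=S, eigenvalues=retained[::-1],
        d=int(retained.size), n_discarded=int(lam.size - retained.size),
        a=float(a), b=float(b), p_value=p_value, critical_values=crit,
    )


def gh_test_full(fit_pl, fit_ml, X,
                 sand_pl: SandwichSet | None = None,
                 sand_ml: SandwichSet | None = None):
    """Full generalized Hausman statistic d' S^-1 d with its chi2_{2p} p-value.

    Returns a ``HausmanResult`` whose ``gh_statistic``/``gh_p_value`` fields
    are populated alongside the GHT quantities.  Raises if S is numerically
    singular (use :func:`ght_test` in that case).
    """
    result = ght_test(fit_pl, fit_ml, X, sand_pl=sand_pl, sand_ml=sand_ml)
    try:
        S_inv = _inv(result.S_hat, "S")
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"{err}; the GHT form avoids this inversion") from err
    gh = float(result.diff @ S_inv @ result.diff)
    dof = result.diff.size
    return HausmanResult(
        **{**result.__dict__, "gh_statistic": gh,
           "gh_p_value": float(chi2.sf(gh, dof))}
    )
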