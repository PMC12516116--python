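"""Monte-Carlo study engine: latent-trait scenarios, data generation,
replication loop and study summaries.

Five latent-trait scenarios are built in: the standard normal (A, for Type I
error), two normal mixtures (B bimodal, C a more extreme separated mixture)
and two skew-normal distributions (D shape 5, E shape 10).  Mixture
components are written N(mean, sd); the second argument is a standard
deviation throughout.

Each study draws one item bank (intercepts Uniform(-.8, 1.12), slopes
Uniform(.5, 1.5)), holds it fixed across replications, and per replication
simulates responses, fits the requested models and tests, and aggregates
rejection rates (with confidence intervals) and information-criterion
selection percentages.  All randomness derives from a single base seed via
spawned child sequences, so results are order-independent and exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, skewnorm

from .estimators import PairwiseIRT2PL, SNPIRT2PL, observed_sandwich
from .gof import information_criteria, lr_test, m2_test, xbar2_test
from .hausman import ght_test
from .likelihood import response_probability

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "scenario_moments",
    "draw_item_parameters",
    "sample_latent",
    "generate_responses",
    "StudyConfig",
    "StudySummary",
    "run_study",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Latent-trait distribution: either a normal mixture or a skew normal.

    ``components`` is a list of (weight, mean, sd); ``skew`` is a
    (location, scale, shape) triple.  Exactly one of the two is populated.
    """

    label: str
    components: tuple = ()
    skew: tuple | None = None

    def __post_init__(self):
        if bool(self.components) == (self.skew is not None):
            raise ValueError("exactly one of components/skew must be given")
        if self.components:
            w = np.array([c[0] for c in self.components])
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("mixture weights must sum to 1")
            if any(c[2] <= 0 for c in self.components):
                raise ValueError("component sds must be positive")
        elif self.skew[1] <= 0:
            raise ValueError("skew-normal scale must be positive")


SCENARIOS = {
    "A": ScenarioSpec("A", components=((1.0, 0.0, 1.0),)),
    "B": ScenarioSpec("B", components=((0.7, -1.0, 0.7), (0.3, 1.0, 0.8))),
    "C": ScenarioSpec("C", components=((0.1, -2.0, 0.25), (0.9, 2.0, 1.0))),
    "D": ScenarioSpec("D", skew=(-2.5, 2.0, 5.0)),
    "E": ScenarioSpec("E", skew=(-2.5, 2.0, 10.0)),
}


def scenario_moments(spec: ScenarioSpec):
    """Closed-form (mean, variance) of the scenario distribution."""
    if spec.components:
        w = np.array([c[0] for c in spec.components])
        m = np.array([c[1] for c in spec.components])
        s = np.array([c[2] for c in spec.components])
        mean = float(w @ m)
        var = float(w @ (s**2 + m**2) - mean**2)
        return mean, var
    loc, scale, lam = spec.skew
    delta = lam / np.sqrt(1.0 + lam**2)
    mean = loc + scale * delta * np.sqrt(2.0 / np.pi)
    var = scale**2 * (1.0 - 2.0 * delta**2 / np.pi)
    return float(mean), float(var)


def draw_item_parameters(p: int, seed) -> tuple:
    """Item bank: intercepts ~ U(-.8, 1.12), slopes ~ U(.5, 1.5)."""
    if p < 2:
        raise ValueError("need at least 2 items")
    rng = np.random.default_rng(seed)
    return rng.uniform(-0.8, 1.12, size=p), rng.uniform(0.5, 1.5, size=p)


def sample_latent(spec: ScenarioSpec, n: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    if spec.components:
        w = np.array([c[0] for c in spec.components])
        which = rng.choice(len(w), size=n, p=w)
        means = np.array([c[1] for c in spec.components])[which]
        sds = np.array([c[2] for c in spec.components])[which]
        return rng.normal(means, sds)
    loc, scale, lam = spec.skew
    return skewnorm.rvs(lam, loc=loc, scale=scale, size=n, random_state=rng)


def generate_responses(intercepts, slopes, latent, seed) -> np.ndarray:
    """Independent Bernoulli responses from the 2PL curves at each latent value."""
    rng = np.random.default_rng(seed)
    probs = response_probability(np.asarray(intercepts)[None, :],
                                 np.asarray(slopes)[None, :],
                                 np.asarray(latent)[:, None])
    return (rng.random(probs.shape) < probs).astype(float)


@dataclass
class StudyConfig:
    scenario: str = "A"
    p: int = 10
    n: int = 1000
    n_replications: int = 500
    alpha_levels: tuple = (0.05, 0.01)
    tests: tuple = ("GHT1",)
    seed: int = 0
    n_quad: int = 49
    redraw_items: bool = False  # one bank per study by default

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from A-E")
        if self.n_replications < 1 or self.p < 2:
            raise ValueError("need n_replications >= 1 and p >= 2")
        known = {"GHT1", "GHT2", "LR1", "LR2", "Xbar2", "M2"}
        bad = set(self.tests) - known
        if bad:
            raise ValueError(f"unknown tests {sorted(bad)}; choose from {sorted(known)}")


@dataclass
class StudySummary:
    """Aggregated study output.

    ``rates``: tidy frame (scenario, p, n, test, alpha, rate, ci_low,
    ci_high, ci_low_wald, ci_high_wald, n_valid).  ``ic_selection``: per
    criterion and model pair, percentage of valid replications in which the
    criterion prefers the larger model.  ``records`` keeps the raw
    per-replication statistics for further analysis.
    """

    config: StudyConfig
    item_intercepts: np.ndarray
    item_slopes: np.ndarray
    rates: pd.DataFrame
    ic_selection: pd.DataFrame
    records: list = field(repr=False, default_factory=list)

    def test_pvalues(self, test: str) -> np.ndarray:
        """p-values of one test over its valid replications."""
        return np.array([r[test]["p_value"] for r in self.records
                         if test in r and r[test]["valid"]])


def _needed_models(tests) -> set:
    need = set()
    for t in tests:
        need |= {
            "GHT1": {"PL", "ML0", "ML1"},
            "GHT2": {"PL", "ML2"},
            "LR1": {"ML0", "ML1"},
            "LR2": {"ML0", "ML2"},
            "Xbar2": {"ML0"},
            "M2": {"ML0"},
        }[t]
    return need


def _phi1_start_sample(rng, n_starts=10, spacing=0.1):
    """The study's multi-start recipe: sample starts from the 0.1-spaced
    grid over (-pi/2, pi/2], without replacement."""
    grid = np.append(np.arange(-1.5, np.pi / 2 - 1e-9, spacing), np.pi / 2)
    return rng.choice(grid, size=n_starts, replace=False)[:, None]


def _fit_models(Y, need, config, true_items, rng):
    """Fit the requested models; non-convergence is recorded, not raised."""
    fits = {}
    if "PL" in need:
        fits["PL"] = PairwiseIRT2PL(n_quad=config.n_quad).fit(Y)
    if need & {"ML0", "ML1"}:
        fits["ML0"] = SNPIRT2PL(L=0, n_quad=config.n_quad).fit(Y)
    if "ML1" in need:
        fits["ML1"] = SNPIRT2PL(L=1, n_quad=config.n_quad,
                                item_starts=fits["ML0"].theta_,
                                phi_starts=_phi1_start_sample(rng)).fit(Y)
    if "ML2" in need:
        # oracle starts: generating item parameters, phi = (0.7, 1.0)
        starts = np.concatenate(true_items)
        fits["ML2"] = SNPIRT2PL(L=2, n_quad=config.n_quad, item_starts=starts).fit(Y)
        if "ML0" in need and "ML0" not in fits:
            fits["ML0"] = SNPIRT2PL(L=0, n_quad=config.n_quad).fit(Y)
    return fits


def _ght_record(fit_pl, fit_ml, Y, alphas):
    if not (fit_pl.converged_ and fit_ml.converged_):
        return {"valid": False, "reason": "non-convergence"}
    try:
        res = ght_test(fit_pl, fit_ml, Y, alpha_levels=alphas)
    except (np.linalg.LinAlgError, FloatingPointError, ValueError) as err:
        return {"valid": False, "reason": str(err)}
    return {"valid": True, "statistic": res.statistic, "p_value": res.p_value,
            "a": res.a, "b": res.b, "d": res.d,
            "reject": {alpha: res.reject(alpha) for alpha in alphas}}


def _simple_record(result, alphas):
    return {"valid": True, "statistic": result.statistic, "p_value": result.p_value,
            "reject": {alpha: result.p_value < alpha for alpha in alphas}}


def _replication(Y, config, true_items, rng):
    alphas = config.alpha_levels
    need = _needed_models(config.tests)
    rec = {}
    try:
        fits = _fit_models(Y, need, config, true_items, rng)
    except FloatingPointError as err:
        return {t: {"valid": False, "reason": str(err)} for t in config.tests}

    if "GHT1" in config.tests:
        rec["GHT1"] = _ght_record(fits["PL"], fits["ML1"], Y, alphas)
    if "GHT2" in config.tests:
        rec["GHT2"] = _ght_record(fits["PL"], fits["ML2"], Y, alphas)
    for name, key in (("LR1", "ML1"), ("LR2", "ML2")):
        if name in config.tests:
            if fits["ML0"].converged_ and fits[key].converged_:
                try:
                    rec[name] = _simple_record(lr_test(fits[key], fits["ML0"]), alphas)
                except FloatingPointError as err:
                    rec[name] = {"valid": False, "reason": str(err)}
            else:
                rec[name] = {"valid": False, "reason": "non-convergence"}
    if "Xbar2" in config.tests:
        if fits["ML0"].converged_:
            rec["Xbar2"] = _simple_record(xbar2_test(Y, fits["ML0"]), alphas)
        else:
            rec["Xbar2"] = {"valid": False, "reason": "non-convergence"}
    if "M2" in config.tests:
        if fits["ML0"].converged_:
            try:
                rec["M2"] = _simple_record(m2_test(Y, fits["ML0"]), alphas)
            except np.linalg.LinAlgError as err:
                rec["M2"] = {"valid": False, "reason": str(err)}
        else:
            rec["M2"] = {"valid": False, "reason": "non-convergence"}

    # information criteria for every fitted ML model
    ics = {}
    for key in ("ML0", "ML1", "ML2"):
        if key in fits and fits[key].converged_:
            ics[key] = information_criteria(fits[key])
    rec["IC"] = ics
    return rec


def run_study(config: StudyConfig, progress=None, initial_records=None,
              on_record=None) -> StudySummary:
    """Run the full replication study for one (scenario, p, n) cell.

    ``initial_records`` resumes a partial run: the first ``len(initial_records)``
    replications are taken as given (seeding is deterministic per index, so
    resumed and fresh runs agree).  ``on_record(index, record)`` is invoked
    after each newly computed replication.
    """
    spec = SCENARIOS[config.scenario]
    root = np.random.SeedSequence(config.seed)
    bank_seed, *rep_seeds = root.spawn(config.n_replications + 1)
    a0, a1 = draw_item_parameters(config.p, bank_seed)

    records = list(initial_records) if initial_records else []
    if len(records) > config.n_replications:
        raise ValueError("more resumed records than configured replications")
    for r, seed in enumerate(rep_seeds):
        if config.redraw_items:
            a0, a1 = draw_item_parameters(config.p, seed.spawn(1)[0])
        if r < len(records):
            continue
        s_lat, s_resp, s_start = seed.spawn(3)
        z = sample_latent(spec, config.n, s_lat)
        Y = generate_responses(a0, a1, z, s_resp)
        rec = _replication(Y, config, (a0, a1), np.random.default_rng(s_start))
        records.append(rec)
        if on_record is not None:
            on_record(r, rec)
        if progress is not None:
            progress(r + 1, config.n_replications)

    # rejection rates with nominal-variance CI (and Wald CI for power use)
    rows = []
    for t in config.tests:
        for alpha in config.alpha_levels:
            valid = [rec[t] for rec in records if rec[t]["valid"]]
            nv = len(valid)
            if nv == 0:
                raise RuntimeError(f"zero valid replications for {t}")
            rate = np.mean([rec["reject"][alpha] for rec in valid])
            zq = norm.ppf(1.0 - alpha / 2.0)
            half = zq * np.sqrt(alpha * (1.0 - alpha) / nv)
            half_wald = zq * np.sqrt(rate * (1.0 - rate) / nv)
            rows.append({
                "scenario": config.scenario, "p": config.p, "n": config.n,
                "test": t, "alpha": alpha, "rate": rate,
                "ci_low": rate - half, "ci_high": rate + half,
                "ci_low_wald": rate - half_wald, "ci_high_wald": rate + half_wald,
                "n_valid": nv,
            })
    rates = pd.DataFrame(rows)

    ic_rows = []
    for pair in (("ML1", "ML0"), ("ML2", "ML0")):
        both = [rec["IC"] for rec in records
                if pair[0] in rec["IC"] and pair[1] in rec["IC"]]
        if not both:
            continue
        for crit in ("aic", "bic", "hq"):
            pct = 100.0 * np.mean([getattr(ic[pair[0]], crit) < getattr(ic[pair[1]], crit)
                                   for ic in both])
            ic_rows.append({
                "scenario": config.scenario, "p": config.p, "n": config.n,
                "criterion": crit.upper(),
                "pair": f"SNP{pair[0][-1]} over SNP0",
                "percent": pct, "n_valid": len(both),
            })
    ic_selection = pd.DataFrame(ic_rows)

    return StudySummary(config=config, item_intercepts=a0, item_slopes=a1,
                        rates=rates, ic_selection=ic_selection, records=records)
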