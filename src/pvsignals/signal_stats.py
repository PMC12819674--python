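"""Disproportionality statistics over 2x2 drug-event contingency tables.

Four algorithms are implemented in their standard published
formulations:

* **ROR** — reporting odds ratio ``ad/(bc)`` with a log-normal 95% CI;
  a Haldane +0.5 correction is applied to every cell, but only when at
  least one cell is zero.
* **PRR** — proportional reporting ratio paired with the Pearson
  chi-squared statistic (no Yates correction).
* **BCPNN IC** — the closed-form shrunk information component
  ``log2((a+0.5)/(E+0.5))`` with its approximate 2.5th credibility
  percentile.
* **MGPS EBGM** — DuMouchel's empirical-Bayes geometric mean under a
  two-component gamma mixture prior fitted by maximising the
  negative-binomial marginal likelihood across all drug-event pairs.

A term is a *signal* under the combined criterion only when all four
algorithms exceed their positivity thresholds simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from pvsignals.meddra import MedDRAMap, normalize_term

__all__ = [
    "ContingencyTable",
    "GammaMixturePrior",
    "PriorFitError",
    "SignalResult",
    "Thresholds",
    "bcpnn_ic",
    "build_table",
    "build_pair_tables",
    "ebgm",
    "evaluate_signal",
    "fit_prior",
    "prr",
    "ror",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts for one drug-term pair.

    ``a``: reports with the target drug and the term; ``b``: target drug
    without the term; ``c``: term without the target drug; ``d``:
    neither. ``N`` is the corpus size and ``E = (a+b)(a+c)/N`` the count
    expected under independence.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name!r} must be a non-negative integer, got {v!r}")
        if self.N <= 0:
            raise ValueError("contingency table is empty (N=0)")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def E(self) -> float:
        return (self.a + self.b) * (self.a + self.c) / self.N


@dataclass(frozen=True)
class Thresholds:
    """Positivity thresholds of the four algorithms (config-overridable).

    Defaults are the standard criteria: ROR lower CI > 1 with at least
    3 reports; PRR >= 2 with chi2 >= 4 and at least 3 reports;
    IC025 > 0; EBGM05 > 2.
    """

    min_count: int = 3
    ror_ci_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass(frozen=True)
class GammaMixturePrior:
    """Fitted hyperparameters of the two-gamma MGPS prior.

    ``w`` is the weight of the first component; ``(alpha1, beta1)`` and
    ``(alpha2, beta2)`` are gamma shape/rate pairs. ``loglik`` is the
    marginal log-likelihood achieved at the fit.
    """

    w: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 < self.w < 1.0):
            raise ValueError(f"mixture weight w must lie in (0,1), got {self.w}")
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name!r} must be positive")

    @property
    def mean(self) -> float:
        """Prior mean of the relative reporting rate lambda."""
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2


#: Documented default start point for the prior fit (DuMouchel's choice).
DEFAULT_PRIOR_START = GammaMixturePrior(w=0.2, alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0)


@dataclass
class SignalResult:
    """All four statistics for one term, with per-algorithm flags."""

    term: str
    level: str  # "PT" or "SOC"
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ror_pos: bool = False
    prr_pos: bool = False
    bcpnn_pos: bool = False
    mgps_pos: bool = False
    combined_pos: bool = False


class PriorFitError(RuntimeError):
    """Prior optimisation failed to converge; carries the best iterate."""

    def __init__(self, message: str, best: GammaMixturePrior, grad_norm: float):
        super().__init__(f"{message} (grad norm {grad_norm:.3g})")
        self.best = best
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# table construction


def build_table(reports: Sequence, term: str, level: str = "PT",
                mapping: MedDRAMap | None = None) -> ContingencyTable:
    """Count the 2x2 table for ``term`` over a labelled corpus.

    ``reports`` is the full deduplicated corpus; each report must carry
    ``is_target`` (target-drug membership) and a ``pts`` set. Counting
    is report-level: a report contributes at most 1 to ``a`` no matter
    how many of its PTs match. At SOC level a report matches when any
    of its PTs maps to the SOC.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    if level == "SOC" and mapping is None:
        raise ValueError("SOC-level counting requires a MedDRA mapping")
    key = normalize_term(term)
    a = b = c = d = 0
    for r in reports:
        if level == "PT":
            has = any(normalize_term(p) == key for p in r.pts)
        else:
            has = any(normalize_term(mapping.pt_to_soc(p)) == key for p in r.pts)
        if r.is_target:
            if has:
                a += 1
            else:
                b += 1
        else:
            if has:
                c += 1
            else:
                d += 1
    return ContingencyTable(a, b, c, d)


def build_all_tables(reports: Sequence, level: str = "PT",
                     mapping: MedDRAMap | None = None) -> dict[str, ContingencyTable]:
    """Tables for every term observed in the corpus, counted in one pass."""
    if level == "SOC" and mapping is None:
        raise ValueError("SOC-level counting requires a MedDRA mapping")
    n_target = sum(1 for r in reports if r.is_target)
    n_total = len(reports)
    target_counts: dict[str, int] = {}
    term_counts: dict[str, int] = {}
    display: dict[str, str] = {}
    for r in reports:
        if level == "PT":
            terms = {normalize_term(p): p for p in r.pts}
        else:
            terms = {normalize_term(mapping.pt_to_soc(p)): mapping.pt_to_soc(p) for p in r.pts}
        for key, disp in terms.items():
            display.setdefault(key, disp)
            term_counts[key] = term_counts.get(key, 0) + 1
            if r.is_target:
                target_counts[key] = target_counts.get(key, 0) + 1
    out = {}
    for key, n_term in term_counts.items():
        a = target_counts.get(key, 0)
        out[display[key]] = ContingencyTable(
            a, n_target - a, n_term - a, n_total - n_target - (n_term - a))
    return out


def build_pair_tables(reports: Sequence) -> dict[tuple[str, str], ContingencyTable]:
    """Tables for every (drug, PT) pair in the corpus, for the prior fit.

    Drug membership counts a report once per distinct normalized drug
    name regardless of role; PT membership once per distinct PT.
    """
    n_total = len(reports)
    drug_counts: dict[str, int] = {}
    pt_counts: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for r in reports:
        drugs = {normalize_term(name) for name, _role in r.drugs}
        pts = {normalize_term(p) for p in r.pts}
        for dname in drugs:
            drug_counts[dname] = drug_counts.get(dname, 0) + 1
        for p in pts:
            pt_counts[p] = pt_counts.get(p, 0) + 1
        for dname in drugs:
            for p in pts:
                pair_counts[(dname, p)] = pair_counts.get((dname, p), 0) + 1
    out = {}
    for dname, nd in drug_counts.items():
        for p, np_ in pt_counts.items():
            a = pair_counts.get((dname, p), 0)
            out[(dname, p)] = ContingencyTable(a, nd - a, np_ - a, n_total - nd - (np_ - a))
    return out


# ---------------------------------------------------------------------------
# frequentist statistics


def ror(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with log-normal 95% CI.

    Returns ``(ror, lo, hi)``. When any cell is zero, all four cells get
    the Haldane +0.5 correction so the estimate and interval stay finite.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(est) - 1.96 * se)
    hi = math.exp(math.log(est) + 1.96 * se)
    return est, lo, hi


def prr(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-squared.

    ``PRR = [a/(a+b)] / [c/(c+d)]``; the chi-squared uses the product
    formula ``N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` without continuity
    correction. A zero margin makes the pair not evaluable and both
    values are returned as NaN rather than raising.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.N
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins or c == 0:
        return float("nan"), float("nan")
    est = (a / (a + b)) / (c / (c + d))
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return est, chi2


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float]:
    """Closed-form BCPNN information component and its IC025 bound.

    ``IC = log2((a+0.5)/(E+0.5))`` with the standard credibility
    approximation ``IC025 = IC - 3.3(a+0.5)^(-1/2) - 2(a+0.5)^(-3/2)``.
    """
    a = t.a
    e = t.E
    ic = math.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025


# ---------------------------------------------------------------------------
# MGPS: prior fit and posterior summaries


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    # negative-binomial marginal of a Gamma(alpha, beta) mixed Poisson with offset e
    p = beta / (beta + e)
    return stats.nbinom.logpmf(a, alpha, p)


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    w = special.expit(theta[0])
    a1, b1, a2, b2 = np.exp(theta[1:])
    l1 = _nb_logpmf(a, a1, b1, e) + math.log(w)
    l2 = _nb_logpmf(a, a2, b2, e) + math.log1p(-w)
    return float(np.sum(np.logaddexp(l1, l2)))


def _theta(prior: GammaMixturePrior) -> np.ndarray:
    return np.array([special.logit(prior.w), math.log(prior.alpha1), math.log(prior.beta1),
                     math.log(prior.alpha2), math.log(prior.beta2)])


def _prior_from_theta(theta: np.ndarray, loglik: float) -> GammaMixturePrior:
    w = float(special.expit(theta[0]))
    a1, b1, a2, b2 = (float(v) for v in np.exp(theta[1:]))
    return GammaMixturePrior(w=w, alpha1=a1, beta1=b1, alpha2=a2, beta2=b2, loglik=loglik)


def fit_prior(tables: Iterable[ContingencyTable],
              start: GammaMixturePrior = DEFAULT_PRIOR_START,
              min_tables: int = 50) -> GammaMixturePrior:
    """Fit the two-gamma mixture prior by marginal maximum likelihood.

    The marginal of each observed count ``a`` given its expected count
    ``E`` is a two-component negative-binomial mixture; the mixture
    weight and the four gamma hyperparameters are optimised jointly
    (L-BFGS-B on unconstrained transforms) from the documented start
    point. Tables with ``E = 0`` are ignored.
    """
    tabs = [t for t in tables if t.E > 0]
    if len(tabs) < min_tables:
        raise ValueError(
            f"prior fit needs at least {min_tables} tables with E > 0, got {len(tabs)}")
    a = np.array([t.a for t in tabs], dtype=float)
    e = np.array([t.E for t in tabs], dtype=float)

    def neg(theta: np.ndarray) -> float:
        return -_mixture_loglik(theta, a, e)

    theta0 = _theta(start)
    # the mixture likelihood has local optima (a component the data do
    # not use is only weakly identified), so the requested start is
    # always complemented by two fixed alternates and the best final
    # likelihood wins; this also makes the result robust to the start
    starts = [
        theta0,
        _theta(DEFAULT_PRIOR_START),
        _theta(GammaMixturePrior(w=0.5, alpha1=1.0, beta1=1.0, alpha2=1.0, beta2=0.5)),
        _theta(GammaMixturePrior(w=0.1, alpha1=0.5, beta1=0.5, alpha2=3.0, beta2=3.0)),
    ]
    starts = [t for i, t in enumerate(starts)
              if not any(np.allclose(t, s) for s in starts[:i])]
    best = None
    for t0 in starts:
        res = optimize.minimize(neg, t0, method="L-BFGS-B",
                                bounds=[(-8, 8)] + [(-10, 10)] * 4,
                                options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    grad_norm = float(np.linalg.norm(best.jac)) if best.jac is not None else float("nan")
    fitted = _prior_from_theta(best.x, loglik=-float(best.fun))
    rel_grad = grad_norm / max(1.0, abs(fitted.loglik))
    if not best.success and rel_grad > 1e-2:
        raise PriorFitError("MGPS prior optimisation did not converge", fitted, grad_norm)
    start_ll = _mixture_loglik(theta0, a, e)
    if fitted.loglik < start_ll - 1e-9:
        # optimiser should never end below its own start point
        raise PriorFitError("fitted likelihood below start point", fitted, grad_norm)
    return fitted


def _posterior_mixture(t: ContingencyTable, prior: GammaMixturePrior):
    """Posterior over lambda: weights and Gamma(shape, rate) components."""
    a, e = t.a, t.E
    l1 = _nb_logpmf(np.array([a]), prior.alpha1, prior.beta1, np.array([e]))[0] \
        + math.log(prior.w)
    l2 = _nb_logpmf(np.array([a]), prior.alpha2, prior.beta2, np.array([e]))[0] \
        + math.log1p(-prior.w)
    m = max(l1, l2)
    q1 = math.exp(l1 - m)
    q2 = math.exp(l2 - m)
    z = q1 + q2
    weights = (q1 / z, q2 / z)
    comps = ((prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e))
    return weights, comps


def ebgm(t: ContingencyTable, prior: GammaMixturePrior) -> tuple[float, float]:
    """Empirical-Bayes geometric mean and its 5th posterior percentile.

    EBGM is ``2**E[log2 lambda]`` under the posterior gamma mixture
    (digamma closed form per component); EBGM05 solves the posterior
    mixture CDF at 0.05 by bracketed root-finding. Returns NaN for
    tables with ``E = 0`` (not evaluable).
    """
    if t.E <= 0:
        return float("nan"), float("nan")
    weights, comps = _posterior_mixture(t, prior)
    elog = sum(w * (special.digamma(shape) - math.log(rate))
               for w, (shape, rate) in zip(weights, comps))
    est = math.exp(elog)

    q = [stats.gamma.ppf(0.05, shape, scale=1.0 / rate) for shape, rate in comps]
    lo, hi = min(q), max(q)

    def cdf_minus(x: float) -> float:
        return sum(w * stats.gamma.cdf(x, shape, scale=1.0 / rate)
                   for w, (shape, rate) in zip(weights, comps)) - 0.05

    if hi - lo < 1e-12:
        return est, float(lo)
    # the component 5% quantiles bracket the mixture quantile up to
    # floating-point slack; widen until the signs actually differ
    for _ in range(60):
        if cdf_minus(lo) <= 0:
            break
        lo *= 0.5
    for _ in range(60):
        if cdf_minus(hi) >= 0:
            break
        hi *= 2.0
    q05 = optimize.brentq(cdf_minus, lo, hi, xtol=1e-12, rtol=1e-10)
    return est, float(q05)


# ---------------------------------------------------------------------------
# combined criterion


def evaluate_signal(t: ContingencyTable, term: str, level: str = "PT",
                    prior: GammaMixturePrior | None = None,
                    thresholds: Thresholds = Thresholds()) -> SignalResult:
    """Compute all four statistics and apply the combined criterion.

    ``combined_pos`` is the conjunction of the four per-algorithm flags;
    a pair flagged by the combination is therefore flagged by every
    single algorithm. Statistics that are not evaluable (zero margins,
    E=0 without a prior) yield NaN and a False flag.
    """
    ror_est, ror_lo, ror_hi = ror(t)
    prr_est, chi2 = prr(t)
    ic, ic025 = bcpnn_ic(t)
    if prior is not None:
        ebgm_est, ebgm05 = ebgm(t, prior)
    else:
        ebgm_est, ebgm05 = float("nan"), float("nan")

    th = thresholds
    ror_pos = t.a >= th.min_count and ror_lo > th.ror_ci_lower
    prr_pos = (t.a >= th.min_count and not math.isnan(prr_est)
               and prr_est >= th.prr_min and chi2 >= th.chi2_min)
    bcpnn_pos = ic025 > th.ic025_min
    mgps_pos = not math.isnan(ebgm05) and ebgm05 > th.ebgm05_min
    return SignalResult(
        term=term, level=level, a=t.a,
        ror=ror_est, ror_lo=ror_lo, ror_hi=ror_hi,
        prr=prr_est, chi2=chi2, ic=ic, ic025=ic025,
        ebgm=ebgm_est, ebgm05=ebgm05,
        ror_pos=ror_pos, prr_pos=prr_pos, bcpnn_pos=bcpnn_pos, mgps_pos=mgps_pos,
        combined_pos=ror_pos and prr_pos and bcpnn_pos and mgps_pos,
    )
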