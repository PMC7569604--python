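"""Development-time distributions and interval-censored AFT fitting.

The spread of event times (stage development, adult senescence, oviposition)
among individuals is captured by a two-parameter family expressed in
*normalized age* ``x = time / median time``: a log-logistic, Weibull or
lognormal CDF with common scale ``delta`` (shape ``alpha = 1/delta``),
normalized so that ``F(1) = 0.5`` for every family.  Median times per
temperature group come from an accelerated failure time (AFT) model fitted
by maximum likelihood to interval-censored observations (events known only
to lie between consecutive daily checks), with one location per group on
the log-time scale, an optional additive sex factor, and a single common
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "DistributionLink",
    "IntervalObservation",
    "AFTFit",
    "link_cdf",
    "link_quantile",
    "alpha_from_delta",
    "fit_aft",
    "select_family",
]

FAMILIES = ("loglogistic", "weibull", "lognormal")

_LN2 = math.log(2.0)


def alpha_from_delta(delta: float) -> float:
    """Shape parameter ``alpha = 1/delta`` of a distribution link."""
    if not delta > 0:
        raise ValueError("delta must be positive")
    return 1.0 / delta


@dataclass(frozen=True)
class DistributionLink:
    """Median-normalized event-time distribution.

    ``family`` is one of loglogistic / weibull / lognormal; ``delta`` the
    common scale on the log-time axis.  All three CDFs satisfy
    ``F(0) = 0``, ``F(1) = 0.5`` (the Weibull carries an explicit ``ln 2``
    factor to enforce this) and tend to 1.
    """

    family: str
    delta: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not self.delta > 0:
            raise ValueError("delta must be positive")

    @property
    def alpha(self) -> float:
        return alpha_from_delta(self.delta)

    def cdf(self, x):
        return link_cdf(self, x)

    def quantile(self, p):
        return link_quantile(self, p)


def link_cdf(link: DistributionLink, x) -> np.ndarray | float:
    """Cumulative probability that the event occurred by normalized age ``x``.

    Log-logistic: ``1 - 1/(1 + x^alpha)``; Weibull: ``1 - exp(-ln2 x^alpha)``;
    lognormal: ``Phi(ln x / delta)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("normalized age must be non-negative")
    a = link.alpha
    with np.errstate(divide="ignore", over="ignore"):
        if link.family == "loglogistic":
            out = 1.0 - 1.0 / (1.0 + x**a)
        elif link.family == "weibull":
            out = 1.0 - np.exp(-_LN2 * x**a)
        else:  # lognormal
            lx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)
            out = stats.norm.cdf(lx / link.delta)
    out = np.where(x == 0, 0.0, out)
    return out if out.ndim else float(out)


def link_quantile(link: DistributionLink, p) -> np.ndarray | float:
    """Normalized age at which the link CDF reaches probability ``p``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    d = link.delta
    if link.family == "loglogistic":
        out = (p / (1.0 - p)) ** d
    elif link.family == "weibull":
        out = (-np.log1p(-p) / _LN2) ** d
    else:  # lognormal
        out = np.exp(d * stats.norm.ppf(p))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class IntervalObservation:
    """One interval-censored event time.

    The event happened between ``lower`` and ``upper`` days (``upper`` may
    be ``inf`` for individuals still event-free at the end of observation).
    ``group`` is the temperature level; ``sex`` is optional ("f"/"m").
    """

    lower: float
    upper: float
    group: float
    event: str = "development"
    sex: str | None = None

    def __post_init__(self):
        if not (0 <= self.lower < self.upper):
            raise ValueError("require 0 <= lower < upper")


@dataclass
class AFTFit:
    """Result of an interval-censored AFT fit with a common scale."""

    family: str
    medians: dict[float, float]
    median_ci: dict[float, tuple[float, float]]
    delta: float
    delta_se: float
    loglik: float
    loglik_intercept: float
    loglik_saturated: float
    deviance: float
    df: int
    h_het: float
    sex_coef: float | None = None
    sex_coef_se: float | None = None
    n: int = 0
    converged: bool = True

    @property
    def alpha(self) -> float:
        return alpha_from_delta(self.delta)

    @property
    def deviance_intercept(self) -> float:
        return 2.0 * (self.loglik_saturated - self.loglik_intercept)


def _interval_loglik(theta, lowers, uppers, gidx, male, family, n_groups, sex_effect):
    """Sum of ln[F(u/med) - F(l/med)] over observations."""
    locs = theta[:n_groups]
    beta = theta[n_groups] if sex_effect else 0.0
    lndelta = theta[-1]
    if not np.isfinite(lndelta) or abs(lndelta) > 20:
        return -np.inf
    link = DistributionLink(family, math.exp(lndelta))
    med = np.exp(locs[gidx] + beta * male)
    with np.errstate(over="ignore", invalid="ignore"):
        cl = link_cdf(link, lowers / med)
        cu = np.where(np.isinf(uppers), 1.0, link_cdf(link, np.minimum(uppers, 1e300) / med))
    prob = np.clip(cu - cl, 1e-300, 1.0)
    return float(np.sum(np.log(prob)))


def _maximize(nll_args, x0):
    fun = lambda th: -_interval_loglik(th, *nll_args)
    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
    res2 = optimize.minimize(fun, res.x, method="BFGS", options={"gtol": 1e-8})
    return res2 if res2.fun <= res.fun else res


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def _saturated_loglik(lowers, uppers, gidx):
    """Multinomial log-likelihood over the distinct intervals within groups.

    Serves as the saturated reference of the deviance table; its parameter
    count is the number of distinct (group, interval) cells.
    """
    total = 0.0
    n_cells = 0
    for g in np.unique(gidx):
        sel = gidx == g
        cells, counts = np.unique(
            np.stack([lowers[sel], uppers[sel]], axis=1), axis=0, return_counts=True
        )
        n_g = counts.sum()
        total += float(np.sum(counts * np.log(counts / n_g)))
        n_cells += len(cells)
    return total, n_cells


def fit_aft(
    observations: Sequence[IntervalObservation],
    family: str,
    sex_effect: bool = False,
    conf_level: float = 0.95,
) -> AFTFit:
    """Fit an interval-censored AFT model with per-group medians.

    Maximizes ``sum ln[F(upper/median_g) - F(lower/median_g)]`` over group
    log-medians (plus an optional additive sex coefficient on log time) and
    one common log-scale.  Confidence limits for the medians use the
    t-distribution inflated by the heterogeneity factor
    ``H = deviance / df`` of the fit against the saturated
    (one-probability-per-observed-interval) model.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    obs = list(observations)
    if not obs:
        raise ValueError("no observations")
    groups = sorted({o.group for o in obs})
    lowers = np.array([o.lower for o in obs])
    uppers = np.array([o.upper for o in obs])
    gidx = np.array([groups.index(o.group) for o in obs])
    male = np.array([1.0 if o.sex == "m" else 0.0 for o in obs])
    if sex_effect and not any(o.sex for o in obs):
        raise ValueError("sex_effect requested but no observation carries a sex label")

    n_groups = len(groups)
    # start from interval-midpoint moments per group
    mids = np.where(np.isinf(uppers), lowers + 1.0, 0.5 * (lowers + uppers))
    mids = np.maximum(mids, 1e-6)
    loc0 = np.array([np.log(np.median(mids[gidx == i])) for i in range(n_groups)])
    spread = np.std(np.log(mids)) or 0.2
    x0 = np.concatenate([loc0, [0.0] if sex_effect else [], [np.log(max(spread * 0.5, 0.02))]])

    args = (lowers, uppers, gidx, male, family, n_groups, sex_effect)
    res = _maximize(args, x0)
    if not np.isfinite(res.fun):
        raise RuntimeError("AFT likelihood maximization failed to converge")
    theta = res.x
    loglik = -float(res.fun)

    # intercept-only model for the deviance table
    x0_int = np.array([np.log(np.median(mids)), np.log(max(spread * 0.5, 0.02))])
    args_int = (lowers, uppers, np.zeros_like(gidx), male, family, 1, False)
    res_int = _maximize(args_int, x0_int)
    loglik_int = -float(res_int.fun)

    loglik_sat, n_cells = _saturated_loglik(lowers, uppers, gidx)
    k_model = len(theta)
    deviance = 2.0 * (loglik_sat - loglik)
    df = max(n_cells - k_model, 1)
    h_het = max(deviance / df, 1.0)

    # standard errors from the observed information
    f = lambda th: -_interval_loglik(th, *args)
    H = _numerical_hessian(f, theta)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k_model, np.nan)

    tq = stats.t.ppf(0.5 + conf_level / 2.0, df)
    medians, cis = {}, {}
    for i, g in enumerate(groups):
        m = math.exp(theta[i])
        half = tq * se[i] * math.sqrt(h_het)
        cis[g] = (m * math.exp(-half), m * math.exp(half))
        medians[g] = m
    delta = math.exp(theta[-1])

    return AFTFit(
        family=family,
        medians=medians,
        median_ci=cis,
        delta=delta,
        delta_se=float(se[-1] * delta),
        loglik=loglik,
        loglik_intercept=loglik_int,
        loglik_saturated=loglik_sat,
        deviance=deviance,
        df=df,
        h_het=h_het,
        sex_coef=float(theta[n_groups]) if sex_effect else None,
        sex_coef_se=float(se[n_groups]) if sex_effect else None,
        n=len(obs),
        converged=bool(res.success or np.isfinite(loglik)),
    )


def select_family(
    observations: Sequence[IntervalObservation],
    families: Sequence[str] = FAMILIES,
    sex_effect: bool = False,
) -> AFTFit:
    """Fit every candidate family and return the maximum-likelihood one."""
    fits = [fit_aft(observations, fam, sex_effect=sex_effect) for fam in families]
    return max(fits, key=lambda f: f.loglik)
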