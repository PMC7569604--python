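"""Nonlinear least-squares calibration of the thermal-response curves.

Median development times are fitted on the ln-time scale (variance of
development times grows with the median, so log residuals are closer to
homoscedastic); stage mortalities are fitted jointly on the proportion
scale with either a shared or stage-specific optimum temperature; mean
fecundities are fitted on the ln(1 + eggs) scale.  Model comparison uses
the small-sample corrected Akaike criterion and, for nested mortality
variants, an F-ratio test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .thermal import (
    FecundityParams,
    JanischParams,
    MortalityParams,
    fecundity_lntransform,
    immature_mortality,
    janisch_time,
)

__all__ = [
    "FitReport",
    "fit_lntime_model",
    "fit_mortality_model",
    "fit_fecundity_model",
    "nested_f_test",
    "aicc",
    "gaussian_loglik",
]


@dataclass
class FitReport:
    """Summary of a least-squares curve fit."""

    model: str
    params: dict[str, float]
    se: dict[str, float]
    rss: float
    tss: float
    n: int
    k: int
    f_value: float
    df: tuple[int, int]
    p_value: float
    r2: float
    adj_r2: float
    aicc: float
    fitted: object = None  # the parameter dataclass(es) on the natural scale
    residual_sd: float = 0.0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "se": self.se,
            "rss": self.rss,
            "n": self.n,
            "k": self.k,
            "f_value": self.f_value,
            "df": list(self.df),
            "p_value": self.p_value,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "aicc": self.aicc,
            "residual_sd": self.residual_sd,
        }


def gaussian_loglik(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood of a least-squares fit."""
    rss = max(rss, 1e-300)
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)


def aicc(loglik: float, n: int, k: int) -> float:
    """Small-sample corrected AIC: ``AIC + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _report(model, names, theta, jac, resid, y, k_extra=0, fitted=None) -> FitReport:
    n = len(y)
    k = len(theta)
    rss = float(resid @ resid)
    tss = float(np.sum((y - np.mean(y)) ** 2))
    dof = max(n - k, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    df1, df2 = max(k - 1, 1), max(n - k, 1)
    if rss <= 0 or tss <= rss:
        f_value = ((tss - rss) / df1) / (rss / df2) if rss > 0 else np.inf
    else:
        f_value = ((tss - rss) / df1) / (rss / df2)
    p_value = float(stats.f.sf(f_value, df1, df2)) if np.isfinite(f_value) else 0.0
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (rss / df2) / (tss / (n - 1)) if n > k and tss > 0 else r2
    return FitReport(
        model=model,
        params=dict(zip(names, map(float, theta))),
        se=dict(zip(names, map(float, se))),
        rss=rss,
        tss=tss,
        n=n,
        k=k,
        f_value=float(f_value),
        df=(df1, df2),
        p_value=p_value,
        r2=r2,
        adj_r2=adj_r2,
        aicc=aicc(gaussian_loglik(rss, n), n, k + 1) if n > k + 2 else float("nan"),
        fitted=fitted,
        residual_sd=math.sqrt(s2),
    )


def fit_lntime_model(
    median_times: Mapping[float, float] | Sequence[tuple[float, float]],
    stage: str = "",
) -> FitReport:
    """Fit the Janisch development model to median times on the ln-time scale.

    Starting values: ``d_min`` at the fastest observed development, ``t_opt``
    at its temperature, ``k = 0.1``; a small grid of alternative ``k`` values
    guards against local minima.
    """
    items = sorted(dict(median_times).items() if isinstance(median_times, Mapping)
                   else median_times)
    T = np.array([t for t, _ in items], dtype=float)
    times = np.array([d for _, d in items], dtype=float)
    if len(T) < 4:
        raise ValueError("need at least 4 (temperature, median time) points")
    if np.any(times <= 0):
        raise ValueError("median times must be positive")
    y = np.log(times)

    def model_ln(theta, T):
        d_min, t_opt, k = theta
        z = k * (T - t_opt)
        return np.log(0.5 * d_min) + np.logaddexp(z, -z)

    def resid(theta):
        if theta[0] <= 0 or theta[2] <= 0:
            return np.full_like(y, 1e6)
        return model_ln(theta, T) - y

    i_min = int(np.argmin(times))
    best = None
    for k0 in (0.1, 0.05, 0.2, 0.4):
        x0 = np.array([times[i_min], T[i_min], k0])
        try:
            sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("Janisch fit failed to converge")
    params = JanischParams(*map(float, best.x), stage=stage)
    return _report(
        "janisch", ["d_min", "t_opt", "k"], best.x, best.jac, best.fun, y, fitted=params
    )


def fit_mortality_model(
    mortalities: Mapping[str, Sequence[tuple[float, float]]],
    share_topt: bool = True,
) -> FitReport:
    """Jointly fit the immature-mortality curve across life stages.

    ``mortalities`` maps stage name to (temperature, mortality proportion)
    pairs.  With ``share_topt`` a single optimum temperature is common to
    all stages (stage-specific magnitude ``H`` and spread ``B``); otherwise
    each stage gets its own optimum.  Fitting is on the proportion scale;
    ``H`` and ``B`` are optimized on the log scale for conditioning.
    """
    stages = list(mortalities)
    data = {s: (np.array([t for t, _ in mortalities[s]], dtype=float),
                np.array([m for _, m in mortalities[s]], dtype=float))
            for s in stages}
    for s, (T, m) in data.items():
        if len(T) < 3:
            raise ValueError(f"stage {s!r} needs at least 3 mortality points")
        if np.any((m < 0) | (m > 1)):
            raise ValueError("mortalities must lie in [0, 1]")
    y = np.concatenate([data[s][1] for s in stages])
    n_st = len(stages)

    def unpack(theta):
        lnH = theta[:n_st]
        lnB = theta[n_st:2 * n_st]
        topts = ([theta[2 * n_st]] * n_st) if share_topt else list(theta[2 * n_st:])
        return [
            MortalityParams(h=math.exp(lnH[i]), b=math.exp(lnB[i]),
                            t_opt=topts[i], stage=stages[i])
            for i in range(n_st)
        ]

    def resid(theta):
        out = []
        for i, s in enumerate(stages):
            T, m = data[s]
            out.append(immature_mortality(unpack(theta)[i], T) - m)
        return np.concatenate(out)

    pooled_T = np.concatenate([data[s][0] for s in stages])
    t0 = float(pooled_T[np.argmin(y)])
    x0s = []
    for t_start in (t0, 20.0, 22.0):
        lnH0, lnB0 = [], []
        for s in stages:
            T, m = data[s]
            m_min = float(np.clip(np.min(m), 1e-4, 0.5))
            lnH0.append(math.log(max(-math.log1p(-m_min) / 4.0, 1e-8)))
            lnB0.append(math.log(2.0))
        tail = [t_start] if share_topt else [t_start] * n_st
        x0s.append(np.array(lnH0 + lnB0 + tail))
    best = None
    for x0 in x0s:
        try:
            sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12, max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("mortality fit failed to converge")

    names = [f"lnH_{s}" for s in stages] + [f"lnB_{s}" for s in stages] + (
        ["t_opt"] if share_topt else [f"t_opt_{s}" for s in stages])
    fitted = unpack(best.x)
    rep = _report(
        "mortality_shared_topt" if share_topt else "mortality_free_topt",
        names, best.x, best.jac, best.fun, y, fitted={p.stage: p for p in fitted},
    )
    # expose natural-scale parameters alongside the optimized log-scale ones
    for p in fitted:
        rep.params[f"H_{p.stage}"] = p.h
        rep.params[f"B_{p.stage}"] = p.b
    return rep


def fit_fecundity_model(
    fecundities: Mapping[float, float] | Sequence[tuple[float, float]],
) -> FitReport:
    """Fit the asymmetric unimodal fecundity curve on the ln(1+eggs) scale."""
    items = sorted(dict(fecundities).items() if isinstance(fecundities, Mapping)
                   else fecundities)
    T = np.array([t for t, _ in items], dtype=float)
    F = np.array([f for _, f in items], dtype=float)
    if len(T) < 5:
        raise ValueError("need at least 5 (temperature, fecundity) points")
    if np.any(F < 0):
        raise ValueError("fecundities must be non-negative")
    y = np.log1p(F)

    def resid(theta):
        h, tl, lnbl, lnbh = theta
        if h <= 0:
            return np.full_like(y, 1e6)
        p = FecundityParams(h=h, tl=tl, bl=math.exp(lnbl), bh=math.exp(lnbh))
        return fecundity_lntransform(p, T) - y

    t_peak = float(T[np.argmax(F)])
    best = None
    for tl0 in (t_peak - 7.0, t_peak - 4.0, t_peak - 10.0):
        for bl0, bh0 in ((2.0, 30.0), (1.0, 10.0), (3.0, 60.0)):
            x0 = np.array([float(np.max(y)) * 2.0, tl0, math.log(bl0), math.log(bh0)])
            try:
                sol = optimize.least_squares(resid, x0, xtol=1e-13, ftol=1e-13,
                                             max_nfev=50000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("fecundity fit failed to converge")
    h, tl, lnbl, lnbh = best.x
    fitted = FecundityParams(h=float(h), tl=float(tl),
                             bl=math.exp(lnbl), bh=math.exp(lnbh))
    rep = _report("fecundity", ["h", "tl", "ln_bl", "ln_bh"], best.x, best.jac,
                  best.fun, y, fitted=fitted)
    rep.params["bl"] = fitted.bl
    rep.params["bh"] = fitted.bh
    return rep


def nested_f_test(simple: FitReport, complex_: FitReport) -> tuple[float, tuple[int, int], float]:
    """F-ratio test of a simpler model nested inside a more complex one.

    Returns ``(F, (df1, df2), p)`` with ``df1`` the extra parameters and
    ``df2`` the residual degrees of freedom of the complex model.
    """
    if complex_.k <= simple.k or simple.n != complex_.n:
        raise ValueError("models are not nested on the same data")
    df1 = complex_.k - simple.k
    df2 = complex_.n - complex_.k
    F = ((simple.rss - complex_.rss) / df1) / (complex_.rss / df2)
    return float(F), (df1, df2), float(stats.f.sf(F, df1, df2))
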