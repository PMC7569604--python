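"""Temperature-response functions for the whitefly life-history processes.

Each life process — immature development, immature mortality, adult
senescence/oviposition timing, and lifetime fecundity — is described by a
closed-form function of temperature.  Development rate follows the Janisch
catenary (fastest development ``1/D_min`` at the optimum ``T_opt``);
immature mortality is a symmetric double-logistic bathtub with a shared
optimum across stages; adult median times decay exponentially with
temperature, with sex acting as a multiplicative (log-additive) factor;
mean fecundity per female is an asymmetric unimodal curve on the
``ln(1 + eggs)`` scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "JanischParams",
    "MortalityParams",
    "AdultTimingParams",
    "FecundityParams",
    "DegreeDayFit",
    "AdjustmentFactors",
    "janisch_rate",
    "janisch_time",
    "immature_mortality",
    "adult_median_time",
    "mean_fecundity",
    "degree_day_fit",
    "apply_adjustment",
]

#: development rates are floored here so that 1/rate never overflows
RATE_FLOOR = 1e-9

#: exponent cap; exp() of anything above this saturates the mortality model
_EXP_CAP = 700.0


def _check_finite(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    return T


@dataclass(frozen=True)
class JanischParams:
    """Janisch development-rate curve for one immature stage.

    ``d_min`` is the minimum stage duration (days) attained at ``t_opt``
    (degrees C); ``k`` (1/degree C) controls how steeply development slows
    away from the optimum.
    """

    d_min: float
    t_opt: float
    k: float
    stage: str = ""

    def __post_init__(self):
        if not self.d_min > 0:
            raise ValueError("d_min must be positive")
        if not self.k > 0:
            raise ValueError("k must be positive")
        if not 0.0 <= self.t_opt <= 40.0:
            raise ValueError("t_opt outside the biologically plausible 0-40 C")


@dataclass(frozen=True)
class MortalityParams:
    """Stage-specific immature mortality parameters.

    ``h`` scales overall mortality, ``b`` (degrees C) the width of the
    low-mortality window around the optimum ``t_opt``, which is shared
    across stages in the default parameterization.
    """

    h: float
    b: float
    t_opt: float
    stage: str = ""

    def __post_init__(self):
        if not self.h > 0:
            raise ValueError("h must be positive")
        if not self.b > 0:
            raise ValueError("b must be positive")


@dataclass(frozen=True)
class AdultTimingParams:
    """Exponential model for adult median times.

    The baseline median oviposition time is ``1 / (intercept * exp(slope*T))``;
    female and male median survival times are the baseline multiplied by
    ``exp(factor)`` for the respective additive (log-time scale) factor.
    """

    intercept: float
    slope: float
    factor_female: float = 0.0
    factor_male: float = 0.0

    def __post_init__(self):
        if not self.intercept > 0:
            raise ValueError("intercept must be positive")


@dataclass(frozen=True)
class FecundityParams:
    """Asymmetric unimodal fecundity curve.

    Parameterized on the ``ln(1 + eggs)`` scale:
    ``ln(1 + F(T)) = h / [(1 + e^{-(T-tl)/bl}) (1 + e^{-(tl-T)/bh})]``
    so predicted fecundity tends to zero at both temperature extremes.
    ``multiplier`` rescales eggs on the natural scale (used by the
    fluctuating-temperature adjustment).
    """

    h: float
    tl: float
    bl: float
    bh: float
    multiplier: float = 1.0

    def __post_init__(self):
        if not (self.h > 0 and self.bl > 0 and self.bh > 0):
            raise ValueError("h, bl, bh must be positive")
        if not self.multiplier > 0:
            raise ValueError("multiplier must be positive")


@dataclass(frozen=True)
class DegreeDayFit:
    """Linear degree-day summary of a stage's development rates.

    ``t0`` is the lower developmental threshold (x-intercept of the
    rate-temperature regression) and ``K = 1/slope`` the thermal constant in
    degree-days.
    """

    t0: float
    K: float
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_used: int
    stage: str = ""


@dataclass(frozen=True)
class AdjustmentFactors:
    """Empirical corrections for fluctuating-temperature conditions."""

    mortality_b: float = 1.3
    adult_time: float = 2.0
    fecundity: float = 4.0

    def __post_init__(self):
        for name in ("mortality_b", "adult_time", "fecundity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} factor must be positive")


def janisch_rate(params: JanischParams, T) -> np.ndarray | float:
    """Development rate (1/day) at temperature ``T`` (degrees C).

    ``r(T) = [ (D_min/2) (e^{k(T - T_opt)} + e^{-k(T - T_opt)}) ]^{-1}``,
    a catenary in T peaking at exactly ``1/D_min`` when ``T == T_opt``.
    """
    T = _check_finite(T)
    z = np.clip(params.k * (T - params.t_opt), -_EXP_CAP, _EXP_CAP)
    denom = 0.5 * params.d_min * (np.exp(z) + np.exp(-z))
    rate = np.maximum(1.0 / denom, RATE_FLOOR)
    return rate if rate.ndim else float(rate)


def janisch_time(params: JanischParams, T) -> np.ndarray | float:
    """Median development time (days) implied by the Janisch rate."""
    rate = janisch_rate(params, T)
    out = 1.0 / np.asarray(rate)
    return out if out.ndim else float(out)


def immature_mortality(params: MortalityParams, T, form: str = "reconstructed"):
    """Stage mortality proportion in [0, 1] at temperature ``T``.

    The default ``reconstructed`` form is
    ``m(T) = 1 - exp(-H (1 + e^{-(T-T_opt)/B})(1 + e^{-(T_opt-T)/B}))``,
    symmetric in ``T - T_opt`` with minimum ``1 - e^{-4H}`` at the optimum.
    ``form="literal"`` evaluates the alternative ratio reading
    ``1 - H / [(1+e^{-(T-T_opt)/B})(1+e^{-(T_opt-T)/B})]``, retained for
    comparison only.
    """
    T = _check_finite(T)
    z = np.clip((T - params.t_opt) / params.b, -_EXP_CAP, _EXP_CAP)
    # (1+e^-z)(1+e^z) = 2 + e^z + e^-z, computed safely for large |z|
    bracket = 2.0 + np.exp(np.minimum(z, _EXP_CAP)) + np.exp(np.minimum(-z, _EXP_CAP))
    if form == "reconstructed":
        m = 1.0 - np.exp(-np.minimum(params.h * bracket, _EXP_CAP))
    elif form == "literal":
        m = 1.0 - params.h / bracket
    else:
        raise ValueError(f"unknown mortality form: {form!r}")
    m = np.clip(m, 0.0, 1.0)
    return m if m.ndim else float(m)


_ADULT_ROLES = ("oviposition", "female_survival", "male_survival")


def adult_median_time(params: AdultTimingParams, T, role: str = "oviposition"):
    """Median adult time (days) for oviposition or sex-specific survival.

    Baseline (oviposition) median: ``t(T) = 1 / (intercept * e^{slope T})``;
    survival medians multiply the baseline by ``e^{factor}`` of the sex.
    Strictly decreasing in T for positive slope.
    """
    T = _check_finite(T)
    if role not in _ADULT_ROLES:
        raise ValueError(f"role must be one of {_ADULT_ROLES}")
    base = 1.0 / (params.intercept * np.exp(np.clip(params.slope * T, -_EXP_CAP, _EXP_CAP)))
    if role == "female_survival":
        base = base * math.exp(params.factor_female)
    elif role == "male_survival":
        base = base * math.exp(params.factor_male)
    return base if base.ndim else float(base)


def mean_fecundity(params: FecundityParams, T) -> np.ndarray | float:
    """Mean lifetime fecundity (eggs/female) at temperature ``T``."""
    T = _check_finite(T)
    lnf = fecundity_lntransform(params, T)
    out = params.multiplier * np.expm1(np.asarray(lnf, dtype=float))
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def fecundity_lntransform(params: FecundityParams, T) -> np.ndarray | float:
    """``ln(1 + F(T)/multiplier)`` — the scale the curve is fitted on."""
    T = np.asarray(T, dtype=float)
    zl = np.clip(-(T - params.tl) / params.bl, -_EXP_CAP, _EXP_CAP)
    zh = np.clip(-(params.tl - T) / params.bh, -_EXP_CAP, _EXP_CAP)
    out = params.h / ((1.0 + np.exp(zl)) * (1.0 + np.exp(zh)))
    return out if out.ndim else float(out)


def degree_day_fit(
    rate_points: Iterable[tuple[float, float]],
    high_T_cutoff: float = 28.0,
    stage: str = "",
) -> DegreeDayFit:
    """Linear degree-day regression of development rate on temperature.

    Points at or above ``high_T_cutoff`` (where the rate curve bends down)
    are discarded; ordinary least squares on the rest gives the lower
    threshold ``T0 = -intercept/slope`` and thermal constant ``K = 1/slope``.
    """
    pts = [(float(t), float(r)) for t, r in rate_points]
    kept = [(t, r) for t, r in pts if t < high_T_cutoff]
    if len(kept) < 3:
        raise ValueError("need at least 3 rate points below the cutoff")
    T = np.array([t for t, _ in kept])
    r = np.array([x for _, x in kept])
    if np.ptp(T) == 0:
        raise ValueError("temperatures must not all be equal")
    res = stats.linregress(T, r)
    if res.slope <= 0:
        raise ValueError("non-positive slope: developmental threshold undefined")
    return DegreeDayFit(
        t0=-res.intercept / res.slope,
        K=1.0 / res.slope,
        slope=res.slope,
        intercept=res.intercept,
        slope_se=res.stderr,
        intercept_se=res.intercept_stderr,
        n_used=len(kept),
        stage=stage,
    )


def apply_adjustment(bundle, factors: AdjustmentFactors | None = None):
    """Return a copy of a model bundle corrected for fluctuating temperature.

    Widens each stage's low-mortality window (``B`` x ``mortality_b``),
    doubles adult survival and oviposition medians by default
    (``intercept / adult_time``), and scales fecundity (``x fecundity``).
    The input bundle is left unmodified.
    """
    if factors is None:
        factors = bundle.adjustment
    mortality = {
        stage: replace(p, b=p.b * factors.mortality_b)
        for stage, p in bundle.mortality.items()
    }
    adult = replace(bundle.adult, intercept=bundle.adult.intercept / factors.adult_time)
    fecundity = replace(
        bundle.fecundity, multiplier=bundle.fecundity.multiplier * factors.fecundity
    )
    return replace(bundle, mortality=mortality, adult=adult, fecundity=fecundity)
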