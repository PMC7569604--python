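"""Life-table statistics and simulation-versus-observation comparison.

A life-table schedule pairs age-specific survival ``l_x`` (proportion of
the initial female cohort alive in daily age class ``x``) with age-specific
fecundity ``m_x`` (female offspring per female per day, the 1:1 sex ratio
already applied).  From a schedule the standard growth parameters follow:

* net reproduction rate ``R0 = sum l_x m_x``
* gross reproduction rate ``GRR = sum m_x``
* intrinsic rate of increase ``r_m``, either from the Euler-Lotka equation
  ``sum e^{-r (x+0.5)} l_x m_x = 1`` (``method="lotka"``) or from the
  approximate method ``r = ln(R0) / T`` with mean generation time
  ``T = sum (x+0.5) l_x m_x / R0``
* finite rate ``lambda = e^{r}`` and doubling time ``Dt = ln 2 / r``.

Ages are daily class lower bounds; the half-day shift places reproduction
at the midpoint of each class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LifeTableSchedule",
    "LifeTableParams",
    "ZComparison",
    "life_table_params",
    "mortality_se",
    "z_compare",
]


@dataclass(frozen=True)
class LifeTableSchedule:
    """Daily age-specific survival and fecundity of a female cohort."""

    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.ages, dtype=float)
        l = np.asarray(self.lx, dtype=float)
        m = np.asarray(self.mx, dtype=float)
        for name, arr in (("ages", a), ("lx", l), ("mx", m)):
            object.__setattr__(self, name, arr)
        if not (a.shape == l.shape == m.shape):
            raise ValueError("ages, lx, mx must have equal length")
        if len(a) == 0:
            raise ValueError("empty schedule")
        if abs(l[0] - 1.0) > 1e-9:
            raise ValueError("l_0 must equal 1")
        if np.any(np.diff(l) > 1e-12):
            raise ValueError("l_x must be non-increasing")
        if np.any(m < 0):
            raise ValueError("m_x must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "lx": self.lx, "mx": self.mx})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTableSchedule":
        return cls(df["age"].to_numpy(), df["lx"].to_numpy(), df["mx"].to_numpy())


@dataclass(frozen=True)
class LifeTableParams:
    """Population growth parameters of one life table."""

    R0: float
    GRR: float
    T: float
    r_m: float
    lam: float
    Dt: float
    method: str = "lotka"

    def to_dict(self) -> dict:
        return {"R0": self.R0, "GRR": self.GRR, "T": self.T,
                "r_m": self.r_m, "lambda": self.lam, "Dt": self.Dt,
                "method": self.method}


@dataclass(frozen=True)
class ZComparison:
    """z-score comparison of an observed value with simulation replicates."""

    observed: float
    simulated_mean: float
    simulated_sd: float
    z: float
    p: float
    n_replicates: int


def life_table_params(schedule: LifeTableSchedule, method: str = "lotka") -> LifeTableParams:
    """Compute R0, GRR, T, r_m, lambda and Dt from a schedule."""
    if method not in ("lotka", "approximate"):
        raise ValueError("method must be 'lotka' or 'approximate'")
    x = schedule.ages + 0.5
    lxmx = schedule.lx * schedule.mx
    R0 = float(np.sum(lxmx))
    GRR = float(np.sum(schedule.mx))
    if not np.isfinite(R0):
        raise ValueError("R0 is not finite")
    if R0 <= 0:
        return LifeTableParams(R0=0.0, GRR=GRR, T=math.inf, r_m=-math.inf,
                               lam=0.0, Dt=math.inf, method=method)
    T_approx = float(np.sum(x * lxmx) / R0)
    if method == "approximate":
        r = math.log(R0) / T_approx
    else:
        def euler(r):
            return float(np.sum(np.exp(-r * x) * lxmx) - 1.0)
        r0 = math.log(R0) / T_approx
        lo, hi = r0 - 1.0, r0 + 1.0
        while euler(lo) < 0:
            lo -= 1.0
        while euler(hi) > 0:
            hi += 1.0
        r = float(optimize.brentq(euler, lo, hi, xtol=1e-14, rtol=1e-15))
    T = math.log(R0) / r if r != 0.0 else T_approx
    Dt = math.log(2.0) / r if r != 0.0 else math.inf
    return LifeTableParams(R0=R0, GRR=GRR, T=T, r_m=r, lam=math.exp(r),
                           Dt=Dt, method=method)


def mortality_se(m: float, N: int) -> float:
    """Binomial standard error ``sqrt(m (1 - m) / N)`` of a mortality rate."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    if N < 1:
        raise ValueError("N must be at least 1")
    return math.sqrt(m * (1.0 - m) / N)


def z_compare(observed: float, simulated: "np.ndarray | list[float]") -> ZComparison:
    """z-score of an observed value against simulation replicates.

    ``z = (observed - mean(simulated)) / sd(simulated)``; the two-sided
    p-value uses the t-distribution with ``n_replicates - 1`` degrees of
    freedom.
    """
    sims = np.asarray(simulated, dtype=float)
    if sims.size < 2:
        raise ValueError("need at least 2 simulated replicates")
    mean = float(np.mean(sims))
    sd = float(np.std(sims, ddof=1))
    if sd == 0:
        raise ValueError("simulated replicates have zero standard deviation")
    z = (observed - mean) / sd
    p = float(2.0 * stats.t.sf(abs(z), sims.size - 1))
    return ZComparison(observed=float(observed), simulated_mean=mean,
                       simulated_sd=sd, z=float(z), p=p, n_replicates=int(sims.size))
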