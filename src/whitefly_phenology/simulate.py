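"""Individual-based stochastic cohort simulation via rate summation.

Each simulated individual starts as an egg at the beginning of a
temperature series and accumulates *normalized age* in every life process
at the temperature-dependent rate ``r(T) = 1 / median_time(T)``: a stage
completes when the accumulated normalized age reaches the individual's
drawn development quantile.  Mortality in each immature stage is a single
uniform draw against the accumulated temperature-based stage mortality
(per-step survival ``(1 - m(T))^{dx}`` with ``dx`` the fraction of the
stage completed in the step, which reduces exactly to ``m(T)`` at constant
temperature).  Sex is assigned at oviposition; females receive a lifetime
fecundity draw around the temperature-dependent mean and lay it out over
their own oviposition window following the oviposition distribution link.

All integrals are piecewise-constant rate summation on the native series
step (hourly for fluctuating series), with linear interpolation inside the
final step, so constant-temperature results match the closed forms exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import ModelBundle
from .distributions import link_cdf, link_quantile
from .lifetable import LifeTableSchedule
from .series import TemperatureSeries
from .thermal import (
    adult_median_time,
    immature_mortality,
    janisch_rate,
    mean_fecundity,
)

__all__ = [
    "CohortResult",
    "rate_summation",
    "simulate_cohort",
    "simulate_replicates",
    "pooled_schedule",
]

IMMATURE_STAGES = ("egg", "nymph", "puparium")

#: mortality clipped just below 1 so its log stays finite (death is then
#: effectively instantaneous anyway)
_M_CAP = 1.0 - 1e-12


class _Accumulator:
    """Piecewise-linear cumulative integral of a rate over a series."""

    def __init__(self, times_days: np.ndarray, values: np.ndarray):
        # values are per-step rates (left endpoints); integral is linear
        # within each step
        dt = np.diff(times_days)
        self.t = times_days
        self.cum = np.concatenate([[0.0], np.cumsum(values[:-1] * dt)])
        self._vals = values

    def at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.cum))

    def invert(self, target: float) -> float:
        """First time the integral reaches ``target`` (inf if never)."""
        if target > self.cum[-1]:
            return math.inf
        return float(np.interp(target, self.cum, self.t))


@dataclass
class CohortResult:
    """One simulated cohort: per-individual records and daily counts."""

    individuals: pd.DataFrame
    counts: pd.DataFrame  # columns: age, n_alive_f, eggs
    n: int
    n_females: int
    sex_ratio: float

    @property
    def schedule(self) -> LifeTableSchedule:
        return _schedule_from_counts(self.counts, self.n_females, self.sex_ratio)


def _schedule_from_counts(counts: pd.DataFrame, n_females: int,
                          sex_ratio: float) -> LifeTableSchedule:
    if n_females == 0:
        raise ValueError("no females in cohort: schedule undefined")
    alive = counts["n_alive_f"].to_numpy(dtype=float)
    eggs = counts["eggs"].to_numpy(dtype=float)
    lx = alive / n_females
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(alive > 0, sex_ratio * eggs / np.maximum(alive, 1), 0.0)
    return LifeTableSchedule(counts["age"].to_numpy(dtype=float), lx, mx)


def rate_summation(rate_fn, series: TemperatureSeries, start_day: float = 0.0,
                   target: float = 1.0) -> float:
    """Completion time (days from series start) of ``target`` normalized age.

    Accumulates ``sum r(T) dt`` from ``start_day``; at constant temperature
    this returns ``start_day + target / r(T)`` exactly.  Returns ``inf``
    when the series ends before the target is reached (right-censored).
    """
    if target <= 0:
        raise ValueError("target normalized age must be positive")
    td = series.times_h / 24.0
    acc = _Accumulator(td, np.asarray(rate_fn(series.temps), dtype=float))
    return acc.invert(acc.at(start_day) + target)


def _build_accumulators(bundle: ModelBundle, series: TemperatureSeries):
    td = series.times_h / 24.0
    temps = series.temps
    dev, mort = {}, {}
    for s in IMMATURE_STAGES:
        r = np.asarray(janisch_rate(bundle.development[s], temps), dtype=float)
        m = np.clip(np.asarray(immature_mortality(bundle.mortality[s], temps),
                               dtype=float), 0.0, _M_CAP)
        dev[s] = _Accumulator(td, r)
        # survival log-integral: r * ln(1 - m); dividing by the individual's
        # development target makes dx sum to 1 over the stage
        mort[s] = _Accumulator(td, r * np.log1p(-m))
    sen = {
        sex: _Accumulator(td, 1.0 / np.asarray(
            adult_median_time(bundle.adult, temps, role), dtype=float))
        for sex, role in (("f", "female_survival"), ("m", "male_survival"))
    }
    ovi = _Accumulator(td, 1.0 / np.asarray(
        adult_median_time(bundle.adult, temps, "oviposition"), dtype=float))
    return td, dev, mort, sen, ovi


def simulate_cohort(bundle: ModelBundle, series: TemperatureSeries, n: int,
                    rng: np.random.Generator | int) -> CohortResult:
    """Simulate ``n`` individuals hatched at the start of the series.

    Returns per-individual life histories and the daily female survival /
    egg-count table from which the life-table schedule derives.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    td, dev, mort, sen_acc, ovi_acc = _build_accumulators(bundle, series)
    t_end = td[-1]
    temps = series.temps

    rows = []
    for i in range(n):
        sex = "f" if rng.uniform() < bundle.sex_ratio else "m"
        rec = {"id": i, "sex": sex, "stage_died": None, "death_day": math.inf,
               "adult_emergence": math.nan, "total_eggs": 0.0}
        t = 0.0
        alive = True
        censored = False
        for stage in IMMATURE_STAGES:
            u = rng.uniform()
            v = rng.uniform()
            x_target = link_quantile(bundle.dev_links[stage],
                                     min(max(u, 1e-12), 1.0 - 1e-12))
            t_complete = dev[stage].invert(dev[stage].at(t) + x_target)
            # death when cumulative stage mortality exceeds v:
            # (G(t') - G(t)) / x_target <= ln(1 - v)
            g_thresh = mort[stage].at(t) + x_target * math.log1p(-v)
            t_death = _invert_decreasing(mort[stage], g_thresh)
            if t_death < t_complete:
                rec["stage_died"] = stage
                rec["death_day"] = t_death
                rec[f"{stage}_exit"] = math.nan
                alive = False
                break
            if math.isinf(t_complete):
                censored = True
                rec[f"{stage}_exit"] = math.nan
                break
            rec[f"{stage}_exit"] = t_complete
            t = t_complete
        if alive and not censored:
            rec["adult_emergence"] = t
            u_sen = rng.uniform()
            u_ovi = rng.uniform()
            z_fec = rng.standard_normal()
            acc = sen_acc[sex]
            x_sen = link_quantile(bundle.senescence_link,
                                  min(max(u_sen, 1e-12), 1.0 - 1e-12))
            t_death = acc.invert(acc.at(t) + x_sen)
            t_death = min(t_death, t_end)  # censored at series end
            rec["death_day"] = t_death
            rec["stage_died"] = "adult"
            if sex == "f":
                rec["total_eggs"], rec["egg_days"], rec["egg_counts"] = _lay_eggs(
                    bundle, series, ovi_acc, t, t_death, u_ovi, z_fec, rng)
        elif censored:
            rec["death_day"] = math.inf
            rec["stage_died"] = "censored"
        rows.append(rec)

    individuals = pd.DataFrame(rows)
    counts = _daily_counts(individuals, t_end)
    n_females = int((individuals["sex"] == "f").sum())
    return CohortResult(individuals=individuals, counts=counts, n=n,
                        n_females=n_females, sex_ratio=bundle.sex_ratio)


def _invert_decreasing(acc: _Accumulator, threshold: float) -> float:
    """First time the (non-increasing) integral drops to ``threshold``."""
    if threshold < acc.cum[-1]:
        return math.inf
    return float(np.interp(-threshold, -acc.cum, acc.t))


def _lay_eggs(bundle, series, ovi_acc, t_emerge, t_death, u_ovi, z_fec, rng):
    """Distribute a female's lifetime fecundity over her daily ages."""
    td = series.times_h / 24.0
    # temperature experienced over the adult span sets the fecundity mean
    sel = (td >= t_emerge) & (td <= max(t_death, t_emerge + 1e-9))
    t_mean = float(np.mean(series.temps[sel])) if np.any(sel) else float(
        np.interp(t_emerge, td, series.temps))
    mu = mean_fecundity(bundle.fecundity, t_mean)
    if mu <= 0:
        return 0.0, [], []
    sigma = bundle.fecundity_sigma
    total = mu * math.exp(sigma * z_fec - 0.5 * sigma * sigma)
    # her oviposition period ends at her own drawn quantile of the link;
    # she lays her lifetime total across that period following the
    # normalized cumulative reproduction curve (truncated by death)
    x_window = link_quantile(bundle.oviposition_link,
                             min(max(u_ovi, 1e-12), 1.0 - 1e-12))
    c_window = link_cdf(bundle.oviposition_link, x_window)
    a0 = ovi_acc.at(t_emerge)
    ages, eggs = [], []
    laid_cum = 0.0
    day = 0
    while t_emerge + day < t_death:
        a_hi = ovi_acc.at(min(t_emerge + day + 1, t_death)) - a0
        frac = link_cdf(bundle.oviposition_link, min(a_hi, x_window)) / c_window
        n_eggs = total * frac - laid_cum
        if n_eggs > 1e-12:
            ages.append(t_emerge + day)
            eggs.append(n_eggs)
            laid_cum = total * frac
        if a_hi >= x_window:
            break
        day += 1
    return laid_cum, ages, eggs


def _daily_counts(individuals: pd.DataFrame, t_end: float) -> pd.DataFrame:
    females = individuals[individuals["sex"] == "f"]
    deaths = females["death_day"].to_numpy(dtype=float)
    finite = deaths[np.isfinite(deaths)]
    horizon = int(math.ceil(max(finite.max() if finite.size else 1.0, 1.0))) + 1
    ages = np.arange(horizon)
    alive = np.array([(deaths > a).sum() for a in ages], dtype=float)
    eggs = np.zeros(horizon)
    for _, row in females.iterrows():
        if isinstance(row.get("egg_days"), list):
            for a, e in zip(row["egg_days"], row["egg_counts"]):
                idx = int(a)
                if idx < horizon:
                    eggs[idx] += e
    return pd.DataFrame({"age": ages, "n_alive_f": alive, "eggs": eggs})


def simulate_replicates(bundle: ModelBundle, series: TemperatureSeries, n: int,
                        reps: int, seed: int) -> list[CohortResult]:
    """Independent replicate cohorts with reproducible per-replicate seeds."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=reps)
    return [simulate_cohort(bundle, series, n, int(s)) for s in seeds]


def pooled_schedule(results: list[CohortResult]) -> LifeTableSchedule:
    """Pool replicate cohorts into one schedule (count-weighted)."""
    if not results:
        raise ValueError("no replicates to pool")
    horizon = max(len(r.counts) for r in results)
    alive = np.zeros(horizon)
    eggs = np.zeros(horizon)
    n_f = 0
    for r in results:
        a = r.counts["n_alive_f"].to_numpy(dtype=float)
        e = r.counts["eggs"].to_numpy(dtype=float)
        alive[: len(a)] += a
        eggs[: len(e)] += e
        n_f += r.n_females
    counts = pd.DataFrame({"age": np.arange(horizon), "n_alive_f": alive, "eggs": eggs})
    return _schedule_from_counts(counts, n_f, results[0].sex_ratio)
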