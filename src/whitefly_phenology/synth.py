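"""Synthetic cohort observation tables with known ground truth.

Emulates the constant-temperature rearing design behind the life tables:
a fixed number of eggs per temperature observed once a day, so every event
time is interval-censored to consecutive daily checks; per-stage attrition
is binomial at the model mortality; emerging adults are sexed and females
produce daily egg counts.  Because every record derives from a known
parameter bundle, the tables support parameter-recovery testing of the
AFT, development, mortality and fecundity fitting routines.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .bundle import ModelBundle
from .distributions import IntervalObservation, link_quantile
from .simulate import IMMATURE_STAGES
from .thermal import (
    adult_median_time,
    immature_mortality,
    janisch_time,
    mean_fecundity,
)

__all__ = ["generate_synthetic_cohort", "observations_from_table"]

COLUMNS = ["individual", "stage", "group", "lower", "upper", "event", "sex"]


def generate_synthetic_cohort(
    bundle: ModelBundle,
    n: int,
    temperatures,
    rng: np.random.Generator | int,
    interval_days: float = 1.0,
    adult_follow_up_days: float = 60.0,
) -> pd.DataFrame:
    """Simulate daily-observation cohort tables at constant temperatures.

    Returns one row per (individual, stage) event with interval bounds in
    days since stage entry; deaths are recorded as ``event="death"`` with
    the day interval in which the individual was found dead; adults still
    alive after ``adult_follow_up_days`` are right-censored
    (``upper = inf``).  Female rows with ``event="fecundity"`` carry the
    lifetime egg count in ``lower`` (and ``upper``).
    """
    if n < 10:
        raise ValueError("need at least 10 individuals per temperature")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rows = []
    uid = 0
    for T in temperatures:
        T = float(T)
        for _ in range(n):
            uid += 1
            alive = True
            for stage in IMMATURE_STAGES:
                med = janisch_time(bundle.development[stage], T)
                m = immature_mortality(bundle.mortality[stage], T)
                u = rng.uniform()
                t = med * link_quantile(bundle.dev_links[stage],
                                        min(max(u, 1e-12), 1 - 1e-12))
                if rng.uniform() < m:
                    # death observed somewhere inside the stage
                    d = t * rng.uniform()
                    lo = math.floor(d / interval_days) * interval_days
                    rows.append([uid, stage, T, lo, lo + interval_days, "death", None])
                    alive = False
                    break
                lo = math.floor(t / interval_days) * interval_days
                rows.append([uid, stage, T, lo, lo + interval_days, "development", None])
            if not alive:
                continue
            sex = "f" if rng.uniform() < bundle.sex_ratio else "m"
            role = "female_survival" if sex == "f" else "male_survival"
            med = adult_median_time(bundle.adult, T, role)
            u = rng.uniform()
            t = med * link_quantile(bundle.senescence_link,
                                    min(max(u, 1e-12), 1 - 1e-12))
            if t >= adult_follow_up_days:
                rows.append([uid, "adult", T, adult_follow_up_days, math.inf,
                             "death", sex])
            else:
                lo = math.floor(t / interval_days) * interval_days
                rows.append([uid, "adult", T, lo, lo + interval_days, "death", sex])
            if sex == "f":
                mu = mean_fecundity(bundle.fecundity, T)
                sigma = bundle.fecundity_sigma
                eggs = mu * math.exp(sigma * rng.standard_normal()
                                     - 0.5 * sigma * sigma)
                rows.append([uid, "adult", T, eggs, eggs, "fecundity", sex])
    return pd.DataFrame(rows, columns=COLUMNS)


def observations_from_table(
    df: pd.DataFrame, stage: str, event: str = "development"
) -> list[IntervalObservation]:
    """Convert table rows for one stage/event into AFT observations."""
    sel = df[(df["stage"] == stage) & (df["event"] == event)]
    return [
        IntervalObservation(
            lower=float(r.lower), upper=float(r.upper), group=float(r.group),
            event=event, sex=(r.sex if isinstance(r.sex, str) else None))
        for r in sel.itertuples()
        if r.lower < r.upper
    ]
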