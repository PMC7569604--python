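"""Published constant-temperature life-table summaries for *T. vaporariorum*.

These are the observed inputs the calibration routines are exercised
against: median development times and immature mortalities per constant
rearing temperature (cohorts of 100 eggs each), adult median survival and
oviposition times, and mean lifetime fecundities.  Temperatures in degrees
C, times in days, mortalities as proportions, fecundities in eggs/female.
"""

from __future__ import annotations

#: median development time (days) by rearing temperature, per stage
EGG_MEDIAN_DEV_TIME = {10: 33.1, 15: 17.3, 18: 9.6, 20: 9.0, 25: 5.2, 28: 5.0, 32: 6.3}
NYMPH_MEDIAN_DEV_TIME = {15: 17.5, 18: 13.8, 20: 11.2, 25: 10.4, 28: 10.2}
PUPARIUM_MEDIAN_DEV_TIME = {15: 11.6, 18: 6.1, 20: 4.9, 25: 3.4, 28: 6.8}

#: stage mortality (proportion) by rearing temperature; all nymphs died at
#: 10 and 32 C, so no puparium estimates exist there
STAGE_MORTALITY = {
    "egg": {10: 0.87, 15: 0.0, 18: 0.0, 20: 0.0, 25: 0.0, 28: 0.0, 32: 0.24},
    "nymph": {10: 1.0, 15: 0.14, 18: 0.13, 20: 0.04, 25: 0.01, 28: 0.14, 32: 1.0},
    "puparium": {15: 0.24, 18: 0.13, 20: 0.05, 25: 0.10, 28: 0.30},
}

#: number of eggs starting each constant-temperature cohort
COHORT_SIZE = 100

#: adult medians (days) by temperature: female survival and oviposition time
FEMALE_MEDIAN_SURVIVAL = {15: 7.2, 18: 7.7, 20: 5.7, 25: 6.1, 28: 4.4}
MEDIAN_OVIPOSITION_TIME = {15: 8.4, 18: 6.8, 20: 5.9, 25: 7.0, 28: 4.0}

#: mean lifetime fecundity (eggs/female) by temperature
MEAN_FECUNDITY = {15: 10.3, 18: 36.4, 20: 40.1, 25: 26.9, 28: 19.2}

#: common AFT scale parameter delta per process (log-time scale)
AFT_SCALE = {
    "egg": 0.044,
    "nymph": 0.072,
    "puparium": 0.298,
    "adult_survival": 0.9271,
    "oviposition": 0.7741,
}

#: additive AFT sex factor on log survival time (males relative to females)
SEX_FACTOR_LOG_TIME = -0.288
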