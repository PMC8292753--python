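"""Reported design constants of the urban light-exposure study.

These are bookkeeping inputs (sample sizes, per-season day counts, the
published fit's summary statistics) used for arithmetic reproduction and
for parameterizing the synthetic cohort; they are not outputs of this
package's computations.
"""

#: Study site: upper Manhattan, New York City.
SITE_LATITUDE = 40.85
SITE_LONGITUDE = -73.93

#: Seasonal sampling sessions (weeks surrounding solstices/equinoxes) and
#: the local civil UTC offset in effect during each.
SEASON_DATES = {
    "summer": "2018-06-18",
    "autumn": "2018-09-19",
    "winter": "2018-12-18",
    "spring": "2019-03-18",
}
SEASON_UTC_OFFSET = {"summer": -4.0, "autumn": -4.0, "winter": -5.0, "spring": -4.0}

#: Observation days recorded before temperature QC, by season (total 367).
PRE_QC_DAYS = {"summer": 109, "autumn": 96, "winter": 90, "spring": 72}

#: Observation days surviving the 28% completeness filter (total 294).
KEPT_DAYS = {"summer": 92, "autumn": 77, "winter": 74, "spring": 51}

#: Participant-season rows entering the final regression (total 59).
MODEL_ROWS = {"summer": 17, "autumn": 15, "winter": 15, "spring": 12}

#: Participants wearing sensors in each season (23 recruited).
PARTICIPANTS = {"summer": 18, "autumn": 16, "winter": 15, "spring": 12}

#: Published summary of the selected phase-timing model.
PUBLISHED_FIT = {
    "n": 59,
    "n_predictors": 5,  # night + morning + 3 season indicators
    "r_squared": 0.2769,
    "adj_r_squared": 0.2087,
    "f_statistic": 4.06,
    "f_df": (5, 53),
    "residual_se": 1.686,
    "residual_df": 53,
    "beta_night": 0.0056,
    "beta_morning": -0.0042,
}
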