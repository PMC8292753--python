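"""Wrist-temperature QC, imputation, smoothing and phase extraction.

The processing order follows the temperature workflow exactly:
mask out-of-range readings -> drop incomplete days -> impute (PMM) ->
smooth (GCV spline) -> take the daily maximum timing as the circadian
phase readout, in decimal observation hours after 17.00.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import ImputationFailureError
from .smoothing import smooth_spline
from .types import ObservationDay, PhaseRecord

#: Normal biological range for wrist temperature, degrees C (inclusive).
TEMP_MIN_C = 29.5
TEMP_MAX_C = 38.5

#: Strict upper bound on the missing fraction for a day to be kept.
COMPLETENESS_THRESHOLD = 0.28

#: PMM donor pool size.
K_DONORS = 5


def mask_biological_range(day: ObservationDay) -> ObservationDay:
    """Replace readings outside [29.5, 38.5] degrees C with missing.

    The bounds themselves are kept: the masking rule is strictly
    "less than 29.5" / "greater than 38.5". Out-of-range readings are
    assumed to be device-removal artifacts.
    """
    v = day.values.copy()
    with np.errstate(invalid="ignore"):
        bad = (v < TEMP_MIN_C) | (v > TEMP_MAX_C)
    v[bad] = np.nan
    return replace(day, values=v)


def filter_days_by_completeness(days, threshold: float = COMPLETENESS_THRESHOLD):
    """Keep a day iff its missing fraction is strictly below ``threshold``.

    At 288 slots, 80 missing (27.78%) is kept and 81 (28.13%) is dropped.
    """
    return [d for d in days if d.n_missing() / d.n_slots < threshold]


def _flank_indices(obs_mask_row: np.ndarray):
    """Nearest observed slot strictly left/right of every slot, circular.

    Excluding the slot itself keeps the flanks informative for observed
    cells too, which form the regression's training rows.
    """
    n = len(obs_mask_row)
    idx = np.flatnonzero(obs_mask_row)
    pos = np.arange(n)
    li = np.searchsorted(idx, pos, side="left") - 1  # greatest idx < pos
    left = idx[li % len(idx)]
    ri = np.searchsorted(idx, pos, side="right")  # smallest idx > pos
    right = idx[ri % len(idx)]
    return left, right


def impute_pmm(matrix: np.ndarray, k_donors: int = K_DONORS, seed: int = 0) -> np.ndarray:
    """Predictive-mean-matching imputation of a days-by-slots matrix.

    For each slot column with missing cells, an OLS of the observed values
    on the day's nearest observed flanking readings (circular within the
    day) gives predicted means; each missing cell is filled with the
    observed value of a donor sampled uniformly from the ``k_donors`` rows
    of that column whose predicted means are closest. Observed values are
    never altered and the fill is reproducible under a fixed seed.

    Raises
    ------
    ImputationFailureError
        If some column has no observed value in any row.
    """
    X = np.asarray(matrix, dtype=float).copy()
    n_days, n_slots = X.shape
    obs = ~np.isnan(X)
    if obs.all():
        return X
    empty_cols = np.flatnonzero(~obs.any(axis=0))
    if empty_cols.size:
        raise ImputationFailureError(
            f"slot column(s) {empty_cols.tolist()} have no observed donors"
        )
    rng = np.random.default_rng(seed)

    # per-row circular flank values (from the original observed entries)
    flank_left = np.empty_like(X)
    flank_right = np.empty_like(X)
    for r in range(n_days):
        if not obs[r].any():
            raise ImputationFailureError(f"day row {r} is entirely missing")
        left, right = _flank_indices(obs[r])
        flank_left[r] = X[r, left]
        flank_right[r] = X[r, right]

    for j in range(n_slots):
        miss_rows = np.flatnonzero(~obs[:, j])
        if miss_rows.size == 0:
            continue
        obs_rows = np.flatnonzero(obs[:, j])
        A = np.column_stack(
            [np.ones(n_days), flank_left[:, j], flank_right[:, j]]
        )
        if obs_rows.size > 3:
            beta, *_ = np.linalg.lstsq(A[obs_rows], X[obs_rows, j], rcond=None)
            pred = A @ beta
        else:  # too few rows for a stable fit: match on the flank mean
            pred = 0.5 * (flank_left[:, j] + flank_right[:, j])
        for r in miss_rows:
            k = min(k_donors, obs_rows.size)
            order = np.argsort(np.abs(pred[obs_rows] - pred[r]), kind="stable")
            donors = obs_rows[order[:k]]
            X[r, j] = X[rng.choice(donors), j]
    return X


def impute_days(days, k_donors: int = K_DONORS, seed: int = 0):
    """Impute a list of masked, filtered days jointly (rows = days).

    Returns new ObservationDay objects with every slot filled, in order.
    """
    if not days:
        return []
    M = np.vstack([d.values for d in days])
    filled = impute_pmm(M, k_donors=k_donors, seed=seed)
    return [replace(d, values=filled[i]) for i, d in enumerate(days)]


def max_timing(day: ObservationDay, fitted: np.ndarray | None = None) -> PhaseRecord:
    """Daily maximum-temperature timing from a smoothed, complete day.

    If ``fitted`` is not supplied, the day is smoothed here. The arg-max
    slot converts to decimal observation hours (slot * cadence / 60); ties
    break to the earliest slot.
    """
    if fitted is None:
        fitted, _ = smooth_spline(day.slot_minutes, day.values)
    i = int(np.argmax(fitted))
    return PhaseRecord(
        source_id=day.source_id,
        season=day.season,
        day_index=day.day_index,
        max_timing_h=float(day.slot_minutes[i]) / 60.0,
        max_value_c=float(fitted[i]),
    )


def extract_phases(days, k_donors: int = K_DONORS, seed: int = 0):
    """Full temperature workflow on raw gridded days.

    mask -> completeness filter -> PMM impute (jointly) -> per-day GCV
    spline -> max timing. Returns (phase_records, attrition) where
    attrition counts days at each stage.
    """
    masked = [mask_biological_range(d) for d in days]
    n_masked_per_day = {id(m): m.n_missing() for m in masked}
    kept = filter_days_by_completeness(masked)
    filled = impute_days(kept, k_donors=k_donors, seed=seed)
    records = []
    for orig, day in zip(kept, filled):
        fitted, _ = smooth_spline(day.slot_minutes, day.values)
        rec = max_timing(day, fitted)
        rec.n_imputed = orig.n_missing()
        rec.n_masked = n_masked_per_day[id(orig)]
        records.append(rec)
    attrition = {"days_in": len(days), "days_kept": len(kept)}
    return records, attrition


def phases_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "season": r.season,
                "day_index": r.day_index,
                "max_timing_h": r.max_timing_h,
                "max_value_c": r.max_value_c,
                "n_imputed": r.n_imputed,
                "n_masked": r.n_masked,
            }
            for r in records
        ]
    )
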