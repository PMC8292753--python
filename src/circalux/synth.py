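"""Seeded synthetic cohort: outdoor illuminance, realized light cycles,
and circadian wrist temperature with a known light -> phase mechanism.

The generator emulates the study conditions: an urban mid-latitude site
where outdoor light tracks the solar day (with sub-10-lux light pollution
after sunset), participants keep roughly 09.00-17.00 indoor schedules with
electric light in the evening and occasional bright outdoor weekend days,
and wrist temperature follows a ~24 h cosine whose daily peak timing
responds linearly to that day's standardized night-time (21.00-02.00) and
morning (04.00-11.59) light AUC:

    phi_d = base + beta_night * AUC_night(d) + beta_morning * AUC_morning(d)
            + N(0, phase_noise_sd_h)

i.e. a pure phase-shift mechanism (rhythm-shape distortion is a plausible
alternative in real physiology and is deliberately not modelled).
High-frequency temperature variation is AR(1) noise; device-removal
artifacts appear as short out-of-range runs, plus occasional long removals
that push a day over the 28% missingness filter, emulating the study's
day attrition. Every series is reproducible from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import study
from .errors import AlignmentError
from .ingest import Manifest, ManifestEntry, to_observation_days
from .light import STD_MORNING, STD_NIGHT, auc_trapezoid, log_illuminance
from .solar import solar_times
from .types import DAY_ANCHOR_HOUR, SEASONS, ObservationDay, SensorSeries


@dataclass
class SynthParams:
    """Study-condition parameters for the synthetic cohort."""

    latitude: float = study.SITE_LATITUDE
    longitude: float = study.SITE_LONGITUDE
    seasons: tuple = SEASONS
    season_dates: dict = field(default_factory=lambda: dict(study.SEASON_DATES))
    utc_offsets: dict = field(default_factory=lambda: dict(study.SEASON_UTC_OFFSET))
    participants_per_season: dict = field(
        default_factory=lambda: dict(study.PARTICIPANTS)
    )
    days_per_season: int = 7
    outdoor_days: int = 9
    indoor_day_lux: tuple = (100.0, 500.0)   # typical office illuminance range
    lan_lux: tuple = (30.0, 1000.0)          # evening light-at-night range
    outdoor_weekend_prob: float = 0.6
    mesor_c: float = 33.5
    amplitude_c: float = 1.5
    base_acrophase_h: float = 8.0            # observation hours (01.00 clock)
    beta_night: float = 0.0056               # h per log10lux-minute
    beta_morning: float = -0.0042
    phase_noise_sd_h: float = 1.5
    noise_sd_c: float = 0.3
    ar_rho: float = 0.7
    artifact_rate: float = 0.25              # short device-removal runs/day
    artifact_minutes: tuple = (30.0, 120.0)
    removal_rate: float = 0.2                # long removals (drop the day)
    removal_minutes: tuple = (420.0, 960.0)
    seed: int = 0


def _rng(params: SynthParams, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) % (2**31), *tags])


def _season_idx(params: SynthParams, season: str) -> int:
    return list(params.seasons).index(season)


def _season_start(params: SynthParams, season: str) -> pd.Timestamp:
    return pd.Timestamp(params.season_dates[season]) + pd.Timedelta(
        hours=DAY_ANCHOR_HOUR
    )


def _solar_cache(params: SynthParams, season: str, dates) -> dict:
    off = params.utc_offsets[season]
    return {
        d: solar_times(d, params.latitude, params.longitude, off)
        for d in pd.DatetimeIndex(dates).normalize().unique()
    }


def _daylight_log10lux(ts: pd.DatetimeIndex, sol_by_date: dict,
                       peak_log10, jitter: np.ndarray) -> np.ndarray:
    """Solar-elevation-driven log10lux during daylight, 0 (sub-LOD) at night."""
    out = np.zeros(len(ts))
    clock = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    dates = ts.normalize()
    for d, sol in sol_by_date.items():
        sel = dates == d
        cl = clock[sel]
        up = (cl > sol.sunrise_hours) & (cl < sol.sunset_hours)
        s = np.sin(
            np.pi
            * (cl[up] - sol.sunrise_hours)
            / (sol.sunset_hours - sol.sunrise_hours)
        )
        day_peak = peak_log10[sel][up] if np.ndim(peak_log10) else peak_log10
        vals = np.zeros(sel.sum())
        vals[up] = day_peak * s**0.6
        out[sel] = vals
    return np.clip(out + jitter, 0.0, None)


def gen_outdoor_lux(params: SynthParams, season: str, site: str = "lit") -> SensorSeries:
    """Outdoor illuminance series, 3-min cadence, ``outdoor_days`` days.

    ``site`` is "lit" (full sun) or "shaded"; daytime peaks land in the
    10^3-10^5 lux band, and everything after sunset reads below the 10-lux
    detection limit (urban light pollution).
    """
    rng = _rng(params, 1, _season_idx(params, season), 0 if site == "lit" else 1)
    start = _season_start(params, season)
    n = int(params.outdoor_days * 1440 / 3)
    ts = start + pd.to_timedelta(np.arange(n) * 3, unit="min")
    sol = _solar_cache(params, season, ts)

    lo, hi = (4.3, 5.0) if site == "lit" else (3.2, 4.0)
    day_ids = ((ts - start).days).to_numpy()
    peaks_by_day = rng.uniform(lo, hi, size=day_ids.max() + 1)
    clouds_by_day = rng.uniform(0.85, 1.0, size=day_ids.max() + 1)
    peak = peaks_by_day[day_ids] * clouds_by_day[day_ids]
    jitter = rng.normal(0.0, 0.05, size=n)

    log10lux = _daylight_log10lux(ts, sol, peak, jitter)
    lux = np.where(log10lux > 1.0, 10.0**log10lux, 0.0)
    # below-LOD light pollution after sunset and at dawn/dusk shoulders
    dark = lux < 10.0
    lux[dark] = rng.uniform(0.0, 9.0, size=int(dark.sum()))
    return SensorSeries(
        source_id=f"out_{site}", kind="lux",
        timestamps=pd.DatetimeIndex(ts), values=np.round(lux, 1), cadence_min=3.0,
    )


def gen_individual_rlc(params: SynthParams, participant: int, season: str) -> SensorSeries:
    """One participant-season realized light cycle, 5-min cadence, 7 days.

    Weekdays: dim mornings, an indoor plateau 09.00-17.00, evening
    light-at-night until a sampled bedtime, darkness after. The final two
    days of the week are weekend days, each replaced by an outdoor-like
    bright day with probability ``outdoor_weekend_prob``.
    """
    trait = _rng(params, 11, participant)
    indoor = np.exp(trait.uniform(*np.log(params.indoor_day_lux)))
    lan = np.exp(trait.uniform(*np.log(np.clip(params.lan_lux, 1e-3, None))))
    bed_mean = trait.uniform(22.5, 25.0)   # clock hours, >24 = past midnight
    wake_mean = trait.uniform(6.5, 8.0)

    rng = _rng(params, 12, participant, _season_idx(params, season))
    start = _season_start(params, season)
    n_days = params.days_per_season
    n = n_days * 288
    ts = start + pd.to_timedelta(np.arange(n) * 5, unit="min")
    sol = _solar_cache(params, season, ts)

    clock = (ts.hour + ts.minute / 60.0).to_numpy()
    day_ids = ((ts - start).days).to_numpy()
    lux = np.zeros(n)

    outdoor_day = np.zeros(n_days, dtype=bool)
    for d in range(n_days):
        if d >= n_days - 2:  # weekend
            outdoor_day[d] = rng.random() < params.outdoor_weekend_prob
    bed = bed_mean + rng.normal(0.0, 0.5, size=n_days)
    wake = wake_mean + rng.normal(0.0, 0.3, size=n_days)
    out_peak = rng.uniform(3.2, 5.0, size=n_days)

    # wrap clock so each observation day owns one continuous night
    for d in range(n_days):
        sel = day_ids == d
        cl = clock[sel]
        m = int(sel.sum())
        v = rng.uniform(0.0, 3.0, size=m)  # darkness baseline
        bed_c = bed[d] % 24.0
        if bed[d] >= 24.0:  # bedtime past midnight
            asleep = (cl >= bed_c) & (cl < wake[d])
        else:
            asleep = (cl >= bed_c) | (cl < wake[d])
        awake = ~asleep
        morning_dim = awake & (cl >= wake[d]) & (cl < 9.0)
        v[morning_dim] = rng.uniform(0.0, 9.0, size=int(morning_dim.sum()))
        office = awake & (cl >= 9.0) & (cl < 17.0)
        v[office] = np.clip(
            indoor * np.exp(rng.normal(0.0, 0.2, size=int(office.sum()))), 0.0, 950.0
        )
        evening = awake & ((cl >= 17.0) | (cl < 4.0))
        v[evening] = lan * np.exp(rng.normal(0.0, 0.2, size=int(evening.sum())))
        if outdoor_day[d]:
            tsel = ts[sel]
            jit = rng.normal(0.0, 0.05, size=m)
            sol_d = {dd: sol[dd] for dd in tsel.normalize().unique()}
            dlog = _daylight_log10lux(tsel, sol_d, out_peak[d], jit)
            daylight = dlog > 1.0
            v[daylight & awake] = 10.0 ** dlog[daylight & awake]
        lux[sel] = v
    return SensorSeries(
        source_id=f"p{participant + 1:02d}", kind="lux",
        timestamps=pd.DatetimeIndex(ts), values=np.round(lux, 1), cadence_min=5.0,
    )


def _exposure_inputs(rlc: SensorSeries, season: str, params: SynthParams):
    """Per-observation-day standardized night/morning AUC of the log series."""
    days = to_observation_days(rlc, season=season)
    out = []
    for d in days:
        logday = replace(d, values=log_illuminance(d.values))
        out.append(
            (
                d.day_index,
                auc_trapezoid(logday, STD_NIGHT),
                auc_trapezoid(logday, STD_MORNING),
            )
        )
    return out


def gen_wrist_temp(rlc: SensorSeries, params: SynthParams, participant: int = 0,
                   season: str = "summer"):
    """Wrist-temperature series aligned to a realized light cycle.

    Returns ``(series, truth)`` where ``truth`` is a per-day DataFrame of
    the realized acrophase and the light AUCs that produced it.
    """
    if rlc.cadence_min != 5.0:
        raise AlignmentError("wrist temperature requires a 5-min gridded RLC")
    rng = _rng(params, 21, participant, _season_idx(params, season))
    exposures = _exposure_inputs(rlc, season, params)
    n_days = len(exposures)
    n = n_days * 288
    start = rlc.timestamps[0]
    ts = start + pd.to_timedelta(np.arange(n) * 5, unit="min")

    truth_rows = []
    temp = np.empty(n)
    t_obs_h = (np.arange(288) * 5) / 60.0
    for d, auc_n, auc_m in exposures:
        phi = (
            params.base_acrophase_h
            + params.beta_night * (auc_n if np.isfinite(auc_n) else 0.0)
            + params.beta_morning * (auc_m if np.isfinite(auc_m) else 0.0)
            + rng.normal(0.0, params.phase_noise_sd_h)
        )
        temp[d * 288:(d + 1) * 288] = params.mesor_c + params.amplitude_c * np.cos(
            2.0 * np.pi * (t_obs_h - phi) / 24.0
        )
        truth_rows.append(
            {
                "source_id": rlc.source_id,
                "season": season,
                "day_index": d,
                "acrophase_true_h": phi,
                "auc_night": auc_n,
                "auc_morning": auc_m,
            }
        )

    if params.noise_sd_c > 0:
        innov = rng.normal(
            0.0, params.noise_sd_c * np.sqrt(1.0 - params.ar_rho**2), size=n
        )
        innov[0] = rng.normal(0.0, params.noise_sd_c)
        temp += lfilter([1.0], [1.0, -params.ar_rho], innov)

    # device-removal artifacts: out-of-range runs the QC stage masks
    for d in range(n_days):
        lo = d * 288
        if rng.random() < params.artifact_rate:
            dur = int(rng.uniform(*params.artifact_minutes) / 5.0)
            s0 = lo + int(rng.integers(0, 288 - dur))
            temp[s0:s0 + dur] = rng.uniform(20.0, 29.0, size=dur)
        if rng.random() < params.removal_rate:
            dur = min(int(rng.uniform(*params.removal_minutes) / 5.0), 287)
            s0 = lo + int(rng.integers(0, 288 - dur))
            temp[s0:s0 + dur] = rng.uniform(20.0, 29.0, size=dur)

    series = SensorSeries(
        source_id=rlc.source_id, kind="temperature",
        timestamps=pd.DatetimeIndex(ts), values=np.round(temp, 3), cadence_min=5.0,
    )
    return series, pd.DataFrame(truth_rows)


def _write_series(series: SensorSeries, path: Path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "value": series.values,
        }
    )
    df.to_csv(path, index=False)


def gen_cohort(params: SynthParams, outdir) -> Path:
    """Write the full synthetic cohort file tree and return the manifest path.

    Layout: ``outdoor/<season>_<site>.csv``, ``participants/<id>_<season>_
    {lux,temp}.csv``, ``manifest.yaml``, and the mechanism-transparency
    sidecar ``truth.csv`` with each day's realized acrophase and AUCs.
    Deterministic (byte-identical) under a fixed seed.
    """
    outdir = Path(outdir)
    (outdir / "outdoor").mkdir(parents=True, exist_ok=True)
    (outdir / "participants").mkdir(parents=True, exist_ok=True)
    entries = []
    truths = []

    for season in params.seasons:
        off = params.utc_offsets[season]
        for site in ("lit", "shaded"):
            s = gen_outdoor_lux(params, season, site)
            rel = f"outdoor/{season}_{site}.csv"
            _write_series(s, outdir / rel)
            entries.append(
                ManifestEntry(
                    path=rel, source_id=s.source_id, kind="lux", season=season,
                    role="outdoor", latitude=params.latitude,
                    longitude=params.longitude, utc_offset_hours=off,
                    start_date=params.season_dates[season],
                )
            )
        for p in range(params.participants_per_season[season]):
            rlc = gen_individual_rlc(params, p, season)
            temp, truth = gen_wrist_temp(rlc, params, p, season)
            truths.append(truth)
            for s, kind, tag in ((rlc, "lux", "lux"), (temp, "temperature", "temp")):
                rel = f"participants/{s.source_id}_{season}_{tag}.csv"
                _write_series(s, outdir / rel)
                entries.append(
                    ManifestEntry(
                        path=rel, source_id=s.source_id, kind=kind, season=season,
                        role="individual", latitude=params.latitude,
                        longitude=params.longitude, utc_offset_hours=off,
                        start_date=params.season_dates[season],
                    )
                )

    truth = pd.concat(truths, ignore_index=True)
    truth["beta_night"] = params.beta_night
    truth["beta_morning"] = params.beta_morning
    truth.to_csv(outdir / "truth.csv", index=False)
    manifest = Manifest(entries)
    mpath = outdir / "manifest.yaml"
    manifest.save(mpath)
    return mpath
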