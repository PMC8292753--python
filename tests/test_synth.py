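"""Synthetic cohort generator: construction guarantees and determinism."""
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd
import pytest

from circalux.errors import AlignmentError
from circalux.ingest import Manifest, read_sensor_csv, to_observation_days
from circalux.light import WINDOWS_BY_NAME, auc_trapezoid, log_illuminance
from circalux.solar import solar_times
from circalux.synth import (
    SynthParams, gen_cohort, gen_individual_rlc, gen_outdoor_lux, gen_wrist_temp,
)
from circalux.temperature import (
    extract_phases, filter_days_by_completeness, mask_biological_range,
)

SMALL = dict(participants_per_season={s: 2 for s in ("summer", "autumn", "winter", "spring")})


class TestOutdoor:
    def test_night_slots_below_lod(self):
        p = SynthParams(seed=4)
        for season in ("summer", "winter"):
            s = gen_outdoor_lux(p, season, "lit")
            sol_by_date = {}
            clock = (s.timestamps.hour + s.timestamps.minute / 60.0).to_numpy()
            dates = s.timestamps.normalize()
            night = np.zeros(len(s), dtype=bool)
            for d in dates.unique():
                sol = solar_times(d, p.latitude, p.longitude, p.utc_offsets[season])
                sel = np.asarray(dates == d)
                night |= sel & ((clock < sol.sunrise_hours) | (clock > sol.sunset_hours))
            assert (s.values[night] < 10.0).all()

    def test_daytime_peaks_in_band(self):
        p = SynthParams(seed=4)
        s = gen_outdoor_lux(p, "summer", "lit")
        assert 1e3 <= s.values.max() <= 1e5 * 1.5

    def test_seasonal_auc_ordering(self):
        p = SynthParams(seed=6)
        means = {}
        for season in ("summer", "autumn", "winter", "spring"):
            s = gen_outdoor_lux(p, season, "lit")
            days = to_observation_days(s, season=season, target_cadence_min=5.0)
            aucs = [
                auc_trapezoid(
                    dc_replace(d, values=log_illuminance(d.values)),
                    WINDOWS_BY_NAME["total_day"],
                )
                for d in days
                if not d.partial
            ]
            means[season] = np.nanmean(aucs)
        assert means["summer"] > means["autumn"] > means["winter"]
        assert means["summer"] > means["spring"] > means["winter"]

    def test_same_seed_identical(self):
        a = gen_outdoor_lux(SynthParams(seed=9), "spring", "shaded")
        b = gen_outdoor_lux(SynthParams(seed=9), "spring", "shaded")
        np.testing.assert_array_equal(a.values, b.values)


class TestIndividualRlc:
    def test_weekday_capped_weekend_outdoor_brighter(self):
        p = SynthParams(seed=7, outdoor_weekend_prob=1.0)
        s = gen_individual_rlc(p, 0, "summer")
        days = np.array([(ts - s.timestamps[0]).days for ts in s.timestamps])
        weekday_max = s.values[days < 5].max()
        weekend_max = s.values[days >= 5].max()
        assert weekday_max <= 1e3
        assert weekend_max > 1e3

    def test_lan_drives_night_exposure(self):
        p = SynthParams(seed=8, outdoor_weekend_prob=0.0)
        sol = solar_times("2018-06-18", p.latitude, p.longitude, -4)
        s = gen_individual_rlc(p, 1, "summer")
        days = to_observation_days(s, season="summer")
        aucs = [
            auc_trapezoid(
                dc_replace(d, values=log_illuminance(d.values)),
                WINDOWS_BY_NAME["night_sunset_0400"], sol,
            )
            for d in days
        ]
        assert np.nanmean(aucs) > 0.0

        dark = SynthParams(seed=8, lan_lux=(1.0, 5.0), outdoor_weekend_prob=0.0)
        s2 = gen_individual_rlc(dark, 1, "summer")
        days2 = to_observation_days(s2, season="summer")
        aucs2 = [
            auc_trapezoid(
                dc_replace(d, values=log_illuminance(d.values)),
                WINDOWS_BY_NAME["night_sunset_0400"], sol,
            )
            for d in days2
        ]
        assert np.nanmean(aucs2) == pytest.approx(0.0)

    def test_same_seed_identical(self):
        a = gen_individual_rlc(SynthParams(seed=10), 2, "autumn")
        b = gen_individual_rlc(SynthParams(seed=10), 2, "autumn")
        np.testing.assert_array_equal(a.values, b.values)


class TestWristTemp:
    def _quiet(self, **kw):
        return SynthParams(
            seed=13, noise_sd_c=0.0, phase_noise_sd_h=0.0,
            artifact_rate=0.0, removal_rate=0.0, **kw,
        )

    def test_zero_betas_peak_at_base_acrophase(self):
        p = self._quiet(beta_night=0.0, beta_morning=0.0)
        rlc = gen_individual_rlc(p, 0, "winter")
        temp, truth = gen_wrist_temp(rlc, p, 0, "winter")
        days = to_observation_days(temp, season="winter")
        for d in days:
            peak_h = d.slot_minutes[np.argmax(d.values)] / 60.0
            assert peak_h == pytest.approx(p.base_acrophase_h, abs=5 / 60 + 1e-9)
        assert (truth["acrophase_true_h"] == p.base_acrophase_h).all()

    def test_night_exposure_delays_peak_by_beta_times_auc(self):
        p = self._quiet(beta_night=0.0056, beta_morning=0.0)
        rlc = gen_individual_rlc(p, 3, "winter")
        temp, truth = gen_wrist_temp(rlc, p, 3, "winter")
        for _, row in truth.iterrows():
            assert row["acrophase_true_h"] == pytest.approx(
                p.base_acrophase_h + 0.0056 * row["auc_night"], abs=1e-9
            )

    def test_misaligned_cadence_rejected(self):
        p = self._quiet()
        out = gen_outdoor_lux(p, "summer", "lit")  # 3-min cadence
        with pytest.raises(AlignmentError):
            gen_wrist_temp(out, p)

    def test_artifacts_drive_day_attrition(self):
        base = SynthParams(seed=5, artifact_rate=0.0, removal_rate=0.0)
        rlc = gen_individual_rlc(base, 0, "summer")
        temp, _ = gen_wrist_temp(rlc, base, 0, "summer")
        days = [mask_biological_range(d) for d in to_observation_days(temp, season="summer")]
        assert len(filter_days_by_completeness(days)) == len(days)

        heavy = SynthParams(
            seed=5, artifact_rate=0.9, artifact_minutes=(300.0, 700.0), removal_rate=0.0
        )
        temp2, _ = gen_wrist_temp(rlc, heavy, 0, "summer")
        days2 = [mask_biological_range(d) for d in to_observation_days(temp2, season="summer")]
        assert len(filter_days_by_completeness(days2)) < len(days2)


class TestCohortTree:
    def test_files_parse_and_truth_sidecar_aligns(self, tmp_path):
        p = SynthParams(seed=2, **SMALL)
        mpath = gen_cohort(p, tmp_path / "cohort")
        manifest = Manifest.load(mpath)
        # 4 seasons x (2 outdoor + 2 participants x 2 kinds)
        assert len(manifest.entries) == 4 * (2 + 2 * 2)
        for e in manifest.entries:
            s = read_sensor_csv(e.path, kind=e.kind, source_id=e.source_id)
            assert len(s) > 0
        truth = pd.read_csv(tmp_path / "cohort" / "truth.csv")
        assert set(truth["season"]) == {"summer", "autumn", "winter", "spring"}
        assert len(truth) == 4 * 2 * p.days_per_season

    def test_byte_identical_under_seed(self, tmp_path):
        p = SynthParams(seed=3, **SMALL)
        gen_cohort(p, tmp_path / "a")
        gen_cohort(p, tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*.csv")):
            g = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == g.read_bytes(), f.name

    def test_zero_artifact_rate_means_no_masking(self, tmp_path):
        p = SynthParams(seed=1, artifact_rate=0.0, removal_rate=0.0, **SMALL)
        mpath = gen_cohort(p, tmp_path / "c")
        manifest = Manifest.load(mpath)
        for e in manifest.entries:
            if e.kind != "temperature":
                continue
            s = read_sensor_csv(e.path, kind=e.kind)
            days = to_observation_days(s, season=e.season)
            for d in days:
                masked = mask_biological_range(d)
                assert masked.n_missing() == 0
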