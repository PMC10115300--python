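"""Simulator checks: schedule, environment, events, rendering, annotations."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from harborsound import acoustics as ac
from harborsound import scene_sim as ss

from conftest import single_producer_truth

T0 = dt.datetime(2019, 3, 15)


def make_config(hours=1.0, n_stations=1, gaps=(), **kw):
    import dataclasses
    base = ss.default_scene_config(start=T0, days=1, n_stations=n_stations,
                                   rng_seed=1)
    return dataclasses.replace(base, end_time=T0 + dt.timedelta(hours=hours),
                               service_gaps=tuple(gaps), **kw)


class TestSchedule:
    def test_one_hour_three_files(self):
        cfg = make_config(hours=1.0)
        assert len(ss.build_schedule(cfg)) == 3

    def test_empty_range_errors(self):
        with pytest.raises(ValueError):
            ss.build_schedule(make_config(hours=0.0))

    def test_gap_exclusion_matches_enumeration(self):
        gap = (T0 + dt.timedelta(hours=6), T0 + dt.timedelta(hours=10))
        cfg = make_config(hours=24.0, n_stations=2, gaps=[gap])
        assert len(ss.build_schedule(cfg)) == 2 * (72 - 12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 71), st.integers(1, 20)),
                    max_size=3))
    def test_schedule_equals_bruteforce_for_arbitrary_gaps(self, raw_gaps):
        gaps = [(T0 + dt.timedelta(minutes=20 * a),
                 T0 + dt.timedelta(minutes=20 * (a + w)))
                for a, w in raw_gaps]
        cfg = make_config(hours=24.0, gaps=gaps)
        got = len(ss.build_schedule(cfg))
        slots = [T0 + dt.timedelta(minutes=20 * k) for k in range(72)]
        want = sum(not any(g0 <= t < g1 for g0, g1 in gaps) for t in slots)
        assert got == want

    def test_same_seed_same_schedule(self):
        a = ss.build_schedule(make_config(hours=24.0))
        b = ss.build_schedule(make_config(hours=24.0))
        assert a == b


class TestEnvironment:
    def test_tidal_range(self, small_scene):
        env = small_scene.env
        assert env["depth_m"].max() - env["depth_m"].min() == pytest.approx(
            1.8, abs=0.01)

    def test_high_tide_spacing_semidiurnal(self, small_scene):
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(small_scene.env["depth_m"].to_numpy())
        times = small_scene.env.index[peaks]
        spacings = np.diff(times).astype("timedelta64[s]").astype(float) / 3600
        assert np.all(np.abs(spacings - 12.42) <= 20 / 60 + 1e-9)

    def test_winter_minimum_at_annual_phase_zero(self):
        cfg = ss.default_scene_config(start=dt.datetime(2019, 1, 13), days=4,
                                      rng_seed=1)
        env = ss.simulate_environment(cfg)
        at_min = env.loc[dt.datetime(2019, 1, 15), "water_temp_c"]
        assert at_min == pytest.approx(cfg.temp_min_c, abs=1e-6)

    def test_invalid_range_errors(self):
        with pytest.raises(ValueError):
            ss.simulate_environment(make_config(hours=0.0))


class TestEvents:
    def test_out_of_season_producer_silent(self, small_scene):
        # July files get zero events from a March-April producer.
        cfg = ss.default_scene_config(start=dt.datetime(2018, 7, 1), days=2,
                                      rng_seed=3)
        env = ss.simulate_environment(cfg)
        truth = ss.simulate_events(ss.build_schedule(cfg), env, cfg)
        assert truth.files["count_black_drum"].sum() == 0

    def test_poisson_thinning_ratio(self):
        probe = ss.ProducerSpec("probe", "fish", 200.0, 300.0, base_rate=5.0,
                                level_db=130.0, event_duration_s=0.5,
                                noise_response=0.2)
        cfg = ss.default_scene_config(
            start=T0, days=28, n_stations=2, rng_seed=5,
            producers=(probe,),
            vessel=ss.VesselSpec(day_rate=0.5, night_rate=0.5,
                                 weekend_multiplier=1.0))
        truth = ss.simulate_events(ss.build_schedule(cfg),
                                   ss.simulate_environment(cfg), cfg)
        f = truth.files
        noisy = f.loc[f.vessel_present == 1, "count_probe"].mean()
        quiet = f.loc[f.vessel_present == 0, "count_probe"].mean()
        assert noisy / quiet == pytest.approx(0.2, rel=0.10)

    def test_determinism_bit_for_bit(self, small_scene):
        cfg = small_scene.cfg
        env = ss.simulate_environment(cfg)
        again = ss.simulate_events(ss.build_schedule(cfg), env, cfg)
        pd.testing.assert_frame_equal(small_scene.truth.files, again.files)

    def test_env_gap_names_file(self, small_scene):
        short_env = small_scene.env.iloc[: len(small_scene.env) // 2]
        with pytest.raises(ValueError, match="does not cover file"):
            ss.simulate_events(small_scene.schedule, short_env,
                               small_scene.cfg)


class TestRendering:
    def test_zero_events_matches_ambient_floor(self, small_scene, quiet_truth,
                                               cal):
        rec = small_scene.schedule[0]
        w = ss.render_waveform(rec, quiet_truth, cal)
        for band in small_scene.cfg.bands:
            spl = ac.band_spl(w, small_scene.cfg.sample_rate_hz, band,
                              cal).spl_db
            assert spl == pytest.approx(small_scene.cfg.ambient_floor_db,
                                        abs=1.0)

    def test_low_band_chorus_out_of_band_rejection(self, small_scene, cal):
        truth, rec = single_producer_truth(small_scene, "spotted_seatrout", 20)
        w = ss.render_waveform(rec, truth, cal)
        low, high = small_scene.cfg.bands
        fs = small_scene.cfg.sample_rate_hz
        low_spl = ac.band_spl(w, fs, low, cal).spl_db
        high_spl = ac.band_spl(w, fs, high, cal).spl_db
        assert low_spl - high_spl >= 20

    def test_single_snap_closed_form_level(self, small_scene, cal):
        cfg = ss.SceneConfig(**{**small_scene.cfg.__dict__,
                                "level_sigma_db": 0.0})
        scene = type(small_scene)(cfg=cfg, schedule=small_scene.schedule,
                                  env=small_scene.env,
                                  truth=ss.GroundTruth(
                                      cfg, small_scene.truth.files.copy()))
        truth, rec = single_producer_truth(scene, "snapping_shrimp", 1)
        shrimp = cfg.producer("snapping_shrimp")
        high = cfg.bands[1]
        overlap = (min(shrimp.band_hi_hz, high.f_hi_hz)
                   - max(shrimp.band_lo_hz, high.f_lo_hz)) / (
            shrimp.band_hi_hz - shrimp.band_lo_hz)
        event_power = (10 ** (shrimp.level_db / 10)
                       * shrimp.event_duration_s / cfg.duty_on_s * overlap)
        ambient_power = 10 ** (cfg.ambient_floor_db / 10)
        closed_form = 10 * np.log10(event_power + ambient_power)
        w = ss.render_waveform(rec, truth, cal)
        measured = ac.band_spl(w, cfg.sample_rate_hz, high, cal).spl_db
        assert measured == pytest.approx(closed_form, abs=1.5)

    def test_band_faithful_rendering(self, small_scene, cal):
        # >=90% of above-floor energy inside the declared band.
        cfg = ss.SceneConfig(**{**small_scene.cfg.__dict__,
                                "ambient_floor_db": 40.0})
        scene = type(small_scene)(cfg=cfg, schedule=small_scene.schedule,
                                  env=small_scene.env,
                                  truth=ss.GroundTruth(
                                      cfg, small_scene.truth.files.copy()))
        truth, rec = single_producer_truth(scene, "silver_perch", 10)
        w = ss.render_waveform(rec, truth, cal)
        pressure = ac.counts_to_pressure(w, cal)
        fs = cfg.sample_rate_hz
        total = ac.band_power(pressure, fs, ac.Band("all", 1.0, fs / 2))
        perch = cfg.producer("silver_perch")
        inband = ac.band_power(pressure, fs, ac.Band(
            "sp", perch.band_lo_hz, perch.band_hi_hz))
        assert inband / total >= 0.90

    def test_rendered_matches_analytic_spl(self, small_scene, cal):
        # The fast SPL path agrees with a rendered file in the event band.
        spl = ss.spl_table_from_truth(small_scene.truth)
        rec = small_scene.schedule[40]
        w = ss.render_waveform(rec, small_scene.truth, cal)
        high = small_scene.cfg.bands[1]
        rendered = ac.band_spl(w, small_scene.cfg.sample_rate_hz, high,
                               cal).spl_db
        analytic = spl.loc[(spl.file_id == rec.file_id)
                           & (spl.band == high.label), "spl_db"].iloc[0]
        assert rendered == pytest.approx(analytic, abs=2.0)

    def test_render_determinism(self, small_scene, cal):
        rec = small_scene.schedule[5]
        a = ss.render_waveform(rec, small_scene.truth, cal)
        b = ss.render_waveform(rec, small_scene.truth, cal)
        assert np.array_equal(a, b)

    def test_band_above_nyquist_refused(self, small_scene, cal):
        # A file recorded at a lower rate than the producer bands require.
        rec = small_scene.schedule[0]
        slow = ss.FileRecord(rec.file_id, rec.station, rec.start,
                             rec.duration_s, 4000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ss.render_waveform(slow, small_scene.truth, cal)


class TestAnnotationExport:
    def test_score_mapping(self):
        counts = np.array([0, 1, 2, 4, 5, 12])
        assert list(ss.intensity_score(counts)) == [0, 1, 2, 2, 3, 3]

    def test_single_call_scores_one(self, small_scene):
        truth, rec = single_producer_truth(small_scene, "spotted_seatrout", 1)
        annot = ss.export_truth_annotations(truth)
        row = annot.loc[annot.file_id == rec.file_id].iloc[0]
        assert row["spotted_seatrout"] == 1

    def test_zero_event_file_all_zero(self, quiet_truth):
        annot = ss.export_truth_annotations(quiet_truth)
        cols = [*ss.FISH_SPECIES, "dolphin_sum", "noise", "rain",
                "right_whale"]
        assert (annot[cols].to_numpy() == 0).all()

    def test_dolphin_counts_additive(self, small_scene):
        annot = ss.export_truth_annotations(small_scene.truth)
        assert (annot["dolphin_sum"] == annot["dolphin_echolocation"]
                + annot["dolphin_whistles"] + annot["dolphin_burst"]).all()
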