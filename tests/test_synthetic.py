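import numpy as np
import pandas as pd
import pytest

from cgmactivity.synthetic import (
    ConfigError,
    SimConfig,
    generate_cohort,
    generate_subject,
    write_ohio_xml,
)

from conftest import NOISE_FREE


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"weight_range": (90.0, 60.0)}, "weight_range"),
            ({"unreported_fraction": 1.5}, "unreported_fraction"),
            ({"cgm_interval": 7}, "cgm_interval"),
            ({"glycemic_lag": 0.0}, "glycemic_lag"),
            ({"exercise_intensity": (0, 8)}, "exercise_intensity"),
            ({"cgm_noise_sd": -1.0}, "cgm_noise_sd"),
        ],
    )
    def test_invalid_field_named_in_error(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs).validate()

    def test_subject_index_out_of_range(self):
        with pytest.raises(ConfigError, match="subject_index"):
            generate_subject(SimConfig(n_subjects=2), 2)


class TestDeterminism:
    def test_same_seed_same_subject_is_identical(self):
        cfg = SimConfig(n_subjects=2, days_per_subject=2, seed=5)
        a = generate_subject(cfg, 1)
        b = generate_subject(cfg, 1)
        pd.testing.assert_frame_equal(a.series.data, b.series.data)
        pd.testing.assert_frame_equal(a.highrate, b.highrate)
        assert a.truth.episodes == b.truth.episodes
        assert a.series.weight == b.series.weight

    def test_ohio_archive_is_byte_identical(self, tmp_path):
        cfg = SimConfig(n_subjects=1, days_per_subject=2, seed=3)
        for name in ("a.xml", "b.xml"):
            write_ohio_xml(
                generate_subject(cfg, 0, include_highrate=False), tmp_path / name
            )
        assert (tmp_path / "a.xml").read_bytes() == (tmp_path / "b.xml").read_bytes()

    def test_noise_substream_does_not_perturb_episodes(self):
        base = SimConfig(n_subjects=1, days_per_subject=5, seed=9)
        noisier = SimConfig(n_subjects=1, days_per_subject=5, seed=9, cgm_noise_sd=25.0)
        a = generate_subject(base, 0, include_highrate=False)
        b = generate_subject(noisier, 0, include_highrate=False)
        assert a.truth.episodes == b.truth.episodes
        assert a.series.weight == b.series.weight
        # HR consumes its own stream, so it is untouched as well
        np.testing.assert_array_equal(
            a.series.data["hr_bpm"].to_numpy(), b.series.data["hr_bpm"].to_numpy()
        )


class TestMechanism:
    def test_no_exercise_means_no_labels_and_resting_hr(self):
        cfg = SimConfig(
            n_subjects=1, days_per_subject=3, seed=2, exercise_rate=0.0, hr_noise_sd=2.0
        )
        bundle = generate_subject(cfg, 0, include_highrate=False)
        assert bundle.truth.episodes == []
        assert int(bundle.series.data["exercise"].sum()) == 0
        hr = bundle.series.data["hr_bpm"]
        assert hr.std() < 3 * cfg.hr_noise_sd  # noise only, no episode elevation

    def test_noise_free_bg_flat_then_strictly_declining(self):
        cfg = SimConfig(n_subjects=1, days_per_subject=2, seed=4, **NOISE_FREE)
        bundle = generate_subject(cfg, 0, include_highrate=False)
        assert bundle.truth.episodes, "expected at least one episode at this seed"
        ep = bundle.truth.episodes[0]
        t_min = (
            bundle.series.data["ts"] - bundle.series.data["ts"].iloc[0]
        ).dt.total_seconds().to_numpy() / 60.0
        bg = bundle.series.data["bg_mgdl"].to_numpy()
        before = t_min < ep.start_min + cfg.glycemic_lag
        assert np.allclose(bg[before], bg[0]), "glucose should be flat pre-onset"
        during = (t_min >= ep.start_min + cfg.glycemic_lag) & (
            t_min < ep.end_min + cfg.glycemic_lag
        )
        assert during.sum() >= 2
        assert np.all(np.diff(bg[during]) < 0), "glucose must fall during the episode"

    def test_noise_free_decline_rate_matches_configuration(self):
        cfg = SimConfig(n_subjects=1, days_per_subject=3, seed=8, **NOISE_FREE)
        bundle = generate_subject(cfg, 0, include_highrate=False)
        data = bundle.series.data
        t_min = (data["ts"] - data["ts"].iloc[0]).dt.total_seconds().to_numpy() / 60.0
        bg = data["bg_mgdl"].to_numpy()
        checked = 0
        prev_end = -np.inf
        for ep in bundle.truth.episodes:
            isolated = ep.start_min - prev_end > 8 * cfg.post_exercise_decay
            prev_end = ep.end_min
            during = (t_min >= ep.start_min + cfg.glycemic_lag) & (
                t_min < ep.end_min + cfg.glycemic_lag
            )
            if not isolated or during.sum() < 2 or bg[during].min() <= 41.0:
                continue  # recovery tail of the previous episode still active,
                # too short to estimate, or clipped at the physiological floor
            slopes = np.diff(bg[during]) / np.diff(t_min[during])
            expected = -cfg.glucose_drop_rate * ep.intensity
            np.testing.assert_allclose(slopes, expected, rtol=1e-3)
            checked += 1
        assert checked >= 1

    def test_hr_elevation_approaches_gain_times_intensity(self):
        fast = dict(NOISE_FREE, hr_onset_tau=0.05)
        cfg = SimConfig(n_subjects=1, days_per_subject=3, seed=6, **fast)
        resting_run = generate_subject(
            SimConfig(n_subjects=1, days_per_subject=3, seed=6, exercise_rate=0.0, **fast),
            0,
            include_highrate=False,
        )
        resting = resting_run.series.data["hr_bpm"].iloc[0]
        bundle = generate_subject(cfg, 0, include_highrate=False)
        data = bundle.series.data
        t_min = (data["ts"] - data["ts"].iloc[0]).dt.total_seconds().to_numpy() / 60.0
        hr = data["hr_bpm"].to_numpy()
        for ep in bundle.truth.episodes:
            inside = (t_min >= ep.start_min + 1.0) & (t_min < ep.end_min)
            if inside.sum() == 0:
                continue
            np.testing.assert_allclose(
                hr[inside] - resting, cfg.hr_gain * ep.intensity, atol=1.0
            )

    def test_injected_noise_sd_matches_configuration(self):
        cfg = SimConfig(
            n_subjects=1,
            days_per_subject=40,
            seed=12,
            exercise_rate=0.0,
            meal_rate=0.0,
            gap_rate=0.0,
            bg_drift=(0.005, 0.0),
            cgm_noise_sd=5.0,
        )
        bundle = generate_subject(cfg, 0, include_highrate=False)
        resid = bundle.series.data["bg_mgdl"].to_numpy()
        resid = resid - resid.mean()
        n = len(resid)
        assert n >= 10_000
        se = cfg.cgm_noise_sd / np.sqrt(2 * n)
        assert abs(resid.std(ddof=1) - cfg.cgm_noise_sd) < 3 * se


class TestCohort:
    def test_cohort_size_and_distinct_weights(self):
        cohort = generate_cohort(
            SimConfig(n_subjects=3, days_per_subject=1, seed=1), include_highrate=False
        )
        assert len(cohort) == 3
        weights = [b.series.weight for b in cohort]
        assert len(set(weights)) == 3
        lo, hi = SimConfig().weight_range
        assert all(lo <= w <= hi for w in weights)

    def test_unreported_fraction_is_binomial(self):
        """Across seeds, about half the episodes carry reported=False at 0.5."""
        total = unreported = 0
        for seed in range(10):
            cfg = SimConfig(
                n_subjects=2, days_per_subject=5, seed=seed, unreported_fraction=0.5
            )
            for bundle in generate_cohort(cfg, include_highrate=False):
                for ep in bundle.truth.episodes:
                    total += 1
                    unreported += not ep.reported
        assert total > 40
        sd = np.sqrt(total * 0.25)
        assert abs(unreported - 0.5 * total) < 3 * sd

    def test_episodes_never_overlap(self, small_cohort):
        for bundle in small_cohort:
            eps = sorted(bundle.truth.episodes, key=lambda e: e.start_min)
            for a, b in zip(eps, eps[1:]):
                assert a.end_min <= b.start_min

    def test_labels_only_on_reported_episodes(self):
        cfg = SimConfig(
            n_subjects=1, days_per_subject=6, seed=21, unreported_fraction=0.6, gap_rate=0.0
        )
        bundle = generate_subject(cfg, 0, include_highrate=False)
        data = bundle.series.data
        t_min = (data["ts"] - data["ts"].iloc[0]).dt.total_seconds().to_numpy() / 60.0
        expected = bundle.truth.membership(t_min, reported_only=True)
        np.testing.assert_array_equal(data["exercise"].to_numpy(), expected)
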