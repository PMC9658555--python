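import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmactivity.features import (
    DELTA_T_MIN,
    FS1_COLUMNS,
    FS2_COLUMNS,
    FeatureWindow,
    WINDOW,
    build_design_matrix,
    extract_features,
)
from cgmactivity.records import make_series_frame, SubjectSeries

from conftest import grid_series
from oracle_features import brute_force_features


def window(bg, hr=None):
    return FeatureWindow(
        bg=np.asarray(bg, float), t=np.arange(WINDOW) * DELTA_T_MIN, hr=hr
    )


class TestExtractFeatures:
    def test_feature_set_widths_and_order(self):
        fs1 = extract_features(window(np.full(15, 100.0)), weight=70.0)
        fs2 = extract_features(
            window(np.full(15, 100.0), hr=np.full(15, 80.0)), weight=70.0, include_hr=True
        )
        assert list(fs1.index) == FS1_COLUMNS and len(fs1) == 50
        assert list(fs2.index) == FS2_COLUMNS and len(fs2) == 52

    def test_constant_glucose_gives_all_zero_dynamics(self):
        out = extract_features(window(np.full(15, 100.0)), weight=70.0)
        assert out["w"] == 70.0
        assert (out.drop("w") == 0.0).all()

    def test_linear_ramp_frozen_values(self):
        # bg(i) = 100 + 2 i, hand-evaluated: every consecutive difference is
        # 2 mg/dL, every mini-window difference 8, all rates 0.4 mg/dL/min
        out = extract_features(window(100.0 + 2.0 * np.arange(15)), weight=70.0)
        assert out["d"] == pytest.approx(28.0)
        assert out["v"] == pytest.approx(0.4)
        for i in range(14):
            assert out[f"dp{i}"] == pytest.approx(2.0)
            assert out[f"vp{i}"] == pytest.approx(0.4)
        for i in range(3):
            assert out[f"dpp{i}"] == pytest.approx(8.0)
            assert out[f"vpp{i}"] == pytest.approx(0.4)
        for i in range(13):
            assert out[f"ap{i}"] == pytest.approx(0.04)

    def test_hr_features_from_last_two_registrations(self):
        hr = np.full(15, 70.0)
        hr[14] = 95.0
        out = extract_features(window(np.full(15, 100.0), hr=hr), 70.0, include_hr=True)
        assert out["hr"] == 95.0
        assert out["hrp"] == 25.0

    @pytest.mark.parametrize("n", [14, 16])
    def test_wrong_window_length_rejected(self, n):
        win = FeatureWindow(bg=np.zeros(n), t=np.arange(n) * DELTA_T_MIN)
        with pytest.raises(ValueError, match="15 records"):
            extract_features(win, 70.0)

    def test_non_uniform_spacing_rejected(self):
        t = np.arange(WINDOW) * DELTA_T_MIN
        t[7] += 2.0
        with pytest.raises(ValueError, match="uniform"):
            extract_features(FeatureWindow(bg=np.zeros(WINDOW), t=t), 70.0)

    def test_hr_requested_but_absent(self):
        with pytest.raises(ValueError, match="heart-rate"):
            extract_features(window(np.zeros(15)), 70.0, include_hr=True)

    @given(
        bg=st.lists(
            st.floats(min_value=40, max_value=400, allow_nan=False), min_size=15, max_size=15
        ),
        hr=st.lists(
            st.floats(min_value=40, max_value=200, allow_nan=False), min_size=15, max_size=15
        ),
        weight=st.floats(min_value=30, max_value=150),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force_evaluator(self, bg, hr, weight):
        out = extract_features(
            window(np.array(bg), hr=np.array(hr)), weight, include_hr=True
        )
        oracle = brute_force_features(bg, np.arange(15) * DELTA_T_MIN, weight, hr)
        for name, expected in oracle.items():
            assert out[name] == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(
        bg=st.lists(st.integers(min_value=40, max_value=400), min_size=15, max_size=15)
    )
    @settings(max_examples=100, deadline=None)
    def test_telescoping_identities_exact_on_integer_glucose(self, bg):
        """CGM readings are integer mg/dL, where differences are exact floats:
        the consecutive differences must sum to the end-to-end difference, and
        each mini-window difference to its four consecutive differences."""
        out = extract_features(window(np.array(bg, dtype=float)), 70.0)
        assert sum(out[f"dp{i}"] for i in range(14)) == out["d"]
        for i in range(3):
            assert (
                sum(out[f"dp{5 * i + j}"] for j in range(4)) == out[f"dpp{i}"]
            )
        for i in range(14):
            assert out[f"vp{i}"] * DELTA_T_MIN == out[f"dp{i}"]

    def test_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        bg = rng.uniform(80, 200, 15)
        base = extract_features(window(bg), 70.0)
        shifted = extract_features(window(bg + 37.0), 70.0)
        pd.testing.assert_series_equal(base.drop("w"), shifted.drop("w"), atol=1e-9)
        scaled = extract_features(window(bg * 3.0), 70.0)
        pd.testing.assert_series_equal(
            base.drop("w") * 3.0, scaled.drop("w"), atol=1e-9
        )


class TestDesignMatrix:
    def _series(self, n, hr=True, exercise=None, gap_at=None):
        ts = pd.Timestamp("2022-03-01") + pd.to_timedelta(np.arange(n) * 5, unit="m")
        frame = make_series_frame(
            ts,
            100.0 + np.arange(n, dtype=float),
            np.full(n, 80.0) if hr else None,
            exercise,
        )
        if gap_at is not None:
            frame = frame.drop(index=gap_at).reset_index(drop=True)
        return SubjectSeries(subject_id="T", weight=70.0, data=frame)

    def test_short_series_is_fully_padded(self):
        out = build_design_matrix(self._series(14))
        assert len(out) == 14
        assert out["padded"].all()
        assert (out[FS1_COLUMNS[1:]] == 0.0).all().all()
        assert (out["w"] == 70.0).all()

    def test_first_populated_row_is_the_fifteenth(self):
        out = build_design_matrix(self._series(20))
        assert (~out["padded"]).sum() == 6  # rows 15..20
        assert out["padded"][:14].all() and not out["padded"][14:].any()

    def test_labels_follow_newest_window_record(self):
        exercise = np.zeros(20, dtype=np.int8)
        exercise[16] = 1
        out = build_design_matrix(self._series(20, exercise=exercise))
        np.testing.assert_array_equal(out["label"].to_numpy(), exercise)

    def test_matrix_row_matches_single_window_extraction(self):
        series = self._series(30)
        out = build_design_matrix(series, include_hr=True)
        i = 20
        win = FeatureWindow(
            bg=series.data["bg_mgdl"].to_numpy()[i - 14 : i + 1],
            t=np.arange(15) * DELTA_T_MIN,
            hr=series.data["hr_bpm"].to_numpy()[i - 14 : i + 1],
        )
        expected = extract_features(win, 70.0, include_hr=True)
        pd.testing.assert_series_equal(
            out.loc[i, FS2_COLUMNS].astype(float), expected, check_names=False
        )

    def test_no_future_leakage(self):
        series = self._series(30)
        out = build_design_matrix(series)
        perturbed = self._series(30)
        perturbed.data.loc[25, "bg_mgdl"] += 100.0
        out2 = build_design_matrix(perturbed)
        pd.testing.assert_frame_equal(out.iloc[:25], out2.iloc[:25])
        assert not out.iloc[25:].equals(out2.iloc[25:])

    def test_window_spanning_gap_is_padded(self):
        out = build_design_matrix(self._series(40, gap_at=20))
        # windows that straddle the missing registration (rows 20..33 of the
        # 39 surviving records) are non-uniform and therefore padded
        assert out["padded"][20:34].all()
        assert not out["padded"].iloc[34:].any()
        assert not out["padded"].iloc[19]

    def test_drop_policy_removes_padded_rows(self):
        out = build_design_matrix(self._series(20), warmup_policy="drop")
        assert len(out) == 6
        assert not out["padded"].any()

    def test_empty_input_gives_empty_matrix(self):
        out = build_design_matrix(self._series(0))
        assert len(out) == 0
        assert list(out.columns[4:]) == FS1_COLUMNS

    def test_fs2_width_on_hr_bearing_series(self):
        out = build_design_matrix(self._series(20), include_hr=True)
        assert list(out.columns[4:]) == FS2_COLUMNS  # 52 feature columns

    def test_hr_missing_but_requested(self):
        with pytest.raises(ValueError, match="heart rate is missing"):
            build_design_matrix(self._series(20, hr=False), include_hr=True)

    def test_chronological_row_order(self):
        series = grid_series(bg=np.linspace(100, 200, 288))
        out = build_design_matrix(series)
        ts = out["ts"].to_numpy()
        assert (ts[1:] > ts[:-1]).all()
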