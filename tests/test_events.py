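"""Feeding-event detection: gape, peak timing, extrema and summaries."""

import numpy as np
import pytest

from jawkin.events import (
    EventTable,
    ChannelExtremum,
    GapeSeries,
    compute_gape,
    expansive_onset_10pct,
    find_angle_extrema,
    find_initial_depression,
    find_peak_gape,
    summarize_across_trials,
)
from jawkin.io import GapeLandmark
from jawkin.jcs import AngleSeries, apply_sign_conventions
from jawkin.rigid import PoseSeries
from jawkin.transforms import rot_z

RATE = 320.0


def gape(values):
    return GapeSeries(np.asarray(values, float), RATE)


def poses(rotations, translations=None, body="b"):
    rotations = np.asarray(rotations, float)
    F = rotations.shape[0]
    translations = np.zeros((F, 3)) if translations is None else np.asarray(translations, float)
    return PoseSeries(body, rotations, translations, np.zeros(F), RATE)


def angle_series(z=None, x=None, frames=None, kind="lower_jaw"):
    n = frames if frames is not None else len(z if z is not None else x)
    raw = np.zeros((n, 3))
    if z is not None:
        raw[:, 0] = z
    if x is not None:
        raw[:, 2] = x
    s = AngleSeries("j", kind, raw, np.empty_like(raw), 0, RATE)
    return apply_sign_conventions(s, kind)


class TestComputeGape:
    def test_coincident_landmarks_give_zero(self):
        eye = np.tile(np.eye(3), (3, 1, 1))
        g = compute_gape(
            poses(eye), poses(eye), GapeLandmark("u", (40, 0, 0)), GapeLandmark("l", (40, 0, 0))
        )
        assert np.allclose(g.gape_mm, 0.0)

    def test_pure_translation_gives_distance(self):
        eye = np.tile(np.eye(3), (2, 1, 1))
        lower = poses(eye, [[0, 0, 0], [0, -5, 0]])
        g = compute_gape(
            poses(eye), lower, GapeLandmark("u", (40, 0, 0)), GapeLandmark("l", (40, 0, 0))
        )
        assert np.allclose(g.gape_mm, [0.0, 5.0])

    def test_rotating_tip_peaks_with_depression(self):
        theta = -25.0 * np.sin(np.linspace(0, np.pi, 50))  # depression pulse
        lower = poses(rot_z(theta))
        upper = poses(np.tile(np.eye(3), (50, 1, 1)))
        g = compute_gape(upper, lower, GapeLandmark("u", (40, 0, 0)), GapeLandmark("l", (40, 0, 0)))
        assert int(np.argmax(g.gape_mm)) == int(np.argmax(-theta))

    def test_missing_pose_gives_missing_gape(self):
        eye = np.tile(np.eye(3), (3, 1, 1)).copy()
        eye[1] = np.nan
        g = compute_gape(
            poses(eye), poses(np.tile(np.eye(3), (3, 1, 1))),
            GapeLandmark("u", (40, 0, 0)), GapeLandmark("l", (0, 0, 0)),
        )
        assert np.isnan(g.gape_mm[1]) and np.isfinite(g.gape_mm[[0, 2]]).all()


class TestPeakGape:
    def test_unimodal_peak(self):
        v = np.concatenate([np.linspace(0, 10, 101), np.linspace(10, 0, 101)[1:]])
        frame, value = find_peak_gape(gape(v))
        assert (frame, value) == (100, 10.0)

    def test_plateau_tie_goes_to_earliest(self):
        v = np.zeros(200)
        v[100:103] = 10.0
        assert find_peak_gape(gape(v))[0] == 100

    def test_window_excludes_ventilatory_bumps(self):
        v = np.zeros(300)
        v[50] = 3.0
        v[120] = 3.5  # ventilatory bumps
        v[200] = 9.0  # strike
        assert find_peak_gape(gape(v))[0] == 200  # strike dominates anyway
        assert find_peak_gape(gape(v), window=(150, 300))[0] == 200

    def test_all_missing_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            find_peak_gape(gape([np.nan, np.nan]))


class TestInitialDepression:
    def test_frame_after_last_closure(self):
        v = np.full(120, 5.0)
        v[40:51] = 0.0  # closed frames 40..50
        assert find_initial_depression(gape(v), peak_frame=100, closure_threshold_mm=0.1) == (51, False)

    def test_monotone_rise_flags_never_closed(self):
        v = np.linspace(1.0, 10.0, 50)
        frame, never = find_initial_depression(gape(v), peak_frame=49, closure_threshold_mm=0.5)
        assert (frame, never) == (0, True)

    def test_last_of_two_closures_wins(self):
        v = np.full(120, 5.0)
        v[20] = 0.0
        v[60] = 0.0
        assert find_initial_depression(gape(v), peak_frame=100, closure_threshold_mm=0.1)[0] == 61


class TestExpansiveOnset:
    def test_linear_ramp_hits_fraction(self):
        v = np.linspace(0.0, 20.0, 101)  # 10% of max at frame 10
        assert expansive_onset_10pct(gape(v), peak_frame=100, initial_depression_frame=0) == 10

    def test_already_above_fraction_returns_start(self):
        v = np.linspace(5.0, 20.0, 101)
        assert expansive_onset_10pct(gape(v), 100, initial_depression_frame=30) == 30

    def test_zero_fraction_degenerates_to_initial_depression(self):
        v = np.linspace(0.0, 20.0, 101)
        assert expansive_onset_10pct(gape(v), 100, initial_depression_frame=7, fraction=0.0) == 7


class TestAngleExtrema:
    def test_single_negative_lar_pulse_timing(self):
        # eversion minimum 6 frames (18.75 ms) before peak gape at frame 100
        x = np.zeros(200)
        x[80:109] = -8.0 * np.sin(np.linspace(0, np.pi, 29))  # min at frame 94
        ext = find_angle_extrema(angle_series(x=x), angle_series(x=np.zeros(200), kind="upper_jaw"), 100, (0, 200))
        ev = ext["lower_jaw_eversion"]
        assert ev.value_deg == pytest.approx(-8.0)
        assert ev.frame == 94
        assert ev.time_ms == pytest.approx((94 - 100) / RATE * 1000.0)

    def test_extremum_at_peak_gape_has_zero_timing(self):
        z = np.zeros(50)
        z[20] = -10.0
        ext = find_angle_extrema(angle_series(z=z), angle_series(z=np.zeros(50), kind="upper_jaw"), 20, (0, 50))
        assert ext["lower_jaw_depression"].time_ms == 0.0

    def test_inversion_is_post_eversion_maximum(self):
        x = np.zeros(100)
        x[10] = 6.0   # pre-strike positive bump must not win
        x[40] = -8.0  # eversion
        x[70] = 5.0   # true inversion follows eversion
        ext = find_angle_extrema(angle_series(x=x), angle_series(x=np.zeros(100), kind="upper_jaw"), 50, (0, 100))
        assert ext["lower_jaw_inversion"].frame == 70
        assert ext["lower_jaw_inversion"].value_deg == pytest.approx(5.0)

    def test_constant_channel_flagged_zero_range(self):
        ext = find_angle_extrema(angle_series(frames=30, z=np.zeros(30)), angle_series(frames=30, kind="upper_jaw", z=np.zeros(30)), 10, (0, 30))
        assert ext["lower_jaw_depression"].value_deg == 0.0
        assert ext["lower_jaw_depression"].zero_range

    def test_window_must_cover_peak(self):
        with pytest.raises(ValueError, match="peak"):
            find_angle_extrema(angle_series(frames=30, z=np.zeros(30)), angle_series(frames=30, kind="upper_jaw", z=np.zeros(30)), 25, (0, 20))


def make_table(trial_id, shift=0, rate=RATE, value=-8.0):
    ext = ChannelExtremum(value_deg=value, frame=94 + shift, time_ms=(94 - 100) / rate * 1000.0)
    return EventTable(
        trial_id=trial_id,
        peak_gape_frame=100 + shift,
        max_gape_mm=10.0,
        initial_depression_frame=50 + shift,
        never_closed=False,
        expansive_onset_frame=55 + shift,
        channels={"lower_jaw_eversion": ext},
        sample_rate_hz=rate,
    )


class TestTimingInvariances:
    def test_shift_invariance(self):
        """Shifting a whole trial by k frames leaves all relative timings
        unchanged."""
        assert make_table("a").quantities() == make_table("b", shift=17).quantities()

    def test_sample_rate_rescales_timings(self):
        q320 = make_table("a", rate=320.0).quantities()
        q330 = make_table("b", rate=330.0).quantities()
        for key in q320:
            if key.endswith("_ms"):
                assert q330[key] == pytest.approx(q320[key] * 320.0 / 330.0)


class TestSummarize:
    def test_hand_computed_mean_and_sem(self):
        tables = [make_table(f"t{v}", value=v) for v in (1.0, 2.0, 3.0)]
        s = summarize_across_trials(tables).set_index("quantity")
        row = s.loc["lower_jaw_eversion_deg"]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3), abs=1e-9)  # s.d. 1, n 3
        assert row["n"] == 3

    def test_single_trial_sem_unavailable(self):
        s = summarize_across_trials([make_table("a")]).set_index("quantity")
        assert np.isnan(s.loc["lower_jaw_eversion_deg", "sem"])
        assert s.loc["lower_jaw_eversion_deg", "mean"] == pytest.approx(-8.0)

    def test_identical_trials_have_zero_sem(self):
        s = summarize_across_trials([make_table("a"), make_table("b")]).set_index("quantity")
        assert s.loc["lower_jaw_eversion_deg", "sem"] == 0.0

    def test_mismatched_channel_sets_raise(self):
        bad = make_table("b")
        bad.channels = {"upper_jaw_eversion": bad.channels["lower_jaw_eversion"]}
        with pytest.raises(ValueError, match="does not match"):
            summarize_across_trials([make_table("a"), bad])
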