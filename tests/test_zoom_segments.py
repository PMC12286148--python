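"""Height-series dynamics, zoom detection and segment extraction/scoring."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from gaitvqa.tracking import TargetSelection, track
from gaitvqa.zoom_segments import (
    EmptySeriesError,
    HeightSeries,
    SeriesTooShortError,
    detect_zoom,
    height_diffs,
    height_series,
    score_segment,
    segment_coronal,
    segment_sagittal,
    step_for_fps,
    walking_direction,
)

from conftest import make_person, make_sequence


def series_from_raw(raw, step=8, tau=0.05, fps=60.0, sigma=2.0):
    raw = np.asarray(raw, dtype=float)
    return HeightSeries(
        normalized_height=raw,
        smoothed=gaussian_filter1d(raw, sigma=sigma, mode="reflect"),
        step=step,
        tau=tau,
        fps=fps,
    )


def _track_with_heights(heights, fps=60.0):
    frames = []
    for h in heights:
        if h is None:
            frames.append([])
        else:
            frames.append([make_person(box=(0.5 - h / 2, 0.4, 0.5 + h / 2, 0.6, 0.9))])
    seq = make_sequence(frames, fps=fps)
    sel_frame = next(i for i, h in enumerate(heights) if h is not None)
    return seq, track(seq, TargetSelection(frame_index=sel_frame, person_index=0))


class TestHeightSeries:
    def test_constant_heights_survive_smoothing(self):
        seq, trk = _track_with_heights([0.5] * 100)
        hs = height_series(trk, seq.fps)
        assert np.allclose(hs.normalized_height, 0.5)
        assert np.allclose(hs.smoothed, 0.5)

    def test_linear_ramp_matches_convolution_oracle(self):
        heights = list(np.linspace(0.3, 0.7, 200))
        seq, trk = _track_with_heights(heights)
        hs = height_series(trk, seq.fps)
        oracle = gaussian_filter1d(np.asarray(heights), sigma=2.0, mode="reflect")
        assert np.allclose(hs.smoothed, oracle, atol=1e-12)
        # interior of a linear trend is preserved by Gaussian smoothing
        assert np.allclose(hs.smoothed[20:-20], heights[20:-20], atol=1e-6)

    def test_absent_frames_carry_last_height(self):
        heights = [0.5] * 10 + [None] * 3 + [0.6] * 10
        seq, trk = _track_with_heights(heights)
        hs = height_series(trk, seq.fps)
        assert np.allclose(hs.normalized_height[10:13], 0.5)

    def test_never_present_is_an_error(self):
        from gaitvqa.tracking import TargetTrack, TrackEntry

        trk = TargetTrack(entries=tuple(TrackEntry(None, False, 0, None) for _ in range(20)))
        with pytest.raises(EmptySeriesError):
            height_series(trk, 60.0)

    def test_step_scales_with_frame_rate(self):
        assert step_for_fps(60.0) == 8
        assert step_for_fps(30.0) == 4
        assert step_for_fps(120.0) == 16
        assert step_for_fps(5.0) == 1  # never below one frame


class TestHeightDiffs:
    def test_constant_series_all_zero(self):
        hs = series_from_raw([0.5] * 50)
        assert np.allclose(height_diffs(hs), 0.0)

    def test_linear_series_constant_step_difference(self):
        hs = series_from_raw(0.001 * np.arange(300))
        dh = height_diffs(hs)
        assert len(dh) == 300 - 8
        assert np.allclose(dh[10:-10], 0.008, atol=1e-9)

    def test_matches_index_shift_oracle(self, rng):
        raw = rng.uniform(0.2, 0.8, size=120)
        hs = series_from_raw(raw)
        dh = height_diffs(hs)
        oracle = np.array([hs.smoothed[i + 8] - hs.smoothed[i] for i in range(112)])
        assert np.allclose(dh, oracle)

    def test_too_short_series_errors(self):
        with pytest.raises(SeriesTooShortError, match="8"):
            height_diffs(series_from_raw([0.5] * 8))


class TestDetectZoom:
    def test_constant_heights_no_events(self):
        events, flag = detect_zoom(series_from_raw([0.5] * 100))
        assert events == [] and flag == 0

    def test_injected_jump_yields_one_zoom_in(self):
        raw = np.full(200, 0.5)
        raw[100:] = 0.7  # completed within 2 frames
        events, flag = detect_zoom(series_from_raw(raw))
        assert flag == 1
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "zoom_in"
        assert ev.start_frame <= 100 <= ev.end_frame

    def test_slow_drift_stays_below_threshold(self):
        raw = 0.3 + 0.0005 * np.arange(400)  # 0.0005 * 8 = 0.004 < tau
        events, flag = detect_zoom(series_from_raw(raw))
        assert events == [] and flag == 0

    def test_drop_yields_zoom_out(self):
        raw = np.full(200, 0.7)
        raw[120:] = 0.5
        events, _ = detect_zoom(series_from_raw(raw))
        assert [e.direction for e in events] == ["zoom_out"]

    def test_recall_on_injected_steps_and_no_false_positives(self, rng):
        """Steps of magnitude >= 2*tau completed within <= s frames are always
        found; noisy constant series (sd 0.003) never fire."""
        for _ in range(100):
            n = 300
            raw = np.full(n, float(rng.uniform(0.3, 0.6)))
            start = int(rng.integers(50, 220))
            span = int(rng.integers(1, 9))
            mag = float(rng.uniform(0.1, 0.3)) * (1 if rng.random() < 0.5 else -1)
            ramp = np.linspace(0, mag, span + 1)
            raw[start: start + span + 1] += ramp
            raw[start + span + 1:] += mag
            raw = np.clip(raw, 0.01, 1.0)
            events, flag = detect_zoom(series_from_raw(raw))
            assert flag == 1
            want = "zoom_in" if mag > 0 else "zoom_out"
            assert any(e.direction == want for e in events)
        for _ in range(100):
            raw = 0.5 + rng.normal(0, 0.003, size=300)
            events, flag = detect_zoom(series_from_raw(np.clip(raw, 0, 1)))
            assert flag == 0


class TestScoreSegment:
    @pytest.mark.parametrize(
        "duration,expected",
        [(8.0, 100.0), (3.0, 0.0), (5.5, 50.0), (0.0, 0.0), (2.9, 0.0), (30.0, 100.0)],
    )
    def test_anchors_and_interpolation(self, duration, expected):
        assert score_segment(duration) == pytest.approx(expected)

    def test_monotone_and_continuous(self):
        grid = np.linspace(0, 12, 400)
        scores = [score_segment(float(d)) for d in grid]
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        assert score_segment(3.0 + 1e-9) < 1e-5      # continuous at 3 s
        assert score_segment(8.0 - 1e-9) > 100 - 1e-5  # continuous at 8 s

    def test_proportional_variant(self):
        assert score_segment(4.0, mode="proportional_0_8") == pytest.approx(50.0)
        assert score_segment(3.0, mode="proportional_0_8") == 0.0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            score_segment(-1.0)


class TestWalkingDirection:
    def test_ears_right_of_nose_means_right_to_left(self):
        det = make_person(
            kp_overrides={"nose": (0.5, 0.2), "left_ear": (0.6, 0.2), "right_ear": (0.6, 0.2)}
        )
        assert walking_direction(det) == "right_to_left"

    def test_ears_left_of_nose_means_left_to_right(self):
        det = make_person(
            kp_overrides={"nose": (0.5, 0.2), "left_ear": (0.4, 0.2), "right_ear": (0.4, 0.2)}
        )
        assert walking_direction(det) == "left_to_right"

    def test_exact_tie_is_undefined(self):
        det = make_person(
            kp_overrides={"nose": (0.5, 0.2), "left_ear": (0.5, 0.2), "right_ear": (0.5, 0.2)}
        )
        assert walking_direction(det) is None

    def test_low_confidence_ears_are_ignored(self):
        det = make_person(
            kp_overrides={"nose": (0.5, 0.2), "left_ear": (0.6, 0.2), "right_ear": (0.6, 0.2)},
            kp_score=0.2,
        )
        assert walking_direction(det) is None


def _coronal_walk(n_each=480, h_lo=0.3, h_hi=0.8, towards_first=True, fps=60.0):
    """Approach then recede (or vice versa), facing encoded in shoulder order."""
    frames = []
    ramps = np.concatenate([np.linspace(h_lo, h_hi, n_each), np.linspace(h_hi, h_lo, n_each)])
    for i, h in enumerate(ramps):
        facing = 1.0 if (i < n_each) == towards_first else -1.0
        half = 0.06
        frames.append(
            [
                make_person(
                    box=(0.5 - h / 2, 0.35, 0.5 + h / 2, 0.65, 0.9),
                    kp_overrides={
                        "left_shoulder": (0.5 + facing * half, 0.35),
                        "right_shoulder": (0.5 - facing * half, 0.35),
                    },
                )
            ]
        )
    return make_sequence(frames, fps=fps)


class TestSegmentCoronal:
    def test_towards_then_away_splits_at_sign_change(self):
        seq = _coronal_walk(n_each=540)  # 9 s per leg
        trk = track(seq, TargetSelection(frame_index=0, person_index=0))
        hs = height_series(trk, seq.fps)
        report = segment_coronal(trk, hs, seq.fps)
        assert len(report.segments) == 2
        labels = [s.label for s in report.segments]
        assert labels == ["towards_camera", "away_from_camera"]
        assert abs(report.segments[0].end_frame - 539) <= 8
        assert report.best_score_dir1 == 100.0 and report.best_score_dir2 == 100.0
        assert report.zoom_flag == 0

    def test_zoom_segment_eliminated_by_orientation_height_mismatch(self):
        """Height falls while the subject faces the camera: a zoom artifact."""
        n = 720
        h = np.concatenate(
            [np.linspace(0.3, 0.6, 300), np.linspace(0.6, 0.45, 60), np.linspace(0.45, 0.7, 360)]
        )
        frames = []
        for i in range(n):
            frames.append(
                [
                    make_person(
                        box=(0.5 - h[i] / 2, 0.35, 0.5 + h[i] / 2, 0.65, 0.9),
                        kp_overrides={
                            "left_shoulder": (0.56, 0.35),
                            "right_shoulder": (0.44, 0.35),
                        },
                    )
                ]
            )
        seq = make_sequence(frames)
        trk = track(seq, TargetSelection(frame_index=0, person_index=0))
        hs = height_series(trk, seq.fps)
        report = segment_coronal(trk, hs, seq.fps)
        # the decreasing-height stretch is gone; no segment covers frame 330
        for s in report.segments:
            assert not (s.start_frame <= 330 <= s.end_frame)
        # a 0.15 drop spread over 60 frames stays under the step threshold,
        # yet the orientation/trend consistency rule still eliminates it
        assert report.zoom_flag == 0

    def test_short_segments_rejected(self):
        seq = _coronal_walk(n_each=150)  # 2.5 s per leg
        trk = track(seq, TargetSelection(frame_index=0, person_index=0))
        hs = height_series(trk, seq.fps)
        report = segment_coronal(trk, hs, seq.fps)
        assert report.segments == ()
        assert report.best_score_dir1 == 0.0 and report.percent_valid_frames == 0.0


def _sagittal_walk(n_each=600, h=0.55, fps=60.0):
    frames = []
    for i in range(2 * n_each):
        direction = 1.0 if i < n_each else -1.0
        frames.append(
            [
                make_person(
                    box=(0.5 - h / 2, 0.35, 0.5 + h / 2, 0.65, 0.9),
                    kp_overrides={
                        "nose": (0.5 + direction * 0.03, 0.25),
                        "left_ear": (0.5 - direction * 0.01, 0.25),
                        "right_ear": (0.5 - direction * 0.01, 0.25),
                    },
                )
            ]
        )
    return make_sequence(frames, fps=fps)


class TestSegmentSagittal:
    def test_direction_transition_splits(self):
        seq = _sagittal_walk(n_each=600)  # 10 s per leg
        trk = track(seq, TargetSelection(frame_index=0, person_index=0))
        hs = height_series(trk, seq.fps)
        report = segment_sagittal(trk, hs, seq.fps)
        assert [s.label for s in report.segments] == ["left_to_right", "right_to_left"]
        assert abs(report.segments[0].end_frame - 599) <= 8
        assert report.best_score_dir1 == 100.0 and report.best_score_dir2 == 100.0

    def test_zoom_spike_excised_and_flanks_kept(self):
        seq = _sagittal_walk(n_each=900)  # 15 s single-direction halves
        # inject a height spike inside the first leg
        frames = [list(f.persons) for f in seq.frames]
        for i in range(400, 460):
            p = frames[i][0]
            grow = 0.2 if i >= 406 else 0.2 * (i - 400) / 6
            box = (0.5 - (0.55 + grow) / 2, 0.35, 0.5 + (0.55 + grow) / 2, 0.65, 0.9)
            frames[i] = [make_person(box=box, kp_overrides={
                "nose": (0.53, 0.25), "left_ear": (0.49, 0.25), "right_ear": (0.49, 0.25)})]
        seq2 = make_sequence(frames)
        trk = track(seq2, TargetSelection(frame_index=0, person_index=0))
        hs = height_series(trk, seq2.fps)
        report = segment_sagittal(trk, hs, seq2.fps)
        assert report.zoom_flag == 1
        l2r = [s for s in report.segments if s.label == "left_to_right"]
        assert len(l2r) >= 2  # split around the excised zoom frames
        for s in report.segments:
            assert s.duration_s > 3.0

    def test_sub_three_second_pieces_rejected(self):
        seq = _sagittal_walk(n_each=150)  # 2.5 s legs
        trk = track(seq, TargetSelection(frame_index=0, person_index=0))
        hs = height_series(trk, seq.fps)
        report = segment_sagittal(trk, hs, seq.fps)
        assert report.segments == ()


def test_valid_segments_disjoint_and_percentage_matches_frame_count():
    seq = _coronal_walk(n_each=480)
    trk = track(seq, TargetSelection(frame_index=0, person_index=0))
    hs = height_series(trk, seq.fps)
    report = segment_coronal(trk, hs, seq.fps)
    spans = sorted((s.start_frame, s.end_frame) for s in report.segments)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        assert b1 < a2
    n_valid = sum(b - a + 1 for a, b in spans)
    assert report.percent_valid_frames == pytest.approx(100.0 * n_valid / len(seq))
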