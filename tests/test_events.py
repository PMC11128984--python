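"""Detection-event algorithm: threshold filter, adjacency grouping,
buffering/clamping and clip requests."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fincam import (
    ArgumentError,
    DataError,
    SceneConfig,
    SegmentationConfig,
    StreamConfig,
    buffer_and_clamp,
    filter_predictions,
    generate_probability_stream,
    group_adjacent,
    render_video,
    run_segmentation,
    segment_events,
)
from fincam.classifier import read_predictions
from fincam.events import write_events

from conftest import predictions_from_scores, rle_runs


def stream_events(scores_by_video, threshold=0.5, buffer_s=20.0):
    preds = predictions_from_scores(scores_by_video)
    cfg = SegmentationConfig(threshold=threshold, buffer_s=buffer_s)
    return run_segmentation(preds, cfg)


class TestFilter:
    def test_threshold_is_inclusive(self):
        preds = predictions_from_scores({"a_20230726_050000.tif": [0.49, 0.50, 0.51]})
        kept = filter_predictions(preds, 0.5)
        assert [p.p_fish for p in kept] == [0.50, 0.51]

    def test_threshold_zero_keeps_all_and_empty_input(self):
        preds = predictions_from_scores({"a_20230726_050000.tif": [0.0, 0.3]})
        assert filter_predictions(preds, 0.0) == preds
        assert filter_predictions([], 0.5) == []

    def test_unordered_input_rejected(self):
        preds = predictions_from_scores({"a_20230726_050000.tif": [0.9, 0.9]})
        with pytest.raises(ArgumentError):
            filter_predictions(list(reversed(preds)), 0.5)

    def test_missing_scores_never_pass(self):
        preds = predictions_from_scores(
            {"a_20230726_050000.tif": [0.9, math.nan, 0.9]}
        )
        kept = filter_predictions(preds, 0.0)
        assert [p.sample.sample_index for p in kept] == [1, 3]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ArgumentError):
            filter_predictions([], 1.01)


class TestGrouping:
    def test_runs_of_adjacent_samples(self):
        scores = [0.1] * 2 + [0.9] * 3 + [0.1] * 3 + [0.9] + [0.1] * 3
        # positives at sample indices 3,4,5 and 9
        events = stream_events({"a_20230726_050000.tif": scores})
        assert [(e.group_id, [m.sample.sample_index for m in e.members]) for e in events] == [
            (1, [3, 4, 5]),
            (2, [9]),
        ]
        assert events[0].start_frame == 801 and events[0].end_frame == 1601

    def test_file_boundary_never_bridged(self):
        events = stream_events(
            {
                "a_20230726_050000.tif": [0.1, 0.1, 0.9],
                "b_20230726_060000.tif": [0.9, 0.1, 0.1],
            }
        )
        assert len(events) == 2
        assert events[0].video.path != events[1].video.path
        assert [e.group_id for e in events] == [1, 1]  # numbering per video

    def test_empty_input_gives_no_events(self):
        assert group_adjacent([]) == []

    def test_duplicate_sample_rejected(self):
        preds = predictions_from_scores({"a_20230726_050000.tif": [0.9]}) * 2
        with pytest.raises(DataError):
            group_adjacent(preds)

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.booleans(), max_size=60))
    def test_equivalence_with_run_length_oracle(self, flags):
        """Grouping output equals a brute-force run-length encoding of the
        boolean above-threshold sequence: same count, membership, bounds."""
        scores = [0.9 if f else 0.1 for f in flags]
        preds = predictions_from_scores({"a_20230726_050000.tif": scores})
        events = group_adjacent(filter_predictions(preds, 0.5))
        expected = rle_runs(flags)
        assert len(events) == len(expected)
        for ev, (start0, end0) in zip(events, expected):
            assert [m.sample.sample_index for m in ev.members] == list(
                range(start0 + 1, end0 + 2)
            )

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.booleans(), max_size=60))
    def test_event_count_identity(self, flags):
        """Number of events equals the number of kept predictions whose
        same-video predecessor is absent or non-adjacent."""
        scores = [0.9 if f else 0.1 for f in flags]
        preds = predictions_from_scores({"a_20230726_050000.tif": scores})
        kept = filter_predictions(preds, 0.5)
        events = group_adjacent(kept)
        starts = sum(
            1
            for i, p in enumerate(kept)
            if i == 0 or p.sample.sample_index - kept[i - 1].sample.sample_index > 1
        )
        assert len(events) == starts

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.0, 1.0), max_size=40),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
    )
    def test_raising_threshold_refines_events(self, scores, t1, t2):
        """A higher threshold never keeps more samples and never merges two
        events that were separate at the lower threshold."""
        lo, hi = sorted((t1, t2))
        preds = predictions_from_scores({"a_20230726_050000.tif": scores})
        ev_lo = group_adjacent(filter_predictions(preds, lo))
        ev_hi = group_adjacent(filter_predictions(preds, hi))
        assert sum(e.n_members for e in ev_hi) <= sum(e.n_members for e in ev_lo)
        spans_lo = [
            (min(m.sample.sample_index for m in e.members),
             max(m.sample.sample_index for m in e.members))
            for e in ev_lo
        ]
        for e in ev_hi:  # each refined event sits inside one coarse event
            s = min(m.sample.sample_index for m in e.members)
            t = max(m.sample.sample_index for m in e.members)
            assert sum(1 for a, b in spans_lo if a <= s and t <= b) == 1


class TestBuffering:
    def test_twenty_seconds_at_twenty_fps_is_400_frames(self):
        [event] = stream_events(
            {"a_20230726_050000.tif": [0.1] * 14 + [0.9] + [0.1] * 10}
        )
        # sample 15 -> frame 5601; +-400 frames of 20 s buffer
        assert event.start_frame == event.end_frame == 5601
        assert event.buffered_start == 5601 - 400
        assert event.buffered_end == 5601 + 400

    def test_clamps_to_video_bounds(self, tmp_path):
        [event] = stream_events({"a_20230726_050000.tif": [0.9, 0.9]})
        # start frame 1 - 400 clamps to 1
        assert event.buffered_start == 1
        [last] = stream_events({"a_20230726_050000.tif": [0.1] * 47 + [0.9]})
        assert last.buffered_end == last.video.total_frames

    def test_plain_arithmetic_away_from_bounds(self):
        [event] = stream_events(
            {"a_20230726_050000.tif": [0.1] * 13 + [0.9, 0.9] + [0.1] * 20}
        )
        # samples 14..15 -> frames 5201..5601, independently: 5201-400=4801,
        # 5601+400=6001
        assert (event.buffered_start, event.buffered_end) == (4801, 6001)

    def test_buffer_uses_video_fps(self):
        events = stream_events({"a_20230726_050000.tif": [0.1] * 5 + [0.9] + [0.1] * 5})
        ev25 = predictions_from_scores(
            {"a_20230726_050000.tif": [0.1] * 5 + [0.9] + [0.1] * 5}, fps=25.0
        )
        [e25] = run_segmentation(ev25, SegmentationConfig(buffer_s=20.0))
        assert events[0].start_frame - events[0].buffered_start == 400
        assert e25.start_frame - e25.buffered_start == 500  # 20 s at 25 fps

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
        st.floats(0.0, 60.0),
    )
    def test_clamp_safety(self, scores, buffer_s):
        preds = predictions_from_scores({"a_20230726_050000.tif": scores})
        cfg = SegmentationConfig(threshold=0.5, buffer_s=buffer_s)
        for ev in run_segmentation(preds, cfg):
            assert 1 <= ev.buffered_start <= ev.start_frame
            assert ev.end_frame <= ev.buffered_end <= ev.video.total_frames

    def test_overlapping_windows_not_merged_by_default(self):
        scores = [0.1, 0.9, 0.1, 0.9, 0.1]
        events = stream_events({"a_20230726_050000.tif": scores}, buffer_s=60.0)
        assert len(events) == 2
        assert events[0].buffered_end >= events[1].buffered_start  # overlap kept
        preds = predictions_from_scores({"a_20230726_050000.tif": scores})
        merged = run_segmentation(
            preds, SegmentationConfig(buffer_s=60.0, merge_overlaps=True)
        )
        assert len(merged) == 1


class TestSegmentRequests:
    def test_filenames_encode_video_group_and_range(self, tmp_path):
        events = stream_events({"a_20230726_050000.tif": [0.1] * 14 + [0.9] + [0.1] * 10})
        [req] = segment_events(events, tmp_path)
        assert req.output_path.name == "a_20230726_050000_g1_f5201-6001.tif"
        assert (req.start_frame, req.end_frame) == (5201, 6001)

    def test_unbuffered_events_rejected(self, tmp_path):
        preds = predictions_from_scores({"a_20230726_050000.tif": [0.9]})
        events = group_adjacent(filter_predictions(preds, 0.5))
        with pytest.raises(ArgumentError):
            segment_events(events, tmp_path)

    def test_write_continues_past_failing_event(self, tmp_path, scene_assets):
        """A missing source video is recorded in the manifest error column
        while the remaining events still produce clips."""
        meta = scene_assets["meta"]
        good = predictions_from_scores(
            {str(meta.path): [0.9] + [0.1] * 4}, interval_s=2.0
        )
        # rebuild with the real probed metadata so frames exist on disk
        from fincam import FrameSample, Prediction

        good = [
            Prediction(
                FrameSample(meta, p.sample.sample_index, p.sample.frame_number,
                            None, p.sample.global_order),
                p.p_fish,
            )
            for p in good
        ]
        bad = predictions_from_scores({"zz_20230727_050000.tif": [0.9]})
        bad = [
            Prediction(
                FrameSample(b.sample.video, 1, 1, None, len(good) + 1), 0.9
            )
            for b in bad
        ]
        cfg = SegmentationConfig(threshold=0.5, buffer_s=1.0)
        events = run_segmentation(good + bad, cfg)
        manifest = write_events(events, tmp_path)
        assert len(manifest) == 2
        ok = manifest[manifest.error == ""]
        failed = manifest[manifest.error != ""]
        assert len(ok) == 1 and len(failed) == 1
        from fincam import probe_video

        assert probe_video(ok.clip_path.iloc[0]).total_frames == (
            ok.buffered_end.iloc[0] - ok.buffered_start.iloc[0] + 1
        )

    def test_zero_events_is_success(self, tmp_path):
        manifest = write_events([], tmp_path)
        assert manifest.empty


class TestGroundTruthRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_runs_recovered_exactly(self, seed, tmp_path):
        """Every planted above-threshold run maps to exactly one event with
        exact sample and frame boundaries, and no spurious events appear."""
        rng = np.random.default_rng(seed)
        runs = []
        pos = 1
        for _ in range(rng.integers(1, 5)):
            start = pos + int(rng.integers(1, 8)) + 1
            length = int(rng.integers(1, 6))
            if start + length - 1 > 60:
                break
            runs.append((start, length, 0.9))
            pos = start + length - 1
        cfg = StreamConfig(
            n_videos=2, samples_per_video=60,
            planted_runs=(tuple(runs),), seed=seed,
        )
        csv = tmp_path / "stream.csv"
        _, truth = generate_probability_stream(cfg, csv)
        preds = read_predictions(csv)
        events = run_segmentation(preds, SegmentationConfig(threshold=0.5))
        assert len(events) == len(truth)
        for ev, row in zip(events, truth.itertuples(index=False)):
            assert str(ev.video.path) == row.video_path
            assert ev.start_frame == row.start_frame
            assert ev.end_frame == row.end_frame

    def test_stream_csv_round_trip(self, tmp_path):
        cfg = StreamConfig(
            n_videos=1, samples_per_video=12,
            planted_runs=(((4, 3, 0.9), (10, 1, 0.9)),), seed=1,
        )
        csv = tmp_path / "stream.csv"
        _, truth = generate_probability_stream(cfg, csv)
        events = run_segmentation(
            read_predictions(csv), SegmentationConfig(threshold=0.5)
        )
        assert len(events) == len(truth) == 2
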