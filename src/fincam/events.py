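"""Detection-event segmentation: threshold per-frame fish probabilities,
group adjacent positives within each video file, buffer and clamp the frame
bounds, and emit frame-accurate clip requests.

The algorithm, on a chronologically ordered prediction stream:

1. keep predictions with ``p_fish >= threshold`` (inclusive; the operating
   default is 0.5, i.e. "at least 50 % fish");
2. split by video file, then group maximal runs of *adjacent* thinned samples
   (consecutive ``sample_index`` values — a gap of more than one sample
   breaks the run) into one detection event each;
3. pad each event's source-frame range by a buffer (default 20 s, converted
   through the video's own fps — 400 frames at 20 fps), clamped to
   ``[1, total_frames]``;
4. write one clip per event.

Runs never span video files, and group numbering restarts per video.
Buffered windows of distinct events may overlap and are not merged by
default; ``merge_overlaps=True`` opts in to merging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .classifier import Prediction
from .errors import ArgumentError, DataError
from .media_io import SegmentRequest, VideoMeta, write_segment

__all__ = [
    "DetectionEvent",
    "SegmentationConfig",
    "filter_predictions",
    "group_adjacent",
    "buffer_and_clamp",
    "segment_events",
    "write_events",
    "run_segmentation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the event algorithm: the probability filter, the clip
    buffer in seconds, and whether overlapping buffered windows merge."""

    threshold: float = 0.5
    buffer_s: float = 20.0
    merge_overlaps: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ArgumentError(f"threshold must be in [0, 1]: {self.threshold}")
        if self.buffer_s < 0:
            raise ArgumentError(f"buffer_s must be >= 0: {self.buffer_s}")


@dataclass(frozen=True)
class DetectionEvent:
    """A maximal run of adjacent above-threshold samples in one video.

    ``start_frame``/``end_frame`` are the min/max member source frames;
    ``buffered_*`` are set by :func:`buffer_and_clamp`.
    """

    video: VideoMeta
    group_id: int
    members: tuple[Prediction, ...]
    start_frame: int
    end_frame: int
    buffered_start: int | None = None
    buffered_end: int | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)


def filter_predictions(
    predictions: Sequence[Prediction], threshold: float
) -> list[Prediction]:
    """Keep predictions with ``p_fish >= threshold``, preserving order.

    Input must already be in chronological order (``global_order`` strictly
    ascending where set) — ordering is the caller's contract and violating it
    is an error, not silently repaired. Missing (NaN) scores never pass the
    filter, so an unreadable frame breaks adjacency instead of fabricating
    continuity.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ArgumentError(f"threshold must be in [0, 1]: {threshold}")
    orders = [p.sample.global_order for p in predictions if p.sample.global_order is not None]
    if any(b <= a for a, b in zip(orders, orders[1:])):
        raise ArgumentError(
            "predictions are not in chronological order (global_order must be "
            "strictly ascending)"
        )
    return [
        p for p in predictions
        if not math.isnan(p.p_fish) and p.p_fish >= threshold
    ]


def group_adjacent(filtered: Sequence[Prediction]) -> list[DetectionEvent]:
    """Group adjacent positive samples into detection events.

    Adjacency means consecutive ``sample_index`` values within the same video
    file; the stream is split by file before grouping, so no event spans two
    files. ``group_id`` restarts at 1 per video and increases in stream
    order. Duplicate ``(video, sample_index)`` pairs are a data error.
    """
    seen: set[tuple[str, int]] = set()
    for p in filtered:
        key = (str(p.sample.video.path), p.sample.sample_index)
        if key in seen:
            raise DataError(f"duplicate prediction for {key}")
        seen.add(key)

    events: list[DetectionEvent] = []
    run: list[Prediction] = []
    group_counters: dict[str, int] = {}

    def close_run() -> None:
        if not run:
            return
        video = run[0].sample.video
        vp = str(video.path)
        group_counters[vp] = group_counters.get(vp, 0) + 1
        frames = [p.sample.frame_number for p in run]
        events.append(
            DetectionEvent(
                video=video,
                group_id=group_counters[vp],
                members=tuple(run),
                start_frame=min(frames),
                end_frame=max(frames),
            )
        )
        run.clear()

    for p in filtered:
        if run:
            prev = run[-1]
            same_video = str(prev.sample.video.path) == str(p.sample.video.path)
            adjacent = p.sample.sample_index - prev.sample.sample_index == 1
            if not (same_video and adjacent):
                close_run()
        run.append(p)
    close_run()
    return events


def buffer_and_clamp(
    event: DetectionEvent, cfg: SegmentationConfig
) -> DetectionEvent:
    """Pad the event's frame range by ``round(buffer_s * fps)`` frames on each
    side, clamped to ``[1, total_frames]`` so the cut stays in bounds."""
    buffer_frames = round(cfg.buffer_s * event.video.fps)
    return replace(
        event,
        buffered_start=max(1, event.start_frame - buffer_frames),
        buffered_end=min(event.video.total_frames, event.end_frame + buffer_frames),
    )


def _merge_overlapping(events: list[DetectionEvent]) -> list[DetectionEvent]:
    """Optional post-pass: merge events of the same video whose buffered
    windows overlap or touch; member lists concatenate, earliest group_id
    wins."""
    merged: list[DetectionEvent] = []
    for ev in events:
        if (
            merged
            and str(merged[-1].video.path) == str(ev.video.path)
            and ev.buffered_start is not None
            and merged[-1].buffered_end is not None
            and ev.buffered_start <= merged[-1].buffered_end + 1
        ):
            prev = merged.pop()
            merged.append(
                replace(
                    prev,
                    members=prev.members + ev.members,
                    end_frame=max(prev.end_frame, ev.end_frame),
                    buffered_end=max(prev.buffered_end, ev.buffered_end),
                )
            )
        else:
            merged.append(ev)
    return merged


def segment_events(
    events: Sequence[DetectionEvent],
    out_dir: Path | str,
    container_suffix: str | None = None,
) -> list[SegmentRequest]:
    """One clip request per buffered event.

    Output names encode video stem, per-video group id and the buffered frame
    range: ``<stem>_g<group>_f<start>-<end><suffix>``. The container suffix
    defaults to the source video's own.
    """
    out_dir = Path(out_dir)
    requests = []
    for ev in events:
        if ev.buffered_start is None or ev.buffered_end is None:
            raise ArgumentError(
                "events must be buffered (buffer_and_clamp) before segmenting"
            )
        suffix = container_suffix or ev.video.path.suffix
        name = (
            f"{ev.video.path.stem}_g{ev.group_id}"
            f"_f{ev.buffered_start}-{ev.buffered_end}{suffix}"
        )
        requests.append(
            SegmentRequest(
                video=ev.video,
                start_frame=ev.buffered_start,
                end_frame=ev.buffered_end,
                output_path=out_dir / name,
            )
        )
    return requests


def write_events(
    events: Sequence[DetectionEvent],
    out_dir: Path | str,
    mode: str = "reencode",
    container_suffix: str | None = None,
) -> pd.DataFrame:
    """Write one clip per event; returns the segment manifest.

    Per-event I/O failures are logged and recorded in the manifest's
    ``error`` column while the remaining events continue; an empty event list
    is a success with an empty manifest.
    """
    requests = segment_events(events, out_dir, container_suffix)
    rows = []
    for ev, req in zip(events, requests):
        error = ""
        try:
            write_segment(req, mode=mode)
        except OSError as exc:
            logger.error("failed to write %s: %s", req.output_path, exc)
            error = str(exc)
        rows.append(
            {
                "video_path": str(ev.video.path),
                "group_id": ev.group_id,
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
                "buffered_start": ev.buffered_start,
                "buffered_end": ev.buffered_end,
                "n_samples": ev.n_members,
                "clip_path": str(req.output_path),
                "error": error,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "video_path", "group_id", "start_frame", "end_frame",
            "buffered_start", "buffered_end", "n_samples", "clip_path", "error",
        ],
    )


def run_segmentation(
    predictions: Sequence[Prediction], cfg: SegmentationConfig
) -> list[DetectionEvent]:
    """Filter → group → buffer in one call; returns buffered events."""
    kept = filter_predictions(predictions, cfg.threshold)
    events = [buffer_and_clamp(ev, cfg) for ev in group_adjacent(kept)]
    if cfg.merge_overlaps:
        events = _merge_overlapping(events)
    return events
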