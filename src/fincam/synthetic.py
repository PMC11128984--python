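"""Seeded synthetic fixtures: rendered scenes with a moving bright "fish",
probability streams with planted above-threshold runs, and two-folder
training sets — all with exact ground truth, so every pipeline stage can be
exercised end-to-end without real footage.

The rendered scene emulates fixed underwater surveillance of a stream bed: a
static mid-gray background with a mild illumination gradient, per-frame
Gaussian noise standing in for turbidity/white-water, and — during configured
presence intervals — a bright moving ellipse standing in for a salmonid
passing the camera. Real footage adds blur, bubbles, debris and partial
fish; what passes here demonstrates the plumbing and the event algorithm,
not real-water classification accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ArgumentError
from .media_io import VideoMeta, chrono_key_for, frame_number_for_sample, write_video

__all__ = [
    "SceneConfig",
    "StreamConfig",
    "scene_frames",
    "render_video",
    "fish_frame_ranges",
    "generate_probability_stream",
    "build_training_set",
]

BACKGROUND_MEAN = 60.0  # stream-bed gray level
FISH_INTENSITY = 230.0  # bright salmonid flank


def _glare_sd(noise_level: float) -> float:
    """Scene-level luminance fluctuation (white-water glare episodes) that
    accompanies pixel noise. Grows quadratically with ``noise_level`` so the
    default regime is essentially glare-free while very turbid settings also
    swing whole-frame brightness — the mechanism that makes class overlap
    (and hence mean-intensity separability) controllable by one knob."""
    return noise_level**2 / 1600.0


@dataclass(frozen=True)
class SceneConfig:
    """One synthetic recording chunk.

    Defaults: 10 s at 20 fps (the NVR recording rate the pipeline's frame
    maths are usually run at), 160×90 grayscale working resolution, noise
    standard deviation 12 gray levels. ``fish_intervals`` are half-open
    ``[start_s, end_s)`` presence windows, sorted and non-overlapping.
    """

    duration_s: float = 10.0
    fps: float = 20.0
    resolution: tuple[int, int] = (160, 90)  # (width, height)
    fish_intervals: tuple[tuple[float, float], ...] = ()
    noise_level: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ArgumentError("duration_s and fps must be positive")
        if self.noise_level < 0:
            raise ArgumentError("noise_level must be >= 0")
        prev_end = 0.0
        for start, end in self.fish_intervals:
            if not 0 <= start < end <= self.duration_s:
                raise ArgumentError(
                    f"interval ({start}, {end}) outside [0, {self.duration_s}]"
                )
            if start < prev_end:
                raise ArgumentError("fish_intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def total_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


def _fish_present(cfg: SceneConfig, frame_number: int) -> bool:
    t = (frame_number - 1) / cfg.fps
    return any(start <= t < end for start, end in cfg.fish_intervals)


def fish_frame_ranges(cfg: SceneConfig) -> list[tuple[int, int]]:
    """Exact 1-based frame ranges containing the object, one per interval:
    frame ``f`` holds the fish iff its timestamp ``(f-1)/fps`` falls in
    ``[start_s, end_s)``."""
    ranges = []
    for start_s, end_s in cfg.fish_intervals:
        first = math.floor(start_s * cfg.fps) + 1
        last = math.ceil(end_s * cfg.fps)
        last = min(last, cfg.total_frames)
        if first <= last:
            ranges.append((first, last))
    return ranges


def scene_frames(cfg: SceneConfig) -> np.ndarray:
    """Render all frames as a ``(T, H, W)`` uint8 array, fully seeded:
    identical configs give byte-identical arrays (pre-encoding)."""
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.resolution
    total = cfg.total_frames
    x = np.linspace(0.0, 15.0, w)[None, :]
    gradient = np.repeat(x, h, axis=0)  # mild horizontal illumination ramp
    frames = np.empty((total, h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    ax, ay = max(2.0, 0.10 * w), max(1.5, 0.055 * h)  # ellipse semi-axes
    glare_sd = _glare_sd(cfg.noise_level)
    for f in range(1, total + 1):
        img = (
            BACKGROUND_MEAN
            + gradient
            + rng.normal(0.0, glare_sd)  # whole-frame luminance swing
            + rng.normal(0.0, cfg.noise_level, size=(h, w))
        )
        if _fish_present(cfg, f):
            # object swims left->right over each presence interval with a
            # slight vertical sway, like a fish crossing the field of view
            for start_s, end_s in cfg.fish_intervals:
                t = (f - 1) / cfg.fps
                if not start_s <= t < end_s:
                    continue
                progress = (t - start_s) / (end_s - start_s)
                cx = ax + progress * (w - 2 * ax)
                cy = h / 2 + 0.15 * h * math.sin(2 * math.pi * progress)
                ellipse = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
                img[ellipse] = FISH_INTENSITY
        frames[f - 1] = np.clip(img, 0, 255).astype(np.uint8)
    return frames


def render_video(
    cfg: SceneConfig, out_path: Path | str, manifest_path: Path | str | None = None
) -> tuple[VideoMeta, pd.DataFrame]:
    """Encode the scene to ``out_path`` (.tif or .gif) and write the
    ground-truth manifest (video_path, start_frame, end_frame — one row per
    presence interval, at frame resolution)."""
    out_path = Path(out_path)
    meta = write_video(out_path, scene_frames(cfg), cfg.fps)
    manifest = pd.DataFrame(
        [
            {"video_path": str(out_path), "start_frame": s, "end_frame": e}
            for s, e in fish_frame_ranges(cfg)
        ],
        columns=["video_path", "start_frame", "end_frame"],
    )
    if manifest_path is not None:
        manifest.to_csv(manifest_path, index=False)
    return meta, manifest


# ---------------------------------------------------------------------------
# probability streams


@dataclass(frozen=True)
class StreamConfig:
    """A chronologically ordered batch of per-frame score sequences with
    planted above-threshold runs.

    ``planted_runs[v]`` lists ``(start_index, length, p_level)`` runs for
    video ``v`` (1-based sample indices). Background scores draw uniformly
    from ``base_noise = (low, high)``; planted samples score exactly
    ``p_level``. Runs must stay below/above the intended threshold for the
    ground truth to be exact, and consecutive runs must leave a gap of at
    least one sample so they do not coalesce into one event.
    """

    n_videos: int = 3
    samples_per_video: int = 120
    planted_runs: tuple[tuple[tuple[int, int, float], ...], ...] = ()
    base_noise: tuple[float, float] = (0.0, 0.30)
    interval_s: float = 20.0
    fps: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_videos < 1 or self.samples_per_video < 1:
            raise ArgumentError("n_videos and samples_per_video must be >= 1")
        low, high = self.base_noise
        if not 0.0 <= low <= high <= 1.0:
            raise ArgumentError(f"invalid base_noise range: {self.base_noise}")
        if len(self.planted_runs) > self.n_videos:
            raise ArgumentError("more planted-run lists than videos")
        for runs in self.planted_runs:
            prev_end = -1  # first run may start at sample 1
            for start, length, p_level in runs:
                if length < 1 or start < 1:
                    raise ArgumentError(f"invalid run ({start}, {length})")
                if start + length - 1 > self.samples_per_video:
                    raise ArgumentError(
                        f"run ({start}, {length}) exceeds {self.samples_per_video} samples"
                    )
                if start <= prev_end + 1:
                    raise ArgumentError(
                        "planted runs must be sorted with a gap of >= 1 sample"
                    )
                if not high < p_level <= 1.0:
                    raise ArgumentError(
                        f"p_level {p_level} must exceed base noise high {high}"
                    )
                prev_end = start + length - 1


def generate_probability_stream(
    cfg: StreamConfig, csv_path: Path | str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the prediction stream and its ground truth.

    Returns ``(predictions, truth)``: predictions in the shared
    prediction-CSV dialect (manifest columns + ``p_fish``), chronologically
    ordered with batch-wide ``global_order``; truth has one row per planted
    run (video_path, start_sample, end_sample, start_frame, end_frame) — the
    exact events thresholding between ``base_noise[1]`` and the lowest
    ``p_level`` must recover.
    """
    rng = np.random.default_rng(cfg.seed)
    stride = max(1, round(cfg.fps * cfg.interval_s))
    total_frames = cfg.samples_per_video * stride
    low, high = cfg.base_noise
    pred_rows, truth_rows = [], []
    order = 1
    for v in range(cfg.n_videos):
        video_path = f"20230726_{v:02d}0000_cam1.tif"
        runs = cfg.planted_runs[v] if v < len(cfg.planted_runs) else ()
        p = rng.uniform(low, high, size=cfg.samples_per_video)
        for start, length, p_level in runs:
            p[start - 1 : start - 1 + length] = p_level
        for i in range(1, cfg.samples_per_video + 1):
            pred_rows.append(
                {
                    "video_path": video_path,
                    "fps": cfg.fps,
                    "total_frames": total_frames,
                    "sample_index": i,
                    "frame_number": frame_number_for_sample(i, cfg.interval_s, cfg.fps),
                    "image_path": "",
                    "global_order": order,
                    "p_fish": float(p[i - 1]),
                }
            )
            order += 1
        for start, length, p_level in runs:
            end = start + length - 1
            truth_rows.append(
                {
                    "video_path": video_path,
                    "start_sample": start,
                    "end_sample": end,
                    "start_frame": frame_number_for_sample(start, cfg.interval_s, cfg.fps),
                    "end_frame": frame_number_for_sample(end, cfg.interval_s, cfg.fps),
                }
            )
    predictions = pd.DataFrame(pred_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["video_path", "start_sample", "end_sample", "start_frame", "end_frame"],
    )
    if csv_path is not None:
        predictions.to_csv(csv_path, index=False)
    return predictions, truth


# ---------------------------------------------------------------------------
# training sets


def build_training_set(
    out_root: Path | str,
    n_fish: int = 200,
    n_nofish: int = 200,
    noise_level: float = 12.0,
    resolution: tuple[int, int] = (160, 90),
    seed: int = 0,
) -> dict[str, int]:
    """Write a two-folder image dataset: ``fish/`` frames containing the
    bright object at random positions, ``no_fish/`` background-only frames.

    Separability is controlled by ``noise_level``: at the default the two
    classes are cleanly separated by mean intensity; at very high noise the
    classes overlap and any classifier approaches chance. Returns the class
    counts.
    """
    if n_fish < 1 or n_nofish < 1:
        raise ArgumentError("n_fish and n_nofish must be >= 1")
    out_root = Path(out_root)
    rng = np.random.default_rng(seed)
    w, h = resolution
    yy, xx = np.mgrid[0:h, 0:w]
    ax, ay = max(2.0, 0.10 * w), max(1.5, 0.055 * h)

    glare_sd = _glare_sd(noise_level)

    def background() -> np.ndarray:
        grad = np.repeat(np.linspace(0.0, 15.0, w)[None, :], h, axis=0)
        return (
            BACKGROUND_MEAN
            + grad
            + rng.normal(0.0, glare_sd)
            + rng.normal(0.0, noise_level, size=(h, w))
        )

    for label, n, with_fish in ((
        "fish", n_fish, True), ("no_fish", n_nofish, False)):
        folder = out_root / label
        folder.mkdir(parents=True, exist_ok=True)
        for k in range(n):
            img = background()
            if with_fish:
                cx = rng.uniform(ax, w - ax)
                cy = rng.uniform(ay, h - ay)
                ellipse = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
                img[ellipse] = FISH_INTENSITY
            Image.fromarray(np.clip(img, 0, 255).astype(np.uint8)).save(
                folder / f"{label}_{k:05d}.png"
            )
    return {"fish": n_fish, "no_fish": n_nofish}
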