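"""Shared fixtures and oracles for the fincam test suite.

All fixture data is generated programmatically (synthetic scenes, planted
probability streams); nothing is read from outside the repository.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from fincam import (
    FrameSample,
    Prediction,
    SceneConfig,
    VideoMeta,
    build_training_set,
    frame_number_for_sample,
    render_video,
)
from fincam.media_io import chrono_key_for


def make_meta(
    path: str = "20230726_050000_cam.tif",
    fps: float = 20.0,
    total_frames: int = 48000,
) -> VideoMeta:
    return VideoMeta(
        path=Path(path), fps=fps, total_frames=total_frames,
        chrono_key=chrono_key_for(path),
    )


def predictions_from_scores(
    scores_by_video: dict[str, list[float]],
    interval_s: float = 20.0,
    fps: float = 20.0,
) -> list[Prediction]:
    """Build a chronologically ordered prediction stream from per-video score
    lists (videos taken in the given order)."""
    out: list[Prediction] = []
    order = 1
    stride = max(1, round(fps * interval_s))
    for path, scores in scores_by_video.items():
        meta = make_meta(path, fps, total_frames=max(1, len(scores)) * stride)
        for i, p in enumerate(scores, start=1):
            sample = FrameSample(
                video=meta,
                sample_index=i,
                frame_number=frame_number_for_sample(i, interval_s, fps),
                image_path=None,
                global_order=order,
            )
            out.append(Prediction(sample=sample, p_fish=p))
            order += 1
    return out


def rle_runs(flags: list[bool]) -> list[tuple[int, int]]:
    """Brute-force run-length encoder: maximal runs of True as (start, end)
    0-based inclusive index pairs. The independent oracle for adjacency
    grouping."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(flags):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


@pytest.fixture(scope="session")
def training_set_dir(tmp_path_factory) -> Path:
    """Separable two-folder dataset: 200 bright-object frames vs 200
    background-only frames at the default noise level."""
    root = tmp_path_factory.mktemp("trainset")
    build_training_set(root, n_fish=200, n_nofish=200, seed=3)
    return root


@pytest.fixture(scope="session")
def scene_assets(tmp_path_factory):
    """A rendered 10 s, 20 fps scene with one fish interval [2 s, 4 s) plus
    its probed metadata and ground-truth manifest."""
    root = tmp_path_factory.mktemp("scene")
    cfg = SceneConfig(
        duration_s=10.0, fps=20.0, fish_intervals=((2.0, 4.0),), seed=7
    )
    path = root / "20230726_050000_cam1.tif"
    meta, manifest = render_video(cfg, path)
    return {"cfg": cfg, "path": path, "meta": meta, "manifest": manifest}
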