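"""Video probing, frame thinning, frame-index bookkeeping and clip writing.

Surveillance footage arrives as one file per recording chunk. The pipeline
needs four media primitives:

* :func:`probe_video` — frame rate and total frame count of a file, plus a
  chronological sort key parsed from its filename;
* :func:`thin_video` — extract one still per fixed time interval ("thinning",
  e.g. one frame every 20 s), keeping the source frame number of every still
  so detections can be mapped back to the video;
* :func:`frame_number_for_sample` — the closed-form sample→frame mapping;
* :func:`write_segment` — cut a frame-accurate sub-clip ``[start, end]``.

Frame indices are 1-based throughout. Sample ``i`` is anchored at the first
frame of its interval: ``frame = (i - 1) * round(fps * interval_s) + 1``.

Containers are handled by pluggable backends. ImageJ-TIFF stacks (``.tif``,
lossless, exact fps metadata) and GIF (``.gif``) are decoded in-process;
MP4/MKV/AVI/MOV route through the ``ffmpeg``/``ffprobe`` binaries when they
are on PATH.
"""

from __future__ import annotations

import json
import math
import re
import shutil
import subprocess
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ArgumentError, CapabilityError, ProbeError, WriteError

__all__ = [
    "VideoMeta",
    "FrameSample",
    "SegmentRequest",
    "probe_video",
    "thin_video",
    "thin_batch",
    "thin_plan",
    "frame_number_for_sample",
    "write_segment",
    "read_frames",
    "write_video",
    "chrono_key_for",
    "samples_to_frame",
    "write_manifest",
    "read_manifest",
    "DEFAULT_TIMESTAMP_PATTERN",
]

#: Default filename timestamp pattern: ``YYYYMMDD[_-]HHMMSS`` with optional
#: separators, the layout most NVRs use when exporting per-chunk files.
DEFAULT_TIMESTAMP_PATTERN = (
    r"(?P<Y>\d{4})[-_.]?(?P<m>\d{2})[-_.]?(?P<d>\d{2})"
    r"[T _-]?(?P<H>\d{2})[-_.:]?(?P<M>\d{2})[-_.:]?(?P<S>\d{2})"
)

_FFMPEG_SUFFIXES = {".mp4", ".mkv", ".avi", ".mov", ".m4v", ".h264", ".ts"}


@dataclass(frozen=True)
class VideoMeta:
    """Probed facts about one video file.

    ``chrono_key`` totally orders the files of a batch: a timestamp string
    parsed from the filename, tie-broken by the path itself.
    ``frame_count_estimated`` flags a total derived from duration × fps when
    the container does not report an exact frame count.
    """

    path: Path
    fps: float
    total_frames: int
    chrono_key: tuple[str, str]
    frame_count_estimated: bool = False

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ArgumentError(f"fps must be positive, got {self.fps}")
        if self.total_frames < 1:
            raise ArgumentError(
                f"total_frames must be >= 1, got {self.total_frames}"
            )

    @property
    def duration_s(self) -> float:
        return self.total_frames / self.fps


@dataclass(frozen=True)
class FrameSample:
    """One thinned frame: its still image, position within the video's sample
    sequence (1-based) and the source frame it was taken from."""

    video: VideoMeta
    sample_index: int
    frame_number: int
    image_path: Path | None = None
    global_order: int | None = None


@dataclass(frozen=True)
class SegmentRequest:
    """A frame-accurate cut ``[start_frame, end_frame]`` (inclusive, 1-based)
    of one video, to be written to ``output_path``."""

    video: VideoMeta
    start_frame: int
    end_frame: int
    output_path: Path

    def __post_init__(self) -> None:
        if not 1 <= self.start_frame <= self.end_frame <= self.video.total_frames:
            raise ArgumentError(
                f"segment [{self.start_frame}, {self.end_frame}] out of bounds "
                f"for {self.video.path} with {self.video.total_frames} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def chrono_key_for(
    path: Path | str, pattern: str = DEFAULT_TIMESTAMP_PATTERN
) -> tuple[str, str]:
    """Sort key for chronological ordering of a batch of video files.

    The first match of ``pattern`` in the file stem is normalised to
    ``YYYYMMDDHHMMSS`` (named groups) or concatenated digits (plain groups);
    files without a match sort by empty timestamp. Ties break lexicographically
    on the full path.
    """
    path = Path(path)
    m = re.search(pattern, path.stem)
    if m is None:
        stamp = ""
    elif m.groupdict():
        g = m.groupdict()
        stamp = "".join(g[k] for k in ("Y", "m", "d", "H", "M", "S") if k in g)
    else:
        stamp = "".join(m.groups()) if m.groups() else m.group(0)
    return (stamp, str(path))


# ---------------------------------------------------------------------------
# container backends


class _TiffBackend:
    """ImageJ-style TIFF stacks: lossless frames, fps in ImageJ metadata."""

    suffixes = (".tif", ".tiff")

    @staticmethod
    def probe(path: Path) -> tuple[float, int, bool]:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            n = len(tf.pages)
            meta = tf.imagej_metadata or {}
            fps = meta.get("fps")
            if fps is None and meta.get("finterval"):
                fps = 1.0 / float(meta["finterval"])
            if fps is None:
                raise ProbeError(f"no frame-rate metadata in {path}")
            return float(fps), n, False

    @staticmethod
    def read(path: Path, indices: Sequence[int]) -> list[np.ndarray]:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            return [tf.pages[i - 1].asarray() for i in indices]

    @staticmethod
    def write(path: Path, frames: np.ndarray, fps: float) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            np.asarray(frames),
            imagej=True,
            metadata={"fps": float(fps), "axes": "TYX"},
        )


class _GifBackend:
    """Animated GIF via Pillow; fps from the per-frame duration (ms)."""

    suffixes = (".gif",)

    @staticmethod
    def probe(path: Path) -> tuple[float, int, bool]:
        with Image.open(path) as im:
            n = getattr(im, "n_frames", 1)
            duration_ms = im.info.get("duration") or 0
        if duration_ms <= 0:
            raise ProbeError(f"no frame-duration metadata in {path}")
        return 1000.0 / duration_ms, n, False

    @staticmethod
    def read(path: Path, indices: Sequence[int]) -> list[np.ndarray]:
        out = []
        with Image.open(path) as im:
            for i in indices:
                im.seek(i - 1)
                out.append(np.asarray(im.convert("L")))
        return out

    @staticmethod
    def write(path: Path, frames: np.ndarray, fps: float) -> None:
        ims = [Image.fromarray(np.asarray(f)) for f in frames]
        ims[0].save(
            path,
            save_all=True,
            append_images=ims[1:],
            duration=round(1000.0 / fps),
            loop=0,
        )


class _FfmpegBackend:
    """MP4/MKV/... through the ffmpeg and ffprobe binaries."""

    suffixes = tuple(_FFMPEG_SUFFIXES)

    @staticmethod
    def available() -> bool:
        return shutil.which("ffprobe") is not None and shutil.which("ffmpeg") is not None

    @staticmethod
    def probe(path: Path) -> tuple[float, int, bool]:
        cmd = [
            "ffprobe", "-v", "error", "-select_streams", "v:0",
            "-show_entries", "stream=nb_frames,avg_frame_rate,duration",
            "-of", "json", str(path),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ProbeError(f"ffprobe failed for {path}: {proc.stderr.strip()}")
        streams = json.loads(proc.stdout).get("streams") or []
        if not streams:
            raise ProbeError(f"no video stream in {path}")
        s = streams[0]
        num, _, den = (s.get("avg_frame_rate") or "0/1").partition("/")
        fps = float(num) / float(den or 1) if float(den or 1) else 0.0
        if fps <= 0:
            raise ProbeError(f"undetermined frame rate for {path}")
        nb = s.get("nb_frames")
        if nb and str(nb).isdigit():
            return fps, int(nb), False
        # container without an exact count: fall back to duration x fps
        duration = float(s.get("duration") or 0.0)
        if duration <= 0:
            raise ProbeError(f"cannot determine frame count of {path}")
        return fps, int(round(duration * fps)), True

    @staticmethod
    def extract_still_cmd(path: Path, frame_number: int, out: Path) -> list[str]:
        return [
            "ffmpeg", "-y", "-v", "error", "-i", str(path),
            "-vf", f"select=eq(n\\,{frame_number - 1})",
            "-vframes", "1", str(out),
        ]

    @staticmethod
    def read(path: Path, indices: Sequence[int]) -> list[np.ndarray]:
        frames = []
        for i in indices:
            with _TempPng() as tmp:
                cmd = _FfmpegBackend.extract_still_cmd(path, i, tmp)
                proc = subprocess.run(cmd, capture_output=True, text=True)
                if proc.returncode != 0:
                    raise ProbeError(
                        f"ffmpeg frame extraction failed for {path}: "
                        f"{proc.stderr.strip()}"
                    )
                frames.append(np.asarray(Image.open(tmp)))
        return frames

    @staticmethod
    def segment_cmd(req: SegmentRequest, fps: float, mode: str) -> list[str]:
        """ffmpeg invocation for a cut; ``reencode`` selects frames exactly,
        ``copy`` seeks by time and snaps to keyframes (fast, approximate)."""
        base = ["ffmpeg", "-y", "-v", "error"]
        if mode == "reencode":
            return base + [
                "-i", str(req.video.path),
                "-vf",
                f"select=between(n\\,{req.start_frame - 1}\\,{req.end_frame - 1}),"
                "setpts=N/FRAME_RATE/TB",
                "-an", str(req.output_path),
            ]
        start_s = (req.start_frame - 1) / fps
        dur_s = req.n_frames / fps
        return base + [
            "-ss", f"{start_s:.6f}", "-i", str(req.video.path),
            "-t", f"{dur_s:.6f}", "-c", "copy", str(req.output_path),
        ]

    @staticmethod
    def write_segment(req: SegmentRequest, fps: float, mode: str) -> None:
        proc = subprocess.run(
            _FfmpegBackend.segment_cmd(req, fps, mode),
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise WriteError(
                f"ffmpeg segment write failed for {req.output_path}: "
                f"{proc.stderr.strip()}"
            )


class _TempPng:
    def __enter__(self) -> Path:
        import tempfile

        fd, name = tempfile.mkstemp(suffix=".png")
        import os

        os.close(fd)
        self._path = Path(name)
        return self._path

    def __exit__(self, *exc) -> None:
        self._path.unlink(missing_ok=True)


_IN_PROCESS_BACKENDS = (_TiffBackend, _GifBackend)


def _backend_for(path: Path):
    suffix = path.suffix.lower()
    for backend in _IN_PROCESS_BACKENDS:
        if suffix in backend.suffixes:
            return backend
    if suffix in _FFMPEG_SUFFIXES:
        if not _FfmpegBackend.available():
            raise CapabilityError(
                f"{suffix} containers require the ffmpeg/ffprobe binaries, "
                "which were not found on PATH; use a .tif/.gif container or "
                "install ffmpeg"
            )
        return _FfmpegBackend
    raise ProbeError(f"unrecognised video container: {path}")


# ---------------------------------------------------------------------------
# public operations


def probe_video(
    path: Path | str, timestamp_pattern: str = DEFAULT_TIMESTAMP_PATTERN
) -> VideoMeta:
    """Probe one video file: fps, total frame count and chronological key.

    Raises :class:`ProbeError` for unreadable or non-video files. When the
    container reports no exact frame count the total falls back to
    ``round(duration * fps)`` and ``frame_count_estimated`` is set.
    """
    path = Path(path)
    if not path.is_file():
        raise ProbeError(f"no such file: {path}")
    backend = _backend_for(path)
    try:
        fps, total, estimated = backend.probe(path)
    except (ProbeError, CapabilityError):
        raise
    except Exception as exc:  # decoder-specific failure
        raise ProbeError(f"cannot decode {path}: {exc}") from exc
    return VideoMeta(
        path=path,
        fps=fps,
        total_frames=total,
        chrono_key=chrono_key_for(path, timestamp_pattern),
        frame_count_estimated=estimated,
    )


def frame_number_for_sample(
    sample_index: int, interval_s: float, fps: float
) -> int:
    """1-based source frame of thinned sample ``sample_index``.

    Sample ``i`` is anchored at the first frame of its interval:
    ``(i - 1) * round(interval_s * fps) + 1``. The stride is rounded to the
    nearest whole frame so frame numbers stay integral and strictly
    increasing for non-integer ``fps * interval_s`` products.
    """
    if sample_index < 1:
        raise ArgumentError(f"sample_index must be >= 1, got {sample_index}")
    if interval_s <= 0 or fps <= 0:
        raise ArgumentError("interval_s and fps must be positive")
    stride = max(1, round(interval_s * fps))
    return (sample_index - 1) * stride + 1


def thin_plan(total_frames: int, fps: float, interval_s: float) -> list[int]:
    """Frame numbers thinning would extract, without touching any file.

    One sample per interval starting at frame 1; the count is
    ``(total_frames - 1) // stride + 1`` with ``stride = round(fps * interval_s)``.
    An interval longer than the video yields exactly one sample (frame 1).
    """
    if interval_s <= 0:
        raise ArgumentError(f"interval_s must be positive, got {interval_s}")
    if total_frames < 1 or fps <= 0:
        raise ArgumentError("total_frames must be >= 1 and fps positive")
    stride = max(1, round(fps * interval_s))
    n = (total_frames - 1) // stride + 1
    return [k * stride + 1 for k in range(n)]


def thin_video(
    video: VideoMeta,
    interval_s: float,
    out_dir: Path | str,
    image_format: str = "png",
) -> list[FrameSample]:
    """Extract one still per ``interval_s`` seconds of ``video``.

    Stills are written to ``out_dir`` as
    ``<stem>_s<sample_index>_f<frame_number>.<fmt>`` (PNG by default —
    lossless; JPEG optional). ``global_order`` is left unset; batch-level
    ordering is assigned by :func:`thin_batch`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame_numbers = thin_plan(video.total_frames, video.fps, interval_s)
    images = read_frames(video, frame_numbers)
    samples = []
    for i, (fn, img) in enumerate(zip(frame_numbers, images), start=1):
        dest = out_dir / f"{video.path.stem}_s{i}_f{fn}.{image_format}"
        Image.fromarray(np.asarray(img)).save(dest)
        samples.append(
            FrameSample(
                video=video, sample_index=i, frame_number=fn, image_path=dest
            )
        )
    return samples


def thin_batch(
    paths: Iterable[Path | str],
    interval_s: float,
    out_dir: Path | str,
    timestamp_pattern: str = DEFAULT_TIMESTAMP_PATTERN,
    image_format: str = "png",
) -> list[FrameSample]:
    """Probe and thin a batch of videos in chronological order.

    Videos are sorted by their filename-derived ``chrono_key``; samples get a
    batch-wide 1-based ``global_order`` so downstream stages can rely on a
    single chronological sequence.
    """
    metas = sorted(
        (probe_video(p, timestamp_pattern) for p in paths),
        key=lambda m: m.chrono_key,
    )
    if not metas:
        raise ArgumentError("no video files given")
    out: list[FrameSample] = []
    order = 1
    for meta in metas:
        for s in thin_video(meta, interval_s, out_dir, image_format):
            out.append(replace(s, global_order=order))
            order += 1
    return out


def read_frames(video: VideoMeta, frame_numbers: Sequence[int]) -> list[np.ndarray]:
    """Decode the given 1-based frames of ``video`` as arrays."""
    bad = [f for f in frame_numbers if not 1 <= f <= video.total_frames]
    if bad:
        raise ArgumentError(
            f"frame numbers {bad} out of bounds for {video.path} "
            f"({video.total_frames} frames)"
        )
    return _backend_for(video.path).read(video.path, frame_numbers)


def write_video(path: Path | str, frames: np.ndarray, fps: float) -> VideoMeta:
    """Encode a ``(T, H, W[, C])`` frame array to ``path`` (format from the
    suffix) and return the probed metadata of the written file."""
    path = Path(path)
    backend = _backend_for(path)
    if backend is _FfmpegBackend:
        raise CapabilityError(
            "writing ffmpeg containers from arrays is not supported; "
            "write a .tif or .gif stack"
        )
    try:
        backend.write(path, np.asarray(frames), fps)
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc
    return probe_video(path)


def write_segment(req: SegmentRequest, mode: str = "reencode") -> Path:
    """Write the clip described by ``req``; returns the output path.

    ``mode="reencode"`` guarantees exactly ``end - start + 1`` frames.
    ``mode="copy"`` (ffmpeg containers only) stream-copies from the nearest
    keyframe: fast, but start/end may be off by up to a GOP length.
    In-process containers (TIFF/GIF) are always frame-exact.
    """
    if mode not in ("reencode", "copy"):
        raise ArgumentError(f"unknown segment mode: {mode!r}")
    backend = _backend_for(req.video.path)
    req.output_path.parent.mkdir(parents=True, exist_ok=True)
    if backend is _FfmpegBackend:
        _FfmpegBackend.write_segment(req, req.video.fps, mode)
        return req.output_path
    frames = backend.read(
        req.video.path, range(req.start_frame, req.end_frame + 1)
    )
    out_backend = _backend_for(req.output_path)
    if out_backend is _FfmpegBackend:
        raise CapabilityError(
            "cannot write an ffmpeg container from an in-process source; "
            "choose a .tif or .gif output path"
        )
    try:
        out_backend.write(req.output_path, np.stack(frames), req.video.fps)
    except OSError as exc:
        raise WriteError(f"cannot write {req.output_path}: {exc}") from exc
    return req.output_path


# ---------------------------------------------------------------------------
# frame-sample manifest (the CSV hand-off between pipeline stages)

_MANIFEST_COLUMNS = [
    "video_path",
    "fps",
    "total_frames",
    "sample_index",
    "frame_number",
    "image_path",
    "global_order",
]


def samples_to_frame(samples: Sequence[FrameSample]) -> pd.DataFrame:
    rows = [
        {
            "video_path": str(s.video.path),
            "fps": s.video.fps,
            "total_frames": s.video.total_frames,
            "sample_index": s.sample_index,
            "frame_number": s.frame_number,
            "image_path": "" if s.image_path is None else str(s.image_path),
            "global_order": s.global_order,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)


def write_manifest(samples: Sequence[FrameSample], path: Path | str) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def read_manifest(path: Path | str) -> list[FrameSample]:
    """Reconstruct frame samples (with per-video metadata) from a manifest CSV."""
    df = pd.read_csv(path)
    missing = set(_MANIFEST_COLUMNS) - {"image_path"} - set(df.columns)
    if missing:
        raise ArgumentError(f"manifest {path} lacks columns: {sorted(missing)}")
    metas: dict[str, VideoMeta] = {}
    samples = []
    for row in df.itertuples(index=False):
        vp = str(row.video_path)
        if vp not in metas:
            metas[vp] = VideoMeta(
                path=Path(vp),
                fps=float(row.fps),
                total_frames=int(row.total_frames),
                chrono_key=chrono_key_for(vp),
            )
        image = getattr(row, "image_path", "")
        samples.append(
            FrameSample(
                video=metas[vp],
                sample_index=int(row.sample_index),
                frame_number=int(row.frame_number),
                image_path=Path(image) if isinstance(image, str) and image else None,
                global_order=int(row.global_order)
                if not math.isnan(float(row.global_order))
                else None,
            )
        )
    return samples
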