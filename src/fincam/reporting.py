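"""Probability-frequency reporting and the manual-review queue.

After batch prediction, each thinned frame carries a fish probability. For
evaluation the probabilities are multiplied by 100 and rounded to the nearest
whole percent, and frames are counted per (percent bin, recording date):
rows are the 101 integer percent bins, columns the dates, cells the image
counts. Row sums say how many images scored each percent overall; the grand
total is the number of images predicted.

A review queue collects every image at or above a percent cutoff (operating
default 3 %) for manual fish/no-fish verdicts — below the cutoff images are
too numerous and too uninformative to scrutinise. Saved verdicts can later
be folded back into the training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .classifier import Prediction
from .errors import ArgumentError, DataError
from .media_io import FrameSample, VideoMeta

__all__ = [
    "ProbabilityTable",
    "ReviewItem",
    "to_percent_bin",
    "build_probability_table",
    "table_marginals",
    "review_queue",
    "render_table",
    "date_from_chrono_key",
    "load_example_counts",
    "counts_to_pseudo_predictions",
    "save_review",
    "load_review",
]

PERCENT_BINS = range(101)


def to_percent_bin(p_fish: float) -> int:
    """Map a probability in [0, 1] to its integer percent bin 0–100.

    ``round(p * 100)`` with halves rounded away from zero (3.5 → 4), applied
    to the float value of ``p * 100``.
    """
    if math.isnan(p_fish) or not 0.0 <= p_fish <= 1.0:
        raise ArgumentError(f"p_fish must be in [0, 1], got {p_fish}")
    return int(math.floor(p_fish * 100.0 + 0.5))


@dataclass(frozen=True)
class ProbabilityTable:
    """Counts of predictions per integer percent bin per date.

    ``counts`` is a dense (101 × n_dates) integer frame — zero cells are
    retained so marginals and machine-readable output are complete; the
    human-readable render compresses to nonzero rows.
    """

    counts: pd.DataFrame  # index: bins 0..100; columns: date labels

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(PERCENT_BINS):
            raise ArgumentError("table index must be the percent bins 0..100")
        if (self.counts.to_numpy() < 0).any():
            raise ArgumentError("counts must be nonnegative")

    @property
    def dates(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class ReviewItem:
    """One image queued for manual scrutiny; ``verdict`` is None until a
    reviewer records 'fish' or 'no_fish'."""

    prediction: Prediction
    percent_bin: int
    verdict: str | None = field(default=None)


def date_from_chrono_key(video: VideoMeta) -> str:
    """Date label derived from the video's filename timestamp
    (``YYYYMMDD...`` → ``YYYY-MM-DD``); falls back to the file stem when no
    timestamp was parsed."""
    stamp = video.chrono_key[0]
    if len(stamp) >= 8:
        return f"{stamp[:4]}-{stamp[4:6]}-{stamp[6:8]}"
    return video.path.stem


DateOf = Mapping[FrameSample, str] | Callable[[FrameSample], str]


def _resolve_date(date_of: DateOf | None, sample: FrameSample) -> str:
    if date_of is None:
        return date_from_chrono_key(sample.video)
    if callable(date_of):
        return date_of(sample)
    try:
        return date_of[sample]
    except KeyError as exc:
        raise DataError(f"no date mapped for sample {sample}") from exc


def build_probability_table(
    predictions: Sequence[Prediction], date_of: DateOf | None = None
) -> ProbabilityTable:
    """Tabulate predictions into percent-bin × date counts.

    ``date_of`` maps a sample to its date label (mapping or callable); by
    default the date comes from the video's filename timestamp. Every
    prediction lands in exactly one cell; missing (NaN) scores are a data
    error here because an unscored image has no bin.
    """
    cells: dict[tuple[int, str], int] = {}
    dates: list[str] = []
    for p in predictions:
        if math.isnan(p.p_fish):
            raise DataError(f"prediction for {p.sample.image_path} has no score")
        date = _resolve_date(date_of, p.sample)
        if date not in dates:
            dates.append(date)
        key = (to_percent_bin(p.p_fish), date)
        cells[key] = cells.get(key, 0) + 1
    counts = pd.DataFrame(0, index=list(PERCENT_BINS), columns=dates, dtype=int)
    for (b, date), n in cells.items():
        counts.loc[b, date] = n
    return ProbabilityTable(counts=counts)


def table_marginals(
    table: ProbabilityTable,
) -> tuple[pd.Series, pd.Series, int]:
    """Row sums (images per percent bin), column sums (images per date) and
    the grand total; the two marginal sums always agree with the total."""
    row_sums = table.counts.sum(axis=1)
    col_sums = table.counts.sum(axis=0)
    return row_sums, col_sums, int(row_sums.sum())


def review_queue(
    predictions: Sequence[Prediction],
    min_percent: int = 3,
    date_of: DateOf | None = None,
) -> list[ReviewItem]:
    """Images whose percent bin is at or above ``min_percent``, ordered by
    percent descending then chronologically — highest-scoring images first.
    Missing scores never enter the queue."""
    if not 0 <= min_percent <= 100:
        raise ArgumentError(f"min_percent must be in [0, 100]: {min_percent}")
    items = [
        ReviewItem(prediction=p, percent_bin=to_percent_bin(p.p_fish))
        for p in predictions
        if not math.isnan(p.p_fish) and to_percent_bin(p.p_fish) >= min_percent
    ]
    items.sort(
        key=lambda it: (
            -it.percent_bin,
            it.prediction.sample.global_order
            if it.prediction.sample.global_order is not None
            else 0,
        )
    )
    return items


def render_table(table: ProbabilityTable) -> str:
    """Human-readable table: only nonzero percent rows, plus a total row."""
    nz = table.counts[table.counts.sum(axis=1) > 0]
    shown = nz.copy()
    shown.index.name = "percent"
    lines = [shown.to_string()]
    totals = table.counts.sum(axis=0)
    lines.append(
        "total    " + "  ".join(str(int(v)) for v in totals.to_numpy())
        + f"   (grand total {table.grand_total})"
    )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# packaged example counts


def load_example_counts() -> ProbabilityTable:
    """Packaged per-date percent-bin frequencies from a six-day salmon
    monitoring campaign (Mörrumsån, 2023-07-22 to 2023-07-27; one thinned
    frame every 20 s over 16 recording hours per day). Useful as a realistic
    reporting fixture and as the scale reference for the review-queue rule.
    """
    ref = resources.files("fincam").joinpath("data/morrumsan_july_counts.csv")
    with resources.as_file(ref) as path:
        long = pd.read_csv(path)
    dates = sorted(long["date"].unique())
    counts = pd.DataFrame(0, index=list(PERCENT_BINS), columns=dates, dtype=int)
    for row in long.itertuples(index=False):
        counts.loc[int(row.percent), str(row.date)] += int(row.count)
    return ProbabilityTable(counts=counts)


def counts_to_pseudo_predictions(
    table: ProbabilityTable,
) -> tuple[list[Prediction], dict[FrameSample, str]]:
    """Expand a counts table into one pseudo-prediction per counted image
    (probability = bin / 100), with the sample→date mapping; lets the full
    tabulation path be exercised against known marginals."""
    predictions: list[Prediction] = []
    date_of: dict[FrameSample, str] = {}
    order = 1
    for date in table.dates:
        video = VideoMeta(
            path=Path(f"{date.replace('-', '')}_000000_pseudo.tif"),
            fps=20.0,
            total_frames=1_152_000,
            chrono_key=(date.replace("-", "") + "000000", date),
        )
        sample_idx = 1
        for b in PERCENT_BINS:
            for _ in range(int(table.counts.loc[b, date])):
                sample = FrameSample(
                    video=video,
                    sample_index=sample_idx,
                    frame_number=(sample_idx - 1) * 400 + 1,
                    global_order=order,
                )
                predictions.append(Prediction(sample=sample, p_fish=b / 100.0))
                date_of[sample] = date
                sample_idx += 1
                order += 1
    return predictions, date_of


# ---------------------------------------------------------------------------
# review persistence


def save_review(items: Sequence[ReviewItem], path: Path | str) -> None:
    """Persist the queue (with any verdicts) to a CSV sidecar."""
    pd.DataFrame(
        [
            {
                "image_path": str(it.prediction.sample.image_path or ""),
                "percent_bin": it.percent_bin,
                "verdict": it.verdict or "",
            }
            for it in items
        ],
        columns=["image_path", "percent_bin", "verdict"],
    ).to_csv(path, index=False)


def load_review(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    needed = {"image_path", "percent_bin", "verdict"}
    if not needed <= set(df.columns):
        raise ArgumentError(f"{path} is not a review sidecar")
    return df
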