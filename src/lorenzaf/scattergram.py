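"""Lorenz-scattergram construction: windowing, labeling, rasterization.

A Lorenz scattergram (Poincaré plot) plots each consecutive RR-interval
pair ``(RR_n, RR_{n+1})`` as a point in the plane; homogeneous rhythms
form characteristic attractors (a tight diagonal dot for sinus rhythm, a
diffuse fan for AF, off-diagonal lobes for ectopy).  Records are cut into
sliding windows of 85 R waves; each window becomes one 32x32 occupancy
grid.  A window of 85 beats yields 84 intervals and hence 83 points, so
every non-binarized grid sums to exactly 83.

A window is labeled AF when it contains a maximal run of consecutive
AF-labeled beats spanning at least 30 seconds (first to last beat of the
run); otherwise non-AF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import BeatClass, RRRecord

__all__ = [
    "WINDOW_BEATS",
    "AUGMENT_STEP",
    "LSWindow",
    "LSImage",
    "RasterSpec",
    "cut_windows",
    "label_window",
    "rasterize",
    "record_to_images",
    "split_dataset",
    "images_to_array",
]

WINDOW_BEATS = 85   # window width in R waves
AUGMENT_STEP = 9    # sliding step in R waves when augmenting


@dataclass
class LSWindow:
    """One window of consecutive beats from a parent record."""

    record_id: str
    window_index: int
    beat_times: np.ndarray
    beat_labels: list[BeatClass]
    start_beat: int

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_labels) != len(self.beat_times):
            raise ValueError("beat_labels length mismatch")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("window beat_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beat_times)


@dataclass
class LSImage:
    """Rasterized scattergram: per-cell point counts plus provenance."""

    grid: np.ndarray
    label: BeatClass
    record_id: str
    window_index: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be square")
        if np.any(self.grid < 0):
            raise ValueError("grid cells must be non-negative")


@dataclass(frozen=True)
class RasterSpec:
    """Rasterization geometry.

    RR values are mapped linearly onto ``grid_size`` bins over
    ``[rr_min_s, rr_max_s)``; out-of-range values clamp to the edge bins.
    ``binarize`` collapses counts to 0/1 occupancy after counting.
    """

    grid_size: int = 32
    rr_min_s: float = 0.0
    rr_max_s: float = 2.0
    binarize: bool = False

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.rr_max_s <= self.rr_min_s:
            raise ValueError("rr_max_s must exceed rr_min_s")

    def bin_index(self, rr: np.ndarray) -> np.ndarray:
        """floor-binning with edge clamping (half-open bins)."""
        x = (np.asarray(rr, dtype=float) - self.rr_min_s) / (self.rr_max_s - self.rr_min_s)
        return np.clip(np.floor(x * self.grid_size).astype(int), 0, self.grid_size - 1)


def cut_windows(record: RRRecord, width: int = WINDOW_BEATS,
                step: int = AUGMENT_STEP) -> list[LSWindow]:
    """Slide a ``width``-beat window over the record at ``step`` beats.

    Windows start at beat offsets 0, step, 2*step, ...; trailing beats that
    cannot fill a whole window are dropped.  A record shorter than
    ``width`` yields an empty list.
    """
    if width < 3:
        raise ValueError("width must be >= 3 beats")
    if step < 1:
        raise ValueError("step must be >= 1 beat")
    n = len(record)
    out: list[LSWindow] = []
    for w, start in enumerate(range(0, n - width + 1, step)):
        out.append(LSWindow(
            record_id=record.record_id,
            window_index=w,
            beat_times=record.beat_times[start:start + width],
            beat_labels=list(record.beat_labels[start:start + width]),
            start_beat=start,
        ))
    return out


def label_window(window: LSWindow, min_af_span_s: float = 30.0) -> BeatClass:
    """AF iff some maximal run of consecutive AF beats spans >= 30 s.

    Span is measured from the first to the last beat of the run; two AF
    runs separated by even one non-AF beat are judged separately.
    """
    af = np.asarray([lbl is BeatClass.AF or lbl == BeatClass.AF
                     for lbl in window.beat_labels], dtype=bool)
    if not af.any():
        return BeatClass.NON_AF
    padded = np.concatenate(([False], af, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    spans = window.beat_times[ends] - window.beat_times[starts]
    return BeatClass.AF if np.any(spans >= min_af_span_s) else BeatClass.NON_AF


def rasterize(window: LSWindow, spec: RasterSpec = RasterSpec(),
              min_af_span_s: float = 30.0) -> LSImage:
    """Bin the window's (RR_n, RR_{n+1}) pairs into the occupancy grid.

    RR_n indexes the first grid axis and RR_{n+1} the second; an 85-beat
    window contributes exactly 83 points.
    """
    rr = np.diff(window.beat_times)
    i = spec.bin_index(rr[:-1])
    j = spec.bin_index(rr[1:])
    grid = np.zeros((spec.grid_size, spec.grid_size), dtype=np.int32)
    np.add.at(grid, (i, j), 1)
    if spec.binarize:
        grid = (grid > 0).astype(np.int32)
    return LSImage(
        grid=grid,
        label=label_window(window, min_af_span_s),
        record_id=window.record_id,
        window_index=window.window_index,
    )


def record_to_images(record: RRRecord, spec: RasterSpec = RasterSpec(),
                     augment: bool = False, min_af_span_s: float = 30.0) -> list[LSImage]:
    """Cut a record into windows and rasterize each.

    ``augment=True`` uses the sliding 9-beat step (overlapping windows,
    used to enlarge training data); otherwise windows are non-overlapping
    (step = window width), the deployment/evaluation setting.
    """
    step = AUGMENT_STEP if augment else WINDOW_BEATS
    return [rasterize(w, spec, min_af_span_s)
            for w in cut_windows(record, WINDOW_BEATS, step)]


def split_dataset(images: Sequence[LSImage], train_fraction: float = 0.9,
                  seed: int = 0) -> tuple[list[LSImage], list[LSImage]]:
    """Random disjoint/exhaustive train-validation split at image level.

    Sizes are ``round(train_fraction * n)`` and the remainder.  The split
    is at image level, so overlapping windows of one record can land on
    both sides; split at record level beforehand if leakage matters.
    """
    n = len(images)
    if n < 2:
        raise ValueError("need at least 2 images to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = set(perm[:n_train].tolist())
    train = [img for k, img in enumerate(images) if k in train_idx]
    val = [img for k, img in enumerate(images) if k not in train_idx]
    return train, val


def images_to_array(images: Iterable[LSImage],
                    scale: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stack images into ``(X, y)`` arrays for the classifier.

    ``X`` has shape (n, 1, G, G), float32; with ``scale`` each grid is
    divided by its max cell count (occupancy in [0, 1]).  ``y`` is 1 for
    AF, 0 for non-AF.
    """
    imgs = list(images)
    if not imgs:
        g = RasterSpec().grid_size
        return np.zeros((0, 1, g, g), dtype=np.float32), np.zeros(0, dtype=np.float32)
    X = np.stack([img.grid for img in imgs]).astype(np.float32)[:, None, :, :]
    if scale:
        mx = X.reshape(len(imgs), -1).max(axis=1)
        mx[mx == 0] = 1.0
        X /= mx[:, None, None, None]
    y = np.asarray([1.0 if img.label is BeatClass.AF else 0.0 for img in imgs],
                   dtype=np.float32)
    return X, y
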