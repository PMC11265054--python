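"""Beat-annotation streams: the pipeline's sole input.

A record is the minimal abstraction of a long-term ambulatory ECG after
QRS detection and rhythm adjudication: a strictly increasing sequence of
R-wave times (seconds) with one rhythm-class label per beat.  Everything
downstream — windowing, Lorenz-scattergram rasterization, classification —
consumes only this.

Rhythm labels are binary at the beat level (``AF`` vs ``NON_AF``); atrial
flutter, ectopy, tachycardias and paced rhythm all map to ``NON_AF``.
Record-level ground truth, when known, is three-way: non-AF, paroxysmal AF
(self-terminating episodes) or persistent AF (continuous).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BeatClass",
    "RecordClass",
    "RRRecord",
    "RRSeries",
    "DEFAULT_CODE_MAP",
    "map_rhythm_code",
    "read_rri_text",
    "write_rri_text",
    "from_annotation_stream",
    "rr_series",
]


class BeatClass(str, enum.Enum):
    """Binary beat-level rhythm class."""

    AF = "AF"
    NON_AF = "NON_AF"


class RecordClass(str, enum.Enum):
    """Three-way record-level diagnosis."""

    NON_AF = "NON_AF"
    PAROXYSMAL_AF = "PAROXYSMAL_AF"
    PERSISTENT_AF = "PERSISTENT_AF"


#: Raw rhythm-code -> binary class. AF-family codes are positive; sinus
#: rhythm and every other arrhythmia (flutter, SVT, PVC, VT, paced ...)
#: count as non-AF.  Kept as data so the mapping is auditable/overridable.
DEFAULT_CODE_MAP: dict[str, BeatClass] = {
    "AF": BeatClass.AF,
    "AFIB": BeatClass.AF,
    "(AFIB": BeatClass.AF,
}


def map_rhythm_code(code: str, code_map: Optional[dict[str, BeatClass]] = None) -> BeatClass:
    """Map a raw rhythm code string to the binary beat class.

    Unknown codes map to ``NON_AF`` (with a logged warning at the I/O
    boundary): only explicitly AF-family codes are positive.
    """
    table = DEFAULT_CODE_MAP if code_map is None else code_map
    return table.get(code.strip().upper().lstrip("("), BeatClass.NON_AF)


@dataclass
class RRRecord:
    """One subject's beat stream.

    Parameters
    ----------
    record_id
        Stable identifier (file stem, database record name, ...).
    beat_times
        R-wave times in seconds from record start; strictly increasing.
    beat_labels
        One :class:`BeatClass` per beat.
    source_codes
        Optional raw rhythm code per beat, retained for audit.
    record_truth
        Optional record-level ground-truth class.
    episodes
        Optional list of ``(start_s, end_s, BeatClass)`` rhythm episodes,
        filled in by the simulator for audit of the 30-s labeling rule.
    """

    record_id: str
    beat_times: np.ndarray
    beat_labels: list[BeatClass]
    source_codes: Optional[list[str]] = None
    record_truth: Optional[RecordClass] = None
    episodes: Optional[list[tuple[float, float, BeatClass]]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1 or self.beat_times.size == 0:
            raise ValueError("beat_times must be a non-empty 1-D sequence")
        if self.beat_times[0] < 0:
            raise ValueError("beat_times must be non-negative")
        diffs = np.diff(self.beat_times)
        if len(diffs) and not np.all(diffs > 0):
            k = int(np.argmin(diffs > 0))
            raise ValueError(
                f"beat_times must be strictly increasing; violation at beat {k + 1} "
                f"(t={self.beat_times[k + 1]:.6f} after t={self.beat_times[k]:.6f})"
            )
        if len(self.beat_labels) != len(self.beat_times):
            raise ValueError(
                f"{len(self.beat_labels)} labels for {len(self.beat_times)} beats"
            )
        if self.source_codes is not None and len(self.source_codes) != len(self.beat_times):
            raise ValueError("source_codes length mismatch")

    def __len__(self) -> int:
        return len(self.beat_times)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass
class RRSeries:
    """RR-interval tachogram derived from a record.

    ``intervals[i] = t[i+1] - t[i]``; each interval carries the label of
    the beat that terminates it, so an interval ending in an AF-annotated
    beat belongs to the AF run.
    """

    intervals: np.ndarray
    interval_labels: list[BeatClass]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if not np.all(self.intervals > 0):
            raise ValueError("all RR intervals must be positive")
        if len(self.interval_labels) != len(self.intervals):
            raise ValueError("interval_labels length mismatch")

    def __len__(self) -> int:
        return len(self.intervals)


def rr_series(record: RRRecord) -> RRSeries:
    """First-difference a record into its RR tachogram (needs >= 2 beats)."""
    if len(record) < 2:
        raise ValueError(f"record {record.record_id!r} has {len(record)} beats; need >= 2")
    return RRSeries(
        intervals=np.diff(record.beat_times),
        interval_labels=list(record.beat_labels[1:]),
    )


# ---------------------------------------------------------------------------
# RRI TSV dialect
#
# UTF-8; '#'-prefixed comment/header lines; then one row per beat:
#     beat_index<TAB>time_s<TAB>code
# beat_index 0-based contiguous, time_s printed to 6 decimals.
# ---------------------------------------------------------------------------

def write_rri_text(record: RRRecord, path: str | Path) -> None:
    """Write a record in the RRI TSV dialect (deterministic formatting)."""
    path = Path(path)
    codes = record.source_codes
    if codes is None:
        codes = [lbl.value for lbl in record.beat_labels]
    lines = [f"# record_id: {record.record_id}"]
    if record.record_truth is not None:
        lines.append(f"# record_truth: {record.record_truth.value}")
    lines.append("# beat_index\ttime_s\tcode")
    for i, (t, c) in enumerate(zip(record.beat_times, codes)):
        lines.append(f"{i}\t{t:.6f}\t{c}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rri_text(
    path: str | Path,
    code_map: Optional[dict[str, BeatClass]] = None,
) -> RRRecord:
    """Read a record from the RRI TSV dialect.

    The raw code column is retained in ``source_codes`` and mapped to the
    binary class via ``code_map`` (default :data:`DEFAULT_CODE_MAP`);
    unknown codes map to ``NON_AF`` with a warning.  Non-monotone times and
    empty files are hard errors.
    """
    path = Path(path)
    record_id = path.stem
    record_truth: Optional[RecordClass] = None
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("record_id:"):
                record_id = body.split(":", 1)[1].strip()
            elif body.startswith("record_truth:"):
                record_truth = RecordClass(body.split(":", 1)[1].strip())
        else:
            break
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["beat_index", "time_s", "code"],
            dtype={"beat_index": int, "time_s": float, "code": str},
        )
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty RRI file") from exc
    if df.empty:
        raise ValueError(f"{path}: no beat rows")

    times = df["time_s"].to_numpy()
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: non-monotone beat times at data row {int(bad[0]) + 1} "
            f"(t={times[bad[0] + 1]:.6f} after t={times[bad[0]]:.6f})"
        )
    table = DEFAULT_CODE_MAP if code_map is None else code_map
    codes = df["code"].astype(str).str.strip().tolist()
    labels: list[BeatClass] = []
    unknown: set[str] = set()
    for c in codes:
        key = c.upper().lstrip("(")
        if key in table:
            labels.append(table[key])
        else:
            if c not in ("N", "NON_AF") and c not in unknown:
                unknown.add(c)
            labels.append(BeatClass.NON_AF)
    if unknown:
        logger.warning("%s: unknown rhythm codes mapped to NON_AF: %s", path, sorted(unknown))
    return RRRecord(
        record_id=record_id,
        beat_times=times,
        beat_labels=labels,
        source_codes=codes,
        record_truth=record_truth,
    )


def from_annotation_stream(
    beat_samples: Sequence[int],
    sampling_rate: float,
    rhythm_change_events: Sequence[tuple[int, str]],
    record_id: str = "annotation_stream",
    code_map: Optional[dict[str, BeatClass]] = None,
) -> RRRecord:
    """Adapter for annotation models where rhythm codes mark change points.

    Ambulatory-ECG annotation files conventionally store beat sample
    indices plus sparse rhythm-change events ``(sample, code)``; each beat
    carries the most recent change at or before it (beats before the first
    event inherit the first event's code).  AF-family codes map to ``AF``,
    everything else to ``NON_AF``.
    """
    samples = np.asarray(beat_samples, dtype=np.int64)
    if samples.size == 0:
        raise ValueError("empty beat list")
    if np.any(np.diff(samples) <= 0):
        raise ValueError("beat_samples must be strictly increasing")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    events = sorted(rhythm_change_events, key=lambda e: e[0])
    if not events:
        raise ValueError("at least one rhythm change event is required")
    ev_samples = np.asarray([e[0] for e in events], dtype=np.int64)
    ev_codes = [str(e[1]) for e in events]
    # index of most recent event at or before each beat; clip pre-first beats
    idx = np.clip(np.searchsorted(ev_samples, samples, side="right") - 1, 0, None)
    codes = [ev_codes[i] for i in idx]
    table = DEFAULT_CODE_MAP if code_map is None else code_map
    labels = [table.get(c.upper().lstrip("("), BeatClass.NON_AF) for c in codes]
    return RRRecord(
        record_id=record_id,
        beat_times=samples / float(sampling_rate),
        beat_labels=labels,
        source_codes=codes,
    )
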