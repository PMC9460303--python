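"""RR-interval series: the core data model and plain-text I/O.

An RR (or NN) interval is the time between two consecutive normal
heartbeats, in milliseconds.  A run is one continuous recording from one
subject; the tachogram is the sequence of RR intervals laid out against
cumulative beat time.  All downstream analysis (windowed feature
extraction, reliability statistics) consumes :class:`RRSeries` objects,
either read from disk or produced by :mod:`ushrv.synthetic_rr`.

Conventions
-----------
* RR values are stored and reported in milliseconds; times in seconds.
* Beat times start at ``t_0 = 0`` (first beat); interval ``rr_i`` is
  attributed to the span ``(t_{i-1}, t_i]``.
* RR files are header-less single-column text (one interval in ms per
  row) or two-column ``t_s,rr_ms`` CSV with a header; the dialect is
  auto-detected from the first row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigurationError, ParseError, ValidationError

__all__ = [
    "RRSeries",
    "StudySet",
    "read_rr_file",
    "write_rr_file",
    "read_study",
    "write_study",
    "filter_runs_by_duration",
]


@dataclass
class RRSeries:
    """One run's RR intervals with derived cumulative beat times.

    Parameters
    ----------
    subject_id, run_id
        Free-text labels identifying the run.
    rr_ms
        Ordered RR intervals in milliseconds; all strictly positive.

    Attributes
    ----------
    t_beats_s
        Cumulative beat times in seconds, ``t_0 = 0``,
        ``t_i = t_{i-1} + rr_i / 1000``; length ``len(rr_ms) + 1``.
    """

    subject_id: str
    run_id: str
    rr_ms: np.ndarray
    t_beats_s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_ms, dtype=float)
        if rr.ndim != 1 or rr.size == 0:
            raise ValidationError(
                f"run {self.subject_id}/{self.run_id}: RR series must be a "
                "non-empty 1-d sequence"
            )
        if not np.all(rr > 0):
            bad = int(np.flatnonzero(rr <= 0)[0])
            raise ValidationError(
                f"run {self.subject_id}/{self.run_id}: non-positive RR "
                f"interval {rr[bad]} ms at index {bad}"
            )
        self.rr_ms = rr
        self.t_beats_s = np.concatenate(([0.0], np.cumsum(rr) / 1000.0))

    @property
    def n_intervals(self) -> int:
        return int(self.rr_ms.size)

    @property
    def duration_s(self) -> float:
        """Total duration in seconds (= last beat time = sum(rr_ms)/1000)."""
        return float(self.t_beats_s[-1])

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.run_id)


@dataclass
class StudySet:
    """A collection of runs entering one reliability analysis."""

    runs: list[RRSeries]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.runs]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (subject_id, run_id) pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)


def read_rr_file(path: str | Path, subject_id: str, run_id: str) -> RRSeries:
    """Read one RR file into an :class:`RRSeries`.

    Accepts a header-less single column of intervals (ms) or a
    two-column ``t_s,rr_ms`` CSV with header; beat times are always
    recomputed from the intervals, preserving input order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ParseError(f"{path}: file contains no data rows")

    two_column = "," in rows[0][1]
    rr: list[float] = []
    for lineno, text in rows:
        if two_column:
            parts = text.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {text!r}")
            if lineno == rows[0][0]:
                try:
                    float(parts[1])
                except ValueError:
                    continue  # header row
            cell = parts[1]
        else:
            cell = text
        try:
            value = float(cell)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value {cell!r}") from None
        if value <= 0:
            raise ValidationError(
                f"{path}:{lineno}: non-positive RR interval {value} ms"
            )
        rr.append(value)
    return RRSeries(subject_id=subject_id, run_id=run_id, rr_ms=np.asarray(rr))


def write_rr_file(series: RRSeries, path: str | Path, decimals: int = 3) -> None:
    """Write a single-column RR file readable by :func:`read_rr_file`."""
    if series.n_intervals == 0:  # pragma: no cover - RRSeries forbids this
        raise ValidationError("refusing to write an empty RR series")
    if decimals < 3:
        raise ConfigurationError("decimals must be >= 3 for a lossless round-trip")
    path = Path(path)
    path.write_text("\n".join(f"{v:.{decimals}f}" for v in series.rr_ms) + "\n")


def read_study(manifest_path: str | Path, provenance: str | None = None) -> StudySet:
    """Load a study from a manifest CSV of (subject_id, run_id, path).

    Relative paths in the manifest resolve against the manifest's
    directory.
    """
    manifest_path = Path(manifest_path)
    runs: list[RRSeries] = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "run_id", "path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(
                f"{manifest_path}: manifest header must contain {sorted(required)}"
            )
        for row in reader:
            p = Path(row["path"])
            if not p.is_absolute():
                p = manifest_path.parent / p
            runs.append(read_rr_file(p, row["subject_id"], row["run_id"]))
    return StudySet(runs=runs, provenance=provenance or f"manifest:{manifest_path}")


def write_study(study: StudySet, out_dir: str | Path) -> Path:
    """Write every run as an RR file plus a ``manifest.csv``; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "run_id", "path"])
        for run in study:
            fname = f"{run.subject_id}_{run.run_id}.rr"
            write_rr_file(run, out_dir / fname)
            writer.writerow([run.subject_id, run.run_id, fname])
    return manifest


def filter_runs_by_duration(study: StudySet, min_duration_s: float) -> StudySet:
    """Keep exactly the runs strictly longer than ``min_duration_s``.

    The strict ``>`` mirrors the reference-window requirement: a run must
    exceed the reference duration to contribute at least one reference
    window placement beyond the degenerate single one.
    """
    if min_duration_s < 0:
        raise ConfigurationError("min_duration_s must be >= 0")
    kept = [r for r in study if r.duration_s > min_duration_s]
    return StudySet(
        runs=kept,
        provenance=f"{study.provenance} | duration>{min_duration_s}s "
        f"({len(kept)}/{len(study)} runs kept)",
    )
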