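"""Per-epoch training traces: data model, CSV/JSONL I/O, and oracle analysis.

A :class:`TrainingTrace` is the object every stopping rule consumes: an
ordered sequence of per-epoch records carrying training/validation loss and
accuracy, plus optional test accuracies on a record-level hold-out
(``test_acc_subset``, records from subjects seen in training) and on a
subject-level hold-out (``test_acc_novel``, entirely unseen subjects).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochRecord",
    "TrainingTrace",
    "StopDecision",
    "TraceFormatError",
    "TraceValidationError",
    "read_trace",
    "write_trace",
    "oracle_epoch",
]

REQUIRED_COLUMNS = ("epoch", "train_loss", "val_loss", "train_acc", "val_acc")
OPTIONAL_COLUMNS = ("test_acc_subset", "test_acc_novel")


class TraceFormatError(ValueError):
    """A trace file is structurally malformed (e.g. a required column is missing)."""


class TraceValidationError(ValueError):
    """Trace contents violate an invariant (e.g. non-consecutive epochs)."""


@dataclass(frozen=True)
class EpochRecord:
    """Metrics recorded at the end of one training epoch.

    Epochs are 1-based. Losses must be finite and non-negative; accuracies
    lie in [0, 1]. Test accuracies are optional because many runs log only
    train/validation metrics.
    """

    epoch: int
    train_loss: float
    val_loss: float
    train_acc: float
    val_acc: float
    test_acc_subset: Optional[float] = None
    test_acc_novel: Optional[float] = None

    def __post_init__(self) -> None:
        if self.epoch < 1:
            raise TraceValidationError(f"epoch must be >= 1, got {self.epoch}")
        for name in ("train_loss", "val_loss"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise TraceValidationError(f"{name} must be finite and >= 0, got {v}")
        for name in ("train_acc", "val_acc", "test_acc_subset", "test_acc_novel"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise TraceValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class TrainingTrace:
    """An ordered, gap-free sequence of :class:`EpochRecord` for one run.

    Invariants: non-empty, and epochs are consecutive integers 1..n.
    ``meta`` carries run metadata (channel label, seed, config id, columns
    preserved from an input file that this model does not interpret).
    """

    records: tuple[EpochRecord, ...]
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise TraceValidationError("trace must contain at least one epoch")
        object.__setattr__(self, "records", tuple(self.records))
        for i, r in enumerate(self.records, start=1):
            if r.epoch != i:
                raise TraceValidationError(
                    f"epochs must be consecutive integers starting at 1; "
                    f"position {i} has epoch {r.epoch}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EpochRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EpochRecord:
        return self.records[i]

    @property
    def val_loss(self) -> np.ndarray:
        return np.array([r.val_loss for r in self.records])

    @property
    def train_loss(self) -> np.ndarray:
        return np.array([r.train_loss for r in self.records])

    @property
    def val_acc(self) -> np.ndarray:
        return np.array([r.val_acc for r in self.records])

    @property
    def train_acc(self) -> np.ndarray:
        return np.array([r.train_acc for r in self.records])

    def truncated(self, last_epoch: int) -> "TrainingTrace":
        """The prefix of this trace up to and including ``last_epoch``."""
        if not 1 <= last_epoch <= len(self):
            raise TraceValidationError(f"epoch {last_epoch} outside trace of length {len(self)}")
        return TrainingTrace(self.records[:last_epoch], dict(self.meta))

    @classmethod
    def from_arrays(
        cls,
        val_loss: Sequence[float],
        train_loss: Optional[Sequence[float]] = None,
        train_acc: Optional[Sequence[float]] = None,
        val_acc: Optional[Sequence[float]] = None,
        meta: Optional[Mapping[str, Any]] = None,
    ) -> "TrainingTrace":
        """Build a trace from parallel arrays; handy for tests and replay.

        Missing metric arrays default to zeros (losses) or 0.5 (accuracies).
        """
        n = len(val_loss)
        tl = train_loss if train_loss is not None else [0.0] * n
        ta = train_acc if train_acc is not None else [0.5] * n
        va = val_acc if val_acc is not None else [0.5] * n
        recs = tuple(
            EpochRecord(i + 1, float(tl[i]), float(val_loss[i]), float(ta[i]), float(va[i]))
            for i in range(n)
        )
        return cls(recs, dict(meta or {}))


@dataclass(frozen=True)
class StopDecision:
    """The outcome of applying one stopping rule to a trace.

    ``stop_epoch`` is the epoch at which the rule fired, or ``None`` if it
    never did (the run completed its full horizon). ``selected_epoch`` is
    the epoch whose model the rule keeps — for every rule here, the epoch
    of minimum validation loss over the epochs the rule observed.
    """

    rule_name: str
    params: Mapping[str, Any]
    stop_epoch: Optional[int]
    selected_epoch: int
    triggered: bool

    def __post_init__(self) -> None:
        if self.selected_epoch < 1:
            raise TraceValidationError("selected_epoch must be >= 1")
        if self.triggered:
            if self.stop_epoch is None:
                raise TraceValidationError("triggered decision must carry a stop_epoch")
            if self.selected_epoch > self.stop_epoch:
                raise TraceValidationError("selected_epoch must not exceed stop_epoch")


def oracle_epoch(trace: TrainingTrace) -> int:
    """Epoch of globally minimal validation loss (first occurrence on ties).

    This is the post-hoc ideal every stopping rule is scored against: with
    the whole trace in hand, pick the epoch with the lowest validation
    loss. Ties resolve to the earliest epoch — the earlier model is cheaper
    to reach and no worse.
    """
    return int(np.argmin(trace.val_loss)) + 1


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".jsonl", ".ndjson"}:
        return "jsonl"
    return "csv"


def _records_from_frame(df: pd.DataFrame) -> tuple[tuple[EpochRecord, ...], dict]:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"required column '{col}' is missing")
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        kwargs = {}
        for col in OPTIONAL_COLUMNS:
            v = d.get(col)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                kwargs[col] = float(v)
        records.append(
            EpochRecord(
                epoch=int(d["epoch"]),
                train_loss=float(d["train_loss"]),
                val_loss=float(d["val_loss"]),
                train_acc=float(d["train_acc"]),
                val_acc=float(d["val_acc"]),
                **kwargs,
            )
        )
    meta: dict = {}
    if extra_cols:
        meta["extra_columns"] = {c: df[c].tolist() for c in extra_cols}
    return tuple(records), meta


def read_trace(path: str | Path, format: Optional[str] = None) -> TrainingTrace:
    """Read a training trace from CSV or JSONL.

    CSV needs a header row with at least the columns
    ``epoch,train_loss,val_loss,train_acc,val_acc``; JSONL expects one
    object per line with the same keys. Unknown columns are preserved in
    ``trace.meta['extra_columns']``.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "jsonl":
        rows = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        if not rows:
            raise TraceFormatError(f"no records in {path}")
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown trace format '{fmt}'")
    records, meta = _records_from_frame(df)
    return TrainingTrace(records, meta)


def write_trace(trace: TrainingTrace, path: str | Path, format: Optional[str] = None) -> None:
    """Write a trace so that :func:`read_trace` recovers it exactly.

    Floats are written with ``repr`` (shortest round-tripping form), so a
    write/read cycle is lossless. Optional test-accuracy columns are
    emitted only when at least one record carries them.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    has_subset = any(r.test_acc_subset is not None for r in trace.records)
    has_novel = any(r.test_acc_novel is not None for r in trace.records)
    cols = list(REQUIRED_COLUMNS)
    if has_subset:
        cols.append("test_acc_subset")
    if has_novel:
        cols.append("test_acc_novel")

    def fmt_val(v: Any) -> str:
        if v is None:
            return ""
        if isinstance(v, int):
            return str(v)
        return repr(float(v))

    if fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(",".join(cols) + "\n")
            for r in trace.records:
                fh.write(",".join(fmt_val(getattr(r, c)) for c in cols) + "\n")
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for r in trace.records:
                obj = {c: getattr(r, c) for c in cols if getattr(r, c) is not None}
                fh.write(json.dumps(obj) + "\n")
    else:
        raise ValueError(f"unknown trace format '{fmt}'")
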