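"""Domain types and readers/writers for RR-interval (RRI) sequences.

An RRI sequence is the discrete series of times between consecutive ECG
R-peaks, in milliseconds.  All values are strictly positive reals; the sum of
the values is the recording's total duration, which the cleaning algorithm is
required to conserve.

Two on-disk formats are supported:

* ``plain`` — one millisecond value per line (the de-facto Holter/Polar
  export style);
* ``csv`` — comma-separated, mandatory header, column ``rri_ms`` and an
  optional ``t_ms`` timestamp column.

Indices everywhere in this package are 0-based and spans are half-open.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RRIError",
    "RRIParseError",
    "RRISequence",
    "IntervalAnnotation",
    "CleanResult",
    "read_rri",
    "write_rri",
    "write_report",
    "write_annotations",
    "REPORT_SCHEMA_KEYS",
]


class RRIError(ValueError):
    """Base class for domain errors raised by this package."""


class RRIParseError(RRIError):
    """A file could not be parsed as an RRI sequence."""


AnnotationStatus = Literal["normal", "filled", "merged", "inserted", "replaced"]


@dataclass(frozen=True)
class RRISequence:
    """An ordered sequence of RR intervals in milliseconds.

    Parameters
    ----------
    values
        Strictly positive interval durations, ms.
    origin_label
        Free-text provenance (file name, generator call, ...).
    sampling_note
        Optional acquisition note, e.g. ``"600 Hz Holter"``.
    """

    values: np.ndarray
    origin_label: str = ""
    sampling_note: str | None = None

    def __init__(
        self,
        values: Iterable[float],
        origin_label: str = "",
        sampling_note: str | None = None,
    ) -> None:
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         dtype=float)
        if arr.ndim != 1:
            raise RRIError("RRI values must form a one-dimensional sequence")
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
            bad = int(np.flatnonzero(~np.isfinite(arr) | (arr <= 0))[0])
            raise RRIError(
                f"RRI values must be finite and strictly positive; "
                f"offending value {arr[bad]!r} at index {bad}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "origin_label", origin_label)
        object.__setattr__(self, "sampling_note", sampling_note)

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, i):
        return self.values[i]

    def __iter__(self):
        return iter(self.values)

    def total_time(self) -> float:
        """Total recording duration in ms (sum of all intervals)."""
        return float(np.sum(self.values))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RRISequence):
            return NotImplemented
        return len(self) == len(other) and bool(np.array_equal(self.values, other.values))


@dataclass
class IntervalAnnotation:
    """Provenance of one value in a cleaned output sequence.

    ``index`` is the 0-based position in the OUTPUT sequence.  ``source_span``
    is the half-open ``[start, end)`` range of INPUT indices this output value
    accounts for (empty for values created out of buffered time).
    ``time_delta_ms`` is the signed time this action moved into (+) or out of
    (−) the reserve buffer.
    """

    index: int
    status: AnnotationStatus
    source_span: tuple[int, int]
    time_delta_ms: float = 0.0
    truncated: bool = False

    def __post_init__(self) -> None:
        s, e = self.source_span
        if e < s:
            raise RRIError(f"source_span must be non-decreasing, got {self.source_span}")
        if self.status == "normal" and self.time_delta_ms != 0.0:
            raise RRIError("a normal interval moves no time to or from the buffer")
        if self.status == "normal" and e - s != 1:
            raise RRIError("a normal interval covers exactly one input index")


@dataclass
class CleanResult:
    """Output of the cleaning pass: corrected sequence plus its ledger.

    ``n_normal``/``n_increased``/``n_decreased`` are the Nr / incNr / decNr
    counters: values passed through unchanged, values added (fills beyond the
    first replacement, plus buffer-overflow insertions), and input values
    removed by aggregation of short artifacts.  ``total_time_difference_ms``
    is the signed duration difference input − output; the algorithm bounds its
    magnitude by one mean RR interval.
    """

    cleaned: RRISequence
    annotations: list[IntervalAnnotation]
    n_normal: int
    n_increased: int
    n_decreased: int
    final_buffer_ms: float
    total_time_difference_ms: float
    criteria_used: "Criteria"  # noqa: F821 - criteria.Criteria, kept untyped to avoid a cycle
    start_index: int = 0
    max_prefix_gap_ratio: float = 0.0
    buffer_peak_ms: float = 0.0
    fill_deviations_ms: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

Format = Literal["plain", "csv"]


def _infer_format(path: Path, fmt: Format | None) -> Format:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "plain"


def read_rri(path: str | Path, format: Format | None = None) -> RRISequence:
    """Read an RRI sequence from ``path``.

    ``format`` may be ``"plain"`` or ``"csv"``; when omitted it is inferred
    from the file suffix (".csv" → csv, anything else → plain).  Non-numeric
    or non-positive entries raise :class:`RRIParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RRI file not found: {path}")
    fmt = _infer_format(path, format)

    if fmt == "plain":
        values: list[float] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                text = raw.strip()
                if not text:
                    continue
                try:
                    v = float(text)
                except ValueError:
                    raise RRIParseError(
                        f"{path}:{lineno}: not a numeric RRI value: {text!r}"
                    ) from None
                if not math.isfinite(v) or v <= 0:
                    raise RRIParseError(
                        f"{path}:{lineno}: RRI values must be positive, got {text!r}"
                    )
                values.append(v)
        if not values:
            raise RRIParseError(f"{path}: no RRI values found")
        return RRISequence(values, origin_label=str(path))

    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if "rri_ms" not in df.columns:
            raise RRIParseError(f"{path}: csv format requires an 'rri_ms' column")
        col = pd.to_numeric(df["rri_ms"], errors="coerce")
        bad = col.isna() | (col <= 0)
        if bad.any():
            # +2: one for the header line, one for 0-based positions
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise RRIParseError(
                f"{path}:{lineno}: non-numeric or non-positive rri_ms value"
            )
        if len(col) == 0:
            raise RRIParseError(f"{path}: no RRI values found")
        return RRISequence(col.to_numpy(dtype=float), origin_label=str(path))

    raise RRIError(f"unknown RRI format: {fmt!r}")


def _fmt_value(v: float) -> str:
    # repr round-trips exactly; integral values are written without ".0"
    return str(int(v)) if v.is_integer() else repr(v)


def write_rri(seq: RRISequence, path: str | Path, format: Format | None = None) -> None:
    """Write ``seq`` to ``path``; ``read_rri`` of the result is value-identical.

    Values are written with ``repr`` round-trip precision so that a
    write/read cycle is bit-for-bit on the values.
    """
    if len(seq) == 0:
        raise RRIError("refusing to write an empty RRI sequence")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "plain":
        with open(path, "w", encoding="utf-8") as fh:
            for v in seq.values:
                fh.write(_fmt_value(float(v)) + "\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rri_ms\n")
            for v in seq.values:
                fh.write(_fmt_value(float(v)) + "\n")
    else:
        raise RRIError(f"unknown RRI format: {fmt!r}")


#: Keys guaranteed to be present in every JSON report written by
#: :func:`write_report`; the contract other tooling may rely on.
REPORT_SCHEMA_KEYS = (
    "mean_before", "mean_after",
    "variance_before", "variance_after", "variance_diff",
    "adj_diff_variance_before", "adj_diff_variance_after",
    "sd1_before", "sd1_after", "sd2_before", "sd2_after",
    "ar_order", "ar_residual_variance_before", "ar_residual_variance_after",
    "noise_reduction_pct",
    "total_time_difference_ms",
    "n_normal", "n_increased", "n_decreased",
    "final_buffer_ms",
    "criteria_low", "criteria_high", "criteria_residual_sd", "criteria_ar1",
)


def write_report(result: CleanResult, comparison, path: str | Path) -> dict:
    """Serialize a before/after HRV comparison plus the cleaning ledger as JSON.

    ``comparison`` is an :class:`rriclean.metrics.HRVComparison`.  Returns the
    dict that was written.  Keys listed in :data:`REPORT_SCHEMA_KEYS` are
    stable across versions.
    """
    b, a = comparison.before, comparison.after
    crit = result.criteria_used
    doc = {
        "mean_before": b.mean_ms, "mean_after": a.mean_ms,
        "variance_before": b.variance_ms2, "variance_after": a.variance_ms2,
        "variance_diff": comparison.variance_diff_ms2,
        "adj_diff_variance_before": b.adj_diff_variance_ms2,
        "adj_diff_variance_after": a.adj_diff_variance_ms2,
        "sd1_before": b.sd1_ms, "sd1_after": a.sd1_ms,
        "sd2_before": b.sd2_ms, "sd2_after": a.sd2_ms,
        "ar_order": b.ar_order,
        "ar_residual_variance_before": b.ar_residual_variance_ms2,
        "ar_residual_variance_after": a.ar_residual_variance_ms2,
        "noise_reduction_pct": comparison.noise_reduction_pct,
        "total_time_difference_ms": result.total_time_difference_ms,
        "n_normal": result.n_normal,
        "n_increased": result.n_increased,
        "n_decreased": result.n_decreased,
        "final_buffer_ms": result.final_buffer_ms,
        "criteria_low": crit.low, "criteria_high": crit.high,
        "criteria_residual_sd": crit.residual_sd, "criteria_ar1": crit.ar1_coefficient,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    return doc


def write_annotations(annotations: Sequence[IntervalAnnotation], path: str | Path) -> None:
    """Write per-interval annotations as CSV.

    Columns: ``index,status,src_start,src_end,time_delta_ms``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("index,status,src_start,src_end,time_delta_ms\n")
        for ann in annotations:
            fh.write(
                f"{ann.index},{ann.status},{ann.source_span[0]},"
                f"{ann.source_span[1]},{ann.time_delta_ms!r}\n"
            )
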