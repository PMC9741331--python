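"""Adaptive, time-conserving artifact correction for RR-interval series.

The cleaner is a single-pass, causal state machine.  Each incoming interval
is compared, as a ratio, to the moving average of the last three accepted
intervals:

* **normal** (ratio inside the detection limits) — emitted unchanged;
* **long artifact** (ratio above the upper limit, e.g. a missed beat) — the
  artifact's duration, plus any banked reserve, is refilled with plausible
  intervals drawn at random from a 30-value backup field of recent normal
  beats;
* **short artifact** (ratio below the lower limit, e.g. a split beat) — the
  artifact is aggregated with the reserve and with subsequent intervals
  until at least one window average of time is accumulated, then re-emitted
  as normal-duration beats.

Whatever time cannot be expressed as a whole beat goes to a non-negative
**buffer**; whenever the buffer exceeds one normal beat an extra interval is
inserted and the buffer drained.  By construction the identity

    time_in == time_out + buffer

holds after every step, so the cleaned recording's duration never drifts
from real elapsed time by more than one average beat — the property that
makes the output safe for synchronised multichannel (polygraphic) analysis.

Corrected emissions are anchored to the *reference mean*: the 3-beat window
average while it is consistent with the 30-value backup field, and the
backup-field average otherwise.  The short window reacts to genuine rhythm
changes; the long field is robust to the window being momentarily poisoned
by borderline artifacts that slipped past wide detection limits.  Without
this guard a run of accepted short beats can drag the window average down
and lock the state machine into re-emitting short intervals indefinitely.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .criteria import Criteria, derive_criteria
from .io import CleanResult, IntervalAnnotation, RRIError, RRISequence

__all__ = [
    "CleanerState",
    "Classification",
    "InitializationError",
    "init_state",
    "classify_next",
    "fill_long_artifact",
    "merge_short_artifacts",
    "process_normal",
    "clean_sequence",
    "BACKUP_LENGTH",
    "DEFAULT_SEED",
]

#: Length of the backup field of recent normal intervals used for filling.
BACKUP_LENGTH = 30
#: Length of the moving-average window.
WINDOW_LENGTH = 3
#: Fixed default seed so repeated runs are reproducible.
DEFAULT_SEED = 1729


class InitializationError(RRIError):
    """No artifact-free run long enough to initialize the state machine."""


@dataclass
class Classification:
    label: str  # "normal" | "long_artifact" | "short_artifact"
    ratio: float


@dataclass
class CleanerState:
    """Working memory of the cleaning pass.

    ``moving_window`` holds the last 3 *accepted* (normal or corrected)
    intervals; ``backup_field`` the last 30 intervals classified normal;
    ``buffer_ms`` the non-negative reserve of unallocated recording time.
    ``time_in_ms``/``time_out_ms`` are the cumulative consumed input and
    emitted output durations used for the conservation ledger.
    """

    moving_window: deque
    backup_field: deque
    criteria: Criteria
    buffer_ms: float = 0.0
    time_in_ms: float = 0.0
    time_out_ms: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(DEFAULT_SEED))
    n_normal: int = 0
    n_increased: int = 0
    n_decreased: int = 0
    max_prefix_gap_ratio: float = 0.0
    buffer_peak_ms: float = 0.0
    fill_deviations_ms: list = field(default_factory=list)

    def window_mean(self) -> float:
        return sum(self.moving_window) / len(self.moving_window)

    def backup_mean(self) -> float:
        return sum(self.backup_field) / len(self.backup_field)

    def reference_mean(self) -> float:
        """Duration anchor for corrected emissions.

        The window average, unless its ratio to the backup-field average
        falls outside the detection limits — then the window itself is
        suspect and the robust backup average is used instead.
        """
        wm = self.window_mean()
        bm = self.backup_mean()
        if self.criteria.low <= wm / bm <= self.criteria.high:
            return wm
        return bm

    def consume(self, value: float) -> None:
        self.time_in_ms += value

    def emit(self, value: float, update_window: bool = True) -> None:
        self.time_out_ms += value
        if update_window:
            self.moving_window.append(value)

    def push_backup(self, value: float) -> None:
        self.backup_field.append(value)

    def note_step(self) -> None:
        """Update the conservation ledger after a completed step."""
        gap = abs(self.time_in_ms - (self.time_out_ms + self.buffer_ms))
        self.max_prefix_gap_ratio = max(self.max_prefix_gap_ratio, gap / self.window_mean())
        self.buffer_peak_ms = max(self.buffer_peak_ms, self.buffer_ms)


def init_state(
    seq: RRISequence,
    criteria: Criteria,
    seed: int = DEFAULT_SEED,
    window: int = WINDOW_LENGTH,
    backup: int = BACKUP_LENGTH,
) -> tuple[CleanerState, int]:
    """Find a clean run to seed the state machine; return (state, start index).

    Scans forward for the first ``window`` consecutive mutually consistent
    values (adjacent ratios inside the criteria) to seed the moving window,
    then collects the next ``backup`` values classified normal against the
    running window into the backup field.  Values before the start index are
    later emitted unchanged; cleaning begins at the start index itself.

    Raises
    ------
    InitializationError
        If no run of ``window + backup`` consistent values exists
        (pathologically noisy input).
    """
    x = seq.values if isinstance(seq, RRISequence) else np.asarray(seq, dtype=float)
    need = window + backup
    n = x.size
    if n < need:
        raise InitializationError(
            f"sequence of length {n} shorter than the {need}-value initialization run"
        )
    lo, hi = criteria.low, criteria.high

    for s in range(n - need + 1):
        # seed run: adjacent ratios mutually consistent
        if not all(lo <= x[s + j + 1] / x[s + j] <= hi for j in range(window - 1)):
            continue
        win = deque(x[s:s + window], maxlen=window)
        bak: deque = deque(maxlen=backup)
        j = s + window
        while len(bak) < backup and j < n:
            wm = sum(win) / len(win)
            if lo <= x[j] / wm <= hi:
                bak.append(float(x[j]))
                win.append(float(x[j]))
                j += 1
            else:
                break
        if len(bak) == backup:
            state = CleanerState(
                moving_window=deque((float(v) for v in x[s:s + window]),
                                    maxlen=window),
                backup_field=bak,
                criteria=criteria,
                rng=np.random.default_rng(seed),
            )
            return state, s

    raise InitializationError(
        "no clean initialization run found: the input has no stretch of "
        f"{need} consecutive values with mutually consistent ratios"
    )


def classify_next(value: float, state: CleanerState, criteria: Criteria | None = None) -> Classification:
    """Classify ``value`` against the current moving-window average."""
    criteria = criteria or state.criteria
    ratio = value / state.window_mean()
    return Classification(label=criteria.classify_ratio(ratio), ratio=ratio)


def fill_long_artifact(value: float, state: CleanerState) -> list[float]:
    """Replace a long artifact with plausible intervals, banking the remainder.

    The available time is the artifact plus the current buffer.  Values are
    drawn one at a time (seeded) from the backup field, rescaled to the
    reference mean and clipped to a normal ratio, and emitted while at least
    one upper-limit beat of time remains; a tail that still amounts to a
    normal-looking beat is emitted as one closing interval, so draws stay
    mutually independent (white) while the segment's time adds up exactly.
    Whatever is left is below one beat and goes back to the buffer.
    """
    ref = state.reference_mean()
    lo, hi = state.criteria.low, state.criteria.high
    bm = state.backup_mean()
    available = value + state.buffer_ms

    def draw() -> float:
        d = state.backup_field[int(state.rng.integers(0, len(state.backup_field)))]
        return float(np.clip(d * ref / bm, lo * ref, hi * ref))

    remaining = available
    fills: list[float] = []
    while remaining >= hi * ref:
        d = draw()
        fills.append(d)
        remaining -= d
    if remaining >= ref:
        # one more beat fits; clamp the draw to the remaining time so the
        # banked remainder stays below one reference beat
        d = min(draw(), remaining)
        fills.append(d)
        remaining -= d
    if not fills:  # ratio barely above the limit and criteria wide: one short fill
        fills.append(remaining)
        remaining = 0.0
    state.buffer_ms = remaining
    state.n_increased += len(fills) - 1
    state.fill_deviations_ms.extend(f - ref for f in fills)
    for f in fills:
        state.emit(f)
    return fills


def merge_short_artifacts(
    first_value: float,
    state: CleanerState,
    upcoming,
) -> tuple[list[float], int, bool]:
    """Aggregate a short artifact (plus buffer and following beats) into
    normal-duration replacements.

    Accumulates ``first_value + buffer`` and then subsequent input intervals
    (``upcoming`` iterator) until at least one window average of time is
    collected; emits ``m = round(accumulated / reference mean)`` replacements
    equal to the reference mean (reduced if rounding would overdraw; ``m``
    may be 0 when the window average is itself depressed) and banks the
    remainder.  Consumed follow-up intervals are charged to the input-time
    ledger here.

    Returns ``(replacements, n_extra_consumed, truncated)``; ``truncated`` is
    True when the input ended mid-accumulation, in which case the accumulated
    time is emitted as a single closing interval so no time is lost.
    """
    wm = state.window_mean()
    ref = state.reference_mean()
    acc = first_value + state.buffer_ms
    state.buffer_ms = 0.0
    consumed_extra = 0
    truncated = False
    while acc < wm:
        try:
            nxt = next(upcoming)
        except StopIteration:
            truncated = True
            break
        state.consume(nxt)
        acc += nxt
        consumed_extra += 1

    if truncated:
        replacements = [acc]
        m = 1
    else:
        m = round(acc / ref)
        while m * ref > acc:
            m -= 1
        replacements = [ref] * m
        state.buffer_ms = acc - m * ref

    total_consumed = 1 + consumed_extra
    if total_consumed >= m:
        state.n_decreased += total_consumed - m
    else:  # cannot happen while the buffer stays below one normal beat
        state.n_increased += m - total_consumed
    for r in replacements:
        state.emit(r)
    return replacements, consumed_extra, truncated


def process_normal(value: float, state: CleanerState) -> list[float]:
    """Emit a normal interval unchanged, then drain the buffer if it can
    afford whole beats.

    After the value is emitted (and enters both the moving window and the
    backup field), as long as the buffer holds at least one post-emission
    reference mean, an extra interval equal to that mean is inserted and
    charged to the buffer.
    """
    state.emit(value)
    state.push_backup(value)
    state.n_normal += 1
    emitted = [value]
    while state.buffer_ms >= state.reference_mean():
        w = state.reference_mean()
        state.buffer_ms -= w
        state.emit(w)
        state.n_increased += 1
        emitted.append(w)
    return emitted


def clean_sequence(
    seq: RRISequence,
    criteria: Criteria | None = None,
    seed: int = DEFAULT_SEED,
    robust: bool = False,
    window: int = WINDOW_LENGTH,
    backup: int = BACKUP_LENGTH,
) -> CleanResult:
    """Run the full single-pass cleaning procedure on ``seq``.

    When ``criteria`` is None the detection limits are first derived from
    the sequence itself.  With ``robust=True`` a second pass is run with
    limits re-derived from the first pass's output: artifacts inflate the
    residual SD of the ratio sequence, so limits derived from heavily
    corrupted data are too permissive, and a one-pass pre-clean restores
    their sharpness.  The result is deterministic given
    ``(seq, criteria, seed, robust)``.
    """
    if len(seq) < 50:
        raise RRIError(f"sequence of length {len(seq)} too short to clean")
    if criteria is None:
        criteria = derive_criteria(seq, window=window)
    if robust:
        first = _clean_once(seq, criteria, seed, window, backup)
        criteria = derive_criteria(first.cleaned, multiplier=criteria.multiplier,
                                   window=window)
    return _clean_once(seq, criteria, seed, window, backup)


def _clean_once(seq: RRISequence, criteria: Criteria, seed: int,
                window: int = WINDOW_LENGTH, backup: int = BACKUP_LENGTH) -> CleanResult:
    x = seq.values
    n = x.size
    state, start = init_state(seq, criteria, seed, window=window, backup=backup)

    out: list[float] = []
    anns: list[IntervalAnnotation] = []

    # Pre-start segment: emitted unchanged (conservation outranks cleaning at
    # the edge); does not touch the moving window seeded from the clean run.
    for i in range(start):
        v = float(x[i])
        state.consume(v)
        state.emit(v, update_window=False)
        state.n_normal += 1
        anns.append(IntervalAnnotation(index=len(out), status="normal",
                                       source_span=(i, i + 1)))
        out.append(v)

    i = start
    while i < n:
        v = float(x[i])
        state.consume(v)
        cls = classify_next(v, state)

        if cls.label == "normal":
            emitted = process_normal(v, state)
            anns.append(IntervalAnnotation(index=len(out), status="normal",
                                           source_span=(i, i + 1)))
            out.append(emitted[0])
            for extra in emitted[1:]:
                anns.append(IntervalAnnotation(index=len(out), status="inserted",
                                               source_span=(i + 1, i + 1),
                                               time_delta_ms=-extra))
                out.append(extra)
            i += 1

        elif cls.label == "long_artifact":
            buffer_in = state.buffer_ms
            fills = fill_long_artifact(v, state)
            status = "replaced" if len(fills) == 1 else "filled"
            delta = state.buffer_ms - buffer_in
            anns.append(IntervalAnnotation(index=len(out), status=status,
                                           source_span=(i, i + 1),
                                           time_delta_ms=delta))
            out.append(fills[0])
            for f in fills[1:]:
                anns.append(IntervalAnnotation(index=len(out), status=status,
                                               source_span=(i + 1, i + 1)))
                out.append(f)
            i += 1

        else:  # short_artifact
            buffer_in = state.buffer_ms
            upcoming = (float(x[j]) for j in range(i + 1, n))
            replacements, extra_consumed, truncated = merge_short_artifacts(
                v, state, upcoming)
            span_end = i + 1 + extra_consumed
            delta = state.buffer_ms - buffer_in
            if replacements:
                anns.append(IntervalAnnotation(index=len(out), status="merged",
                                               source_span=(i, span_end),
                                               time_delta_ms=delta,
                                               truncated=truncated))
                out.append(replacements[0])
                for r in replacements[1:]:
                    anns.append(IntervalAnnotation(index=len(out), status="merged",
                                                   source_span=(span_end, span_end)))
                    out.append(r)
            else:
                # swallowed entirely into the buffer; the time reappears at the
                # next insertion, so point the annotation at the previous value
                anns.append(IntervalAnnotation(index=max(len(out) - 1, 0),
                                               status="merged",
                                               source_span=(i, span_end),
                                               time_delta_ms=delta,
                                               truncated=truncated))
            i = span_end

        state.note_step()

    cleaned = RRISequence(out, origin_label=f"cleaned({seq.origin_label})")
    total_diff = seq.total_time() - cleaned.total_time()
    return CleanResult(
        cleaned=cleaned,
        annotations=anns,
        n_normal=state.n_normal,
        n_increased=state.n_increased,
        n_decreased=state.n_decreased,
        final_buffer_ms=state.buffer_ms,
        total_time_difference_ms=total_diff,
        criteria_used=criteria,
        start_index=start,
        max_prefix_gap_ratio=state.max_prefix_gap_ratio,
        buffer_peak_ms=state.buffer_peak_ms,
        fill_deviations_ms=list(state.fill_deviations_ms),
    )
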