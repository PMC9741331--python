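"""Data-adaptive derivation of the artifact-detection limits.

Artifacts in an RR-interval series are found by comparing each interval to
the moving average of the three preceding accepted intervals.  The ratio of
two (approximately) normally distributed intervals follows a heavy-tailed
Cauchy-like law, so a plain 3-sigma rule on the raw ratios is unreliable.
The fix is prewhitening: fit a first-order autoregressive model to the ratio
sequence,

    e_n = x_n + a1 * x_{n-1},

take the residual noise ``e_n`` (close to Gaussian white noise with a
non-zero mean), and place the limits three residual standard deviations
either side of 1 — the ratio mean on clean data.  Ratios outside

    [1 - m * sd_e, 1 + m * sd_e],   m = 3 by default,

are classified as artifacts; inside (limits inclusive) they are normal.  The
limits are recording-specific: a recording with large respiratory sinus
arrhythmia earns a wider window than a metronomic one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RRIError, RRISequence

__all__ = [
    "RatioSequence",
    "Criteria",
    "DegenerateCriteriaError",
    "adjacent_ratios",
    "fit_ar1",
    "residual_sd",
    "derive_criteria",
]

#: Beats in the trailing moving-average window used for ratios.
DEFAULT_WINDOW = 3
#: Standard-deviation multiplier for the detection limits (99.7% coverage).
DEFAULT_MULTIPLIER = 3.0
#: Minimum sequence length for a stable residual-SD estimate.
MIN_SEQUENCE_LENGTH = 50


class DegenerateCriteriaError(RRIError):
    """The ratio residuals have zero spread, giving a zero-width window."""


@dataclass(frozen=True)
class RatioSequence:
    """Ratios of each interval to the trailing moving average.

    ``ratios[i]`` corresponds to input index ``start_index + i`` and equals
    that interval divided by the mean of the ``window`` preceding intervals.
    """

    ratios: np.ndarray
    start_index: int

    def __len__(self) -> int:
        return int(self.ratios.size)


@dataclass(frozen=True)
class Criteria:
    """Artifact-detection limits, symmetric about 1.

    ``low``/``high`` are the minimal/maximal acceptable ratios of an interval
    to the trailing window average; ``residual_sd`` is the standard deviation
    of the AR(1)-prewhitened ratio noise they derive from, and
    ``ar1_coefficient`` the fitted AR(1) coefficient (residual convention
    ``e_n = x_n + a1 x_{n-1}``).
    """

    residual_sd: float
    multiplier: float = DEFAULT_MULTIPLIER
    ar1_coefficient: float = 0.0

    @property
    def low(self) -> float:
        return 1.0 - self.multiplier * self.residual_sd

    @property
    def high(self) -> float:
        return 1.0 + self.multiplier * self.residual_sd

    def classify_ratio(self, ratio: float) -> str:
        """Label a ratio: ``normal`` (limits inclusive), ``long_artifact``
        (above ``high``) or ``short_artifact`` (below ``low``)."""
        if ratio > self.high:
            return "long_artifact"
        if ratio < self.low:
            return "short_artifact"
        return "normal"


def adjacent_ratios(seq: RRISequence | np.ndarray, window: int = DEFAULT_WINDOW) -> RatioSequence:
    """Ratio of each interval to the mean of the ``window`` previous ones.

    Strictly causal: the ratio at input position ``n`` (``n >= window``) is
    ``seq[n] / mean(seq[n - window : n])``; the first ``window`` positions
    have no ratio.
    """
    values = seq.values if isinstance(seq, RRISequence) else np.asarray(seq, dtype=float)
    if values.size < window + 1:
        raise RRIError(
            f"sequence of length {values.size} too short for a {window}-beat window"
        )
    csum = np.concatenate(([0.0], np.cumsum(values)))
    trailing_mean = (csum[window:-1] - csum[:-window - 1]) / window
    ratios = values[window:] / trailing_mean
    return RatioSequence(ratios=ratios, start_index=window)


def fit_ar1(series: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares AR(1) fit in the residual convention ``e_n = x_n + a1 x_{n-1}``.

    The coefficient minimizes ``sum((x_n + a1 x_{n-1} - c)^2)`` jointly with
    an intercept ``c`` (the residual noise has a non-zero mean, so the fit
    must not force it through zero).  Returns ``(a1, residuals)`` with
    ``residuals[j] = x_{j+1} + a1 * x_j``.  A zero-variance input yields
    ``a1 = 0`` and constant residuals.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise RRIError(f"need at least 3 values to fit an AR(1) model, got {x.size}")
    lagged, current = x[:-1], x[1:]
    var_lagged = np.var(lagged)
    if var_lagged == 0.0 or np.var(x) == 0.0:
        return 0.0, current.copy()
    # OLS slope of x_n on x_{n-1}; the residual convention negates it.
    slope = np.cov(lagged, current, bias=True)[0, 1] / var_lagged
    a1 = -float(slope)
    residuals = current + a1 * lagged
    return a1, residuals


def residual_sd(residuals: np.ndarray) -> float:
    """Sample standard deviation (N−1 denominator) about the residual mean."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise RRIError("need at least 2 residuals for a standard deviation")
    return float(np.std(e, ddof=1))


def derive_criteria(
    seq: RRISequence | np.ndarray,
    multiplier: float = DEFAULT_MULTIPLIER,
    window: int = DEFAULT_WINDOW,
) -> Criteria:
    """Derive recording-specific detection limits from the sequence itself.

    Pipeline: trailing-window ratios → AR(1) prewhitening → residual SD →
    limits ``1 ± multiplier * SD``.  The limits are centred on 1 (the ratio
    mean on clean data) rather than on the empirical residual mean; the two
    differ by well under 0.01 on physiological recordings.

    Raises
    ------
    DegenerateCriteriaError
        If the residual SD is zero (e.g. a constant sequence), which would
        make every subsequent value an artifact.
    """
    values = seq.values if isinstance(seq, RRISequence) else np.asarray(seq, dtype=float)
    if values.size < MIN_SEQUENCE_LENGTH:
        raise RRIError(
            f"need at least {MIN_SEQUENCE_LENGTH} intervals to derive criteria, "
            f"got {values.size}"
        )
    ratio_seq = adjacent_ratios(values, window=window)
    a1, residuals = fit_ar1(ratio_seq.ratios)
    sd = residual_sd(residuals)
    if sd == 0.0:
        raise DegenerateCriteriaError(
            "ratio residuals have zero spread (constant input?); "
            "detection limits would be zero-width"
        )
    return Criteria(residual_sd=sd, multiplier=multiplier, ar1_coefficient=a1)
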