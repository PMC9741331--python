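"""Synthetic sinus-rhythm RRI sequences with ground-truth artifact injection.

The generator produces a stationary, positive tachogram built from a base
level plus two sinusoidal modulations — a fast one (~4-beat period, standing
in for respiratory sinus arrhythmia) and a slower one (~10-beat period,
standing in for baroreflex/Mayer-wave rhythm) — plus AR(1) Gaussian noise.
This gives the short-range serial correlation (a few to a few tens of beats)
that the detection window relies on, without claiming physiological realism
beyond the mean and variability ranges of adult sinus rhythm.

The injectors emulate the two beat-detection failure modes and segment
noise:

* **missed beat** — an undetected R-peak: two adjacent intervals are
  replaced by their sum (one abnormally long interval);
* **split beat** — a false extra detection: one interval becomes several
  short ones summing exactly to the original;
* **noise burst** — a short segment replaced by wildly jittered values whose
  sum still matches the segment.

All injectors preserve total recording time *exactly*, because misdetection
redistributes time rather than creating or destroying it; this is what makes
the cleaner's time-conservation claim falsifiable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RRIError, RRISequence

__all__ = [
    "ArtifactSpec",
    "GroundTruth",
    "generate_clean_rri",
    "inject_missed_beats",
    "inject_split_beats",
    "inject_noise_burst",
    "apply_artifacts",
]

#: Maximum artifact fraction the injectors accept; beyond a few percent the
#: corrupted series no longer resembles a mostly-sinus recording.
MAX_ARTIFACT_RATE = 0.05


@dataclass(frozen=True)
class ArtifactSpec:
    """Artifact mix for :func:`apply_artifacts` (rates are beat fractions)."""

    missed_beat_rate: float = 0.0
    split_beat_rate: float = 0.0
    split_parts: int = 2
    noise_burst_count: int = 0
    noise_burst_len: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missed_beat_rate <= MAX_ARTIFACT_RATE):
            raise RRIError(f"missed_beat_rate must be in [0, {MAX_ARTIFACT_RATE}]")
        if not (0.0 <= self.split_beat_rate <= MAX_ARTIFACT_RATE):
            raise RRIError(f"split_beat_rate must be in [0, {MAX_ARTIFACT_RATE}]")
        if self.split_parts < 2:
            raise RRIError("split_parts must be >= 2")
        if self.noise_burst_count < 0 or self.noise_burst_len < 1:
            raise RRIError("noise burst counts must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """A clean/corrupted pair with per-index artifact labels.

    ``mask[i]`` labels corrupted index ``i`` as ``"normal"``, ``"missed"``,
    ``"split"`` or ``"noise"``.  ``mapping`` lists
    ``(corrupted_start, corrupted_end, clean_start, clean_end)`` half-open
    span pairs for every artifact.
    """

    clean: RRISequence
    corrupted: RRISequence
    mask: list[str]
    mapping: list[tuple[int, int, int, int]] = field(default_factory=list)


def generate_clean_rri(
    n: int,
    mean_ms: float = 900.0,
    sd_ms: float = 50.0,
    seed: int = 0,
) -> RRISequence:
    """Generate an artifact-free sinus-rhythm-like tachogram.

    ``mean_ms`` sets the base level (normal adult sinus rhythm spans roughly
    650–1250 ms), ``sd_ms`` the overall beat-to-beat spread, split between
    the two sinusoidal modulations and AR(1) noise.  Values are clipped to
    [0.5, 1.5] × ``mean_ms`` so the clean series can never contain anything
    resembling a missed or split beat.
    """
    if n < 100:
        raise RRIError(f"need n >= 100 clean beats, got {n}")
    if not (400.0 <= mean_ms <= 1500.0):
        raise RRIError(f"mean_ms must be in [400, 1500], got {mean_ms}")
    if sd_ms <= 0:
        raise RRIError("sd_ms must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    # ~respiratory (4-beat) and ~baroreflex (10.5-beat) modulations
    amp = 0.5 * sd_ms
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    modulation = (amp * np.sin(2 * np.pi * t / 4.0 + phase1)
                  + amp * np.sin(2 * np.pi * t / 10.5 + phase2))
    # AR(1) noise carrying the remaining variance
    phi = 0.5
    target_var = max(sd_ms**2 - 2 * (amp**2 / 2.0), (0.3 * sd_ms) ** 2)
    innov_sd = np.sqrt(target_var * (1 - phi**2))
    eps = rng.normal(0.0, innov_sd, size=n)
    noise = np.empty(n)
    noise[0] = eps[0] / np.sqrt(1 - phi**2)
    for i in range(1, n):
        noise[i] = phi * noise[i - 1] + eps[i]
    values = np.clip(mean_ms + modulation + noise, 0.5 * mean_ms, 1.5 * mean_ms)
    return RRISequence(values, origin_label=f"synthetic(mean={mean_ms},sd={sd_ms},seed={seed})")


def inject_missed_beats(seq: RRISequence, k: int, seed: int = 0) -> GroundTruth:
    """Merge ``k`` random non-overlapping adjacent pairs into single long beats."""
    x = seq.values
    n = x.size
    if k < 0 or k > MAX_ARTIFACT_RATE * n:
        raise RRIError(f"k must be in [0, {int(MAX_ARTIFACT_RATE * n)}] for n={n}")
    rng = np.random.default_rng(seed)
    starts = _pick_nonoverlapping(rng, n, k, length=2)
    merged = set(starts)
    out: list[float] = []
    mask: list[str] = []
    mapping: list[tuple[int, int, int, int]] = []
    i = 0
    while i < n:
        if i in merged:
            out.append(float(x[i] + x[i + 1]))
            mapping.append((len(out) - 1, len(out), i, i + 2))
            mask.append("missed")
            i += 2
        else:
            out.append(float(x[i]))
            mask.append("normal")
            i += 1
    corrupted = RRISequence(out, origin_label=f"missed_beats(k={k},seed={seed})")
    return GroundTruth(clean=seq, corrupted=corrupted, mask=mask, mapping=mapping)


def inject_split_beats(
    seq: RRISequence,
    k: int,
    parts: int = 2,
    seed: int = 0,
) -> GroundTruth:
    """Split ``k`` random intervals into ``parts`` short ones with the same sum.

    Proportions are random but each part receives at least 20% of an equal
    share, so no part degenerates to (near-)zero duration.
    """
    if parts < 2:
        raise RRIError("parts must be >= 2")
    x = seq.values
    n = x.size
    if k < 0 or k > MAX_ARTIFACT_RATE * n:
        raise RRIError(f"k must be in [0, {int(MAX_ARTIFACT_RATE * n)}] for n={n}")
    rng = np.random.default_rng(seed)
    chosen = set(int(i) for i in rng.choice(n, size=k, replace=False)) if k else set()
    out: list[float] = []
    mask: list[str] = []
    mapping: list[tuple[int, int, int, int]] = []
    for i in range(n):
        v = float(x[i])
        if i in chosen:
            u = rng.dirichlet(np.ones(parts))
            p = 0.2 / parts + 0.8 * u  # each part >= 20% of an equal share
            pieces = v * p
            pieces[-1] = v - float(np.sum(pieces[:-1]))  # exact sum
            start = len(out)
            out.extend(float(q) for q in pieces)
            mapping.append((start, len(out), i, i + 1))
            mask.extend(["split"] * parts)
        else:
            out.append(v)
            mask.append("normal")
    corrupted = RRISequence(out, origin_label=f"split_beats(k={k},parts={parts},seed={seed})")
    return GroundTruth(clean=seq, corrupted=corrupted, mask=mask, mapping=mapping)


def inject_noise_burst(
    seq: RRISequence,
    count: int,
    burst_len: int = 5,
    seed: int = 0,
) -> GroundTruth:
    """Replace ``count`` random segments of ``burst_len`` beats with jitter.

    Replacement values are drawn uniformly in [0.3, 2.5] × the local mean and
    rescaled so the segment's total duration is unchanged; most of them land
    outside any plausible detection limits, emulating a stretch of muscle or
    channel noise.
    """
    x = seq.values
    n = x.size
    if count < 0 or burst_len < 1:
        raise RRIError("count and burst_len must be non-negative/positive")
    if count * burst_len > MAX_ARTIFACT_RATE * n:
        raise RRIError(
            f"count*burst_len={count * burst_len} exceeds {MAX_ARTIFACT_RATE:.0%} of n={n}"
        )
    rng = np.random.default_rng(seed)
    starts = _pick_nonoverlapping(rng, n, count, length=burst_len)
    out = x.astype(float).copy()
    mask = ["normal"] * n
    mapping: list[tuple[int, int, int, int]] = []
    for s in starts:
        seg = out[s:s + burst_len]
        seg_sum = float(np.sum(seg))
        local_mean = seg_sum / burst_len
        # additive sum-matching keeps the full draw spread (a multiplicative
        # rescale would compress excursions toward the mean); redraw the rare
        # segments the shift would push to non-positive values
        for _ in range(100):
            draws = rng.uniform(0.3, 2.5, size=burst_len) * local_mean
            draws += (seg_sum - float(np.sum(draws))) / burst_len
            if draws.min() > 0.05 * local_mean:
                break
        else:
            draws = rng.uniform(0.3, 2.5, size=burst_len) * local_mean
            draws *= seg_sum / float(np.sum(draws))
        draws[-1] += seg_sum - float(np.sum(draws))  # cancel float dust
        out[s:s + burst_len] = draws
        mapping.append((s, s + burst_len, s, s + burst_len))
        for j in range(s, s + burst_len):
            mask[j] = "noise"
    corrupted = RRISequence(out, origin_label=f"noise_burst(count={count},seed={seed})")
    return GroundTruth(clean=seq, corrupted=corrupted, mask=mask, mapping=mapping)


def apply_artifacts(seq: RRISequence, spec: ArtifactSpec) -> GroundTruth:
    """Apply the full artifact mix of ``spec`` to ``seq``.

    Missed beats are injected first, then splits, then noise bursts, each
    stage seeded from ``spec.seed``.  The composite mask and mapping are
    expressed in the coordinates of the final corrupted sequence (a missed
    beat that is later split or overwritten by a burst keeps the later
    label).  Total time is preserved exactly throughout.
    """
    n = len(seq)
    gt1 = inject_missed_beats(seq, k=round(spec.missed_beat_rate * n), seed=spec.seed)
    gt2 = inject_split_beats(gt1.corrupted, k=round(spec.split_beat_rate * n),
                             parts=spec.split_parts, seed=spec.seed + 1)
    gt3 = inject_noise_burst(gt2.corrupted, count=spec.noise_burst_count,
                             burst_len=spec.noise_burst_len, seed=spec.seed + 2)

    # carry stage-1 labels through the split re-indexing (the noise stage does
    # not re-index, so stage-2 output coordinates are final)
    split_spans = {src_start: (c_start, c_end) for c_start, c_end, src_start, _ in gt2.mapping}
    mask: list[str] = []
    missed_spans: list[tuple[int, int, int, int]] = []  # clean coords untraceable: -1
    for i1, lab1 in enumerate(gt1.mask):
        if i1 in split_spans:
            c0, c1 = split_spans[i1]
            mask.extend(["split"] * (c1 - c0))
        else:
            if lab1 == "missed":
                missed_spans.append((len(mask), len(mask) + 1, -1, -1))
            mask.append(lab1)
    for s, e, _, _ in gt3.mapping:
        for j in range(s, e):
            mask[j] = "noise"
    mapping = (missed_spans
               + [(c0, c1, -1, -1) for c0, c1 in split_spans.values()]
               + [(s, e, s, e) for s, e, _, _ in gt3.mapping])
    return GroundTruth(clean=seq, corrupted=gt3.corrupted, mask=mask,
                       mapping=sorted(mapping))


def _pick_nonoverlapping(rng: np.random.Generator, n: int, k: int, length: int) -> list[int]:
    """Pick ``k`` non-overlapping start indices for segments of ``length``."""
    if k == 0:
        return []
    starts: list[int] = []
    occupied = np.zeros(n, dtype=bool)
    attempts = 0
    while len(starts) < k:
        attempts += 1
        if attempts > 200 * k:
            raise RRIError("could not place non-overlapping artifact segments")
        s = int(rng.integers(0, n - length + 1))
        if not occupied[s:s + length].any():
            occupied[s:s + length] = True
            starts.append(s)
    return sorted(starts)
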