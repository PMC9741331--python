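# Methods

## Detection criteria

The detector works on the ratio of each RR interval to the trailing moving
average of the three preceding accepted intervals (strictly causal; a
centred window would let an artifact contaminate its own reference). On
artifact-free data this ratio sequence is centred on 1, but it is
heavy-tailed — the ratio of two near-normal variables is Cauchy-like — so
thresholds are not taken from the ratios directly. A first-order
autoregressive model is fitted by ordinary least squares with an intercept
(the residual noise has a non-zero mean), in the residual convention

    e_n = x_n + a1 * x_{n-1},

and the detection limits are `1 ± m·sd(e)` with `m = 3` by default (99.7%
Gaussian coverage). A ratio exactly on a limit counts as normal. The limits
are derived **once per recording from the full ratio sequence, artifacts
included**. That choice keeps the procedure single-pass, but it means heavy
corruption widens the limits: at ~2% split-beat density the residual SD
roughly triples, and lopsided split halves (ratio 0.6–0.9) fall inside the
limits and are undetectable in principle. The optional `robust` mode
(`--robust`) re-derives the limits from the output of a first cleaning pass
and cleans again; on 2%-corrupted synthetic data this restores the limits to
within a few percent of their clean-data values. It is off by default
because the single-pass behaviour is the reference behaviour.

Two quantitative consequences worth knowing:

* the limits use the *prewhitened* residual SD, which is slightly narrower
  than the raw ratio SD (by `sqrt(1 − a1²)`); the false-positive rate on
  clean data is therefore a little above the nominal 0.3% (measured ≈0.5–0.7%
  on the synthetic generator), and
* `derive_criteria` refuses constant input (zero residual SD would flag
  everything).

## Correction state machine

A single forward pass with five ingredients of working memory: the 3-beat
moving window (accepted values only), a 30-value FIFO backup field of beats
classified normal (so fills always reflect the current rhythm), the
non-negative time buffer, and the cumulative input/output time counters.
Initialization scans for the first three consecutive mutually consistent
values, then fills the backup field from the following values classified
normal against the running window; anything before that start point is
emitted unchanged (conservation outranks cleaning at the edges).

**Reference mean.** All corrected emissions are sized by a reference mean:
the window mean while its ratio to the backup-field mean lies within the
detection limits, otherwise the backup-field mean. The 3-beat window tracks
genuine rhythm changes but is fragile — with wide limits, a run of
borderline-short accepted beats can drag it down, after which window-sized
fills would re-emit short beats indefinitely (a measured failure mode, not a
theoretical one: cleaned variance several times the corrupted variance).
The 30-beat field is the robust estimate of the same quantity; switching to
it when the two disagree makes the machine self-correcting within a couple
of beats.

**Long artifacts** (ratio above the upper limit): the artifact's time plus
the buffer is refilled by independent seeded draws from the backup field,
rescaled to the reference mean and clipped to a normal ratio; draws are
emitted while at least one upper-limit beat of time remains, one closing
draw is clamped to the remaining time, and the sub-beat remainder goes to
the buffer. Independent draws keep the fill deviations serially
uncorrelated (white): per-event exact-sum rescaling was tried first and
rejected because the zero-sum constraint made consecutive fill deviations
anticorrelate at lag 1 by up to −0.5.

**Short artifacts** (ratio below the lower limit): the artifact is summed
with the buffer and then with subsequent input intervals until one window
mean of time is accumulated, then re-emitted as `round(acc / reference)`
reference-mean beats (rounded down if it would overdraw; possibly zero when
the window is depressed, in which case the time simply waits in the buffer).
If the input ends mid-accumulation the collected time is emitted as one
closing interval flagged truncated.

**Normal values** are emitted unchanged; afterwards, while the buffer holds
at least one reference mean, an inserted beat of that size is emitted and
charged to the buffer.

By construction `time_in == time_out + buffer` holds exactly (to float
rounding) after every step, the buffer is non-negative and below roughly one
beat, and the terminal time difference equals the final buffer. The
counters report beats passed through (`Nr`), added (`incNr`: fills beyond
the first replacement, plus insertions) and removed (`decNr`: aggregation
deficit). Determinism: identical (sequence, criteria, seed) gives
bit-identical output. Different seeds conserve the same total time but may
flip rare borderline classifications, so counters agree only to within a
couple of counts.

## HRV metric suite

Standard time-domain estimators: mean with denominator N and sample
variance with N−1 about the mean. (Some printed formulations of these
quantities use N−1 in the mean and a dimensionally inconsistent variance
form; the standard estimators are the only ones consistent with reported
group means, and the divergence is noted at the function level.) Poincaré
descriptors use `SD1² = var(ΔRRI)/2` and `SD2² = 2·var(RRI) − var(ΔRRI)/2`,
so `SD1² + SD2² = 2·var(RRI)` is an exact identity; the SD2 radicand is
clamped at zero for degenerate inputs.

Residual noise uses a Burg (forward-backward least squares) autoregressive
fit of order 16 by default on the mean-centred series, via
`statsmodels.regression.linear_model.burg`, with coefficients sign-flipped
into the residual convention above and residuals computed for `n ≥ k`. The
residual variance uses the population (N) denominator. Artifacts are
serially uncorrelated, so they load onto the AR residual almost entirely;
the percent reduction of residual variance is the most sensitive
before/after summary (≈80% on 2%-corrupted synthetic data).

## Synthetic ground truth

`generate_clean_rri` builds a stationary positive tachogram: base level
(default 900 ms, valid range 400–1500 ms) plus a ~4-beat and a ~10.5-beat
sinusoidal modulation (stand-ins for respiratory sinus arrhythmia and
baroreflex rhythm, each with amplitude half the target SD) plus AR(1)
Gaussian noise (lag coefficient 0.5) carrying the remaining variance,
clipped to [0.5, 1.5]× the mean. Default SD is 50 ms at 900 ms. This gives
the short-range serial structure the 3-beat detector relies on; it does
**not** model circadian drift, ectopic beats with compensatory pauses, or
non-stationary variance, so passing tests bound behaviour on stationary
sinus-like rhythm only.

The injectors preserve total time exactly — misdetection redistributes
time, it does not create it — which is what makes the conservation claims
falsifiable end to end. Missed beats merge non-overlapping adjacent pairs;
split beats divide one interval into parts of random proportions (each at
least 20% of an equal share); noise bursts replace short segments with
U(0.3, 2.5)×local-mean draws shifted additively to match the segment sum
(an additive shift keeps the draw spread; a multiplicative rescale would
compress excursions — even so, exact sum matching re-centres each segment
on its local mean, so roughly 72–83% rather than all burst beats land
outside clean-data limits). Rates are capped at 5% of beats; the method is
validated in the few-percent regime and repair quality at 2% split density
depends on the robust mode, as above.

## Sizes and defaults

| parameter | default | meaning |
|---|---|---|
| window | 3 beats | moving-average reference for ratios |
| backup | 30 beats | fill source / robust rhythm estimate |
| multiplier | 3.0 | SD multiplier for limits (99.7%) |
| ar_order | 16 | Burg order for residual-noise metrics |
| seed | fixed constant | reproducible CLI runs |

Test and acceptance workloads use 20,000-beat tachograms (the scale the
method targets, ≈5 h), except the 100-run conservation sweep, which uses
4,000 beats per run across means 656–1255 ms to keep the whole sweep in a
few seconds; conservation is a per-step invariant, so run length does not
weaken the check.

## Known limitations

* Everything outside the ratio limits is treated as an artifact; ectopic
  beats are "corrected" like artifacts rather than classified
  physiologically.
* Detection quality is bounded by the once-per-recording criteria: at split
  densities ≳2% use `robust=True`.
* No frequency-domain HRV metrics and no spectral-density comparison; the
  AR residual variance is the spectral summary used.
* The tool starts at detected RRIs; it does not read ECG waveforms or
  perform beat detection.
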