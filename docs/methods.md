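# Methods

This note documents the models, conventions, and numerical choices behind
laminamod, and what the synthetic-data validation does and does not show.

## Conventions

All times are in seconds, depths in micrometres below the pia, rates in Hz.
Time windows are half-open `[start, end)`. An undefined modulation index
(zero activity in both conditions) is NaN in memory and an empty field on
disk; it is never conflated with MI = 0 ("no change"). Classification
inequalities are strict for MI thresholds (`mi > 1/9`) and non-strict for
the gain-fit cut-offs (`slope ≥ 1.3`, `slope ≤ 0.7`, `intercept ≥ 0.15`,
`intercept ≤ −0.08`), matching how the criteria are conventionally printed.

## Trial protocol and measurement windows

Tone trials present nine pure-tone frequencies, 4–64 kHz in 0.5-octave
steps, 200 ms, nine repeats per condition, with LED and No-LED trials
interleaved; on LED trials the illumination starts 1 s before tone onset
and ends 1 s after tone offset. Spontaneous rate is measured in the 500 ms
preceding the tone — on LED trials this window sits inside the LED steady
state. Tone-evoked responses subtract the same-condition baseline (0–200 ms
pre-tone) and sum only the positive-going PSTH during the tone, so
LED-induced changes of the spontaneous rate do not contaminate the evoked
measure. PSTHs use 25-ms bins (10 ms for LED-onset dynamics, 0.5 ms for
suppression-kinetics fitting).

## Responsiveness test

A unit–frequency pair is responsive when (1) some response bin exceeds a
fixed threshold in more than one third of trials, and (2) the
trial-averaged PSTH exceeds the threshold at some bin. The threshold is the
baseline mean plus 3.7 × SD, where mean and SD are taken over the bins of
the **trial-averaged** pre-LED baseline PSTH. The alternative reading — SD
over single-trial baseline bins — quantizes the threshold to ≥ 2 spikes
per 25-ms bin at ordinary baseline rates and makes 25–40 Hz evoked
responses undetectable at nine trials, so it was rejected. The 3.7
multiplier itself can be re-derived with `calibrate_threshold_roc`, which
returns the most stringent multiplier that still reaches a 90% true-positive
rate on a labeled set (the "smallest multiplier ≥ 90% TPR" formulation is
degenerate because TPR is monotone non-increasing in the multiplier).

## Laminar assignment

CSD is the plain negated second spatial difference (no Vaknin channels, no
spline iCSD): it is the simplest standard estimator and the border rule
downstream only needs relative amplitudes. The early sink is the most
negative CSD in 0–20 ms post-click; L4 borders are the contiguous channels
at or below half the sink amplitude. A sink must be at least twice as deep
as the most extreme pre-click excursion of the same per-channel
min-statistic — comparing the minimum of many samples against a raw
3×SD floor would flag pure noise as a sink. Ties at layer borders go to
the deeper layer; the L4-lower→white-matter span splits at its midpoint
into L5/L6, and units in its lowest third carry a conservative-L6 flag for
single-unit analyses (guarding against opsin-expressing L5 cells). Depth
normalization maps each layer linearly onto 4/4/6/6 bins (RS) or 2/2/3/3
(FS).

## Unit quality and classes

Fast-spiking units have trough-to-peak width ≤ 0.4 ms (boundary
inclusive). ISI screening compares the observed fraction of intervals
shorter than the refractory period (2 ms for RS, 1.5 ms for FS/thalamus)
with the chance fraction `1 − exp(−rate·t_ref)` of a rate-matched Poisson
train; the single-unit flag requires this contamination ratio to stay
below 5%. Units whose firing MI in the first 50 ms of LED exceeds +1/3 are
treated as directly photoactivated and excluded from multi-unit pools.

## Gain decomposition

Responses per frequency are normalized to the unit's control
best-frequency response. Points with both normalized responses above 10%
of the peak are fit, plus the largest-response excluded point, by ordinary
least squares; good fits require Pearson R > 0.4 and at least three
points. Class assignment: two same-direction criteria (divisive +
subtractive, or multiplicative + additive) give `mixed`; opposing criteria
give `other`; no criterion with an unchanged overall evoked MI (|MI| ≤ 1/6
over the responsive frequencies) gives `no_change`. BW70 is
`(n_responsive − 1) × 0.5` octaves on the 0.5-octave grid — a deliberate,
monotone stand-in since no continuous bandwidth formula is prescribed for
this nine-tone protocol.

## Suppression-onset decomposition

The LED-aligned pooled PSTH, normalized to the pre-LED baseline, is fit on
[0, 60 ms] by `r(t) = 1 − Σ Aᵢ(1 − e^{−(t−dᵢ)/τᵢ})` with one or two
components. Numerical scheme: delays on a 1-ms grid over 0–30 ms (the
second delay ≥ the first), amplitudes by nonnegative linear least squares
over a log-spaced τ grid (variable projection), then a bounded polish
(`A ∈ [0, 1.5]`, `τ ∈ [0.5, 60] ms`) alternating with delay re-grids from
the four best starting candidates. τ is capped at the 60-ms window because
larger values degenerate into an unconstrained linear ramp. The two
components must satisfy τ_slow ≥ 2 τ_fast (otherwise the decomposition is
a degenerate split of a single exponential); the slow component is kept
only if its amplitude exceeds 0.05 — the scale reported as negligible for
single-component layers — and if it beats a BIC-style residual margin for
its three extra parameters. The PSTH is denoised by a Gaussian-weighted
moving average with a 2-ms window (σ = window/5), and the model bases are
convolved with the same kernel so smoothing introduces no bias. The start
level is anchored at the normalized baseline (=1) rather than left free:
with a free intercept, the reported delay ("first time the fitted curve
falls below one") becomes degenerate whenever the fitted start dips below
one. Suppression is declared present when the mean drop over the last
third of the window clears three times its standard error.

Kinetics crossings (latency 20%, decay 100%→30%, FWHM 50%) are linearly
interpolated between bin centers; closed forms (decay of a pure
exponential = τ·ln(10/3), Gaussian FWHM = 2.355σ) are reproduced to 2% at
1-ms bins.

**Identifiability.** A Cramér–Rao analysis of the two-component model at
0.5-ms sampling over the 60-ms window shows the fast fraction
`A₁/(A₁+A₂)` is only estimable to ±0.1 when both time constants act well
inside the window (fast ≈ 2–5 ms, slow ≈ 10–20 ms) and the per-sample
noise SD is ≲ 0.02–0.03; with a slow τ comparable to the window the bound
exceeds ±0.3 regardless of estimator. The generator's superficial-layer
kinetics (delay 9 ms, fast τ 3 ms / slow τ 18 ms, fast fraction 0.63; L4:
delay 18.5 ms, single τ 15 ms) were chosen in that identifiable,
physiologically plausible regime. Recovery tests therefore run either at
Gaussian noise SD 0.02 or with Poisson counts at the pooled-across-mice
scale (~400–1000 baseline counts per 0.5-ms bin, e.g. ≥10 mice × ~1–1.5 kHz
pooled layer rate × ~200 LED trials); single-session fits are reported but
treated as qualitative.

## Synthetic-data generator

Units are inhomogeneous-Poisson with rate
`baseline × pupil_modifier × led_factor(t) + tuning_response(t)`:

* **Layers** — uniform depths within L1–3 (0–400 µm), L4 (400–500), L5
  (500–800), L6 (800–1100); 20 RS + 4 FS per layer by default.
* **LED gains** — multiplicative steady-state factors per layer, default
  (0.3, 0.55, 2.5, 0.9) for (L2/3, L4, L5, L6): photoactivated L5,
  suppression stronger in L2/3 than L4, variable L6; per-unit lognormal
  jitter (σ = 0.10). The gain is approached through the layer's
  delayed fast/slow exponential kinetics, so a normalized PSTH during
  suppression is exactly the model the kinetics module fits.
* **Tuning** — Gaussian in log₂ frequency, σ = 0.5 octaves (≈1–2 octave
  BW70 range), best frequencies on the tone grid, peak evoked rates
  10–40 Hz; the evoked bump is rectangular-rise/exponential-decay (onset
  10 ms, decay τ 30 ms) so latency, decay, and FWHM ground truths are
  closed-form.
* **FS dynamics** — superficial FS units are transient (onset gain 3
  decaying with τ 40 ms onto a suppressed steady state), sustained
  (gain 2), or suppressed, in proportions 0.4/0.2/0.4.
* **Arousal** — a bounded random walk of normalized pupil diameter across
  trials; the rate modifier is the U-shape `0.8 + 1.6(p − 0.5)²`.
* **LFP** — a negative spatial Gaussian (σ = 80 µm) at the L4 center with
  an early temporal bump; amplitudes are scaled in the CSD domain so the
  configured SNR is sink-to-CSD-noise (the second difference amplifies
  white potential noise by √6/h²).
* **Eye movie** — dark pupil ellipse on a brighter iris, additive Gaussian
  noise, 120×160 px at 30 Hz; occluded frames draw a dark eyelid band that
  reaches into the pupil and are flagged in the ground truth.

Spike sampling is exact: thinning for rate factors below 1, additive
Poisson spikes above 1, inverse-CDF sampling of the evoked template, so
counts in any window are Poisson with the integrated rate. An optional
2-ms dead time supports ISI-violation tests; the default is pure Poisson
since every analysis here consumes only rates.

What the generator does **not** emulate: spike-sorting errors and drift,
correlated (non-Poisson) variability, burst structure, tone-evoked
latency differences across layers, eye blinks with partial occlusion, or
the recurrent network dynamics that produce biphasic FS responses (the
biphasic shape is imposed, not emergent). Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed statistical
model, not robustness to every feature of real recordings.

## Validation problem sizes

* Steady-state MI: 20 seeds × 20 units × 162 trials; the seed-mean must be
  within ±0.02 of `(g−1)/(g+1)` (per-seed Monte-Carlo SE ≈ 0.011).
* L4 sink: 20 seeds at SNR 10, recovered center within one 25-µm channel.
* Best frequency: ≥90% exact grid recovery among units with peak evoked
  rate ≥ 25 Hz (20 seeds).
* Gain classes: ≥70% correct at |slope−1| ≥ 0.5 or |intercept| ≥ 0.2 with
  nine Poisson trials per condition (20 seeds).
* Null scenario (gain 1 everywhere): < 20% of units classified
  enhanced/suppressed in every one of 20 seeds.
* Fast fraction: within ±0.1 in ≥80% of 20 seeds (conditions above).
* Arousal: with constant gain 0.5 and U-shaped coupling, per-bin MI flat
  to ±0.05 and the control-rate U-shape preserved.

## Known limitations

Per-session suppression-delay estimates are noisy (the delay/τ ridge);
pooling across sessions is required for quantitative kinetics, as in the
underlying experimental design. The L4 border rule (half-amplitude extent)
is an explicit stand-in for a judgment call that is usually made by eye.
Deviant-frame detection replaces a manual curation step with a rolling
median/MAD rule and will not catch artifacts that mimic smooth diameter
changes. The ISI contamination correction assumes Poisson statistics for
the contaminating spikes.
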