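# Methods

This note documents the models, parameter choices and known limitations of
the `capcompare` pipeline in one place. Empirical numbers quoted here are the
ones the test suite and `scripts/acceptance.py` compute.

## Head model and montages

The head is a unit sphere; every analysis is radius-independent, so no
digitization or individual geometry is modeled. The extended ten-twenty
layout is generated from the idealized spherical 10-10 construction: each
row (Fp, AF, F, FC, C, CP, P, PO, O) crosses the midline at a multiple of
18° from the vertex, and lateral indices place electrodes at 18/36/54/72°
along the great circle through both preauricular points. The 64-label set
includes Fp1/Fp2, the full F/FC/C/CP/P rows, PO5/PO6 and Iz. The equidistant
layout covers the same cap with five concentric rings at polar angles
9–81° (half-step offset from the ten-twenty rows so the union contains no
coincident sites), ring populations roughly proportional to circumference,
64 sites total; lateral pairs are labeled `1L/1R, 2L/2R, …` front-to-back
starting at the outermost ring, midline sites `1Z, 2Z, …`. Nearest-neighbor
angular spacing has a coefficient of variation of ~0.08, comfortably inside
the quasi-uniformity requirement (< 0.35). The union of the two layouts is
the 128-site combined montage used as the common interpolation target.

## Synthetic sessions

The generator produces the four-segment paradigm (eyes open, eyes closed,
cued blinks, pattern-reversal VEP) as one continuous recording at 500 Hz
with per-segment annotations and trigger grids. It emulates, per channel:

| component | model | default |
|---|---|---|
| background | FFT-shaped 1/f^β noise, β = 1, flattened below 0.5 Hz | 5 µV SD |
| sensor noise | white Gaussian | 2 µV SD |
| alpha rhythm | sinusoid × slow random envelope, Gaussian spatial weight (σ = 35°) centered 65° behind the vertex | 10 Hz; 10 µV closed, 3 µV open |
| blinks | biphasic derivative-of-Gaussian transient (lobe σ = 60 ms, ~300 ms span) at each 2-s beep, frontal weight (σ = 30°) | 200 µV at the frontal maximum |
| VEP | two Gaussian-windowed lobes (σ = 10 ms) at 72 ms (negative, occipital) and 120 ms (positive, occipital) per reversal | 7.38 / 17.57 µV |
| bad channels | per-segment Bernoulli; replaced by near-zero (isoelectric) or 300 µV-SD noise traces with equal probability | gel 0.015, dry 0.19 |
| impedances | log-normal per cap; dry values boosted up to 2.5× centro-parietally | gel median 12 kΩ (σ=0.9), dry 400 kΩ (σ=0.75) |

Two choices deserve justification. First, the VEP scalp patterns are
standardized to unit *spatial standard deviation* before scaling, so the
configured component amplitudes are GFP amplitudes in µV — this makes the
generator's inputs directly comparable to the GFPt peaks the pipeline
measures. Second, bad channels are drawn independently per segment rather
than per session, so channel reliability aggregated over subjects × segments
is binomial with the per-draw probability as its mean; the defaults were
chosen to emulate the reported contrast between near-perfect gel reliability
and ~80% dry reliability with a centro-parietal impedance excess.

Session metadata (preparation and acquisition times, attention on a
sleepiness scale clipped at 8, comfort on a pain scale clipped at 10) is
drawn from per-cap normal distributions whose means and SDs equal the
published grand averages (gel preparation 32.3 ± 13.8 min, dry 12.4 ± 6.5
min, etc.), truncated at the scale bounds. The source material states the
attention scale inconsistently (1–8 in the text, 1–10 in the summary table);
the clip bound is therefore a config field and defaults to 8.

Randomness: one master seed; each (subject, cap, purpose) tuple hashes into
a `SeedSequence`, so any session is reproducible independent of execution
order, and the same seed yields bit-identical data.

What the generator does **not** emulate: realistic forward-modeled
topographies, EMG/line-noise/movement artifacts, inter-subject latency or
frequency variability, electrode drift within a session, or any coupling
between impedance and signal quality beyond the bad-channel probability.
Passing tests therefore show that the *pipeline* recovers what was injected
under its own assumptions, not that it would behave identically on human
recordings.

## Preprocessing

*Filters.* "24 dB slope" is read as 24 dB/octave, i.e. a 4th-order
Butterworth band-pass (1–40 Hz); the 50 Hz notch is a 3rd-order Butterworth
band-stop over 49–51 Hz. Both are applied forward–backward
(`sosfiltfilt`), doubling the magnitude slope and preserving component
latencies, which the evoked analysis compares at 2-ms resolution. Whether
the original analyses were zero-phase is not documented; zero-phase is the
defensible default when latencies matter.

*Channel rating.* The published procedure was manual inspection; the
automated surrogate rates 1-s windows and declares a channel bad when ≥ 50%
of its windows fail as isoelectric (SD < 0.1 µV) or artifactual
(peak-to-peak > 400 µV or SD > 8× the across-channel median). In the blink
segment the cued blinks *are* the signal, and a human rater would not count
them as artifacts; the rating grid is therefore shifted so each trigger is
centered in one window, and windows overlapping ±0.3 s around triggers are
excluded from rating. Channels are rated after filtering.

*Spherical splines.* m = 4 and N = 50 Legendre terms are the
literature-standard settings; increasing N from 20 to 50 changes smooth-field
interpolations by < 0.1%, i.e. the series is converged. The ridge on the
kernel diagonal is 10⁻⁶: large enough to keep the solve well-conditioned,
small enough that a degree-2 spherical-harmonic field sampled at the 64
ten-twenty sites is reconstructed at all 128 combined sites with a maximum
error of ~1.1% of the field range (the acceptance bound is 2%; a 10⁻⁵ ridge
misses it). The spline is fitted on good channels only; native good channels
pass through untouched, everything else (including native bad channels) is
interpolated. At least 16 good source channels are required.

## Analyses

*Resting state.* Analysis windows are taken from the segment center (30 s at
full scale; the desk-scale configuration uses 10 s against its 18-s
segments). Welch parameters — 2-s Hamming windows, 50% overlap — give 0.5 Hz
resolution over 1–40 Hz; band edges at exactly 8 or 13 Hz are included.
Topographic maps use the azimuthal-equidistant projection about the vertex
with spline interpolation on the back-projected grid directions.

*Evoked.* VEP epochs are −100/+400 ms with pre-stimulus baseline
correction (applied although the source procedure does not mention it;
switchable). Trials with any channel exceeding 150 µV peak-to-peak are
rejected whole. GFPt is the per-sample *population* SD (divide by N) across
channels — reference-independent by construction. Peak search windows
(N75: 50–100 ms, P100: 90–170 ms) bracket the published grand-average
latencies; ties break to the earliest sample and flat windows are flagged
low-confidence. Latency alignment shifts the *averaged* waveform (not raw
data) by a whole-sample amount toward the cohort-mean N75 latency, zero-
filling vacated samples; shifts beyond 50 ms raise an error.

*Comparison.* Blink overlays are compared as the mean of each cap's native
frontal pair (Fp1/Fp2 or 1L/1R) so that mixed-layout subjects remain
comparable; PSDs and VEPs are compared on the full combined montage
(flattened channels × bins/samples), GFPt as a time series. The KS normality
check estimates mean and SD from the sample (Lilliefors variant, via
statsmodels) because testing against a fully specified normal with estimated
moments would be anticonservative. The U test uses exact enumeration when
n_a·n_b ≤ 400 and the pooled sample is tie-free, otherwise the normal
approximation with midranks, tie and continuity correction (scipy). The
abstract-level "average channel reliability" has no unique aggregation rule,
so the report prints three: mean over per-channel ratios pooled across
layouts, mean of per-layout means, and pooled good/total ratings.

## Problem sizes

The desk-scale configuration used by the analysis scripts, the test suite
and the acceptance script runs 10 subjects with ten-fold shortened segments
(18/18/12/21 s), 40 VEP epochs at 0.5-s reversal intervals and a 10-s
resting-state analysis window. These sizes keep a full simulate–analyze–
compare cycle around half a minute on one CPU while leaving every stage with
enough data (≥ 5 Welch averages per window, ≥ 6 blinks, 40 evoked trials).
Full-scale segment durations (184/183/67/205 s, 150 epochs) remain the
defaults of `SimulationConfig`.

## Known limitations

- Grand-average spectral power and GFP amplitudes from 115 human volunteers
  are not reproducible from a 10-subject synthetic cohort; only parameter
  recovery, directions and calibrations are asserted.
- The bad-channel surrogate is threshold-based and blind to artifact types
  a human rater distinguishes (EMG bursts, electrode pops, drift).
- Blink overlays on mixed-layout subjects compare different physical sites
  (Fp1/Fp2 vs 1L/1R); the simulated frontal field is smooth enough that this
  is benign, real data may differ.
- EDF export quantizes to 16 bits over each channel's recorded range;
  round-trip error is bounded by range/65535 per channel.
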