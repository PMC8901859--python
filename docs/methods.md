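# Methods

This note records the models behind each analysis, the defaults and
their units, the choices made where the procedure was genuinely open,
and what the synthetic generator does and does not emulate.

## Imaging model and ΔF/F₀

Fluorescence is modelled as F(t) = F₀·(1 + ΔF/F(t)) with ΔF/F the sum
of exponential transients.  Two baseline conventions are implemented
(`compute_dff`):

* `global-median` (default, spontaneous recordings): F₀ is the
  per-neuron median of the whole trace — robust as long as transients
  occupy a minority of frames;
* `prestim-mean` (stimulus sessions): within each trial window the
  baseline is the mean of the 1-s pre-stimulus segment, falling back to
  the global median between trials.

Frames are 0-based and frame *k* occurs at time *k/f*; all stimulus
windows are half-open, [onset, onset + 2 s).

## Transient detection

The acceptance rule is a 2.5 × SD threshold on ΔF/F₀, with the SD taken
from the quiescent baseline.  Implementation details that matter:

* **Baseline SD** (`baseline_sd`): initialized from the MAD
  (× 1.4826) and refined by iterative ±3σ clipping about the median.
  Starting from the raw SD fails when transients occupy much of the
  trace (the clip never reaches the noise floor); the MAD start
  converges to the noise SD within ~10% even at 60% transient
  occupancy.
* **Peak finding** runs on a 0.15-s boxcar-smoothed copy of ΔF/F while
  the threshold stays anchored to the raw-trace SD.  Smoothing shrinks
  single-frame noise excursions by √3 but leaves the much slower
  (τ ≈ 1 s) indicator transients intact.
* **Transient shape criteria.**  A bare threshold-plus-local-maximum
  rule produced precision ≈ 0.25 on ground-truth rasters: Gaussian
  noise creates suprathreshold local maxima both at baseline and,
  after a −3σ dip, on the decay tail of a real transient.  Two
  additional criteria remove both failure classes: the peak's
  *prominence* must itself exceed the threshold (a bump riding a tail
  rises only by the noise amplitude), and the trace must stay elevated
  after the peak (mean ΔF/F over 0.3 s ≥ half the threshold; a noise
  spike at baseline decays immediately).  Minimum peak separation is
  0.25 s, ties resolved to the earliest frame.
* **Peak refinement.**  The smoothed peak drifts a few frames into the
  decay, which systematically pushed events evoked late in a stimulus
  window past its edge.  The marked frame is therefore the earliest
  raw-trace sample within 2 baseline SDs of the local maximum inside a
  ±0.25-s refinement window — on a single-frame rise this is the
  transient onset.  With the defaults, ground-truth evaluation gives
  recall 1.0 and precision 1.0 on isolated 6σ transients (0.5-s match
  tolerance) and a residual classification bias below 0.3 percentage
  points.

## Responsiveness, percent responsive, NAI

A neuron is responsive in a trial iff ≥ 1 detected peak lies in the
trial's window; response probability is responsive trials / trials.
"Percent responsive" for a stimulus is the across-trial average of the
percentage of cells responding in that trial — equivalently 100 × the
population-mean probability.  (The alternative reading, cells with ≥ 1
response across all 5 trials, would give ~41% at p = 0.10 and is not
what the summary figures of this assay report.)  NAI =
%responsive(S1)/%responsive(S4); it is undefined (raised as an error)
when the S4 percentage is zero.

## High-order synchrony

Total_n = ⌈T·f⌉ (1500 frames for 73.5 s at 20.4 Hz).  Firing(n) counts
frames with exactly *n* coincident transient peaks among the N
subsampled neurons (n ≥ 1; silent frames belong to no order), and
Correlation_prob(n) = Firing(n)/Total_n, so Σₙ Correlation_prob(n) ≤ 1.
The independent model shuffles each neuron's spike frames by an
independent uniform permutation — all cross-neuron structure is
destroyed, each neuron's spike count (hence rate) is exactly preserved.
A circular-shift variant (`method="circular"`), which additionally
preserves within-train interval structure, is available; the default is
the permutation because the observed trains' interval structure is not
part of the independence hypothesis being tested.  Range aggregation
sums Correlation_prob over 1–10 and 11–∞; percentiles of the range
aggregates are computed per shuffle, then across shuffles.  Default
10,000 shuffles; the calibration studies in the tests and acceptance
script use 1,000, which changes the 97.5th-percentile estimate of these
heavily discrete statistics negligibly.  Calibration under the study
conditions (30 neurons, 1500 frames, 0.03 spikes/frame): the high-order
band exceeds its null in 0% of independent runs, and in ≥ 95% of runs
containing population events (0.05 Hz, recruiting ≥ 12 of 30 neurons).

## Pairwise correlation and spatial structure

Preprocessing: 4th-order Butterworth low-pass at 2 Hz, applied
zero-phase (forward–backward) so transient timing is preserved; the
order and cutoff are conventions — the assay only fixes "Butterworth".
Deconvolution is the exact discrete inverse of the 3-s exponential
kernel, a(t) = x(t) − e^(−Δt/τ)·x(t−1), stable and parameter-free
beyond τ; thresholding zeroes everything below 2 × SD of the
deconvolved trace (negatives included), leaving sparse non-negative
vectors.  Without the filter an isolated noiseless transient
deconvolves to literally one impulse of its amplitude; with the filter
the impulse acquires the filter's (zero-phase, symmetric) footprint,
≥ 90% of its energy within ±0.25 s.  The pair coefficient is cosine
similarity; a zero vector yields NaN (flagged missing, excluded from
bin means).  Distance bins are half-open, default 50 µm.

## Random-k-subgroup NND

For each neuron of a group, k others are drawn uniformly without
replacement from the whole recorded population (the default pool;
a same-group-only mode exists) and the distance to the nearest of the
k is recorded; the per-neuron value is the running mean, iterated until
it changes by < 10⁻³ (relative) over 100 consecutive draws, capped at
10,000.  Group dispersion is the mean over members.  Draws for a k-sweep
are nested (first k of one random permutation), which makes dispersion
exactly nonincreasing in k — the finite-sample counterpart of the
order-statistics fact E[min of k+1] ≤ E[min of k] — and this is
asserted on every sweep.  The exact expectation over all C(m, k)
subgroups is available in closed form
(P(min = d₍ⱼ₎) = C(m−1−j, k−1)/C(m, k)) and agrees with the Monte-Carlo
estimate within 3 standard errors on small populations.

## Vidget

Score: 1000 → 100 Hz by 10-sample block means, (F − F₀)/F₀ with F₀ the
session-mean voltage, elementwise rectification √(x²), mean over
[onset, onset + 0.5 s].  Rectify-then-average is the default reading;
an RMS-over-window variant is selectable (`mode="rms"`).  Delay: first
post-onset time at which the rectified relative signal exceeds the
pre-onset baseline mean + 3 SD continuously for 50 ms (threshold rule
and parameters are declared conventions; the assay's original delay
estimator is not specified).  A trace that never crosses yields NaN,
not an error.  Cumulative slopes: the cumulative sum of the rectified
signal, scaled by the sample interval (units a.u./s), is fit by two
independent OLS lines with the breakpoint fixed at stimulus onset —
fixing the breakpoint matches the baseline/stimulation segmentation and
avoids an unidentifiable free-changepoint fit.  Exactly
piecewise-linear input is recovered exactly; slopes are unbiased under
additive Gaussian noise.

## Morphometrics

Only dendrite-typed SWC nodes (types 3/4) contribute; axons are
excluded; stems may hang off any soma-typed node.  Branch order is
centrifugal: a stem leaving the soma has order 1, +1 at every branch
point (≥ 2 dendritic children); a terminal's order is its segment's
order.  "Mean dendrite length" is ambiguous in the field (per primary
vs per segment); the default is total length / #primaries, consistent
with the DC formula's second factor, with a per-segment option.  DC is
linear in length, so rigid motions leave it unchanged and uniform
scaling scales it proportionally; both are asserted in tests.

## Synthetic generator

The generator emulates exactly the statistical structure the analyses
assume: per-trial Bernoulli evoked responses (uniform spike time within
the 2-s window — the assay does not constrain the latency
distribution), homogeneous Poisson background transients, shared
population events recruiting independent Bernoulli subsets, a single
exponential calcium kernel (τ = 1 s, an OGB-1-like convention), i.i.d.
Gaussian noise in ΔF/F units, piezo deflections as exponential bumps
with fixed latency, and random binary-branching trees.  Defaults:
f = 20.4 Hz, spontaneous T = 73.5 s, FOV 517.77 µm, amp = 0.10 ΔF/F
(matching typical evoked amplitudes of this preparation),
noise_sd = 0.02 (5σ transients), bg_rate = 0.05 Hz.  Protocols default
to 5 repeats of S1/S4 in randomized order (2 s on, 20 s ISI); the
4-stimulus, 3-repeat variant is configurable.  S1 denotes the small
(10.2°) and S4 the large (70.8°) spot throughout.

Not emulated: shot noise and photobleaching, motion artifacts, optical
point-spread blur (movies paint flat discs), neuropil contamination,
refractory or bursty spike statistics, and any biophysical network
dynamics.  Passing tests therefore certify the estimators under the
stated statistical model, not robustness to these real-data nuisances.

Parameter-recovery studies (and the corresponding acceptance
quantities) run stimulus sessions with bg_rate = 0: a background
transient inside a stimulus window is indistinguishable from an evoked
one by construction, so any nonzero background adds a known
1 − exp(−bg_rate·2 s) offset to every probability estimate rather than
testing the estimator.  The pipeline demo keeps the realistic 0.05-Hz
background.

## Problem sizes and determinism

Simulation sizes throughout tests and the acceptance script are chosen
at desk scale: 20 populations × 50 neurons × 5 trials for recovery,
200 runs × 1000 shuffles for each calibration arm, 30-neuron circuits
with 1500-frame recordings for synchrony, populations ≤ 8 for exact NND
enumeration.  Every stochastic component takes an explicit seed;
the pipeline derives per-stage sub-seeds from the master seed via
`SeedSequence.spawn`, so a fixed config reproduces byte-identical
summaries.

## Known limitations

* The detector's shape criteria assume transient decay well above the
  frame interval (τ·f ≫ 1); at much faster indicators the sustain
  window should be shortened.
* The NND convergence rule bounds the running mean's stability, not its
  distance to the true expectation; accuracy is the Monte-Carlo
  σ/√reps at stopping (~10³ draws at the default tolerance).
* Cosine coefficients of nonnegative sparse vectors are bounded below
  by 0 in practice; the [−1, 1] range is only exercised by signed
  inputs.
* The movie renderer targets extraction testing, not realistic imaging.
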