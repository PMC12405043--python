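# Methods

This note documents the models, numerical choices and limitations behind
`neuropinch`, in the spirit of the methods documentation of simulation
and statistics packages: what is computed, under which assumptions, and
what the synthetic validation does and does not demonstrate.

## Protocol model

A trial is a trapezoidal isometric contraction: 0.5 s rest, a 2 s ramp to
the target force, a 10 s hold, a 2 s ramp down, 0.5 s rest (15 s total).
Targets are 15/35/55/70% of maximal voluntary contraction (MVC), three
repeats each (12 trials per participant). EMG is sampled at 2222 Hz with
a 20–450 Hz bandwidth, four channels per muscle with channel 1 analysed;
force is sampled at 1000 Hz (the acquisition rate is configurable — the
default is a common force-plate/transducer rate). All of these are
`ProtocolSpec` fields.

## Synthetic motor pools

Each muscle is a pool of `n_units` (default 25) rate-coded motor units:

* **Recruitment.** Excitation thresholds follow the classic exponential
  spacing t_i = t_max·(e^{a·i/(n−1)} − 1)/(e^a − 1) with a = ln 30 and
  t_max = 0.6, so many low- and few high-threshold units; units recruit
  in fixed order (size principle by construction).
* **Rate coding.** Firing rate is min_rate (8 Hz) at recruitment and
  rises linearly with excess drive, saturating at a peak that declines
  from 35 Hz (first unit) to 25 Hz (last). Saturation is reached at an
  excitation of 1.2, above the working range, so drive noise near full
  excitation does not rectify against the cap.
* **Force.** Twitches are P·(t/T)·e^{1−t/T} kernels; amplitude P grows
  ~30-fold across the pool while contraction time T shrinks 60→20 ms
  (fast units dominate force). A unit firing steadily at rate r
  contributes r·P·T·e, which gives the pool an analytic static
  force-vs-excitation curve F(e).
* **EMG.** Motor-unit action potentials are biphasic
  (derivative-of-Gaussian) kernels of 5–15 ms support whose amplitude
  scales with P^0.6; channels 2–4 carry random per-unit gains. White
  measurement noise (5% of signal RMS) is added and the channel is
  band-limited to 20–450 Hz (4th-order zero-phase Butterworth).

**Closed-loop drive command.** The excitation sent to a pool is
F⁻¹(target(t)), the inverse of its static curve applied to the target
profile, advanced by the twitch-centroid lag (2·T̄) — emulating a
participant tracking the on-screen force trace feed-forward. Two
consequences: simulated hold force lands on the target (within a few
percent) at every level, and recruitment thresholds can be reported
directly in force units (% MVC), which is the scale the threshold
detector estimates. The residual mismatch between detected and
programmed thresholds (mean absolute error ≈ 1.7–1.8% MVC) reflects the
physical lag of force behind neural drive plus drive noise at the
crossing — the same biases the method faces on real data.

**Spike generation.** Spikes are drawn by time rescaling: the
instantaneous rate (zero below threshold) is integrated to operational
time Λ(t) and spikes fall where Λ crosses a cumulative sum of unit-mean
lognormal intervals with CV `isi_cv` (default 0.15). Time rescaling
phase-locks spikes to oscillatory drive components, makes a zero-jitter
unit under constant drive exactly periodic at its programmed rate, and
handles brief noise-driven de-recruitments without double-firing.

**Common drive.** Oscillatory drive is band-limited Gaussian noise
(default 20 ± 3 Hz) of which a fraction `strength` of variance is shared
between the two muscles' pools; sharing is injected *pre-pool*, so
intermuscular coherence in the synthetic EMG is physiological in origin
(shared synaptic input), not post-hoc signal mixing. Noise is
signal-dependent: oscillatory (sd 0.10) and broadband (sd 0.02)
components scale with the momentary command (nominal at command 0.5), as
in signal-dependent-noise models of motor output. This keeps recruitment
near zero drive precise while the hold phase carries a full-strength
oscillation. The 20 Hz drive barely moves force (twitches low-pass it)
but modulates firing, which is exactly the dissociation that makes
beta-band EMG coherence detectable in practice.

**Seeding.** All randomness flows from one integer through splittable
`SeedSequence` branches per participant/trial/muscle; any trial is
reproducible in isolation.

### What the generator does not emulate

No volume conductor (MUAPs are stylised kernels, channels differ only by
gain), no fatigue, no dynamic tasks, no decomposition errors beyond an
accuracy score drawn from N(96, 3). Simulated force COV (≈ 4–8% of
target) is higher than well-trained humans because the pool is small
(tens of units, so unfused-tetanus ripple is large) — adequate for
validating the metrics, not a claim about human steadiness values.
Passing tests therefore demonstrate that the *analysis chain* recovers
known ground truth under realistic signal structure, not that the
simulator reproduces any particular human dataset.

## Force metrics

* The "centre 6 s" COV window is centred on the midpoint of the hold as
  given by protocol timestamps, not detected from the force signal.
* The steadiest-window search runs over the whole trial; ramps
  self-exclude through their enormous target-referenced COV. Ties break
  to the earliest start. Windows and steps convert to samples by
  rounding half away from zero, so results are bit-stable across
  sampling rates. The search is exact (cumulative-sum implementation,
  verified against brute force).

## Firing statistics

* The accuracy gate (90%), minimum IPI count (7) and COV_IPIs cut (30%)
  are configurable; the COV rule removes only *strictly greater* than
  30%, with a 1e-12 relative slack so a value sitting exactly on the
  boundary is kept regardless of rounding.
* The 750 ms regular-onset window anchors at each candidate IPI's first
  spike and requires ≥ 2 IPIs to define a COV; force at onset is
  linearly interpolated.
* The mixed model is fitted by REML (statsmodels `MixedLM`) with two
  crossed variance components — participant, and firing threshold binned
  at 1% MVC (a continuous covariate cannot serve as a grouping factor
  directly; binning preserves the intent of absorbing size-principle
  variance). Singular fits pin the offending component at zero and are
  flagged. Marginal/conditional R² follow Nakagawa. EMM contrasts per
  (level, muscle) cell use a t critical value on between-participant
  degrees of freedom (participants − groups): a normal quantile
  undercovers on cohorts of ten per group. Cells with fewer than three
  units in either group are flagged "interpret cautiously".

## Coherence

* The printed form of the confidence limit is implemented as
  CL = 1 − 0.05^{1/(L−1)}; the alternative reading 0.05^{1/L}−1 would be
  negative for every L ≥ 2, so the standard formulation is used.
* 460 ms at 2222 Hz is ⌊1022.12⌋ = 1022 samples; a 4 s window yields
  exactly 8 whole segments and a 2222/1022 ≈ 2.174 Hz grid.
* Segments are mean-removed and transformed with a plain rectangular
  window (the classical multi-segment estimator); no taper by default.
* "Rectified and enveloped" is one operation: the magnitude of the
  analytic signal.
* Pooling sums L_i-weighted spectra (equivalently, the grand sum over
  all segments of all records) and re-applies the coherence formula;
  the CL uses ΣL_i. All trials of a group pool directly (trials are not
  pre-averaged within participants).
* Heterogeneity: per bin, z_i = atanh|R_i| with variance ≈ 1/(2L_i);
  χ² = Σ2L_i(z_i − z̄_w)² on k−1 df. Between-group differences use
  z_a − z_b with limits ±1.96·√(1/(2L_a) + 1/(2L_b)).
* Bands are half-open ([8,16), [16,30), [30,60) Hz) so each bin belongs
  to exactly one band; bins below 8 Hz are computed but marked
  unreliable (envelope coherence there does not reflect low-frequency
  common input), and peak detection runs on the reliable range.
* Cross-talk QC flags records whose coherence exceeds 0.8 in *all*
  bands simultaneously.

## Clustering

* The 500 ms RMS window slides one sample at a time and shrinks at the
  record edges (no padding).
* The shape-based distance is 1 − the shift-maximised, coefficient-
  normalised cross-correlation of z-normalised series. A `max_shift`
  parameter restricts the alignment search (0 disables it); with
  unrestricted shifts a series and its negation are rarely exactly 2
  apart, because some lag correlates positively.
* Centroids come from shape extraction: the leading right singular
  vector of the shift-aligned, column-centred member matrix (computed
  by SVD, so envelope length is not a bottleneck), sign-fixed against
  the member mean and z-normalised.
* k-shape starts from a seeded random partition, restarts three times
  and keeps the lowest-inertia model; iteration caps at 100. The elbow
  (WCSS) is reported for visual inspection, not auto-detected; chosen_k
  is the silhouette argmax over k = 2..5, and a best silhouette below
  0.25 flags the data as not supporting clustering.
* The pipeline decimates envelopes (default factor 22, ≈ 100 Hz) before
  clustering; the envelopes are already 500 ms-smoothed, so this loses
  nothing and keeps distance computations fast.

## Bootstrap statistics

Percentile CIs (10,000 resamples by default), the simplest method
consistent with small-sample estimation practice; resampling is
group-wise independent. Effect-size labels apply to |d| with half-open
intervals — a boundary value belongs to the upper class (d = 0.5 is
"moderate"). Degenerate resamples with zero pooled SD are dropped from
the d distribution.

## Validation workloads

The acceptance script and test suite size their simulations to run on a
single CPU in minutes: 500 Monte-Carlo replicates for the null
calibration at L = 8 and 96; 20 cohort seeds × 10 participants
(12-unit pools) for injected-drive recovery; 100 simulated cohorts
(2 groups × 5 participants × 2 levels × 2 muscles × 5 units) for
mixed-model coverage; 3 seeds × 4 levels with 25-unit pools for
threshold recovery; 20 two-template envelopes for cluster recovery.
These sizes were chosen once as the smallest cohorts at which the
corresponding group-level phenomena are stably expressed.

## Known limitations

* `MixedLM` variance components use nested optimisation that can hit
  boundary (singular) solutions on very small cohorts; such fits are
  flagged rather than rejected.
* The χ² heterogeneity and difference tests rely on the large-L
  Gaussianity of atanh|R|; with L = 8 per trial they are approximate,
  which is why group inferences pool segments first.
* Envelope coherence magnitudes depend on preprocessing choices
  (high-pass corner, rectification method); the defaults match the
  pipeline described above and are configurable, but results should be
  compared only within one preprocessing configuration.
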