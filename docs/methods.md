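# Methods

This note documents the models and procedures implemented in
`deviantcoding`, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical conventions that matter for
reproducing results.

## Stimulus model

A trial is a train of `n = 7` vibrissa deflections at 10 Hz. Onsets are at
`k/rate` seconds (train-relative), amplitudes equal the per-trial baseline
velocity (nominally ~25 mm/s, jittered ±10 % trial-to-trial) except at the
single deviant position, where the amplitude is `baseline · (1 + f)` with
`|f|` drawn from 5–15 %. Deviants occupy 0-based positions 2–6 — a deviant
always follows at least two repeated baseline deflections — except in the
head-fixed behavior generator, where deviants sit at positions 2–4 so that
deviant onsets fall at 200–400 ms (trials with later deviants are excluded
downstream). Deflections after a deviant are never analyzed.

Because deviant positions are randomized, baseline deflections outnumber
deviant deflections and skew earlier in the train. All deviant/baseline
comparisons therefore use **histogram matching**: the baseline set is
subsampled (uniformly at random, without replacement) to reproduce the
deviant set's position histogram exactly. When two trial sets must share an
amplitude distribution (stimulus-history analyses), per-bin subsampling
with a default bin width of 5 % of baseline equalizes the histograms; only
the larger set is subsampled within a bin.

## Spike-count model and the planted change coefficient

Counts are taken in half-open windows `[onset, onset + w)` with
`w = 100 ms`, the full inter-deflection epoch (configurable; the driven
classifier's six bins span the same epoch). The synthetic spike generator
is an inhomogeneous Poisson process:

- spontaneous rate `base_rate` (default 0.5 Hz),
- per deflection, a phasic kernel (half-cosine bump, 25 ms long at 10 ms
  latency — any phasic kernel inside the window is equivalent for the
  window statistics, and the shape is configurable) whose expected count is
  `adaptation[d] · (response_gain + amplitude_gain · (A_t − 25))`, with a
  geometric adaptation profile `0.9^d` and `response_gain = 0.15`
  spikes/deflection,
- at the deviant position, an additive term `(c/2) · sign` so that the
  expected increase-minus-decrease count difference equals the planted `c`
  exactly. The amplitude-gain term deliberately applies only to the
  trial-to-trial baseline variation, not additionally to the deviant step,
  so the planted `c` is the complete deviant effect.

The default rates encode the sparse-firing regime of awake supragranular
regular-spiking cells: spontaneous rates of ~0.5 Hz and evoked responses
of ~0.1–0.2 spikes per small deflection, the regime in which population
change coefficients of a few hundredths of a spike per deflection are the
relevant effect size. Per-layer defaults plant the qualitative structure
the analyses are designed to detect — heterogeneous two-signed
coefficients (|c| = 0.05) in L2/3, a uniform positive shift (c = +0.015)
in L4, no deviant coding in L5, and sparse responsiveness (13 % driven)
with amplitude gain in L6. These encode direction and realistic
magnitudes, not fidelity to any particular recorded animal.

Negative instantaneous rates (possible for large planted |c|) are clipped
at zero and counted in the output metadata.

A counts-first fast path (`simulate_count_tensor`) draws the per-window
counts directly from the same rate model; it is marginally equivalent to
the spike-time path (the kernel lies inside the window) and is used for
the large population calibrations, where only window counts matter. A test
verifies the two paths agree in their means.

## Driven-unit classifier

A unit is phasically driven if either of two Poisson-GLM criteria holds.
Counts are aggregated over trials (with trial count as exposure), in six
non-overlapping boxcar bins of ~16.7 ms:

1. **First-deflection criterion.** Offset (identified by a 100 ms
   pre-stimulus epoch) plus six bin coefficients for the first deflection;
   the unit passes if ≥ 2 bin coefficients have Wald p < 0.03 and some
   non-offset coefficient has `estimate − SE > 0.002`. The p-level is not
   corrected across the six bins (a calibration caveat; the conjunction
   with the lower-bound condition keeps the null false-positive rate at
   ~1 % empirically). "Lower standard-error bound" is read as
   `estimate − 1·SE`; a CI-bound variant would only be stricter.
2. **Shared-bin criterion.** The six bin coefficients are shared across
   deflections 1–3 (capturing weak but sustained drive); every deflection
   period after the first carries its own nuisance offset so that slow
   within-trial rate changes load on the offsets, not the phasic bins. The
   shared coefficients must satisfy the criteria of (1). Removing the
   drift protection (for its paired false-positive comparison) removes
   both the nuisance offsets and the later-period observations — the
   protection consists of modeling the later periods, not merely of extra
   parameters.

Wald p-values and IRLS fits come from statsmodels. Degenerate units
(all-zero counts, failed fits) are classified not-driven with a flag, never
raised as errors. The RS/FS waveform split uses a 0.4 ms trough-to-peak
threshold (configurable); the depth-to-layer map is L2/3: 100–350 µm,
L4: 350–450, L5: 450–650, L6: > 650, boundaries to the deeper layer.

## Change coefficients, surrogate null, broadening

The per-cell estimator is the **mean** count difference (medians
degenerate on small integer counts). The surrogate null resamples within
cell: per draw, each unit's position-matched baseline counts are split
without replacement into pseudo-groups of the true increase/decrease
sizes. Because the resampling is within-cell, the null inherits each
cell's count variability exactly as the observed distribution does; its
calibration is approximate (the draws share fixed baseline pools), which
the null-calibration test quantifies (empirical rejection ~4–9 % at
α = 5 % over 200 simulated populations).

ΔIQR uses the median surrogate IQR over draws; ΔH uses 15 equal-width bins
spanning the pooled observed∪surrogate range (a bin-count robustness test
checks the sign of ΔH over 10–30 bins). One-sided p-values use the add-one
estimator `p = (1 + #{draws ≥ observed}) / (1 + n_draws)`, so p = 0 cannot
occur. Defaults: 1,000 surrogate draws, 10,000 bootstrap resamples for
median CIs. The paired-condition (laser) sharpening statistic is
`S = median_u |c_u − median(c)|` per condition, bootstrapped over paired
units with mid-p tie handling (identical conditions give p ≈ 0.5).

## Penalized per-neuron GLM

One observation per analyzed deflection. Features: constant; signed
deviation (−1/+1 at the deviant deflection, 0 elsewhere — a signed
regressor rather than two per-direction indicators); standardized baseline
amplitude; raw spike counts of the 7 preceding deflections (zero-padded at
train start, not binarized); adaptation-position indicators with position
0 as the reference absorbed by the constant, so the unpenalized design is
full rank. Penalty `Q = ridge·I + diff·DᵀD` with the ridge zeroed on the
constant and `D` the first-difference operator over adjacent adaptation
coefficients (the literal expression `I + 10·D` is not a quadratic form;
`DᵀD` is the only PSD reading of a pairwise-difference penalty). Defaults
ridge = 1, diff = 10.

The objective (Poisson NLL + quadratic) is convex; a damped Newton solver
with backtracking converges to gradient norm < 1e−8 in a handful of
iterations, and the zero-penalty fit matches statsmodels IRLS to < 1e−6.
Bootstrap CIs resample deflection rows (100-fold); the interval endpoints
are the (B+1)-convention order statistics (2nd smallest / 99th of 100)
rather than interpolated percentiles — with only 100 draws, interpolation
understates the tails and measurably inflates the null false-positive rate
(~8 % vs ~4 % with order statistics, at a nominal 5 %). Null designs for
false-positive calibration relabel baseline-only trains with pseudo
deviant positions and signs.

## Calcium chain

`F0` is the 30th percentile in a 200 s sliding window, centered, shrinking
at the trace edges (avoids startup bias); ΔF/F = (F − F0)/F0 and is
invariant under global gain. Neuropil annuli dilate each somatic ROI
20 px along the scan (x) axis only and exclude all somata; they serve the
artifact-brightening profile and are not subtracted from somatic traces by
default (an optional r = 0.7 subtraction exists behind config).

Flyback-artifact correction is two-stage: (1) every flagged scan line
(every 4th or 8th) is replaced by the mean of its neighboring clean lines,
unconditionally (LED on or off), with one-sided interpolation at frame
edges; (2) the session-mean fractional brightening profile — each neuropil
trace divided by its own low-percentile session baseline (30th percentile,
anchoring the profile to LED-off frames), averaged across neuropil ROIs —
divides the somatic traces. On the synthetic closed loop (5 % line
brightening plus 1 % whole-frame scatter during LED-on blocks) the
post-correction residual is ~0.1 %.

Responsiveness: an ROI is stimulus-driven when the 10 % quantile of its
stimulus-period ΔF/F (0.5–1.5 s post onset, pooled over the selected
condition's trials) exceeds the 90 % quantile of its pre-stimulus period
(−1.5–0 s); the false-positive rate on null ROIs is ≈ 0. Evoked responses
are mean ΔF/F over 0–2 s after stimulus offset; the per-cell laser effect
bootstraps trial means of the ΔF/F value at the frame nearest 1 s post
onset (10,000 resamples, two-sided, threshold p < 0.0025). Selection
effects ("regression to the mean") are controlled by the cross-validated
variant: ROIs are classified on a training split of trials and encoding is
evaluated on held-out trials only.

The calcium generator convolves event trains with a double-exponential
GCaMP6s-like kernel (rise 0.18 s, decay 1.5 s — standard indicator
values), on a drifting baseline (±5 %, 300 s period) with neuropil
contamination and additive noise (ΔF/F SD 0.05, giving evoked transients
of ~0.8–1.6 peak ΔF/F against that noise). It emulates sparse
responsiveness (13 % driven), amplitude scaling of responses, and a
weak-laser ensemble shuffle that swaps half the driven set with previously
silent ROIs while preserving the mean population response. It does not
emulate motion artifacts, bleaching, or spatially structured neuropil.

## Behavior

The psychometric model is
`P(hit | A) = guess + (1 − guess − lapse) · Φ((A − μ)/σ)`, fit by binomial
maximum likelihood (L-BFGS-B, bounded guess/lapse); the threshold is the
median point of the scaled curve, i.e. μ, and amplitudes are subsequently
normalized by it. Non-identifiable fits (flat data, curve not rising
inside the sampled range) are flagged, not returned silently. Trial
filters implement the named exclusion rules (session d′ floors of 0.8 for
fitting and 1.2 for inclusion; responses within 50 ms of stimulus onset;
deviants later than 400 ms; the sub-threshold band below 60 % of
threshold). d′ clips rates to `[1/(2N), 1 − 1/(2N)]`. Hit-rate intervals
are exact Clopper–Pearson; rate contrasts (deviant benefit, gap-crossing
probabilities) use a two-sided 10,000-sample binomial bootstrap. The
synthetic observer (μ = 15 mm/s, σ = 3, guess 0.1, lapse 0.02) gains
+0.15 hit probability on sub-threshold deviant trials, removable under a
simulated laser condition; it also plants early licks (< 50 ms) and late
deviants so the exclusion rules are exercised.

## Problem sizes and determinism

The statistical calibrations run at the population scales the analyses
target: 90-unit populations with ~300 deviant deflections per unit (150
per sign) and 1,000 surrogate draws for the broadening calibrations (200
null populations; 100 runs per power regime); 100 units for the classifier
operating characteristics; 100-fold bootstraps with 50–100 replicates for
GLM coverage and false positives; 500 null ROIs for the responsiveness
calibration. The acceptance script re-runs scaled-but-representative
versions of each (for example 60 null populations) and completes in a few
minutes on one CPU.

Every stochastic stage takes an explicit seed (numpy `default_rng` /
`SeedSequence`); identical configuration and seed give byte-identical
outputs, which the CLI determinism tests assert file-by-file, including
the report figure.

## Known limitations

- The surrogate broadening test is approximately calibrated (fixed-pool
  permutation vs. population sampling); its empirical null rejection can
  sit slightly above the nominal level.
- The driven classifier's condition (i) leaves the 0.03 p-level
  uncorrected across bins, as a deliberate reading of the procedure.
- Synthetic data plant phasic, kernel-shaped responses; real units with
  multi-phasic or offset responses may interact differently with the
  six-bin basis (a raised-cosine basis sits behind config).
- The calcium chain assumes accurate ROI masks and a known flagged-line
  schedule; it does not attempt registration or segmentation.
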