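# Methods

`avmvpa` is a synthetic-data re-implementation of a multivoxel fMRI
analysis chain built to study one question: can audiovisual context change
how *discriminable* and how *reliable* stimulus-evoked activation patterns
in early visual cortex are, without changing their mean amplitude?  All
data are simulated; the ground truth is known by construction, so every
analysis stage can be validated against it.

## Generative model

A session consists of `n_runs` (default 18, allowed 17–24) event-related
runs.  Each run holds 16 stimulus trials — 4 natural-scene stimuli × 4
conditions (audiovisual congruent, audiovisual incongruent, visual-only V,
auditory-only A) — plus 4 blank trials, in a seeded uniform random order.
Trials occupy a fixed 5 s grid (3 s stimulus + 2 s inter-stimulus
interval).  A run spans 42 volumes at TR 2.72 s (114.24 s), of which 3
leading and 2 trailing volumes are dummies.

The trial-wise activation pattern of stimulus *s* in condition *c* within
an ROI of *K* voxels is

    y(s, c) = g_c · t_s + σ_c · η + β₀,     η ~ N(0, I_K)

* `t_s` — unit-norm stimulus template, **identical across conditions**;
* `g_c` — condition gain: 1 for all visual conditions, 0 for A, so
  auditory-only patterns carry no stimulus information;
* `σ_c` — condition-specific trial-to-trial pattern-noise SD;
* `β₀` — per-voxel intercept (mean 1.0, SD 0.1), shared by all trials.

Mean amplitude is `mean(β₀) + g_c·mean(t_s)` and therefore identical
across visual conditions whenever the gains are equal; pattern
discriminability and split-half reliability are governed by `σ_c` alone.
Amplitude and reliability are thus independent dials, which is the point
of the design: the simulated effect is a pure noise-modulation, not a gain
change.  (The noise term is not multiplied by the gain; otherwise the
zero-gain auditory condition would degenerate to a constant pattern
instead of the intended "intercept plus noise".)

### Default study configuration

15 subjects, 18 runs, three ROI slabs ("V1", "V2", "V3") of 150 voxels
carved from a 40×40×20 grey-matter grid (3 mm isotropic affine).  The
noise SDs are σ = 0.75 for every condition and ROI except the V2-analogue
AV-incongruent cell, which uses σ = 1.3.  These values were fixed by an
a-priori power calculation: with unit-norm templates, σ = 0.75 puts
single-trial pairwise separation at d′ = √2/σ ≈ 1.9, yielding four-way
accuracies around 0.35–0.45 (the empirically plausible range), and the
0.75 → 1.3 step gives a paired-t noncentrality ≈ 4 for the reliability
contrast at n = 15, so the dissociation is detectable but not trivial.

### A useful exact null

Patterns are mean-corrected across the four stimuli within each
(run, condition) cell before decoding and correlation analyses.  A
consequence worth spelling out: for the *similarity* analysis (correlation
between run-averaged patterns of different stimuli), the cell-mean
subtraction injects an anticorrelation of exactly the size needed to
cancel the noise attenuation of the correlation, so the expected
inter-stimulus correlation is −1/(n_stimuli − 1) = −1/3 **independently of
σ_c**.  The similarity and amplitude nulls in the headline configuration
are therefore structural, not a matter of statistical power; only
accuracy and reliability carry the condition effect.

## Analysis chain

1. **GLM** (`glm`) — per run: one boxcar regressor per trial type (16)
   convolved with the canonical double-gamma HRF (Γ(6,1) − Γ(16,1)/6 on
   [0, 32] s, peak-normalised, 16× oversampled convolution sampled at
   volume times), plus a blank regressor, a response-interval regressor,
   optional nuisance columns and a constant.  Estimation is OLS; the
   synthetic noise is white, so no prewhitening or temporal filtering is
   applied.  t-maps feed the multivariate analyses, beta maps feed the
   univariate amplitudes.
2. **Decoding** (`mvpa`) — four-way stimulus classification from ROI
   patterns using six pairwise linear SVMs (C = 1, no kernel, no feature
   scaling) with one-against-one voting; ties are resolved by the largest
   sum of signed decision values among tied classes, then the lowest
   stimulus index.  Accuracy is the unweighted fold mean of a
   leave-one-run-out jackknife (folds = runs, 4 test patterns per fold;
   chance = 0.25).
3. **Pattern statistics** (`patstats`) — reliability: Pearson correlation
   between a stimulus's mean pattern over odd vs even runs (1-based
   acquisition order, so run 1 is odd), Fisher z-transformed, averaged
   over stimuli.  Similarity: mean Fisher z over the six inter-stimulus
   correlations of all-run mean patterns.  Correlations are clipped to
   1 − 1e−12 before `atanh` so noiseless (r = 1) cases stay finite.  The
   16×16 trial-type matrix stores odd/even correlations on the diagonal
   and all-run correlations off it.  Averaging happens in z space;
   per-stimulus z values are kept for audit.
4. **Searchlight** (`searchlight`) — spheres of radius 4 voxels (257
   offsets) centred on every grey voxel, truncated at mask borders;
   spheres with fewer than 2 in-mask voxels are undefined.  The same
   mean-correct + OvO jackknife is applied locally and the fold-mean
   accuracy is written to the seed voxel.  Group inference on accuracy
   contrasts: one-sample t map, cluster-forming threshold p < .001,
   6-connected clusters (18/26 available as options), and family-wise
   error by the max-cluster-size distribution over sign-flip permutations.
   Subject rows are canonicalised (content-sorted) before sign assignment
   so the result is exactly invariant to input order.
5. **Retinotopy** (`retino`) — phase-encoded mapping: wedge 12 cycles ×
   20 steps, ring 20 cycles × 12 steps (240 timepoints).  Voxel series are
   normalised to percent signal change and linearly detrended; the trend
   is estimated jointly with the stimulus sinusoid and only the trend is
   removed, so detrending cannot leak into the stimulus bin (a plain
   least-squares detrend perturbs noiseless phases by ~1e−3 rad).  The
   phase lag −arg F[f] mapped to [0, 2π) gives the polar angle (wedge,
   clockwise from the upper vertical meridian) or eccentricity (ring,
   linear up to 8°; the discrete equal-step ring motivates the linear
   rather than logarithmic map).  Spectral SNR = power at the stimulus bin
   / mean power over bins 3..Nyquist excluding the stimulus bin ± 1 and
   its second harmonic; responsiveness threshold defaults to 3.  A
   constant hemodynamic-delay offset parameter exists (default 0).
6. **Group statistics** (`groupstats`) — two-sided one-sample and paired
   t-tests; one-way repeated-measures ANOVA with Greenhouse–Geisser ε from
   the double-centred sample covariance, bounded to [1/(k−1), 1] and
   forced to 1 at k = 2 (where F = t² exactly); within-subject error bars
   use Cousineau subject-centering with Morey's √(k/(k−1)) correction.
   Zero-variance t-tests return p ∈ {0, 1} by convention with a warning.

## What the simulation does and does not emulate

It emulates: the run/trial structure and its arithmetic; condition-
dependent trial-to-trial pattern variability around condition-invariant
templates; HRF-convolved time series with white scanner noise; periodic
mapping responses with known phases.  It does **not** emulate: AR(1) or
physiological noise structure, drift, motion, spatial noise correlations,
vasculature, surface topology, foveal confluence, or any audio/visual
stimulus content.  Passing tests therefore show that the analysis chain
is correct and that the noise-modulation account *suffices* to produce
the accuracy/reliability dissociation with flat amplitudes and
similarities; they cannot show that real cortex behaves this way.

## Numerical and design choices

* Seeds are explicit everywhere; child seeds derive from a master via
  `numpy.random.SeedSequence` spawning (all < 2³¹).  Identical configs
  give byte-identical outputs.
* Trial onsets sit on the fixed 5 s grid; no jitter scheme is modelled.
* Odd/even run parity uses 1-based acquisition order.
* The per-(run, condition) mean correction is the default; a pooled
  per-condition variant is available behind a flag.
* Degenerate SVM training (identical rows across classes) yields zero
  decision values and falls through the deterministic tie-break — the
  classifier never raises.
* Cluster connectivity defaults to 6; SPM-style inference uses 18, which
  is available as an option.
* The pipeline runs at the trial-pattern level by default; `use_glm=True`
  additionally realises BOLD runs and re-estimates the patterns through
  the GLM (validated to ≤ 1e−8 relative error in the noiseless limit).
  The searchlight stage can also consume volumetric trial maps generated
  directly from the pattern model when the full BOLD realisation is not
  needed; requesting the searchlight without the GLM auto-enables this
  and logs it.
* Spatial smoothing (3-D Gaussian, FWHM parameter) exists as a utility
  and defaults to off; whether 5 mm smoothing changes synthetic results
  is left as an experiment.
* Desk-scale problem sizes in the test suite (smaller grids, ROI sizes,
  run subsets, permutation counts) are the package's own choices for
  quick iteration; the default configuration above is what the analysis
  drivers use.

## Known limitations

* The reliability metric's variance across subjects is driven by the
  voxel count (z-scale SD ≈ 1/√(K−3)); conclusions about borderline
  effects at very small ROIs will be noisy.
* The OvO accuracy at chance has slightly heavier tails than a binomial
  with the same trial count because folds share training data; group
  tests against chance use subject-level accuracies, which absorbs this.
* Permutation cluster p-values are discrete ((1+k)/(1+N)); with 200
  permutations the smallest attainable p is ~0.005 and the test is
  mildly conservative.
* With zero-variance inputs (noiseless limits) several statistics hit
  documented conventions (clipped z, t = 0 where SE = 0, p ∈ {0, 1});
  these paths are exercised by tests, not just guarded.
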