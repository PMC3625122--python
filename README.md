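# avmvpa

Synthetic-data pipeline for studying how audiovisual context modulates the
discriminability and trial-to-trial reliability of multivoxel BOLD
patterns in retinotopic visual cortex — without changing mean signal
amplitude.

## The problem

In multisensory fMRI experiments, decoding a visual stimulus from early
visual cortex can succeed better or worse depending on whether a
co-occurring sound is congruent with the video.  A drop in decoding
accuracy admits two very different explanations: the stimulus
representations could move closer together (a *similarity* change), or
each representation could become noisier from trial to trial (a
*reliability* change) — and neither needs to show up in the overall
response amplitude.  Disentangling these requires an analysis chain that
measures all three quantities on the same patterns:

* four-way stimulus decoding from ROI patterns, using six pairwise linear
  SVMs with one-against-one voting and a leave-one-run-out jackknife
  (chance = 1/4);
* split-half **pattern reliability**: Fisher-z of the correlation between a
  stimulus's mean pattern in odd vs even runs;
* **pattern similarity**: mean Fisher-z over the six inter-stimulus
  correlations of run-averaged patterns;
* ROI-mean **amplitude** from (non-mean-corrected) GLM betas.

This package implements that chain end to end on simulated data with
known ground truth: an event-related design generator (16 stimulus + 4
blank trials per run, 3 s stimuli, 2 s ISI, TR 2.72 s, 42 volumes =
114.24 s per run), a trial-pattern model in which condition changes only
the pattern-noise SD (`y = g_c·t_s + σ_c·η + β₀`), BOLD time-series
synthesis via canonical-HRF convolution, run-wise trial GLMs, searchlight
mapping with sign-flip permutation cluster inference, phase-encoded
retinotopy (wedge 12 cycles × 20 steps, ring 20 cycles × 12 steps), and
group statistics (t-tests, Greenhouse–Geisser-corrected repeated-measures
ANOVA, within-subject SEM).  See `docs/methods.md` for the model and all
conventions.

## Worked example

```python
from avmvpa.pipeline import Config, run_pipeline

results = run_pipeline(Config(retinotopy=False), out_dir="results/pipeline")
metrics = results["metrics"]          # tidy: subject, roi, condition, metric, value
print(metrics.groupby(["roi", "metric", "condition"]).value.mean()
      .unstack("condition").round(3).loc["V2"])
```

With the default configuration (15 subjects, 18 runs, 150-voxel ROIs,
noise SD 0.75 everywhere except 1.3 for AV-incongruent in the V2
analogue) this prints:

```
condition          A  AV_congruent  AV_incongruent      V
metric
accuracy       0.285         0.376           0.294  0.377
mean_beta      0.998         0.998           0.999  0.998
reliability_z  0.002         0.098           0.035  0.080
similarity_z  -0.348        -0.347          -0.348 -0.348
```

Reading the table: stimulus identity decodes well above the 0.25 chance
level in every visual condition but drops for AV-incongruent; split-half
reliability drops in step; mean amplitude is flat at ~1.0 (the injected
intercept) and inter-stimulus similarity is pinned at atanh(−1/3) ≈ −0.347
for every condition — mean correction across stimuli makes the expected
similarity independent of the noise level, so the manipulation is visible
*only* as a reliability/accuracy change.  The accompanying group table
(`results/pipeline/group.tsv`) bears this out in V2: paired t(14) = −3.07
(p = .008) for accuracy and t(14) = −3.77 (p = .002) for reliability
against AV-congruent, while the condition ANOVAs for amplitude
(p = .93) and similarity (p = .42) stay null.

The numbered drivers under `analysis/` run the same stages as a
narrative: `01_simulate_cohort.py` (design arithmetic and one subject's
data), `02_roi_metrics.py` (the table above), `03_group_stats.py` (ANOVAs
and post-hocs per ROI), `04_searchlight.py` (accuracy-contrast cluster
table), `05_retinotopy.py` (phase-recovery RMSE ≈ 0.018 rad at a 5:1
response-to-noise ratio).

## Command line

A thin CLI wraps the pipeline:

```bash
avmvpa simulate --out results/sim           # synthetic data only
avmvpa decode --seed 3 --out results/dec    # ROI decoding accuracies
avmvpa all --config myconfig.json           # every stage
```

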