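# netcollapse

Gray-matter atrophy in neurodegenerative disease (Alzheimer-type dementia and
the frontotemporal dementia spectrum) is accompanied by both decreases and
increases of resting-state functional connectivity (FC).  `netcollapse`
implements a complete analysis chain that explains those FC alterations
through the dynamics of a small number of brain activity **gradients** —
spatial principal components of regional BOLD timeseries — and tests every
stage of the chain on synthetic cohorts with planted ground truth.  It is
written for neuroimaging methodologists who want to run, probe, or extend the
analysis without access to patient data.

## What it computes

1. **Atrophy W-scores** — per-region normative regressions of gray matter on
   covariates; a subject's deviation `(predicted − actual) / residual SD`,
   oriented so positive values mean atrophy (`WScoreModel`).
2. **Gradient space** — PCA of temporally concatenated regional timeseries
   from a normative pool yields an orthonormal `R×K` basis; projecting a
   subject's centered timeseries gives the `T×K` gradient timeseries, and the
   `K×K` gradient covariance Σ rebuilds region FC via `E Σ Eᵀ` (exactly equal
   to direct Pearson FC at full rank) (`GradientPCA`,
   `fc_from_gradient_covariance`).
3. **Structure-function components** — partial least squares regression of the
   subjects×regions atrophy matrix against the subjects×edges FC matrix,
   with split-half reliability, FC-independent atrophy PCA scores, and
   out-of-fold ridge function scores (`PLSStructureFunction`,
   `RidgeFunctionScorer`).
4. **Coupled-oscillator model** — each gradient's acceleration is regressed on
   all gradients' positions and velocities,

   ```
   G_k'' = β_k0 + Σ_j β_{Gj,k} G_j + Σ_j β_{Gj',k} G_j'
   ```

   giving the companion state matrix `A = [[0, I], [P, V]]` of
   `dY/dt = A Y`.  Its eigenmodes `λ = α + iβ` (damping per TR, angular
   frequency rad/TR, reported in Hz as `β/2π/TR`) carry each gradient's
   complex amplitude and phase (`OscillatorModel`).
5. **Collapse metrics** — per subject, each gradient's cumulative amplitude
   `Σ_m √((b−a)² + (a+b)²) = √2 Σ_m |a+ib|` across modes, and each gradient
   pair's amplitude-weighted circular mean phase angle.  90° means temporally
   orthogonal gradients; departures ("collapse") translate into
   between-gradient correlation ≈ cos(angle), producing paired hypo- and
   hyper-connectivity between the gradients' poles (`eigenmetrics`).
6. **Synthetic cohorts** — a generator that plants all of the above: a
   unipolar first gradient, severity-dependent gradient-1 amplitude loss and
   gradient-1/4 phase collapse, focal atrophy factors, and behavior scores
   (`synth.make_cohort`, `synth.make_structure_function_cohort`).

Estimators follow scikit-learn conventions (`fit`, `transform`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn model selection; every operation is also exposed as a plain function.

## Worked example

Run the full pipeline (synthesize → QC → gradients → PLSR/ridge →
oscillator → collapse metrics) on a 60-subject synthetic cohort:

```python
from netcollapse.pipeline import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(
    n_subjects=60, n_regions=40, n_timepoints=400, seed=1, out_dir="demo"))
```

which prints (abridged from `demo/summary.json`):

```
n_input: 60          n_analyzed: 52         n_excluded: 8
plsr_score_correlations:            [0.563, 0.634, 0.445]
plsr_atrophy_variance_explained:    [0.520, 0.192, 0.225]
ridge_median_oof_r:                 0.344
metric_moment_median_corresponding_r:     0.860
metric_moment_median_noncorresponding_r:  0.112
```

Reading the numbers: 8 of 60 scans were excluded by the head-motion filter
(mean framewise displacement > 0.55 mm) or the FC-outlier PCA flag.  The
first structure-function component carries 52% of the atrophy variance and
its structure and function scores correlate at r ≈ 0.56 — the planted
global-severity factor.  The out-of-fold ridge correlation (0.34) shows the
structure-function coupling survives cross-validation without leakage.
The last two numbers are the heart of the collapse analysis: across subjects,
fitted eigenmode amplitudes/angles correlate with the matching gradient
variances/covariances at median |r| = 0.86 while non-matching pairs sit at
0.11 — each metric tracks its own moment and nothing else.

The same stages are available from the shell:

```bash
netcollapse synthesize --seed 1 --n-subjects 40 --out cohort/
netcollapse run-all --seed 1 --out demo/
netcollapse fit-oscillator --gradients grads.tsv --tr 2.0 --out modes.json
```

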