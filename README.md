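# connfroi

Predict individual category-selective visual regions (fROIs) from
resting-state functional-connectivity fingerprints, exercised end to end on
a synthetic cohort with known ground truth.

For each of 18 bilateral regions (FFA, OFA, STS, EBA, PPA, RSC, TOS, LO,
PFS x two hemispheres) the pipeline:

1. **simulates** a cohort of subjects, each with one ~9.67-min resting run
   (580 volumes at TR = 1 s) and two 234-volume localizer runs (five
   conditions in 18-s blocks), on a flat two-hemisphere vertex sheet with a
   179-parcel ipsilateral parcellation — the resting signal carries a known
   linear coupling between each vertex's connectivity fingerprint and its
   latent category selectivity, so recovery is measurable;
2. builds per-region **connectomes**: Fisher-z Pearson correlations of every
   search-space vertex against all 179 ipsilateral parcel-mean timeseries,
   after censoring frames with framewise displacement > 0.5 mm;
3. fits first-level **GLMs** to the task runs (gamma HRF with 2.25 s delay
   and 1.25 s dispersion, boxcar blocks, 6 motion regressors, spike
   regressors for frames with > 1 mm movement, intercept and drift) and
   computes category contrast maps;
4. **trains** an L2-regularized linear model per region that maps the 184
   features (179 connectivity + curvature, thickness, x, y, z) to the
   contrast effect, using nested leave-one-subject-out cross-validation over
   a 100-point logarithmic penalty grid spanning 1e-5..1e2;
5. defines **fROIs** as the top 10% (optionally 20% / 30%) of search-space
   vertices of the predicted or actual contrast maps, plus three synthetic
   group atlases (union-threshold, dilated, shifted) and the ground truth;
6. **evaluates** selectivity (PSC difference between preferred and contrast
   categories on the held-out run), per-region paired t-tests with
   Bonferroni correction (0.05/18), Dice/explainable-overlap metrics, a
   category x hemisphere ANOVA with subject as random factor (Type III
   sums of squares), and method comparisons.

## CLI

```bash
connfroi run-all --seed 1 --out runs/demo            # everything, default config
connfroi simulate --seed 1 --out runs/demo           # just the synthetic cohort
connfroi run-all --config cfg.yaml --froi lFFA --fraction 0.1 --fraction 0.2
```

Configuration is YAML with strict validation (unknown keys rejected); all
defaults match the documented constants. Subcommands `simulate`,
`connectome`, `glm`, `train`, `predict`, `define-froi`, `evaluate` run the
pipeline through the corresponding stage; `--cohort-dir` reuses a
previously simulated cohort. Outputs are TSV tables (selectivity, tests,
ANOVA, overlap, CV report, fROIs), JSON ridge models, and a
`manifest.json` with per-stage wall times and sha256 checksums —
re-running with the same config and seed reproduces identical bytes.

Exit codes: 0 success, 1 configuration error, 2 runtime failure.

## Layout

```
src/connfroi/
  synth/         # registry, block designs, surface, cohort generator, atlases
  connectome.py  # frame censoring, Fisher z, vertex-to-parcel connectomes
  glm.py         # HRF, design matrices, OLS, contrasts, percent signal change
  model.py       # ridge, penalty grid, nested LOSO cross-validation
  froi.py        # top-fraction thresholding, Dice, overlap metrics
  evaluation.py  # selectivity tables, t-tests, Bonferroni, mixed ANOVA
  config.py      # validated pipeline configuration
  pipeline.py    # stage orchestration and artifact writing
  io.py          # cohort/model (de)serialization
  cli.py         # click-based CLI
```
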