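# lapref

Loss aversion from keypress behavior, neural differential sensitivity
from block-design fMRI, and the three-way inference tying them to age —
as a tested, reproducible desk-scale pipeline.

## The scientific problem

Do people weigh losses more heavily than gains differently as they age,
and does the brain's reward/aversion circuitry change even when
behavior does not?  One way to ask this couples two measurements made
with the same affective face stimuli (angry, fearful, happy, sad,
neutral):

1. **Behavioral loss aversion (LA).**  Outside the scanner, subjects
   trade keypress effort for viewing time: keys that lengthen viewing
   index approach, keys that shorten it index avoidance.  Relative
   preference theory summarises each stimulus category by the mean net
   keypress count *K* (signed: approach positive, avoidance negative)
   and the Shannon entropy *H* (bits) of how that effort distributes
   across the category's pictures.  Fitting a value curve to each limb
   of the (H, K) graph and taking the local slopes nearest the origin
   gives s− (avoidance) and s+ (approach); loss aversion is
   **λ = |s−/s+|**, the keypress analogue of the prospect-theory
   loss-aversion coefficient (λ ≈ 2 in the monetary literature).

2. **Neural differential sensitivity (NDS).**  In the scanner, subjects
   passively view 20-s blocks of the same faces in a counterbalanced
   order (no ordered condition pair repeats within a run).  A
   per-voxel GLM with HRF-convolved block regressors yields the
   contrast **mean(β_angry, β_fearful, β_sad) − β_happy**; NDS is the
   mean contrast over ventral-striatum/nucleus-accumbens (VS/NAc)
   voxels exceeding z = 1.96.

3. **Group inference.**  Pearson correlation of NDS with λ (α = 0.05),
   and regressions of NDS and λ on age at the Bonferroni-corrected
   α = 0.05/2 = 0.025, after excluding λ outliers (> 2 SD from the
   cohort mean) and subjects without valid imaging.

Because no subject-level data are public for this paradigm, the package
includes a first-class synthetic-cohort generator (ages 20–55, λ
log-normal around 2 with heavy-tailed contamination, NDS rising with
age and correlated with λ) so the entire chain runs end to end against
known ground truth.  It is aimed at researchers in decision
neuroscience who want a transparent reference implementation of the
K–H valuation / local-λ statistic and a calibrated harness for the
surrounding design and inference machinery.

## Layout

* `src/lapref/` — the library: `task_design` (counterbalanced
  sequences, timelines, events TSV), `synthetic_cohort` (ground-truth
  cohorts, keypress and voxel simulation), `keypress_analysis`
  (viewtimes, K, H), `valuation` (curve fits, local slopes, λ, outlier
  rule), `fmri_nds` (design matrix, GLM, contrast, ROI NDS),
  `group_inference` (associations, pipeline driver), `cli`.
* `analysis/01–05_*.py` — numbered narrative drivers that run the
  stages over staged CSV/TSV artifacts and write tables to `results/`.
* `scripts/acceptance.py` — recomputes the headline quantities from
  scratch (below).
* `docs/methods.md` — models, assumptions, parameter defaults, and
  limitations.

## Worked example

```python
from lapref.group_inference import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
for a in report.associations.values():
    print(a.name, round(a.estimate, 3), round(a.test_statistic, 2),
          round(a.p, 4), a.n_used, a.significant)
```

prints

```
nds_la 0.489 2.1 0.0544 16 False
nds_age 0.026 11.65 0.0038 17 True
la_age -0.018 0.69 0.42 16 False
```

Reading: one subject of the 17 was flagged as a λ outlier and excluded
from λ statistics.  NDS rises with age (slope 0.026 contrast units per
year, F = 11.65, p = 0.0038, significant at the corrected α = 0.025)
while λ shows no age relationship (p = 0.42) — the
neurocompensation-style dissociation the generator encodes: an aging
reward circuit needs a growing neural differential to produce the same
behavioral loss aversion.  The NDS–λ correlation in this particular
n = 16 draw is r = 0.489 (p = 0.054), just missing α = 0.05 — at
desk-scale n, that association hovers around significance exactly as a
population correlation near 0.5–0.6 would.  The included-cohort λ is
1.85 ± 0.21 (mean ± SE), consistent with the ≈ 2 scale of published
loss-aversion estimates.

The same stages can be run piecewise over files
(`python analysis/01_design_sequences.py` … `05_group_inference.py`),
or from the shell:

```
lapref design --blocks 25 --seed 1 --out events.tsv
lapref simulate --n 17 --seed 1 --outdir sim/
lapref behavior --events sim/keypress.csv --out valuation.csv
lapref la --valuation valuation.csv --out la.csv
lapref nds --voxels sim/voxels_sub01.tsv --events sim/events.tsv --out nds.csv
lapref run --config config.yaml --outdir out/
```

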