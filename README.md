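# pibquant

Multicentre [¹¹C]PIB amyloid-PET quantification on synthetic phantoms:
cohort simulation, grey-matter ROI construction, cerebellar-scaled retention
ratios (SUVR), a normative positivity cutoff derived from the control
distribution, and the downstream group and survival analyses for MCI
conversion to Alzheimer's disease.

## The problem

Amyloid PET with [¹¹C]PIB separates Alzheimer's disease (AD) patients from
healthy controls and splits mild cognitive impairment (MCI) into
amyloid-positive and amyloid-negative subgroups with very different
prognoses. Pooling scans from several centres — different scanners, doses,
frame schedules and reconstruction blur — requires a standardized
quantification chain whose readout, the **neocortical retention ratio**
(mean uptake over frontal, parietal and basal/lateral temporal cortex,
scaled by the median cerebellar grey-matter voxel value), is robust to those
centre effects.

No raw data from such studies is public, so `pibquant` pairs the analysis
chain with a first-class synthetic-data generator: ground-truth cohorts with
a calibrated bimodal retention structure are rendered into template-space PET
phantoms with centre-specific point-spread blur, signal-proportional noise,
dose scaling and axial field-of-view truncation. Every analysis step can then
be validated by calibration recovery: known truth in, measured estimate out.

The package is aimed at methodologists who need a tested, seeded sandbox for
amyloid-PET harmonization questions: cutoff derivation procedures, reference
region statistics, partial-volume/erosion trade-offs, and survival analyses
of biomarker-defined subgroups.

## Method summary

- **Quantification.** PET frames fully inside the 40–60 min window are
  summed; a grey-matter mask (mean of 10 subject probability maps ≥ 0.5,
  eroded by two voxels, 6-connected) intersected with a 23-region atlas gives
  cortical/subcortical ROIs plus cerebellar grey. Each integral image is
  divided by its **median** cerebellar voxel value (median, not mean —
  insensitive to outlier voxels in low-count slices); ROI means of the ratio
  image and the 3-region neocortical composite are the readouts. Subjects
  with more than 25 % of the cerebellar reference outside the axial FOV are
  excluded.
- **Normative cutoff.** Control composites are bimodal: iterative
  mean + 2 SD upper trimming isolates the normally distributed main cluster;
  the cutoff is the upper bound of its central 95 % range,
  `mean + 1.96 × SD`. Composites strictly above the cutoff are PIB-positive.
- **Statistics.** One-way ANOVA across diagnoses, a diagnosis × centre GLM
  variance partition (Type II sums of squares, η² per effect), Pearson
  correlations and OLS slopes for retention–cognition coupling, Pearson
  χ² for proportions.
- **Survival.** Kaplan-Meier dementia-free survival of MCI subgroups,
  Mantel-Cox log-rank, crude conversion percentage among positives, negative
  predictive value of a negative scan, and an annual conversion rate
  operationalized as `1 − S_KM(12 months)`.

## Worked example

One fully seeded end-to-end run (simulate → mask → quantify → classify →
analyze → survival) on the default 64×64×48 template at 3 mm:

```bash
pibquant run-all --out out/ --seed 9
```

which prints `included 220/220 subjects; cutoff 1.3937` and writes
`report.json`, from which (seed 9):

| quantity | value | meaning |
|---|---|---|
| control main cluster | 1.260 ± 0.068 (n=49) | recovered narrow normal control range |
| cutoff | 1.394 | mean + 1.96 SD of the main cluster |
| group means | 1.27 / 1.62 / 1.83 | measured composite: controls / MCI / AD |
| ANOVA | F₂,₂₁₇ = 61.2, p < 0.001 | AD > MCI > controls |
| η² diagnosis / centre | 0.324 / 0.003 | diagnosis dwarfs centre effects |
| PIB-positive | 4 % / 61 % / 87 % | controls / MCI / AD at the cutoff |
| r(composite, delayed recall) | −0.56 (n=187) | pooled retention–memory coupling |
| MCI follow-up | 39 positive, 26 negative | crude conversion 51.3 % of positives |
| NPV | 100 % | no PIB-negative MCI converter |
| log-rank | p = 1.6 × 10⁻⁵ | positives vs negatives |
| restricted mean survival | 29.1 ± 3.9 months | PIB-positive MCI |

Identical config + seed reproduce this report byte-for-byte. The library API
mirrors the CLI:

```python
from pibquant import PipelineConfig, run_all
manifest, report = run_all(PipelineConfig(seed=9))
print(report["threshold"]["cutoff"])        # 1.3937...
```

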