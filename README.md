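# gfcpipe

Voxel-wise **global-brain functional connectivity (GFC)** analysis of
resting-state fMRI for two-group clinical studies, built as a tested,
reusable pipeline with a synthetic-cohort generator so every stage can
be validated without access to patient data.

The package targets the kind of study that compares a patient group
against matched controls — here modelled on a dry-eye-disease cohort of
20 patients and 23 controls scanned for 250 volumes at TR = 2 s — and
asks: *which gray-matter voxels are less globally connected in
patients, do those connectivity values track illness duration, and can
they serve as a diagnostic biomarker?*

## The statistic

For gray-matter voxel *a* with time series *T<sub>a</sub>*, GFC is the
average correlation with every other gray-matter voxel:

```
GFC(a) = Σ_{b≠a} r(T_a, T_b) / (n − 1)
```

where *r* is the Pearson correlation and *n* the number of gray-matter
voxels (probability > 0.2). Pairwise correlations are Fisher
z-transformed (z = atanh r) before averaging in the default `mean_z`
mode; a `mean_r` mode (average raw correlations, computable in
O(n·T) via the identity Σ_b r(a,b) = z_a·Σ_b z_b over standardized
columns) is provided for cross-checks and large masks.

Around the statistic the pipeline implements:

* **preprocessing** — drop first 10 volumes, 2 mm/2° motion QC, 4 mm
  FWHM smoothing, linear detrend, 0.01–0.08 Hz ideal band-pass,
  Friston-24 + white-matter + CSF nuisance regression (global signal
  retained), Power framewise-displacement scrubbing at FD > 0.2 mm;
* **group inference** — per-voxel OLS of GFC on
  `intercept + group + mean FD + age`, family-wise error controlled by
  the permutation distribution of the maximum |t| (Freedman–Lane
  scheme), descriptive cluster extraction with peak mm coordinates;
* **clinical correlation** — cluster-mean GFC vs illness duration in
  patients (Pearson, Bonferroni over clusters);
* **classification** — per-cluster Gaussian-kernel SVM with
  leave-one-out cross-validation over a (C, γ) grid, plus ROC analysis
  with the Youden-index cut-off on the raw feature scale.

## Worked example

```python
from gfcpipe.config import PipelineConfig
from gfcpipe.simulate import CohortSpec, generate_cohort
from gfcpipe.pipeline import analyze_cohort

cfg = PipelineConfig(seed=1)
cfg.simulate.grid_shape = (16, 16, 16)     # reduced demo grid
spec = CohortSpec(grid_shape=(16, 16, 16), seed=1)
result = analyze_cohort(generate_cohort(spec), cfg)

for c in result.clusters:
    print(c.cluster_id, c.size, round(c.peak_t, 2), c.direction)
print(result.correlations[0])
print(result.classification[0].metrics["accuracy"])
print(round(result.roc[0].auc, 3))
```

prints (seed 1):

```
1 19 -9.39 decrease
2 3 -6.34 decrease
{'cluster_id': 1, 'r': 0.6306473234788907, 'p': 0.0028717201973041786, 'n': 20, 'p_bonferroni': 0.005743440394608357}
93.02% (40/43)
0.97
```

Two clusters of decreased connectivity are recovered exactly where the
generator implanted them (negative peak t: patients < controls), the
larger cluster's mean GFC correlates with illness duration within the
patient group (r = 0.63, Bonferroni-corrected p = 0.006), and that
cluster separates patients from controls with 93% leave-one-out
accuracy and AUC 0.97.

The same analysis is available from the shell:

```bash
gfcpipe run --seed 1 --data demo/data --out demo/run
gfcpipe report --out demo/run        # Table-1..4 style TSVs + summary.json
```

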