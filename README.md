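# mprog

Meningioma is the most common primary tumor of the central nervous system.
Most meningiomas are benign (WHO grade I) and cured by surgery, but a
minority recur and progress, and the WHO grade alone predicts this poorly.
`mprog` implements a transcriptome-based progression analysis for bulk
RNA-seq meningioma cohorts, for computational biologists who want to
subtype a cohort and score individual tumors for progression risk:

- **consensus clustering** (resampled average-linkage hierarchical
  clustering on 1 − Pearson distance) discovers robust expression subtypes
  and selects the cluster count from consensus-CDF stability;
- **one-vs-rest moderated differential expression** (empirical-Bayes
  shrunken t statistics, Benjamini–Hochberg FDR) derives the progressive
  subtype's up/down signature gene lists;
- the **meningioma progression score (MPscore)** summarizes each sample's
  enrichment of that signature by single-sample GSEA:

  MPscore(s) = ssGSEA_up(s) − ssGSEA_down(s)

  where ssGSEA is a rank-weighted running-sum enrichment statistic
  (weights |rank|^τ, τ = 0.25) computed within one sample;
- **stemness index** (Spearman correlation against a stem-cell weight
  vector, min–max rescaled to [0, 1]), **immune population scores**
  (marker-gene log2 means for eight immune populations), and
  **random-forest marker ranking** with recursive feature elimination and
  single-gene ROC/AUC;
- **DNA-methylation rules**: CpG-island methylator phenotype (CIMP)
  detection, differentially methylated CpG signatures on M values,
  chr1p/chr22q arm-loss calls (arm mean < 0.1), and the rule-based subtype
  assignment for methylation-only cohorts (1p+22q co-loss → subtype 3;
  22q loss alone → subtype 2; stemness index > 0.5 → subtype 4; no loss →
  subtype 1);
- **survival validation**: Kaplan–Meier curves and log-rank test for
  median-dichotomized MPscore, and multivariable Cox regression of
  recurrence-free survival on MPscore, location, sex, and MIB-1.

Because the analysis was developed against controlled-access cohorts, the
package ships a first-class **synthetic cohort generator** that emulates
the study's statistical structure — 179 samples in four subtypes
(67/38/59/15), WHO grade II/III concentrated in the progressive subtype 3,
a planted ±2 log2FC signature, batch effects, immune marker structure,
subtype-3 CpG hypermethylation, chr1p/chr22q losses, and a 3× recurrence
hazard for subtype 3 — so the entire pipeline runs and is tested without
any download.

## Worked example

```python
import pandas as pd, json
from mprog import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, outdir="demo_run", n_resamples=200)
rundir = run_pipeline(cfg)   # simulate -> ... -> survival, writes a manifest

assignments = pd.read_csv(rundir / "assignments.csv", index_col=0)
scores = pd.read_csv(rundir / "scores.csv", index_col=0)
ann = pd.read_csv(rundir / "annotations.csv", index_col=0)
cox = pd.read_csv(rundir / "cox_table.csv", index_col=0)
tests = json.loads((rundir / "survival_tests.json").read_text())

print("clusters found:", assignments["cluster"].nunique())
print(scores.groupby(ann["subtype"])["mpscore"].mean().round(3))
print(cox.loc[["mpscore"], ["coefficient", "hazard_ratio", "p_value"]].round(4))
print("log-rank p: %.4g" % tests["logrank"]["p_value"])
```

prints

```
clusters found: 4
subtype
1   -0.051
2   -0.047
3    1.390
4    0.153
Name: mpscore, dtype: float64
           coefficient  hazard_ratio  p_value
covariate
mpscore         0.5984        1.8192      0.0
log-rank p: 0.00476
```

Consensus clustering recovers the four planted subtypes; the mean MPscore
of the progressive subtype 3 (1.39) clearly exceeds the other subtypes
(≤ 0.15); in the multivariable Cox model a unit increase of MPscore
carries a hazard ratio of 1.8 for recurrence, and the median-split
Kaplan–Meier groups separate at log-rank p ≈ 0.005.

The same stages are available from the shell:

```bash
mprog simulate --outdir sim --seed 7
mprog all --seed 7 --outdir run7          # full pipeline
mprog cluster --in log2.tsv --k-min 2 --k-max 6 --resamples 1000 --seed 1
mprog score --in log2.tsv --sig signature.gmt --tau 0.25
```

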