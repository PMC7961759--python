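# Methods

This note documents the models, defaults, and design choices behind
`mprog`, in the order the pipeline runs them.

## Synthetic cohort generator (`simcohort`)

The generator draws a cohort whose marginal structure matches what the
downstream stages assume, so every stage can be exercised and its planted
truth recovered.

**Expression.** Per-gene baseline log2 abundances are Normal(4, 2) —
heavy-tailed realistic abundances after exponentiation — with per-sample
noise Normal(0, 0.5) in log2 space. On top of the baseline:

- the progressive subtype (subtype 3) carries `n_signature_up = 30` genes
  at +`effect_log2fc` and `n_signature_down = 23` genes at
  −`effect_log2fc` (53 signature genes in total; default effect 2 log2
  units);
- each non-progressive subtype (1, 2, 4) carries its own 30-gene
  up-regulated identity program at the same effect, making all four
  subtypes transcriptionally separable, as the per-subtype one-vs-rest
  signatures of a real cohort imply;
- eight immune populations (T cells, CD8 T cells, cytotoxic lymphocytes,
  NK cells, B lineage, monocytic lineage, myeloid dendritic cells,
  neutrophils) each contribute five marker genes whose expression is
  shifted by a per-subtype log2 abundance (cytotoxic lymphocytes peak in
  subtype 3 at +2, NK cells in subtype 4 at +2, neutrophils in subtype 1);
- a stemness weight vector w ~ Normal(0, 1) over all genes enters as a
  per-gene shift `stemness_align[subtype] * w_g` with alignment
  (0, 0, 0.15, 0.6): subtypes 3 and 4 are stem-like and subtype 4
  strongest, so its min–max-rescaled Spearman stemness index exceeds 0.5
  while the others stay below — the signal the methylation-cohort
  assignment rule requires;
- two batches receive per-gene shifts Normal(0, `batch_sd` = 0.5),
  assigned round-robin within subtype (the study pooled two source
  cohorts).

Values are exponentiated and renormalized to TPM (columns sum to 1e6).
Note the unit-exact consequence: a planted shift of exactly 2 log2 units
is slightly attenuated on the log2(TPM + 1) scale for low-abundance
genes, so one-vs-rest fold changes cluster just below 2.

**Clinical labels.** Subtype sizes default to (67, 38, 59, 15) — the
column sums of the cohort's WHO-grade table — and per-sample grades are
multinomial with probabilities proportional to that table's cells, which
concentrates grade II/III in subtype 3 and makes subtype 1 all grade I.
The table's per-subtype gender totals are internally inconsistent with
its WHO rows (they sum to 164, not 179), so sex is simulated
independently at the cohort-wide ratio 107:72.

**Survival.** Recurrence times are exponential with baseline hazard
0.01/month multiplied by `hazard_ratio_progressive` = 3 for subtype 3;
independent exponential censoring is calibrated to a 20% marginal censor
fraction at the baseline hazard (progressive samples are censored
slightly less often, as in real follow-up).

**Methylation.** Three CpG classes emulate a 450k-style beta landscape:
background loci are tight and bimodal (Beta with concentration 40, means
in {0.1, 0.25, 0.75, 0.9}); `n_cpg_variable = 300` "CIMP" loci are broad
(mean 0.35, concentration 4, within-group SD ≈ 0.24) and shifted
+`cpg_hyper_shift` = 0.3 in subtype 3, so they satisfy the per-group
SD > 0.2 variability rule in every subtype but are majority-hypermethylated
only in subtype 3; `n_cpg_dm = 150` promoter loci are tight and low
(mean 0.07, concentration 100) with the same +0.3 subtype-3 shift, which
yields ΔM ≈ 3 on the M-value scale and is what the differential-methylation
signature recovers. One class cannot serve both purposes: the CIMP rule
needs large within-group spread, high-sensitivity moderated-t recovery
needs small spread.

**Copy number.** Arm-level means are Normal with per-subtype centers:
chr1p and chr22q both at −0.3 in subtype 3, chr22q alone at −0.3 in
subtype 2, 0.5 (neutral) elsewhere; SD 0.05. The loss threshold is 0.1 on
this scale, so planted losses and neutrals are ~8 SD from the boundary.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: gene–gene correlation beyond the planted
programs, count-level sampling noise (expression is drawn directly on the
log scale), segment-level CNA structure, probe-level methylation
artifacts, fusion transcripts, and informative censoring. Effects enter
additively in log space with equal magnitude across genes, which is
cleaner than real signatures.

Determinism: one `numpy` Generator seeded from `CohortSpec.seed` drives
every draw; identical specs give bit-identical cohorts.

## Preprocessing

Counts convert to TPM by length normalization; the log transform is
log2(TPM + 1). The pseudocount is a convention choice (exposed as
`log_pseudocount`). Batch correction fits per-gene least-squares batch
coefficients with no other covariates and subtracts them, restoring the
per-gene grand mean — idempotent, and the identity for a single batch.
"Top variable genes" ranks by variance of log2(TPM + 1) (variance rather
than MAD/IQR; the dispersion statistic is otherwise unspecified), with
lexicographic tie-breaks for determinism. PCA is the SVD of the centered
log2 matrix with the sign convention that each component's
largest-magnitude gene loading is positive.

## Consensus clustering and cluster count

Each of `n_resamples` = 1000 resamples draws ⌈0.8·n⌉ samples without
replacement (genes are not subsampled), clusters them by average-linkage
agglomeration on 1 − Pearson correlation over the selected genes, and
cuts the dendrogram at each k in 2..6. The consensus entry for a sample
pair is its co-clustering count over its co-draw count; final assignments
cluster 1 − consensus by average linkage.

The cluster count is chosen from the consensus-CDF area A(k):
Δ(k) = (A(k) − A(k−1))/A(k−1) with Δ(k_min) = A(k_min), and the chosen k
is the largest k with Δ(k) ≥ 0.025. Two guards reject degenerate
candidates, because average linkage splits unstructured data into one
giant cluster plus outliers, which keeps the *relative* delta large while
producing meaningless cuts: a candidate k is dropped when its consensus
matrix is predominantly ambiguous (PAC, the fraction of off-diagonal
entries in (0.1, 0.9), above 0.2) or when its cut contains a cluster
below max(2, 5% of n) samples. If no candidate beyond k_min survives, the
smallest k is returned with a "no structure" warning. On planted
4-subtype cohorts the rule selects k = 4; on pure-noise cohorts it flags
no structure.

Silhouette widths use distance 1 − consensus, with singleton clusters
assigned width 0 by convention.

## Pairwise cluster significance

For each cluster pair, the statistic is the 2-means cluster index
(within-cluster SS over total SS, best of 5 k-means restarts) of the
pooled samples. The null is a single Gaussian with diagonal covariance
fitted to the pooled pair: background variance is the median per-gene
variance; sample-covariance eigenvalues are treated as genuine signal
directions only when they clear the Marchenko–Pastur bulk edge
σ²(1 + √(d/n))² with a 1.1× buffer against edge fluctuation, and are then
debiased under the spiked-covariance model. The p-value is the fraction
of `n_sim` null cluster indices at or below the observed one (floored at
1/(n_sim + 1)). The edge threshold and debiasing matter: using the raw
top eigenvalue always over-elongates the null (the sample eigenvalue
exceeds its population value) and drives the type-I error to zero;
with the spectrum rule the measured type-I error at α = 0.05 is ≈ 0.03
on isotropic nulls (n = 30, d = 200).

## Moderated differential expression and signatures

One-vs-rest two-group linear models per gene; residual variances are
shrunk toward an inverse-gamma prior fitted by the method of moments on
log s² (trigamma inversion by Newton iteration; when the observed spread
of log s² is below sampling noise, the prior df is infinite and the prior
variance is the arithmetic mean of s²). The moderated t uses the
augmented degrees of freedom. With prior df forced to 0 the statistic
reduces exactly to the ordinary pooled t. The implementation agrees with
the R reference implementation to ~1e-8 on shared fixtures (cross-checked
in the test suite via `Rscript`). No expression-level trend is fitted and
no covariates enter the design, matching the analysis as described.

BH adjustment is the exact step-up with stable sort. Signature extraction
takes up = {adjusted p < 0.05, log2FC > 2} and down = {adjusted p < 0.05,
log2FC < −2}, strict inequalities, sorted by adjusted p. "log FC"
is interpreted on the log2 scale (the convention of the underlying
linear-model machinery). In the pipeline, if one direction is empty at
the configured fold change — possible when true effects sit exactly at
the threshold and the log2(TPM + 1) transform compresses low-abundance
genes — that side is filled at half the threshold with a logged warning;
the library-level `extract_signature` stays strict.

## Single-sample GSEA and the MPscore

Genes are ranked within one sample by expression (average ranks on ties;
the top gene has rank score G). Walking the list in decreasing order, the
in-set CDF accumulates |rank|^τ over set members (τ = 0.25) and the
out-set CDF is uniform over non-members; the enrichment score is the sum
of their differences over all positions. Cohort-range normalization
(dividing each set's scores by max − min across samples) is on by
default, following the reference implementation's default; whether the
original analysis used it is unknown, and the raw running sum is
available via `SsgseaParams(normalize=False)`.

MPscore = ssGSEA(up) − ssGSEA(down), one up set and one down set; with
multiple set pairs the differences would sum pairwise. The score is
rank-based, hence invariant to any monotone transform of expression, and
antisymmetric under swapping the up/down lists.

## Stemness, immune scores, marker ranking

The stemness index is the Spearman correlation between a per-gene weight
vector and the sample's expression over overlapping genes (≥ 10
required), min–max rescaled across the cohort. The weight vector is an
external artifact; the package accepts any weight file and the generator
ships its own synthetic one.

Immune scores are arithmetic means of marker-gene log2 expression per
population; panels are supplied as GMT (the generator writes its own
panels; published marker lists are not reproduced).

Marker ranking fits a bagged ensemble of decision trees (bootstrap rows,
√d features per split — sklearn trees under an ensemble authored here,
since the needed out-of-bag permutation importance is not exposed by the
library's forest). Importance is the mean decrease in out-of-bag accuracy
when a feature is permuted; recursive elimination divides the retained
count by 1.5 per round ("removal of 1.5 variables in each step" read as
the cross-validation utility's step > 1 convention), recording 10-fold
cross-validated error at each size. AUC is the Mann–Whitney identity with
ties counted 0.5; orientation is the caller's.

## Methylation rules

M = log2(β/(1−β)) with β clipped to [1e-6, 1−1e-6]. CIMP: a group's
variable loci are those with within-group β SD > 0.2; the group is
CIMP-positive when a majority of them have group-mean β > 0.5 (the
hypermethylation cut of 0.5 is our definition; only the SD threshold is
given). Differentially methylated signatures reuse the moderated-t
machinery on M values pairwise; a locus enters a group's signature when
significant in *all* pairwise contrasts at |ΔM| > 2 and BH p < 0.05.
Arm loss is arm mean < 0.1 (strict; the scale of the threshold is
preserved as quoted and configurable since the source scale is ambiguous).
Subtype assignment applies rules in order: 1p+22q co-loss → 3; 22q loss
alone → 2; SI > 0.5 → 4; no loss → 1; a sample with a 1p loss alone and
low SI is left unassigned with a warning. The precedence (losses before
stemness) is our resolution of the narrative ordering; an NF2-mutation
condition cannot be evaluated from methylation alone, so the co-loss arm
of the subtype-3 criterion is used.

## Survival

Kaplan–Meier, log-rank, and Cox partial likelihood are delegated to
`lifelines` (Breslow tie handling; Efron is out of scope), behind
validated interfaces: times must be positive, events 0/1, constant
covariates are rejected by name, categorical covariates are dummy-coded
against a stated reference level, and the fit requires more events than
coefficients. The Cox table reports coefficients and 95% CIs on the log
scale and hazard-ratio scale side by side, to avoid the ambiguity of
mixing scales in one table. MPscore is dichotomized at the cohort median
with ties to "low" (the original split is unstated; the cutpoint is
recorded and overridable). The endpoint (overall vs recurrence-free) is
selected by a flag naming the event column.

## Pipeline and numerical conventions

Stage seeds are derived deterministically from the global seed and stage
name, so stages rerun independently yet reproducibly; the manifest
records per-stage parameters hash, seed, wall time, and output checksums.
Floats serialize with ≥ 10 significant digits; every table has a header
row. Gene identifiers match by exact string; no symbol aliasing.

Problem sizes in the test suite and acceptance script — 65-sample
fixtures for unit tests, the 179-sample default cohort with 500 consensus
resamples and 400-replicate calibration loops for the end-to-end checks —
were chosen so the full suite completes in a few minutes while keeping
every statistical check at a scale where its expected behavior is
unambiguous.

## Known limitations

The SigClust-style test assumes a diagonal-spectrum Gaussian null and a
2-means index; strongly non-Gaussian elongated clusters can be declared
significant for the wrong reason. The delta-area/PAC k-selection is a
heuristic and, like all consensus-stability rules, can under-select k
when subtypes are extremely unbalanced. The generator's additive
log-scale effects make recovery easier than in real cohorts with
correlated programs; passing planted-recovery tests demonstrates
implementation correctness, not field performance. Methylation-array
preprocessing, raw-read processing, fusion detection, and compound
screening are out of scope.
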