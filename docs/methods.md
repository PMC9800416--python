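# Methods

`seedsoil` re-implements, as a reusable and fully tested pipeline, a
seed-and-soil transcriptomic analysis of histopathological growth
patterns (HGPs) in colorectal cancer liver metastases (CRLM).  Liver
metastases grow either with a desmoplastic pattern (dHGP — a fibrous rim
separates tumor from liver) or a replacement pattern (rHGP — tumor cells
replace hepatocytes).  The analysis asks how much of that morphology is
explained by expression programs of the primary tumor (the "seed") and
of the surrounding normal liver (the "soil"), and whether a composite
clinical–molecular score stratifies early-relapse risk.

Because the original patient-level data are access-restricted, every
stage runs against a synthetic cohort generator that plants the same
statistical structure the analysis assumes.  All quantitative claims in
this note are computed by the test suite or by `scripts/acceptance.py`.

## Cohort and sample structure

A cohort consists of patients with up to three matched tissues:

* `C` — primary colorectal lesion (one per patient),
* `L` — liver metastasis lesions (one to four per patient),
* `Ln` — tumor-distant normal liver (one per patient),

with a patient-level HGP label (`dHGP`, `rHGP`, `impure`).  All
expression values are TPM (each sample column sums to 10^6); all
analyses operate on TPM directly, using rank-based tests that are
insensitive to monotone within-sample transforms.

## Synthetic cohort generator

`seedsoil.simulate` draws a 35-patient cohort (20 dHGP, 15 rHGP) with 90
metastasis lesions, 35 primaries, and 35 normal-liver samples — 160
expression columns in total.  Expression follows a log2-normal model:

    x_gs = 2^( mu_g + delta_gs + eps_gs ),   eps_gs ~ N(0, sigma^2)

with gene baselines `mu_g ~ N(5, 2)` on the log2 scale and `sigma = 0.5`
of biological noise.  Columns are rescaled to TPM after the draw.  Four
disjoint gene modules carry class/tissue effects `delta`:

| module                 | size | effect (log2) | up in              |
|------------------------|-----:|--------------:|--------------------|
| `emt_angio`            |  100 |           1.5 | dHGP, C and L      |
| `immune`               |  100 |           1.5 | dHGP, L only       |
| `metabolism_cellcycle` |  100 |           1.5 | rHGP, C and L      |
| `ln_fibrosis`          |    9 |           0.8 | dHGP, Ln only      |

The module sizes of 100 genes are a deliberate scale-down of the
hundreds-to-thousands of differential genes a real cohort yields; they
keep the planted/background contrast realistic (2% of a 5,000-gene
transcriptome per program) while making sensitivity measurable.  The
9-gene fibrosis panel uses the conventional gene symbols LUM, LOXL4,
EPHA3, ITGBL1, NALCN, MOXD1, EFEMP1, DTNA plus a configurable ninth
placeholder (`LN9_G9`); only eight members of this panel have fixed
names in the literature.

Relapse-free survival is exponential with a baseline hazard of
0.05/month, multiplied by a hazard ratio of 3 for the high-risk stratum
(the non-dHGP patients), with administrative censoring at 24 months.
Only the relative ordering of times matters for the rank-based survival
tests downstream.

What the generator does **not** emulate: within-patient correlation
between lesions beyond the shared class effect, library-size and
GC-content artifacts, mixed-HGP lesions, graded immune/stromal
infiltration continua, or chemotherapy effects.  Consequently, passing
tests demonstrate that the pipeline recovers structure it is pointed at
— not that the biological findings replicate on new patients.

## Differential expression

`run_de` tests each gene with the two-sided Wilcoxon rank-sum test and
adjusts across all tested genes with Benjamini–Hochberg.  For tie-free
genes with at most 50 samples per group the exact rank-sum null
distribution is used — the convention of R's `wilcox.test`, and
necessary at these sample sizes: with 5,000 genes the smallest
Bonferroni-surviving p-values live in a tail region where the normal
approximation (which saturates near 5e-7 for 20-vs-15 complete
separation, against an exact 6e-10) is badly truncated.  Genes with ties
use the tie- and continuity-corrected normal approximation; constant
genes are assigned p = 1 rather than dropped.

Fold change is `log2((mean_A + 1) / (mean_B + 1))` on mean TPM with a
pseudocount of 1.  A gene is called only when both gates pass:
|log2FC| above the threshold **and** FDR below the threshold.  The
default gates are |log2FC| > 1, FDR < 0.05 for the metastasis and
primary comparisons and |log2FC| > 0.5, FDR < 0.05 for normal liver.

The dHGP signature (`dHGP_shared`) is the set of genes significantly up
in dHGP in **both** the primary-lesion and the metastasis comparison;
`rHGP_shared` analogously.  The normal-liver (fibrosis) signature is the
set of genes up in dHGP normal liver.  At the planted effect of 0.8 the
fibrosis panel is only partially recovered (typically 3–7 of 9 genes
across seeds) — realistic behavior for a small effect under
5,000-fold multiplicity, and sufficient for the downstream score.

## Single-sample enrichment and the seed/soil scores

The enrichment score (ES) of gene set S in one sample is a rank-weighted
running-sum integral.  Sort the N measured genes by decreasing
expression (ties broken by gene identifier); position i carries weight
`w_i = (N - i + 1)^alpha` if the gene is in S.  With

    P_in(i)  = sum_{j<=i, j in S} w_j / sum_{j in S} w_j
    P_out(i) = #{j <= i, j not in S} / (N - |S|)

the score is `ES = sum_i (P_in(i) - P_out(i))` — the full integral of
the running sum, not its maximum deviation.  `alpha = 0.25` by
convention.  Using rank weights (rather than raw expression) makes the
ES exactly invariant under monotone transforms of a sample's values,
a property the test suite checks against a naive loop-based reference
implementation.

Scores for a set × sample matrix are optionally normalized by dividing
every ES by the (max − min) range over the whole matrix; a zero range
falls back to raw scores with a warning.

Per patient: the **dHGP score** and **rHGP score** are the ES of the two
shared signatures in the patient's primary (C) sample, normalized
jointly; the **C-score** is their difference (the "seed" statistic); the
**Ln-score** is the ES of the fibrosis panel in the patient's normal
liver (the "soil" statistic).  `c_score == dhgp_score − rhgp_score`
holds to machine precision by construction.

## Seed–soil classification

Patients are dichotomized at the cohort median of each score (strictly
above the median is "high"; ties at the median go "low" — deterministic
and conservative toward the dHGP-like call), yielding quadrants
HH/HL/LH/LL.  The association between the strata {HH, discordant, LL}
and the HGP label is tested by uncorrected Pearson chi-square.  Note the
median split forces ≈ half the cohort to "low" on each axis, so with
unbalanced classes even perfectly separated scores leave some
majority-class patients in discordant quadrants.

Patients are also clustered on the z-scored (C-score, Ln-score) pair
with Euclidean complete-linkage agglomeration, and the predictive
accuracy of the C-score, Ln-score, and their combination for the HGP
label is measured by ROC curves.  The AUC is the Mann–Whitney
probability with half-credit for ties; its 95% CI uses the DeLong
variance.  The combined marker is the in-sample logistic linear
predictor `b0 + b1·C + b2·Ln` (Newton–Raphson, tol 1e-8, max 100
iterations); under perfect separation it falls back to the sum of
rank-standardized markers.  Because the combination is fitted in-sample
on ~35 patients, it carries optimism: on null cohorts the combined AUC
averages ≈ 0.65 rather than 0.5 — a property of the method, reported
as-is by the acceptance checks.

## Transcriptome subtypes and the composite risk score

Metastasis lesions are clustered on z-scored signature score profiles
(Ward linkage, Euclidean) and cut at k = 3; clusters are ranked by their
mean immune + stromal signature z-score and labeled High-IS ≥ Medium-IS
≥ Low-IS.  A patient carries the Medium-IS flag if any lesion is
Medium-IS (default; a majority rule with a deterministic tie-break
toward Medium-IS is available).

The composite risk score adds one point for a non-dHGP growth pattern
(impure patients count as non-dHGP) and one point for the Medium-IS
flag; 0–1 points is low-risk, 2 points high-risk.  On the default
synthetic cohort the two planted lesion classes force the k = 3 cut to
split one class on noise, so the risk grouping can be degenerate there;
the pipeline reports the dHGP vs non-dHGP survival contrast (which
carries the planted hazard) alongside the risk-group contrast.

## Survival

Kaplan–Meier product-limit curves, the standard log-rank test
(hypergeometric variance at each event time, df = 1), and univariate Cox
proportional hazards (Breslow tie handling, Wald CI) compare groups on
relapse-free survival.  The 6-month endpoint (RFS6M) censors
administratively at 6 months; an event at exactly the horizon counts as
an early relapse.  Early-relapse rates are compared by chi-square.  The
chi-square p-value on small 2×2 count tables is lattice-valued, so its
null calibration is verified as type-I-error control (≤ nominal + Monte
Carlo slack), not as distributional uniformity.

## Numerical and implementation choices

* Standard primitives are delegated: scipy (rank tests, chi-square,
  Spearman, agglomerative linkage), statsmodels (BH, logistic fit),
  scikit-learn (PCA, ROC curve points), lifelines (KM, log-rank, Cox).
  The ssGSEA running sum and the DeLong variance are implemented here.
* PCA z-scores features by default (the two scores live on different
  scales); zero-variance features are centered only.
* The scalar Wilcoxon helper uses the exact distribution for tie-free
  samples up to n = 25 per group; the vectorized DE engine extends the
  exact path to 50 per group (see above).
* Hierarchical clustering follows scipy's deterministic tie-breaking
  (lowest-index pair first).
* TSV is the canonical table format (gzip transparent); gene sets use
  GMT; expression round-trips bit-exactly (`float_precision="round_trip"`
  on read).
* Missing values are rejected, never imputed; gene identifiers are
  opaque case-sensitive strings.

## Problem sizes used in the checks

The test suite runs mostly on a scaled-down cohort (800 genes, 40-gene
modules, identical structure otherwise); the acceptance checks use the
full default design (5,000 genes, 160 samples) — 20 cohorts for DE
sensitivity/FDR, 5 null cohorts for AUC calibration, 1,000 null
replicates at n = 50/50 for the log-rank level, 20 simulations at
n = 200 for Cox hazard-ratio recovery, and one complete end-to-end
pipeline run.  These sizes give Monte-Carlo standard errors comfortably
below the acceptance tolerances.

## Known limitations

* The study's patient-level results (its exact DEG counts, 0.963 AUC,
  quadrant counts, survival p-values) are data-dependent and are not —
  and cannot be — reproduced from synthetic data; the pipeline
  reproduces the *procedures* and verifies them on planted truth.
* ssGSEA is the only scoring method offered (no GSVA/KS variant), and
  enrichment p-values by permutation are not implemented.
* Cox regression is univariate only; no competing risks, no
  multivariable adjustment.
* The lesion-to-patient subtype rule is a design choice; the original
  analysis does not specify how multi-lesion patients with discordant
  subtypes were scored.
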