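# seedsoil

Seed-and-soil transcriptomics of histopathological growth patterns
(HGPs) in colorectal cancer liver metastases (CRLM).

Liver metastases grow with either a **desmoplastic** pattern (dHGP: a
fibrous rim separates tumor from liver; better prognosis) or a
**replacement** pattern (rHGP: tumor cells replace hepatocytes).
`seedsoil` implements, as a tested and reusable pipeline, the analysis
that links these morphologies to expression programs of the primary
tumor (the *seed*) and the normal liver (the *soil*):

1. **Differential expression** on TPM — per-gene two-sided Wilcoxon
   rank-sum with Benjamini–Hochberg FDR, gated on
   |log2FC| > 1 (metastasis/primary) or > 0.5 (normal liver) and
   FDR < 0.05;
2. **Signature construction** — genes up-regulated in a growth pattern
   in *both* the primary and the metastasis comparison
   (`dHGP_shared`, `rHGP_shared`), plus the fibrosis genes up in dHGP
   normal liver;
3. **Single-sample enrichment (ssGSEA)** — for gene set S in one sample,
   with genes ranked by decreasing expression and rank weights
   w_i = (N−i+1)^α (α = 0.25),

       ES(S) = Σ_i [ P_in(i) − P_out(i) ]

   the full running-sum integral; from it the per-patient seed statistic
   **C-score = dHGP score − rHGP score** (primary lesion) and the soil
   statistic **Ln-score** (fibrosis-panel enrichment in normal liver);
4. **Seed–soil classification** — median dichotomization into score
   quadrants with a chi-square association test, hierarchical clustering
   of patients, and ROC/AUC (DeLong 95% CI) for each score and their
   in-sample logistic combination;
5. **Transcriptome subtyping & risk** — Ward clustering of lesions on
   signature profiles into High/Medium/Low-IS (immune + stromal score),
   and the composite risk score: non-dHGP = 1 point, Medium-IS = 1
   point; 2 points = high risk;
6. **Survival** — Kaplan–Meier, log-rank, univariate Cox (Breslow), and
   the 6-month relapse-free-survival endpoint.

Because the original cohort is access-restricted, the package ships a
**synthetic cohort generator** that reproduces the study's structure (20
dHGP vs 15 rHGP patients; 90 metastasis lesions, 35 primaries, 35
normal-liver samples; planted EMT/angiogenesis, immune, metabolism and
9-gene fibrosis modules) with known ground truth, so every stage is
verifiable end to end.  See `docs/methods.md` for the model and all
conventions.

## Worked example

Simulate a cohort and run the whole pipeline:

```sh
seedsoil simulate --outdir demo --seed 1
seedsoil run-all --cohort demo --outdir demo_run
```

The run directory receives the DE tables, signature GMT, score table,
quadrant/cluster/subtype/risk tables, ROC and survival JSON summaries,
KM/ROC figures and a run log.  The command prints a summary (seed 1):

```json
{
  "signatures": {"dHGP_shared": 100, "rHGP_shared": 100, "Ln_fibrosis": 4},
  "quadrant_chi2_p": 2.511e-08,
  "roc": {
    "c_score":  {"auc": 1.0, "ci95_low": 1.0, "ci95_high": 1.0},
    "ln_score": {"auc": 1.0, "ci95_low": 1.0, "ci95_high": 1.0},
    "combined": {"auc": 1.0, "ci95_low": 1.0, "ci95_high": 1.0}
  },
  "survival": {
    "n": 35,
    "hgp_group": {
      "log_rank": {"statistic": 3.999, "p_value": 0.0455},
      "cox": {"reference_level": "dHGP", "hazard_ratio": 3.634,
              "ci95_low": 0.939, "ci95_high": 14.07, "p_value": 0.0617}
    }
  }
}
```

Reading it: the 100-gene planted seed programs are recovered exactly as
the shared dHGP/rHGP signatures; 4 of the 9 planted fibrosis genes pass
the stringent normal-liver gates (the planted effect there is small by
design); score quadrants associate with the growth pattern at
p ≈ 2.5e-08; both scores separate the classes perfectly on this cohort
(AUC 1.0); and the dHGP vs non-dHGP relapse contrast recovers the
planted hazard ratio of 3 as HR ≈ 3.6 (log-rank p ≈ 0.046).

The same machinery is available as a library:

```python
from seedsoil.simulate import CohortDesign, generate
from seedsoil.pipeline import PipelineConfig, run_all

cohort = generate(CohortDesign(seed=1))
```

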