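"""Synthetic CRLM cohort generator.

Emulates a 35-patient cohort (20 desmoplastic-HGP, 15 replacement-HGP)
with matched primary-tumor (C), liver-metastasis (L, 1-4 lesions per
patient, 90 in total) and normal-liver (Ln) samples — 160 expression
columns altogether.

Expression follows a log2-normal model: each gene has a baseline log2
mean drawn from Normal(5, 2); a sample's value is
``2 ** (baseline + class/tissue effect + Normal(0, sigma))`` and columns
are then scaled to TPM (sum 1e6).  Planted modules mirror the programs
that separate the two growth patterns:

* ``emt_angio``              up in dHGP C and L samples (EMT/angiogenesis/stroma)
* ``immune``                 up in dHGP L samples only
* ``metabolism_cellcycle``   up in rHGP C and L samples
* ``ln_fibrosis``            a 9-gene fibrosis panel up in dHGP Ln samples

Relapse-free survival is exponential with administrative censoring; the
high-risk stratum (non-dHGP patients) has its hazard multiplied by a
configurable hazard ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataValidationError
from .io import (
    ExpressionMatrix,
    GeneSet,
    validate_annotations,
    validate_clinical,
    write_annotations,
    write_clinical,
    write_expression,
    write_gmt,
)

logger = logging.getLogger(__name__)

#: Fibrosis-associated genes up-regulated in dHGP normal liver.  Only eight
#: are fixed by convention; the ninth slot is a configurable placeholder.
DEFAULT_LN_PANEL = (
    "LUM", "LOXL4", "EPHA3", "ITGBL1", "NALCN", "MOXD1", "EFEMP1", "DTNA",
    "LN9_G9",
)

MODULES = ("emt_angio", "immune", "metabolism_cellcycle", "ln_fibrosis")


@dataclass
class CohortDesign:
    """Parameters of the simulated cohort.

    Defaults reproduce the study conditions: 20 dHGP vs 15 rHGP patients,
    90 metastatic lesions in total (1-4 per patient), 5000 genes, planted
    effects of 1.5 log2-fold (0.8 for the 9-gene normal-liver fibrosis
    panel) on top of biological noise with SD 0.5 on the log2 scale.
    """

    n_dhgp_patients: int = 20
    n_rhgp_patients: int = 15
    lesions_min: int = 1
    lesions_max: int = 4
    n_lesions_total: int = 90
    n_genes: int = 5000
    module_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "emt_angio": 100,
            "immune": 100,
            "metabolism_cellcycle": 100,
            "ln_fibrosis": 9,
        }
    )
    effect_log2fc: dict[str, float] = field(
        default_factory=lambda: {
            "emt_angio": 1.5,
            "immune": 1.5,
            "metabolism_cellcycle": 1.5,
            "ln_fibrosis": 0.8,
        }
    )
    sigma: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    ln_panel: tuple[str, ...] = DEFAULT_LN_PANEL
    #: monthly exponential hazard of relapse in the low-risk stratum
    baseline_hazard: float = 0.05
    #: hazard multiplier for the high-risk (non-dHGP) stratum
    hazard_ratio: float = 3.0
    #: administrative censoring horizon, months
    censor_horizon: float = 24.0
    seed: int = 0

    def validate(self) -> None:
        for name, size in self.module_sizes.items():
            if name not in MODULES:
                raise DataValidationError(f"unknown module {name!r}")
            if size < 1:
                raise DataValidationError(f"module {name!r} has size {size} < 1")
        if sum(self.module_sizes.values()) > self.n_genes:
            raise DataValidationError(
                f"module sizes sum to {sum(self.module_sizes.values())} "
                f"> n_genes = {self.n_genes}"
            )
        if len(self.ln_panel) < self.module_sizes.get("ln_fibrosis", 0):
            raise DataValidationError(
                "ln_panel shorter than the ln_fibrosis module size"
            )
        if not (1 <= self.lesions_min <= self.lesions_max):
            raise DataValidationError("need 1 <= lesions_min <= lesions_max")
        n_pat = self.n_dhgp_patients + self.n_rhgp_patients
        if not (n_pat * self.lesions_min <= self.n_lesions_total <= n_pat * self.lesions_max):
            raise DataValidationError(
                f"n_lesions_total = {self.n_lesions_total} unreachable with "
                f"{n_pat} patients and {self.lesions_min}-{self.lesions_max} lesions each"
            )
        for eff in self.effect_log2fc.values():
            if not np.isfinite(eff):
                raise DataValidationError("effects must be finite")
        if self.sigma < 0:
            raise DataValidationError("sigma must be >= 0")


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    annotations: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict


def _lesion_counts(design: CohortDesign, rng: np.random.Generator) -> np.ndarray:
    n_pat = design.n_dhgp_patients + design.n_rhgp_patients
    counts = rng.integers(design.lesions_min, design.lesions_max + 1, size=n_pat)
    # repair to the exact study total while staying within bounds
    while counts.sum() != design.n_lesions_total:
        if counts.sum() < design.n_lesions_total:
            candidates = np.flatnonzero(counts < design.lesions_max)
            counts[rng.choice(candidates)] += 1
        else:
            candidates = np.flatnonzero(counts > design.lesions_min)
            counts[rng.choice(candidates)] -= 1
    return counts


def generate(design: CohortDesign | None = None) -> SimulatedCohort:
    """Generate a cohort; deterministic given ``design.seed``."""
    design = design or CohortDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)

    n_pat = design.n_dhgp_patients + design.n_rhgp_patients
    patient_ids = [f"P{i + 1:02d}" for i in range(n_pat)]
    hgp = np.array(["dHGP"] * design.n_dhgp_patients + ["rHGP"] * design.n_rhgp_patients)

    # gene ids: planted modules first, then background
    modules: dict[str, list[str]] = {}
    gene_ids: list[str] = []
    cursor = 0
    for name in MODULES:
        size = design.module_sizes.get(name, 0)
        if name == "ln_fibrosis":
            genes = list(design.ln_panel[:size])
        else:
            genes = [f"{name.upper()}_{j + 1:03d}" for j in range(size)]
        modules[name] = genes
        gene_ids.extend(genes)
        cursor += size
    gene_ids.extend(f"G{j + 1:05d}" for j in range(design.n_genes - cursor))
    if len(set(gene_ids)) != len(gene_ids):
        raise DataValidationError("gene id clash between modules and background")

    # samples
    lesion_counts = _lesion_counts(design, rng)
    rows = []
    for p, pid in enumerate(patient_ids):
        rows.append((f"{pid}_C", pid, "C", hgp[p]))
        rows.append((f"{pid}_Ln", pid, "Ln", hgp[p]))
        for m in range(lesion_counts[p]):
            rows.append((f"{pid}_L{m + 1}", pid, "L", hgp[p]))
    ann = pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue", "hgp"])

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=design.n_genes)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    effect = np.zeros((design.n_genes, len(ann)), dtype=float)
    for name, genes in modules.items():
        eff = design.effect_log2fc.get(name, 0.0)
        if eff == 0.0 or not genes:
            continue
        gidx = [gene_index[g] for g in genes]
        is_d = (ann["hgp"] == "dHGP").to_numpy()
        is_r = (ann["hgp"] == "rHGP").to_numpy()
        tis = ann["tissue"].to_numpy()
        if name == "emt_angio":
            cols = is_d & np.isin(tis, ("C", "L"))
        elif name == "immune":
            cols = is_d & (tis == "L")
        elif name == "metabolism_cellcycle":
            cols = is_r & np.isin(tis, ("C", "L"))
        else:  # ln_fibrosis
            cols = is_d & (tis == "Ln")
        effect[np.ix_(gidx, np.flatnonzero(cols))] += eff

    noise = rng.normal(0.0, design.sigma, size=effect.shape)
    log2_expr = baseline[:, None] + effect + noise
    values = np.exp2(log2_expr)
    values *= 1e6 / values.sum(axis=0, keepdims=True)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=ann["sample_id"].tolist()),
        tpm=True,
    )

    # clinical covariates + exponential relapse-free survival
    high_risk = hgp != "dHGP"
    rate = design.baseline_hazard * np.where(high_risk, design.hazard_ratio, 1.0)
    latent = rng.exponential(1.0 / rate)
    time = np.minimum(latent, design.censor_horizon)
    event = latent <= design.censor_horizon
    clin = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "gender": rng.choice(["male", "female"], size=n_pat, p=[0.7, 0.3]),
            "location": rng.choice(["left", "right"], size=n_pat, p=[0.68, 0.32]),
            "hgp": hgp,
            "rfs_time_months": np.round(time, 3),
            "rfs_event": event,
        }
    )
    # rounding can make a very early event hit 0.0 months; keep times positive
    clin.loc[clin["rfs_time_months"] <= 0, "rfs_time_months"] = 0.001

    truth = {
        "seed": design.seed,
        "modules": {name: list(genes) for name, genes in modules.items()},
        "effect_log2fc": dict(design.effect_log2fc),
        "sigma": design.sigma,
        "high_risk_patients": [p for p, h in zip(patient_ids, high_risk) if h],
        "lesion_counts": {p: int(c) for p, c in zip(patient_ids, lesion_counts)},
    }
    return SimulatedCohort(
        expression=expr,
        annotations=validate_annotations(ann),
        clinical=validate_clinical(clin),
        truth=truth,
    )


def module_gene_sets(cohort: SimulatedCohort) -> list[GeneSet]:
    """Planted modules as gene sets (for signature scoring demos)."""
    return [
        GeneSet(name=name, genes=tuple(genes), description="planted module")
        for name, genes in cohort.truth["modules"].items()
    ]


def write_fixture(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the four canonical cohort files plus the planted-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotations": outdir / "annotations.tsv",
        "clinical": outdir / "clinical.tsv",
        "modules": outdir / "modules.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression(cohort.expression, paths["expression"])
    write_annotations(cohort.annotations, paths["annotations"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_gmt(module_gene_sets(cohort), paths["modules"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    logger.info("cohort fixture written to %s", outdir)
    return paths
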