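"""End-to-end orchestration of the seed-soil analysis.

Stages, in order: differential expression (liver metastases, primary
lesions, normal liver) -> shared-signature construction -> ssGSEA
scoring (C-score / Ln-score) -> seed-soil classification and ROC ->
transcriptome subtyping and composite risk score -> relapse-free
survival.  Every stage writes its artifact into the run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import AnalysisError, DataValidationError, SeedSoilError
from . import classify, diffexp, ssgsea, subtypes, survival
from .io import (
    GeneSet,
    align_cohort,
    read_annotations,
    read_clinical,
    read_expression,
    read_gmt,
    write_gmt,
)

logger = logging.getLogger(__name__)


@dataclass
class DEThresholds:
    lfc: float = 1.0
    fdr: float = 0.05


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; every threshold is a named key."""

    expression: str = "expression.tsv"
    annotations: str = "annotations.tsv"
    clinical: str = "clinical.tsv"
    signature_gmt: str = "modules.gmt"

    # DE gates per comparison (dHGP is always group A)
    de_liver: DEThresholds = field(default_factory=lambda: DEThresholds(1.0, 0.05))
    de_primary: DEThresholds = field(default_factory=lambda: DEThresholds(1.0, 0.05))
    de_normal_liver: DEThresholds = field(default_factory=lambda: DEThresholds(0.5, 0.05))

    ssgsea_alpha: float = 0.25
    normalize_scores: bool = True

    seed_soil_linkage: str = "complete"
    subtype_linkage: str = "ward"
    patient_rule: str = "any_medium"
    immune_sets: list[str] = field(default_factory=lambda: ["immune"])
    stromal_sets: list[str] = field(default_factory=lambda: ["emt_angio"])

    survival_horizon: float = 6.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key in ("de_liver", "de_primary", "de_normal_liver"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = DEThresholds(**kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**kwargs)
        for th in (cfg.de_liver, cfg.de_primary, cfg.de_normal_liver):
            if th.lfc <= 0 or not (0 < th.fdr <= 1):
                raise DataValidationError("DE thresholds must be positive")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _hgp_groups(ann: pd.DataFrame, tissue: str) -> tuple[list[str], list[str]]:
    sub = ann[ann["tissue"] == tissue]
    a = sub.loc[sub["hgp"] == "dHGP", "sample_id"].tolist()
    b = sub.loc[sub["hgp"] == "rHGP", "sample_id"].tolist()
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError(
            f"{tissue} comparison needs >= 2 samples per HGP class "
            f"(got {len(a)} dHGP, {len(b)} rHGP)"
        )
    return a, b


def _survival_block(
    surv: pd.DataFrame,
    group_col: str,
    horizon: float,
    out: Path,
    km_tables: dict,
) -> dict:
    """KM per group, log-rank/Cox between two groups, 6-month endpoint."""
    block: dict = {}
    surv_h = survival.censor_at(surv, horizon)
    for grp, sub in surv_h.groupby(group_col):
        km = survival.km_curve(sub)
        km.to_csv(out / f"km_{grp}.tsv", sep="\t", index=False)
        km_tables[str(grp)] = km
    levels = sorted(surv_h[group_col].unique())
    if len(levels) == 2:
        g0 = surv_h[surv_h[group_col] == levels[0]]
        g1 = surv_h[surv_h[group_col] == levels[1]]
        if g0["event"].any() or g1["event"].any():
            stat, p = survival.log_rank(g0, g1)
            block["log_rank"] = {"statistic": stat, "p_value": p}
        try:
            cox = survival.cox_univariate(
                surv_h.assign(_x=(surv_h[group_col] == levels[1]).astype(float)),
                "_x",
            )
            block["cox"] = {"reference_level": str(levels[0]), **cox.summary()}
        except Exception as exc:  # degenerate or non-converging small-cohort fit
            logger.warning("Cox fit for %s skipped: %s", group_col, exc)
    r6 = survival.rfs6m(surv.assign(group=surv[group_col]), group_col="group",
                        horizon=horizon)
    block["rfs6m"] = {
        "counts": {str(c): r6.counts[c].to_dict() for c in r6.counts.columns},
        "chi2_p": None if np.isnan(r6.p_value) else r6.p_value,
    }
    return block


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns a dict of result summaries."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        expr = read_expression(config.expression, tpm_check=True)
        ann = read_annotations(config.annotations)
        clin = read_clinical(config.clinical)
        signature_sets = read_gmt(config.signature_gmt)

        # ---- differential expression ------------------------------------
        stage = "diffexp"
        de_tables = {}
        for tissue, th, fname in (
            ("L", config.de_liver, "de_liver.tsv"),
            ("C", config.de_primary, "de_primary.tsv"),
            ("Ln", config.de_normal_liver, "de_normal_liver.tsv"),
        ):
            sub = align_cohort(expr, ann, tissue)
            a, b = _hgp_groups(ann, tissue)
            de = diffexp.run_de(sub, a, b, lfc_threshold=th.lfc, fdr_threshold=th.fdr)
            diffexp.write_de(de, out / fname)
            de_tables[tissue] = de

        # ---- signature construction -------------------------------------
        stage = "signatures"
        dhgp_set = diffexp.intersect_up_sets(de_tables["C"], de_tables["L"], "up_in_A")
        rhgp_set = diffexp.intersect_up_sets(de_tables["C"], de_tables["L"], "up_in_B")
        ln_genes = diffexp.significant_genes(de_tables["Ln"], "up_in_A")
        if dhgp_set is None or rhgp_set is None or not ln_genes:
            raise AnalysisError(
                "signature construction failed: an intersection or the "
                "normal-liver DEG list is empty"
            )
        ln_set = GeneSet("Ln_fibrosis", tuple(sorted(ln_genes)),
                         "genes up in dHGP normal liver")
        write_gmt([dhgp_set, rhgp_set, ln_set], out / "signatures.gmt")

        # ---- scoring ------------------------------------------------------
        stage = "scoring"
        expr_c = align_cohort(expr, ann, "C")
        expr_ln = align_cohort(expr, ann, "Ln")
        scores = ssgsea.compute_scores(
            expr_c, expr_ln, dhgp_set, rhgp_set, ln_set, ann,
            alpha=config.ssgsea_alpha, normalize=config.normalize_scores,
        )
        scores = ssgsea.attach_hgp(scores, ann)
        pure = scores[scores["hgp"].isin(["dHGP", "rHGP"])].reset_index(drop=True)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)

        # ---- seed-soil classification ------------------------------------
        stage = "seed_soil"
        quad = classify.quadrant_classify(pure)
        quad.assignments.to_csv(out / "quadrants.tsv", sep="\t", index=False)
        clusters = classify.cluster_patients(pure, k=2,
                                             linkage=config.seed_soil_linkage)
        clusters.rename_axis("patient_id").reset_index().to_csv(
            out / "clusters.tsv", sep="\t", index=False)
        rocs = classify.evaluate_predictors(pure)
        roc_summary = {name: r.summary() for name, r in rocs.items()}
        with open(out / "roc.json", "w") as fh:
            json.dump(
                {"quadrant_chi2_p": quad.p_value, "roc": roc_summary}, fh, indent=2
            )

        # ---- subtyping and risk ------------------------------------------
        stage = "subtype_risk"
        expr_l = align_cohort(expr, ann, "L")
        sig_matrix = ssgsea.score_matrix(
            expr_l, signature_sets, alpha=config.ssgsea_alpha,
            normalize=config.normalize_scores,
        )
        sig_matrix.to_csv(out / "signature_matrix.tsv", sep="\t",
                          index_label="signature")
        lesion_subtypes = subtypes.assign_subtypes(
            sig_matrix, config.immune_sets, config.stromal_sets,
            k=3, linkage=config.subtype_linkage,
        )
        lesion_subtypes.to_csv(out / "subtypes.tsv", sep="\t", index=False)
        pat_subtypes = subtypes.patient_subtype(lesion_subtypes, ann,
                                                rule=config.patient_rule)
        risk = subtypes.assign_risk(pat_subtypes, ann)
        risk.to_csv(out / "risk.tsv", sep="\t", index=False)

        # ---- survival -----------------------------------------------------
        stage = "survival"
        hgp_by_patient = ann.drop_duplicates("patient_id").set_index(
            "patient_id")["hgp"]
        surv = clin.merge(risk[["patient_id", "risk_group"]], on="patient_id",
                          how="inner")
        surv = surv.rename(columns={"rfs_time_months": "time", "rfs_event": "event"})
        surv["hgp_group"] = np.where(
            surv["patient_id"].map(hgp_by_patient) == "dHGP", "dHGP", "non_dHGP"
        )
        surv_summary: dict = {"n": int(len(surv))}
        km_tables: dict[str, pd.DataFrame] = {}
        for group_col in ("hgp_group", "risk_group"):
            surv_summary[group_col] = _survival_block(
                surv, group_col, config.survival_horizon, out, km_tables
            )
        with open(out / "survival.json", "w") as fh:
            json.dump(surv_summary, fh, indent=2)

        # ---- plots + run log ---------------------------------------------
        stage = "report"
        from . import plotting

        plotting.plot_km(km_tables, out / "km.png")
        plotting.plot_roc(rocs, out / "roc.png")
        run_log = {
            "config_digest": config.digest(),
            "config": config.to_dict(),
            "seed": config.seed,
            "package_version": __version__,
            "stages": ["diffexp", "signatures", "scoring", "seed_soil",
                       "subtype_risk", "survival", "report"],
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2)
    except SeedSoilError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    return {
        "signatures": {"dHGP_shared": len(dhgp_set), "rHGP_shared": len(rhgp_set),
                       "Ln_fibrosis": len(ln_set)},
        "quadrant_chi2_p": quad.p_value,
        "roc": roc_summary,
        "risk_groups": risk["risk_group"].value_counts().to_dict(),
        "survival": surv_summary,
        "outdir": str(out),
    }
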