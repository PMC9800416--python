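"""Transcriptome subtyping of liver metastases and the composite risk score.

Lesions are clustered (Ward linkage, Euclidean) on z-scored signature
score profiles into three subtypes ranked by their mean immune + stromal
signature score: High-IS >= Medium-IS >= Low-IS.

The composite risk score per patient adds one point for a non-dHGP
growth pattern and one point for carrying the Medium-IS subtype;
0-1 points = low risk, 2 points = high risk.  (Impure-HGP patients count
as non-dHGP.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import AnalysisError, DataValidationError
from .stats import hierarchical_cluster

logger = logging.getLogger(__name__)

SUBTYPE_LABELS_K3 = ("High_IS", "Medium_IS", "Low_IS")
PATIENT_RULES = ("any_medium", "majority")


def assign_subtypes(
    signatures: pd.DataFrame,
    immune_sets: Sequence[str],
    stromal_sets: Sequence[str],
    k: int = 3,
    linkage: str = "ward",
) -> pd.DataFrame:
    """Cluster lesions on signature profiles and label subtypes by rank.

    ``signatures`` is a set-by-sample score matrix.  Rows are z-scored,
    lesions clustered at ``k`` (default 3), and clusters ordered by the
    mean of their immune + stromal signature z-scores; with k = 3 the
    ordered labels are High_IS, Medium_IS, Low_IS.  Returns a DataFrame
    (sample_id, subtype).
    """
    for name in list(immune_sets) + list(stromal_sets):
        if name not in signatures.index:
            raise DataValidationError(f"signature set {name!r} not in matrix")
    X = signatures.to_numpy(dtype=float)
    if X.shape[1] < k:
        raise DataValidationError(
            f"fewer lesions ({X.shape[1]}) than clusters requested ({k})"
        )
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise AnalysisError("all signature rows are constant; clustering degenerate")
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    zmat = pd.DataFrame(Z, index=signatures.index[keep], columns=signatures.columns)

    labels, _ = hierarchical_cluster(zmat.to_numpy().T, k=k, linkage=linkage)

    ranking_rows = [n for n in list(immune_sets) + list(stromal_sets)
                    if n in zmat.index]
    if not ranking_rows:
        raise AnalysisError("immune/stromal signature rows are constant; "
                            "cannot rank subtypes")
    is_score = zmat.loc[ranking_rows].mean(axis=0).to_numpy()
    cluster_means = [is_score[labels == c].mean() for c in range(k)]
    order = np.argsort(cluster_means)[::-1]  # highest immune+stromal first
    if k == 3:
        names = SUBTYPE_LABELS_K3
    else:
        names = tuple(f"IS_rank{r + 1}" for r in range(k))
    label_map = {int(cluster): names[rank] for rank, cluster in enumerate(order)}
    return pd.DataFrame(
        {
            "sample_id": signatures.columns,
            "subtype": [label_map[int(c)] for c in labels],
        }
    )


def patient_subtype(
    assignments: pd.DataFrame,
    annotations: pd.DataFrame,
    rule: str = "any_medium",
) -> pd.DataFrame:
    """Patient-level Medium-IS flag from lesion-level subtypes.

    ``any_medium`` (default): flagged when any lesion is Medium_IS.
    ``majority``: modal lesion subtype, ties broken toward Medium_IS.
    Returns a DataFrame (patient_id, subtype, medium_flag).
    """
    if rule not in PATIENT_RULES:
        raise DataValidationError(f"unknown rule {rule!r}; expected {PATIENT_RULES}")
    merged = assignments.merge(
        annotations[["sample_id", "patient_id"]], on="sample_id", how="left"
    )
    if merged["patient_id"].isna().any():
        bad = merged.loc[merged["patient_id"].isna(), "sample_id"].tolist()
        raise DataValidationError(f"unannotated lesions: {bad}")
    l_patients = set(annotations.loc[annotations["tissue"] == "L", "patient_id"])
    missing = sorted(l_patients - set(merged["patient_id"]))
    if missing:
        raise DataValidationError(f"patients with no subtyped lesion: {missing}")

    rows = []
    for pid, grp in merged.groupby("patient_id", sort=False):
        subs = grp["subtype"].tolist()
        if rule == "any_medium":
            flag = "Medium_IS" in subs
            modal = "Medium_IS" if flag else pd.Series(subs).mode().iloc[0]
        else:
            counts = pd.Series(subs).value_counts()
            top = counts[counts == counts.max()].index.tolist()
            modal = "Medium_IS" if "Medium_IS" in top else sorted(top)[0]
            flag = modal == "Medium_IS"
        rows.append((pid, modal, flag))
    return pd.DataFrame(rows, columns=["patient_id", "subtype", "medium_flag"])


@dataclass(frozen=True)
class RiskAssignment:
    patient_id: str
    hgp_point: int
    subtype_point: int

    @property
    def total(self) -> int:
        return self.hgp_point + self.subtype_point

    @property
    def risk_group(self) -> str:
        return "high" if self.total == 2 else "low"


def risk_score(hgp: str, medium_flag: bool, patient_id: str = "") -> RiskAssignment:
    """Composite point score: non-dHGP -> 1 point, Medium-IS -> 1 point.

    0-1 points = low risk; 2 points = high risk.  ``hgp`` accepts the
    patient labels dHGP / rHGP / impure (the latter two are non-dHGP) or
    the literal "non_dHGP".
    """
    if hgp == "dHGP":
        hgp_point = 0
    elif hgp in ("rHGP", "impure", "non_dHGP"):
        hgp_point = 1
    else:
        raise DataValidationError(f"unknown HGP label {hgp!r}")
    return RiskAssignment(
        patient_id=patient_id,
        hgp_point=hgp_point,
        subtype_point=1 if medium_flag else 0,
    )


def assign_risk(
    patient_subtypes: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Risk table (patient_id, hgp_point, subtype_point, total, risk_group)."""
    hgp = annotations.drop_duplicates("patient_id").set_index("patient_id")["hgp"]
    rows = []
    for _, rec in patient_subtypes.iterrows():
        pid = rec["patient_id"]
        if pid not in hgp.index:
            raise DataValidationError(f"patient {pid!r} has no HGP annotation")
        ra = risk_score(hgp[pid], bool(rec["medium_flag"]), patient_id=pid)
        rows.append((pid, ra.hgp_point, ra.subtype_point, ra.total, ra.risk_group))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "hgp_point", "subtype_point", "total", "risk_group"],
    )
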