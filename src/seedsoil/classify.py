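"""Seed-soil classification from the C-score and Ln-score.

Patients are dichotomized at the cohort median of each score, placed in
score quadrants (HH / HL / LH / LL), clustered on the standardized score
pair, and the scores' predictive accuracy for the growth pattern is
measured by ROC curves (C-score, Ln-score, and their logistic
combination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import AnalysisError, DataValidationError
from .stats import ROCResult, chi_square_test, combine_markers, hierarchical_cluster, roc_auc

logger = logging.getLogger(__name__)

QUADRANTS = ("HH", "HL", "LH", "LL")


def median_split(values) -> pd.Series:
    """High/low dichotomization at the median: value > median -> "high".

    Values tied with the median go to "low" (deterministic, conservative
    toward the high-score call).
    """
    s = pd.Series(values, dtype=float)
    if s.size < 2:
        raise DataValidationError("median split needs at least 2 values")
    if s.isna().any():
        raise DataValidationError("median split got missing values")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index)


@dataclass
class QuadrantResult:
    assignments: pd.DataFrame     # patient_id, c_level, ln_level, quadrant, hgp
    counts: pd.DataFrame          # strata x HGP contingency counts
    statistic: float
    df: int
    p_value: float


def quadrant_classify(scores_with_hgp: pd.DataFrame) -> QuadrantResult:
    """Quadrant membership from median-split C-score and Ln-score.

    Expects columns patient_id, c_score, ln_score, hgp (see
    :func:`seedsoil.ssgsea.attach_hgp`).  Patients with a missing score
    are dropped with a warning.  The association with the HGP label is
    tested by chi-square on the strata HH / discordant (HL or LH) / LL;
    strata with no patients are omitted from the table.
    """
    df = scores_with_hgp
    for col in ("patient_id", "c_score", "ln_score", "hgp"):
        if col not in df.columns:
            raise DataValidationError(f"score table missing column {col!r}")
    complete = df.dropna(subset=["c_score", "ln_score"]).reset_index(drop=True)
    if len(complete) < len(df):
        logger.warning("dropping %d patients with incomplete scores",
                       len(df) - len(complete))
    if complete.empty:
        raise DataValidationError("no patients with both scores")

    c_level = median_split(complete["c_score"])
    ln_level = median_split(complete["ln_score"])
    quadrant = pd.Series(
        np.where(c_level == "high", "H", "L"), index=complete.index
    ) + pd.Series(np.where(ln_level == "high", "H", "L"), index=complete.index)

    assignments = pd.DataFrame(
        {
            "patient_id": complete["patient_id"],
            "c_level": c_level.to_numpy(),
            "ln_level": ln_level.to_numpy(),
            "quadrant": quadrant.to_numpy(),
            "hgp": complete["hgp"].to_numpy(),
        }
    )
    stratum = assignments["quadrant"].map(
        {"HH": "HH", "LL": "LL", "HL": "discordant", "LH": "discordant"}
    )
    counts = pd.crosstab(stratum, assignments["hgp"])
    counts = counts.loc[(counts.sum(axis=1) > 0), (counts.sum(axis=0) > 0)]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise AnalysisError("quadrant association degenerate: a margin is empty")
    stat, ddf, p = chi_square_test(counts.to_numpy())
    return QuadrantResult(assignments=assignments, counts=counts,
                          statistic=stat, df=ddf, p_value=p)


def cluster_patients(
    scores: pd.DataFrame, k: int = 2, standardize: bool = True,
    linkage: str = "complete",
) -> pd.Series:
    """Hierarchical clustering of patients on (C-score, Ln-score).

    The two scores are z-scored by default (they live on different
    scales), distances are Euclidean, linkage complete; the tree is cut
    at ``k`` clusters.  Returns labels indexed by patient id.
    """
    complete = scores.dropna(subset=["c_score", "ln_score"])
    X = complete[["c_score", "ln_score"]].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - X.mean(axis=0)) / sd
    labels, _ = hierarchical_cluster(X, k=k, linkage=linkage)
    return pd.Series(labels, index=complete["patient_id"].to_numpy(), name="cluster")


def evaluate_predictors(scores_with_hgp: pd.DataFrame) -> dict[str, ROCResult]:
    """ROC accuracy of the C-score, Ln-score and their combination.

    The positive class is dHGP.  The combined marker is the in-sample
    logistic linear predictor of the two scores.
    """
    df = scores_with_hgp.dropna(subset=["c_score", "ln_score"])
    y = (df["hgp"] == "dHGP").to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise AnalysisError("ROC evaluation needs >= 2 patients per class")
    c = df["c_score"].to_numpy(dtype=float)
    ln = df["ln_score"].to_numpy(dtype=float)
    combined = combine_markers(c, ln, y)
    return {
        "c_score": roc_auc(c, y),
        "ln_score": roc_auc(ln, y),
        "combined": roc_auc(combined, y),
    }
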