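"""Two-group differential expression on TPM and signature construction.

The engine is the two-sided Wilcoxon rank-sum test per gene with
Benjamini-Hochberg FDR across all tested genes.  Fold change is defined
on mean TPM with a pseudocount of 1:

    log2fc = log2((mean_A + 1) / (mean_B + 1))

A gene is called (``up_in_A`` / ``up_in_B``) only when BOTH gates pass:
|log2fc| > lfc_threshold AND fdr < fdr_threshold; otherwise ``ns``.

The dHGP/rHGP signatures are the genes significant and direction-
concordant in both the primary-lesion and liver-metastasis comparisons
(with dHGP as group A in each).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import DataValidationError
from .io import ExpressionMatrix, GeneSet
from .stats import bh_adjust

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1.0

#: largest per-group size at which the exact rank-sum distribution is used
EXACT_MAX_GROUP = 50

RESULT_COLUMNS = ("gene_id", "log2fc", "p_value", "fdr", "direction")


def run_de(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE of group A over group B.

    Returns a DataFrame with columns gene_id, log2fc, p_value, fdr,
    direction.  For tie-free genes with both groups <= 50 samples the
    exact rank-sum distribution is used (the convention of R's
    ``wilcox.test``, and necessary for BH-surviving tail p-values at
    cohort-scale n); genes with ties fall back to the tie- and
    continuity-corrected normal approximation, and genes constant across
    both groups get p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise DataValidationError(
            f"groups overlap: {sorted(set(group_a) & set(group_b))}"
        )
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataValidationError("each group needs at least 2 samples")
    A = expr.subset_samples(group_a).data.to_numpy()
    B = expr.subset_samples(group_b).data.to_numpy()

    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))

    pooled = np.concatenate([A, B], axis=1)
    has_ties = (np.diff(np.sort(pooled, axis=1), axis=1) == 0).any(axis=1)
    p = np.empty(pooled.shape[0], dtype=float)
    exact_ok = max(A.shape[1], B.shape[1]) <= EXACT_MAX_GROUP
    exact_rows = ~has_ties if exact_ok else np.zeros(pooled.shape[0], bool)
    with np.errstate(all="ignore"):
        if exact_rows.any():
            p[exact_rows] = sps.mannwhitneyu(
                A[exact_rows], B[exact_rows], axis=1,
                alternative="two-sided", method="exact",
            ).pvalue
        if (~exact_rows).any():
            p[~exact_rows] = sps.mannwhitneyu(
                A[~exact_rows], B[~exact_rows], axis=1,
                alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
    # constant genes (all ties): the statistic is degenerate -> p = 1
    constant = np.ptp(pooled, axis=1) == 0
    p[constant | ~np.isfinite(p)] = 1.0
    p = np.clip(p, 0.0, 1.0)

    fdr = bh_adjust(p)
    direction = np.where(
        (np.abs(log2fc) > lfc_threshold) & (fdr < fdr_threshold),
        np.where(log2fc > 0, "up_in_A", "up_in_B"),
        "ns",
    )
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        }
    )


def significant_genes(de: pd.DataFrame, direction: str) -> list[str]:
    """Genes called in the given direction (``up_in_A`` or ``up_in_B``)."""
    if direction not in ("up_in_A", "up_in_B"):
        raise DataValidationError(f"direction must be up_in_A/up_in_B, got {direction!r}")
    return de.loc[de["direction"] == direction, "gene_id"].tolist()


def intersect_up_sets(
    de_primary: pd.DataFrame,
    de_mets: pd.DataFrame,
    direction: str = "up_in_A",
) -> GeneSet | None:
    """Signature gene set: significant and concordant in both comparisons.

    Both result tables must have been computed with the same group
    orientation (dHGP as group A).  ``up_in_A`` yields the shared
    dHGP-up signature ("dHGP_shared"), ``up_in_B`` the rHGP one
    ("rHGP_shared").  An empty intersection returns None with a warning.
    """
    genes_primary = set(significant_genes(de_primary, direction))
    genes_mets = set(significant_genes(de_mets, direction))
    shared = sorted(genes_primary & genes_mets)
    name = "dHGP_shared" if direction == "up_in_A" else "rHGP_shared"
    if not shared:
        logger.warning("empty intersection for %s", name)
        return None
    return GeneSet(
        name=name,
        genes=tuple(shared),
        description=f"genes {direction} in both primary and metastasis DE",
    )


def write_de(de: pd.DataFrame, path: str | Path) -> None:
    de.loc[:, list(RESULT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_de(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in de.columns]
    if missing:
        raise DataValidationError(f"DE table missing columns: {missing}")
    return de
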