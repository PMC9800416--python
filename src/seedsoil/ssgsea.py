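"""Single-sample gene-set enrichment (ssGSEA) and the seed/soil scores.

The enrichment score of a gene set S in one sample is a rank-weighted
running-sum integral.  With genes sorted by decreasing expression
(ties broken by lexicographic gene id), position ``i`` (1-based, N genes
in total) carries weight ``w_i = (N - i + 1) ** alpha`` when the gene is
in S.  Walking down the list,

    P_in(i)  = sum of w_j for set genes at positions j <= i / total set weight
    P_out(i) = (# non-set genes at positions <= i) / (N - |S|)
    ES       = sum_i (P_in(i) - P_out(i))

i.e. the full running-sum integral, not its maximum deviation.  Because
weights depend on ranks only, the score is invariant under any strictly
monotone transform of a sample's expression values.

Built on these: the dHGP score and rHGP score of a primary lesion
(its shared dHGP-up / rHGP-up signature enrichment), the seed statistic
C-score = dHGP score - rHGP score, and the soil statistic Ln-score
(enrichment of the 9-gene fibrosis panel in the patient's normal liver).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import AnalysisError, DataValidationError
from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25

SCORE_COLUMNS = ("patient_id", "dhgp_score", "rhgp_score", "c_score", "ln_score")


def _ranked_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting genes by decreasing expression, gene id as tie-break."""
    # lexsort: last key is primary
    return np.lexsort((gene_ids, -values))


def ssgsea_es(
    sample_values: Mapping[str, float] | pd.Series,
    gene_set: GeneSet | Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Enrichment score of one gene set in one sample."""
    series = pd.Series(sample_values, dtype=float)
    genes = np.asarray(series.index, dtype=object)
    if len(set(genes)) != len(genes):
        raise DataValidationError("duplicate gene ids in sample")
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    in_set = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    return float(
        _es_from_order(
            series.to_numpy(dtype=float), genes, in_set, alpha
        )
    )


def _es_from_order(
    values: np.ndarray, gene_ids: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    N = values.size
    if N < 2:
        raise DataValidationError("need at least 2 measured genes")
    n_in = int(in_set.sum())
    if n_in == 0:
        raise AnalysisError("gene set does not intersect the measured genes")
    if n_in == N:
        raise AnalysisError("gene set covers every measured gene; ES undefined")
    order = _ranked_order(values, gene_ids)
    hit = in_set[order]
    weights = (N - np.arange(1, N + 1) + 1).astype(float) ** alpha
    w_hit = np.where(hit, weights, 0.0)
    p_in = np.cumsum(w_hit) / w_hit.sum()
    p_out = np.cumsum(~hit) / (N - n_in)
    return float(np.sum(p_in - p_out))


def score_matrix(
    expr: ExpressionMatrix,
    sets: Sequence[GeneSet],
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> pd.DataFrame:
    """Enrichment scores for every (gene set, sample) pair.

    Returns a set-by-sample DataFrame.  With ``normalize`` the scores are
    jointly rescaled by the (max - min) range over the whole matrix — the
    conventional ssGSEA normalization.  A zero range leaves the raw
    scores in place with a warning.
    """
    if not sets:
        raise DataValidationError("no gene sets supplied")
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    values = expr.data.to_numpy(dtype=float)
    memberships = []
    for gs in sets:
        in_set = np.isin(gene_ids, np.asarray(tuple(gs.genes), dtype=object))
        memberships.append(in_set)

    out = np.empty((len(sets), values.shape[1]))
    for j in range(values.shape[1]):
        col = values[:, j]
        for i, in_set in enumerate(memberships):
            out[i, j] = _es_from_order(col, gene_ids, in_set, alpha)
    mat = pd.DataFrame(out, index=[gs.name for gs in sets], columns=expr.sample_ids)
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            mat = mat / rng
        else:
            logger.warning("zero score range; normalization skipped")
    return mat


def compute_scores(
    expr_c: ExpressionMatrix,
    expr_ln: ExpressionMatrix,
    dhgp_set: GeneSet,
    rhgp_set: GeneSet,
    ln_set: GeneSet,
    annotations: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-patient score table: dHGP score, rHGP score, C-score, Ln-score.

    dHGP/rHGP scores come from the patient's primary (C) sample, jointly
    normalized before differencing; the Ln-score from the patient's
    normal-liver (Ln) sample.  Patients missing a sample get NaN in the
    affected fields (logged), so C-score rows always satisfy
    ``c_score == dhgp_score - rhgp_score`` where both are present.
    """
    ann = annotations
    sample_to_patient = dict(zip(ann["sample_id"], ann["patient_id"]))
    for s in expr_c.sample_ids + expr_ln.sample_ids:
        if s not in sample_to_patient:
            raise DataValidationError(f"sample {s!r} is not annotated")

    c_scores = score_matrix(expr_c, [dhgp_set, rhgp_set], alpha=alpha,
                            normalize=normalize)
    ln_scores = score_matrix(expr_ln, [ln_set], alpha=alpha, normalize=normalize)

    c_by_patient = {
        sample_to_patient[s]: (
            c_scores.loc[dhgp_set.name, s], c_scores.loc[rhgp_set.name, s]
        )
        for s in c_scores.columns
    }
    ln_by_patient = {
        sample_to_patient[s]: ln_scores.loc[ln_set.name, s]
        for s in ln_scores.columns
    }
    patients = list(dict.fromkeys(ann["patient_id"]))
    rows = []
    for pid in patients:
        d, r = c_by_patient.get(pid, (np.nan, np.nan))
        ln = ln_by_patient.get(pid, np.nan)
        if pid not in c_by_patient:
            logger.warning("patient %s has no primary (C) sample; C-score missing", pid)
        if pid not in ln_by_patient:
            logger.warning("patient %s has no normal-liver (Ln) sample; "
                           "Ln-score missing", pid)
        rows.append((pid, d, r, d - r, ln))
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))


def attach_hgp(scores: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Add the patient-level HGP label to a score table."""
    hgp = annotations.drop_duplicates("patient_id").set_index("patient_id")["hgp"]
    out = scores.copy()
    out["hgp"] = out["patient_id"].map(hgp)
    return out
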