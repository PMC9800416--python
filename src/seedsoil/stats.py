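"""Statistical primitives used throughout the pipeline.

Thin, validated wrappers over scipy / statsmodels / scikit-learn with the
exact conventions the analysis relies on:

* Pearson chi-square WITHOUT continuity correction (the convention that
  reproduces standard clinical contingency-table p-values),
* two-sided Wilcoxon rank-sum, exact for small tie-free samples and
  normal-approximated (tie- and continuity-corrected) otherwise,
* Benjamini-Hochberg step-up FDR,
* Spearman correlation,
* PCA on z-scored features,
* agglomerative hierarchical clustering (Euclidean),
* ROC/AUC with the Mann-Whitney tie convention and a DeLong 95% CI,
* two-marker combination through an in-sample logistic linear predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._errors import AnalysisError, DataValidationError

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction is applied.  Returns ``(statistic, df, p)``.
    A zero row or column margin makes the expected counts degenerate and
    raises :class:`AnalysisError`.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DataValidationError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.isfinite(t).all():
        raise DataValidationError("contingency table must hold non-negative counts")
    if t.sum() <= 0:
        raise DataValidationError("contingency table is empty")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise AnalysisError("zero row or column margin: chi-square df degenerate")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p-value when both samples have <= 25 observations and the pooled
    values are tie-free; otherwise the normal approximation with tie and
    continuity corrections.  Returns ``(U, p)`` with U the Mann-Whitney
    statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DataValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataValidationError("x and y must have equal length")
    if x.size < 3:
        raise DataValidationError("Spearman correlation needs n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise AnalysisError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class PCAResult:
    scores: np.ndarray          # samples x components
    loadings: np.ndarray        # features x components, orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None


def pca(matrix, n_components: int, scale: bool = True) -> PCAResult:
    """Principal component analysis of a samples x features matrix.

    Features are centered, and z-scored by default (the score columns fed
    to it live on different scales).  Zero-variance features are left
    centered only.
    """
    from sklearn.decomposition import PCA as _SKPCA

    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataValidationError("PCA needs a 2-D matrix with >= 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Xc = Xc / sd
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise AnalysisError(
            f"n_components = {n_components} exceeds matrix rank {rank}"
        )
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Xc)
    return PCAResult(
        scores=scores,
        loadings=model.components_.T,
        explained_variance=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
        mean=mean,
        scale=sd,
    )


def hierarchical_cluster(points, k: int, linkage: str = "complete"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering with Euclidean distances.

    Returns 0-based cluster labels (cut at ``k``) and the merge heights.
    scipy's agglomeration is deterministic, merging the lowest-index pair
    among ties first.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not (1 <= k <= n):
        raise DataValidationError(f"k = {k} must be in 1..{n}")
    if n == 1:
        return np.zeros(1, dtype=int), np.empty(0)
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    if np.unique(labels).size != k:
        raise AnalysisError(
            f"clustering degenerate: requested {k} clusters, "
            f"obtained {np.unique(labels).size} (indistinguishable points?)"
        )
    return labels.astype(int), Z[:, 2].copy()


@dataclass
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def summary(self) -> dict:
        return {"auc": self.auc, "ci95_low": self.ci95[0], "ci95_high": self.ci95[1]}


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC from placement values."""
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    # V10: per-positive placement; V01: per-negative placement
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC (Mann-Whitney form, ties get 0.5 credit).

    The 95% CI uses the DeLong variance estimate, clipped to [0, 1].
    """
    from sklearn.metrics import roc_curve

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.size != y.size:
        raise DataValidationError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise AnalysisError("ROC needs both classes present")
    pos, neg = s[y], s[~y]
    ranks = _midrank(s)
    # Mann-Whitney AUC: average placement of positives among negatives
    auc = (ranks[y].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    var = _delong_variance(pos, neg)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    fpr, tpr, thr = roc_curve(y.astype(int), s)
    return ROCResult(auc=float(auc), ci95=ci, fpr=fpr, tpr=tpr, thresholds=thr)


def combine_markers(m1, m2, labels) -> np.ndarray:
    """Combine two markers into one score via an in-sample logistic fit.

    Returns the linear predictor b0 + b1*m1 + b2*m2 of a logistic
    regression fitted by Newton-Raphson (tol 1e-8, max 100 iterations).
    Under perfect separation (or a failed fit) it falls back to the sum
    of the per-marker rank-standardized values, with a warning.
    """
    import statsmodels.api as sm

    x1 = np.asarray(m1, dtype=float)
    x2 = np.asarray(m2, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (x1.size == x2.size == y.size):
        raise DataValidationError("markers and labels must have equal length")
    if not y.any() or y.all():
        raise AnalysisError("marker combination needs both classes present")
    X = sm.add_constant(np.column_stack([x1, x2]), has_constant="add")
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y.astype(float), X).fit(
                method="newton", tol=1e-8, maxiter=100, disp=False,
            )
        beta = np.asarray(fit.params, dtype=float)
        if not np.isfinite(beta).all() or not fit.mle_retvals.get("converged", False):
            raise np.linalg.LinAlgError("logistic fit did not converge")
        return X @ beta
    except Exception:  # perfect separation, singular Hessian, ...
        logger.warning(
            "logistic combination failed (perfect separation?); "
            "falling back to summed rank-standardized markers"
        )
        r1 = _midrank(x1) / x1.size
        r2 = _midrank(x2) / x2.size
        return r1 + r2
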