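"""geneset_scoring: running-sum enrichment and the C-/Ln-score table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seedsoil import AnalysisError
from seedsoil.io import ExpressionMatrix, GeneSet
from seedsoil.ssgsea import attach_hgp, compute_scores, score_matrix, ssgsea_es
from seedsoil.stats import roc_auc

from conftest import naive_ssgsea_es


class TestEnrichmentScore:
    def test_hand_walked_five_gene_example(self):
        """Five genes at TPM (50,40,30,20,10), set {g1,g2}, alpha 0.25.

        Walking the ranked list: the two set genes occupy ranks 1-2 with
        weights 5**0.25 and 4**0.25, so P_in reaches w1/(w1+w2) then 1;
        P_out climbs 1/3 per non-set gene from rank 3 on.  The running-sum
        integral is w1/(w1+w2) + 1 + 2/3 + 1/3 + 0.
        """
        sample = {"g1": 50.0, "g2": 40.0, "g3": 30.0, "g4": 20.0, "g5": 10.0}
        w1, w2 = 5 ** 0.25, 4 ** 0.25
        expected = w1 / (w1 + w2) + 1 + 2 / 3 + 1 / 3
        assert ssgsea_es(sample, {"g1", "g2"}, alpha=0.25) == pytest.approx(
            expected, abs=1e-12)

    def test_matches_naive_reference(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 21))
            genes = [f"g{i}" for i in range(n)]
            values = dict(zip(genes, rng.random(n) * 100))
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            assert ssgsea_es(values, members) == pytest.approx(
                naive_ssgsea_es(values, members), abs=1e-12)

    def test_single_gene_set_rank_one_maximal(self):
        values = {f"g{i}": float(10 - i) for i in range(10)}
        top = ssgsea_es(values, {"g0"})
        for other in range(1, 10):
            assert top > ssgsea_es(values, {f"g{other}"})

    def test_gene_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(15)]
        vals = rng.random(15) * 10
        sample = pd.Series(vals, index=genes)
        perm = rng.permutation(15)
        shuffled = sample.iloc[perm]
        assert ssgsea_es(sample, {"g3", "g7"}) == pytest.approx(
            ssgsea_es(shuffled, {"g3", "g7"}), abs=1e-12)

    def test_full_set_rejected(self):
        with pytest.raises(AnalysisError, match="every measured gene"):
            ssgsea_es({"a": 1.0, "b": 2.0}, {"a", "b"})

    def test_disjoint_set_rejected(self):
        with pytest.raises(AnalysisError, match="does not intersect"):
            ssgsea_es({"a": 1.0, "b": 2.0}, {"zzz"})


class TestScoreMatrix:
    def _expr(self, values, genes=None):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        cols = [f"s{j}" for j in range(values.shape[1])]
        return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols))

    def test_identical_samples_zero_range_warns(self, caplog):
        expr = self._expr(np.tile([[5.0], [3.0], [1.0]], (1, 2)))
        with caplog.at_level("WARNING"):
            mat = score_matrix(expr, [GeneSet("s", ("g0",))], normalize=True)
        assert mat.iloc[0, 0] == mat.iloc[0, 1]
        assert "normalization skipped" in caplog.text

    def test_normalized_range_is_one(self, rng):
        expr = self._expr(rng.random((30, 6)) * 100)
        sets = [GeneSet("a", ("g0", "g1", "g2")), GeneSet("b", ("g5", "g9"))]
        mat = score_matrix(expr, sets, normalize=True)
        rng_val = mat.to_numpy().max() - mat.to_numpy().min()
        assert rng_val == pytest.approx(1.0, abs=1e-12)

    def test_rank_invariance_under_scaling(self, rng):
        values = rng.random((25, 4)) * 50
        expr = self._expr(values)
        doubled = self._expr(values * 2)
        sets = [GeneSet("a", ("g0", "g3", "g11"))]
        m1 = score_matrix(expr, sets, normalize=False)
        m2 = score_matrix(doubled, sets, normalize=False)
        pd.testing.assert_frame_equal(m1, m2)


class TestComputeScores:
    def _cohort_frames(self, rng, n_pat=8):
        genes = [f"g{i}" for i in range(60)]
        patients = [f"P{i}" for i in range(n_pat)]
        ann = pd.DataFrame(
            [(f"{p}_C", p, "C", "dHGP") for p in patients]
            + [(f"{p}_Ln", p, "Ln", "dHGP") for p in patients],
            columns=["sample_id", "patient_id", "tissue", "hgp"],
        )
        make = lambda suffix: ExpressionMatrix(pd.DataFrame(
            rng.random((60, n_pat)) * 100, index=genes,
            columns=[f"{p}_{suffix}" for p in patients]))
        return make("C"), make("Ln"), ann

    def test_c_score_is_exact_difference(self, rng):
        expr_c, expr_ln, ann = self._cohort_frames(rng)
        d = GeneSet("d", ("g0", "g1", "g2"))
        r = GeneSet("r", ("g10", "g11"))
        ln = GeneSet("ln", ("g20", "g21"))
        scores = compute_scores(expr_c, expr_ln, d, r, ln, ann)
        np.testing.assert_allclose(
            scores["c_score"], scores["dhgp_score"] - scores["rhgp_score"],
            rtol=0, atol=0)

    def test_identical_sets_cancel(self, rng):
        expr_c, expr_ln, ann = self._cohort_frames(rng)
        d = GeneSet("d", ("g0", "g1", "g2"))
        r = GeneSet("r", ("g0", "g1", "g2"))
        ln = GeneSet("ln", ("g20",))
        scores = compute_scores(expr_c, expr_ln, d, r, ln, ann)
        np.testing.assert_allclose(scores["c_score"], 0.0, atol=1e-14)

    def test_missing_tissue_gives_nan_row(self, rng, caplog):
        expr_c, expr_ln, ann = self._cohort_frames(rng)
        expr_ln = expr_ln.subset_samples(expr_ln.sample_ids[1:])
        d = GeneSet("d", ("g0", "g1"))
        r = GeneSet("r", ("g10",))
        ln = GeneSet("ln", ("g20",))
        with caplog.at_level("WARNING"):
            scores = compute_scores(expr_c, expr_ln, d, r, ln, ann)
        assert np.isnan(scores.loc[0, "ln_score"])
        assert scores["ln_score"].notna().sum() == 7
        assert "Ln-score missing" in caplog.text


class TestPlantedSeparation:
    def test_c_and_ln_scores_separate_hgp_classes(self, small_cohort):
        """dHGP patients score higher on both seed and soil statistics
        (one-sided Wilcoxon p < 0.01 at the default planted effects)."""
        truth = small_cohort.truth["modules"]
        ann = small_cohort.annotations
        expr = small_cohort.expression
        c_ids = ann.query("tissue == 'C'")["sample_id"].tolist()
        ln_ids = ann.query("tissue == 'Ln'")["sample_id"].tolist()
        scores = compute_scores(
            expr.subset_samples(c_ids), expr.subset_samples(ln_ids),
            GeneSet("d", tuple(truth["emt_angio"])),
            GeneSet("r", tuple(truth["metabolism_cellcycle"])),
            GeneSet("ln", tuple(truth["ln_fibrosis"])),
            ann,
        )
        scores = attach_hgp(scores, ann)
        d = scores[scores["hgp"] == "dHGP"]
        r = scores[scores["hgp"] == "rHGP"]
        from scipy.stats import mannwhitneyu

        for col in ("c_score", "ln_score"):
            p = mannwhitneyu(d[col], r[col], alternative="greater").pvalue
            assert p < 0.01, col

    def test_null_ln_effect_gives_chance_auc(self):
        """With the fibrosis effect removed, the Ln-score cannot predict
        the growth pattern (AUC within 0.5 +/- 0.15 at n = 35)."""
        from conftest import small_design
        from seedsoil.simulate import generate

        design = small_design(seed=21)
        design.effect_log2fc["ln_fibrosis"] = 0.0
        cohort = generate(design)
        ann = cohort.annotations
        ln_ids = ann.query("tissue == 'Ln'")["sample_id"].tolist()
        mat = score_matrix(
            cohort.expression.subset_samples(ln_ids),
            [GeneSet("ln", tuple(cohort.truth["modules"]["ln_fibrosis"]))],
        )
        hgp = ann.set_index("sample_id").loc[ln_ids, "hgp"]
        auc = roc_auc(mat.iloc[0].to_numpy(), (hgp == "dHGP").to_numpy()).auc
        assert abs(auc - 0.5) <= 0.15
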