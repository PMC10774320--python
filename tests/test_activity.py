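"""Activity module: z-scoring, enrichment engine, signatures."""

import numpy as np
import pandas as pd
import pytest

from mechnet import (GeneSet, Regulon, Signature, gsea_enrichment,
                     phenotype_signature, regulon_enrichment,
                     single_sample_activities, zscore_genes)
from mechnet.simulate import make_cohort

from _oracles import exhaustive_pvalue, running_sum_es, welch_t
from conftest import make_signature


# ---------------------------------------------------------------------------
# z-scoring


class TestZscore:
    def test_symmetric_row(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=list("abc"))
        np.testing.assert_allclose(zscore_genes(df).loc["g1"], [-1, 0, 1])

    def test_constant_row_zeroed(self, caplog):
        df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]], index=["flat", "ok"],
                          columns=list("abc"))
        with caplog.at_level("WARNING", logger="mechnet.activity"):
            out = zscore_genes(df)
        np.testing.assert_array_equal(out.loc["flat"], [0, 0, 0])
        assert "constant" in caplog.text

    def test_random_matrix_moments(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(2, 3, size=(20, 6)))
        out = zscore_genes(df).to_numpy()
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, rtol=1e-10)

    def test_too_few_samples(self):
        df = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="samples"):
            zscore_genes(df)


# ---------------------------------------------------------------------------
# plain gene-set enrichment


class TestGseaEnrichment:
    def test_sign_convention(self, toy_signature):
        top = GeneSet("top", frozenset(["g01", "g02", "g03", "g04", "g05"]))
        bottom = GeneSet("bottom", frozenset(["g16", "g17", "g18", "g19", "g20"]))
        r_top = gsea_enrichment(toy_signature, top, rng_seed=0)
        r_bot = gsea_enrichment(toy_signature, bottom, rng_seed=0)
        assert r_top.es > 0 and r_top.nes > 0
        assert r_bot.es < 0 and r_bot.nes < 0

    def test_es_matches_running_sum_oracle(self):
        sig = make_signature(np.arange(10, 0, -1))  # scores 10..1
        geneset = GeneSet("s", frozenset([sig.gene_ids[0], sig.gene_ids[1]]))
        res = gsea_enrichment(sig, geneset, rng_seed=3, min_overlap=2)
        mask = np.isin(sig.gene_ids[sig.rank_order()], list(geneset.genes))
        expected = running_sum_es(sig.scores[sig.rank_order()], mask, 1.0)
        assert res.es == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("scores", [
        np.array([9.0, 7.5, 6.0, 4.0, 2.5, 1.0, -2.0, -5.0]),
        np.array([3.0, 2.0, 1.5, 1.0, 0.5, -0.5, -1.0, -3.0]),
    ])
    def test_permutation_p_matches_exhaustive_enumeration(self, scores):
        """p from 2000 gene permutations agrees with the exact C(8,3) null."""
        sig = make_signature(scores)
        geneset = GeneSet("s", frozenset(sig.gene_ids[[0, 1, 4]]))
        res = gsea_enrichment(sig, geneset, n_perm=2000, rng_seed=5, min_overlap=3)
        ranked = sig.scores[sig.rank_order()]
        p_exact = exhaustive_pvalue(ranked, 3, res.es)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / 2000)
        assert abs(res.pvalue - p_exact) < 3 * se + 1 / 2001

    def test_pvalue_floor(self, toy_signature):
        top = GeneSet("top", frozenset(["g01", "g02", "g03", "g04", "g05"]))
        res = gsea_enrichment(toy_signature, top, n_perm=200, rng_seed=0)
        assert res.pvalue >= 1 / 201

    def test_small_overlap_skipped(self, toy_signature):
        tiny = GeneSet("tiny", frozenset(["g01", "g02"]))
        res = gsea_enrichment(toy_signature, tiny, rng_seed=0)
        assert res.skipped and "overlap" in res.skipped_reason

    def test_nes_sign_matches_es(self, toy_signature):
        gs = GeneSet("mix", frozenset(["g01", "g05", "g11", "g15", "g19"]))
        res = gsea_enrichment(toy_signature, gs, rng_seed=2)
        if res.es != 0:
            assert np.sign(res.nes) == np.sign(res.es)

    def test_rank_only_mode_invariant_under_monotone_transform(self, toy_signature):
        gs = GeneSet("s", frozenset(["g02", "g03", "g07", "g11", "g13"]))
        r1 = gsea_enrichment(toy_signature, gs, weight_exponent=0.0, rng_seed=9)
        warped = Signature(toy_signature.gene_ids, np.exp(toy_signature.scores / 4.0))
        r2 = gsea_enrichment(warped, gs, weight_exponent=0.0, rng_seed=9)
        assert r1.es == pytest.approx(r2.es, rel=1e-12)
        assert r1.nes == pytest.approx(r2.nes, rel=1e-12)


# ---------------------------------------------------------------------------
# regulon enrichment


def _symmetric_signature():
    """Non-target scores symmetric about 0: mode-flip antisymmetry is exact (ES)."""
    scores = np.array([8.0, 6.0, 5.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -5.0,
                       -6.0, -8.0, 7.0, 4.5, 2.6, -2.4, -4.4])
    return make_signature(scores, prefix="t")


class TestRegulonEnrichment:
    def test_activated_targets_at_top(self, toy_signature):
        reg = Regulon("TR", np.array(["g01", "g02", "g03", "g04", "g05"], dtype=object),
                      np.ones(5))
        res = regulon_enrichment(toy_signature, reg, rng_seed=0)
        assert res.nes > 0

    def test_mode_flip_antisymmetry_on_symmetric_background(self):
        """Flipping every mode negates the ES exactly when the non-target score
        distribution is symmetric about zero; the NES (a ratio of the ES to a
        finite-permutation null mean) converges to the negated value."""
        sig = _symmetric_signature()
        targets = sig.gene_ids[[12, 13, 14, 15, 16]]  # asymmetric target block
        plus = Regulon("TR", targets, np.ones(5))
        minus = Regulon("TR", targets, -np.ones(5))
        r_plus = regulon_enrichment(sig, plus, n_perm=4000, rng_seed=4)
        r_minus = regulon_enrichment(sig, minus, n_perm=4000, rng_seed=4)
        assert r_minus.es == pytest.approx(-r_plus.es, rel=1e-9)
        assert np.sign(r_minus.nes) == -np.sign(r_plus.nes)
        assert abs(r_minus.nes) == pytest.approx(abs(r_plus.nes), rel=0.1)

    def test_mixed_modes_equal_sign_flip_oracle(self):
        """Flipping negative-mode target scores and running plain enrichment."""
        rng = np.random.default_rng(7)
        sig = make_signature(rng.normal(size=15))
        targets = sig.gene_ids[[0, 3, 5, 8, 11, 13]]
        modes = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        reg = Regulon("TR", targets, modes)
        res = regulon_enrichment(sig, reg, n_perm=500, rng_seed=21, min_overlap=5)
        flipped = sig.scores.copy()
        for t, m in zip(targets, modes):
            if m < 0:
                flipped[list(sig.gene_ids).index(t)] *= -1
        oracle_sig = Signature(sig.gene_ids, flipped)
        oracle = gsea_enrichment(oracle_sig, GeneSet("T", frozenset(targets)),
                                 n_perm=500, rng_seed=21, min_overlap=5)
        assert res.es == pytest.approx(oracle.es, rel=1e-12)
        assert res.nes == pytest.approx(oracle.nes, rel=1e-12)
        assert res.pvalue == oracle.pvalue

    def test_zero_mode_targets_dropped(self, toy_signature):
        reg = Regulon("TR", np.array([f"g{i:02d}" for i in range(1, 9)], dtype=object),
                      np.array([1, 1, 1, 1, 1, 0, 0, 0], dtype=float))
        res = regulon_enrichment(toy_signature, reg, rng_seed=0)
        assert res.n_overlap == 5


# ---------------------------------------------------------------------------
# single-sample activities


@pytest.fixture(scope="module")
def small_cohort():
    return make_cohort(n_samples=12, n_genes=220, n_trs=4, n_pathways=2,
                       targets_per_tr=15, genes_per_pathway=15, rng_seed=7)


class TestSingleSampleActivities:
    def test_planted_tr_activity_tracks_latent(self, small_cohort):
        expr, genesets, regulons, truth = small_cohort
        res = single_sample_activities(expr, genesets, regulons, n_perm=300, rng_seed=1)
        for tr in truth.tr_activities.index:
            latent = truth.tr_activities.loc[tr]
            carriers = latent > 0.5
            non = latent < -0.5
            assert res.trs.loc[tr, carriers.index[carriers]].mean() > \
                   res.trs.loc[tr, non.index[non]].mean()

    def test_column_equivariance_under_sample_shuffle(self, small_cohort):
        expr, genesets, regulons, _ = small_cohort
        res = single_sample_activities(expr, genesets, regulons, n_perm=100, rng_seed=5)
        perm = expr.columns[::-1]
        res2 = single_sample_activities(expr[perm], genesets, regulons,
                                        n_perm=100, rng_seed=5)
        # equality up to float summation-order noise in the cohort z-scores
        pd.testing.assert_frame_equal(res.trs[perm], res2.trs, rtol=1e-9, atol=1e-9)
        pd.testing.assert_frame_equal(res.pathways[perm], res2.pathways,
                                      rtol=1e-9, atol=1e-9)

    def test_top_gene_pathway_positive(self, small_cohort):
        expr, genesets, regulons, _ = small_cohort
        z = zscore_genes(expr)
        sample = z.columns[0]
        top_genes = z[sample].nlargest(10).index
        gs = GeneSet("TOP10", frozenset(top_genes))
        res = single_sample_activities(expr, [gs], regulons, n_perm=300, rng_seed=2)
        assert res.pathways.loc["TOP10", sample] > 0

    def test_empty_lists_rejected(self, small_cohort):
        expr, genesets, regulons, _ = small_cohort
        with pytest.raises(ValueError):
            single_sample_activities(expr, [], regulons, rng_seed=0)
        with pytest.raises(ValueError):
            single_sample_activities(expr, genesets, [], rng_seed=0)


# ---------------------------------------------------------------------------
# phenotype signatures


class TestPhenotypeSignature:
    def test_identical_groups_zero_contrast(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.normal(size=(30, 4)) + rng.normal(0, 1e-9, (30, 4)),
                            index=[f"g{i}" for i in range(30)], columns=list("abcd"))
        sig = phenotype_signature(base, base.copy())
        assert np.all(np.abs(sig.scores) < 1e-6)

    def test_matches_closed_form_welch(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame(rng.normal(0, 1, (5, 4)), index=[f"g{i}" for i in range(5)])
        b = pd.DataFrame(rng.normal(2, 1, (5, 4)), index=[f"g{i}" for i in range(5)])
        sig = phenotype_signature(a, b)
        for i, g in enumerate(sig.gene_ids):
            expected = welch_t(a.loc[g].to_numpy(), b.loc[g].to_numpy())
            assert sig.scores[i] == pytest.approx(expected, rel=1e-10)

    def test_swap_negates(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame(rng.normal(size=(8, 5)), index=[f"g{i}" for i in range(8)])
        b = pd.DataFrame(rng.normal(size=(8, 5)), index=[f"g{i}" for i in range(8)])
        s_ab = phenotype_signature(a, b)
        s_ba = phenotype_signature(b, a)
        np.testing.assert_allclose(s_ab.scores, -s_ba.scores, rtol=1e-10)

    def test_disjoint_universes_rejected(self):
        a = pd.DataFrame(np.ones((3, 2)) + np.arange(2), index=["g1", "g2", "g3"])
        b = pd.DataFrame(np.ones((3, 2)) + np.arange(2), index=["h1", "h2", "h3"])
        with pytest.raises(ValueError, match="disjoint"):
            phenotype_signature(a, b)
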