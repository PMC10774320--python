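"""VIF, latent variables, correlation circle, closeness clustering, effect scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mechnet import (closeness_and_cluster, correlation_circle, effect_scores,
                     pls_fit, prioritize_trs, vif)
from mechnet.datatypes import CirclePoint, MechanismNetwork, TRGroup
from mechnet.prioritize import PLSLatentRegression
from mechnet.simulate import make_collinear_block, make_prioritization_scenario

from _oracles import vif_by_ols


def _frame(values, prefix="TR"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, index=[f"{prefix}{i + 1}" for i in range(len(values))],
                        columns=[f"s{j + 1}" for j in range(values.shape[1])])


class TestVif:
    def test_orthogonal_vectors_vif_one(self):
        acts = _frame([[1, 1, -1, -1], [1, -1, 1, -1]])
        out = vif(acts)
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-10)

    def test_near_duplicate_exceeds_ten(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=30)
        acts = _frame([base, base + rng.normal(0, 1e-6, 30)])
        out = vif(acts)
        assert (out["vif"] > 10).all()

    def test_matches_independent_ols_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(3, 25))
        x[2] += 0.6 * x[0] - 0.4 * x[1]
        acts = _frame(x)
        out = vif(acts)
        np.testing.assert_allclose(out["vif"], vif_by_ols(x), rtol=1e-8)

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        x = rng.normal(size=(4, 40))
        x[3] = 0.9 * x[1] + 0.3 * rng.normal(size=40)
        acts = _frame(x)
        out = vif(acts)
        design = sm.add_constant(x.T)
        expected = [variance_inflation_factor(design, i + 1) for i in range(4)]
        np.testing.assert_allclose(out["vif"], expected, rtol=1e-8)

    def test_ridge_fallback_flagged(self):
        rng = np.random.default_rng(1)
        acts = _frame(rng.normal(size=(6, 5)))  # more TRs than samples
        out = vif(acts)
        assert (out["method"] == "ridge").all()


class TestPlsFit:
    def test_single_tr_component_tracks_it(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        acts = _frame([v])
        model = pls_fit(acts, 2 * v + 1, n_components=1)
        r = stats.pearsonr(model.components[0].scores, v).statistic
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_two_orthonormal_trs_pathway_equals_first(self):
        t1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]) / np.sqrt(6)
        t2 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        t2 = t2 - t2 @ t1 * t1
        t2 /= np.linalg.norm(t2)
        acts = _frame([t1, t2])
        model = pls_fit(acts, t1, n_components=2)
        w = model.components[0].weights
        np.testing.assert_allclose(np.abs(w), [1.0, 0.0], atol=1e-10)
        assert abs(model.components[0].r_with_pathway) == pytest.approx(1.0, abs=1e-10)

    def test_successive_scores_uncorrelated(self):
        rng = np.random.default_rng(9)
        acts = _frame(rng.normal(size=(5, 50)))
        y = rng.normal(size=50)
        model = pls_fit(acts, y, n_components=3)
        S = model.scores_matrix()
        for i in range(S.shape[1]):
            for j in range(i + 1, S.shape[1]):
                assert abs(stats.pearsonr(S[:, i], S[:, j]).statistic) < 1e-8

    def test_explained_variance_nondecreasing(self):
        rng = np.random.default_rng(14)
        acts = _frame(rng.normal(size=(4, 40)))
        y = acts.iloc[0].to_numpy() + 0.5 * rng.normal(size=40)
        explained = []
        for k in (1, 2, 3):
            model = pls_fit(acts, y, n_components=k)
            S = model.scores_matrix()
            design = np.column_stack([np.ones(len(y)), S])
            resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
            explained.append(1 - resid.var() / y.var())
        assert explained[0] <= explained[1] + 1e-12 <= explained[2] + 2e-12

    def test_collinear_block_stops_early(self):
        blk = make_collinear_block(n_samples=40, n_trs=6, latent_dim=1,
                                   noise_sd=1e-9, rng_seed=8)
        y = blk.iloc[0].to_numpy()
        model = pls_fit(blk, y, n_components=4)
        # one shared factor: everything after the first couple of components
        # is numerically exhausted
        assert model.n_components <= 2

    def test_too_many_components_rejected(self):
        acts = _frame(np.random.default_rng(0).normal(size=(2, 10)))
        with pytest.raises(ValueError, match="n_components"):
            pls_fit(acts, np.ones(10), n_components=3)

    def test_sklearn_estimator_wrapper(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        y = X[:, 0] + 0.3 * rng.normal(size=30)
        est = PLSLatentRegression(n_components=2).fit(X, y)
        assert est.x_scores_.shape == (30, 2)
        assert est.x_weights_.shape == (4, 2)
        r = stats.pearsonr(est.x_scores_[:, 0], est.x_scores_[:, 1]).statistic
        assert abs(r) < 1e-8


class TestCorrelationCircle:
    @pytest.fixture()
    def fixture_model(self):
        rng = np.random.default_rng(11)
        acts = _frame(rng.normal(size=(4, 30)))
        y = acts.iloc[0].to_numpy() + 0.4 * rng.normal(size=30)
        return acts, y, pls_fit(acts, y, n_components=2)

    def test_points_match_direct_pearson(self, fixture_model):
        acts, y, model = fixture_model
        points, pw_point = correlation_circle(model, acts, y)
        s1 = model.components[0].scores
        s2 = model.components[1].scores
        for p in points:
            vec = acts.loc[p.mechanism_id].to_numpy()
            assert p.x == pytest.approx(stats.pearsonr(vec, s1).statistic, rel=1e-10)
            assert p.y == pytest.approx(stats.pearsonr(vec, s2).statistic, rel=1e-10)
        assert pw_point.x == pytest.approx(stats.pearsonr(y, s1).statistic, rel=1e-10)

    def test_radius_bounded_by_one(self, fixture_model):
        acts, y, model = fixture_model
        points, pw_point = correlation_circle(model, acts, y)
        for p in points + [pw_point]:
            assert p.radius <= 1 + 1e-9

    def test_axis_aligned_vectors(self, fixture_model):
        acts, y, model = fixture_model
        s1 = model.components[0].scores
        s2 = model.components[1].scores
        aligned = pd.DataFrame([s1, s2], index=["A1", "A2"], columns=acts.columns)
        model2 = pls_fit(acts, y, n_components=2)
        model2.tr_ids = ["A1", "A2"]
        points, _ = correlation_circle(model2, aligned, y)
        assert points[0].x == pytest.approx(1.0) and points[0].angle_deg == pytest.approx(0.0)
        assert points[1].y == pytest.approx(1.0) and points[1].angle_deg == pytest.approx(90.0)

    def test_constant_vector_rejected(self, fixture_model):
        acts, y, model = fixture_model
        bad = acts.copy()
        bad.iloc[0] = 1.0
        with pytest.raises(ValueError, match="constant"):
            correlation_circle(model, bad, y)


class TestClosenessAndCluster:
    def _pt(self, name, angle_deg, r=0.9):
        a = np.radians(angle_deg)
        return CirclePoint(name, r * np.cos(a), r * np.sin(a))

    def test_same_angle_zero_closeness(self):
        g = closeness_and_cluster([self._pt("t", 30)], self._pt("pw", 30))
        assert g[0].mean_closeness_deg == pytest.approx(0.0, abs=1e-9)

    def test_wraparound_metric(self):
        g = closeness_and_cluster([self._pt("t", 350)], self._pt("pw", 10))
        assert g[0].mean_closeness_deg == pytest.approx(20.0, abs=1e-9)

    def test_two_planted_bands_recovered(self):
        points = [self._pt(f"t{i}", a) for i, a in enumerate([5, 7, 9, 80, 82, 84])]
        groups = closeness_and_cluster(points, self._pt("pw", 0), n_groups=2)
        members = sorted(tuple(g.members) for g in groups)
        assert members == [("t0", "t1", "t2"), ("t3", "t4", "t5")]

    def test_auto_choice_on_separable_bands(self):
        points = [self._pt(f"t{i}", a)
                  for i, a in enumerate([5, 7, 9, 80, 82, 84, 150, 152])]
        groups = closeness_and_cluster(points, self._pt("pw", 0), n_groups="auto")
        assert len(groups) == 3


class TestEffectScores:
    def _network(self, trs, weights):
        edges = pd.DataFrame({
            "tr": trs, "pathway": "PW", "alpha": 0.0, "beta": 1.0,
            "pvalue": 1e-6, "fdr": 1e-5, "sign": 1, "weight": weights})
        return MechanismNetwork(edges=edges, tr_ids=list(trs), pathway_ids=["PW"])

    def test_geometric_mean_arithmetic(self):
        assert stats.gmean([1, 1, 1]) == pytest.approx(1.0)
        assert stats.gmean([2, 8, 4]) == pytest.approx(4.0)

    def test_dominant_singleton_ranks_first(self):
        points = [CirclePoint("DOM", 0.99, 0.01),
                  CirclePoint("D1", 0.05, 0.9), CirclePoint("D2", 0.02, 0.85)]
        pw_point = CirclePoint("PW", 0.97, 0.05)
        net = self._network(["DOM", "D1", "D2"], [100.0, 20.0, 10.0])
        groups = closeness_and_cluster(points, pw_point, n_groups=2)
        ranked = effect_scores(groups, points, None, net, "PW")
        best = min(ranked, key=lambda g: g.final_rank)
        assert best.members == ["DOM"]
        assert best.effect_score == pytest.approx(1.0)

    def test_member_without_edge_is_contract_error(self):
        points = [CirclePoint("A", 0.9, 0.1), CirclePoint("B", 0.1, 0.9)]
        net = self._network(["A"], [50.0])
        net.tr_ids.append("B")
        groups = [TRGroup(members=["A"], mean_closeness_deg=5.0),
                  TRGroup(members=["B"], mean_closeness_deg=80.0)]
        with pytest.raises(KeyError, match="no edge"):
            effect_scores(groups, points, None, net, "PW")

    def test_order_and_scale_invariance(self):
        tr_acts, pvec, net, dom = make_prioritization_scenario(n_decoys=6, rng_seed=3)
        g1, *_ = prioritize_trs(net, tr_acts, pvec.to_numpy(), "PW01")
        g2, *_ = prioritize_trs(net, tr_acts.iloc[::-1] * 3.0,
                                pvec.to_numpy() * 3.0, "PW01")
        key = lambda gs: sorted((tuple(g.members), round(g.effect_score, 9),
                                 g.final_rank) for g in gs)
        assert key(g1) == key(g2)


class TestScenarioRecovery:
    def test_dominant_tr_wins_across_seeds(self):
        wins = 0
        for seed in range(5):
            tr_acts, pvec, net, dom = make_prioritization_scenario(n_decoys=10,
                                                                   rng_seed=seed)
            groups, model, *_ = prioritize_trs(net, tr_acts, pvec.to_numpy(), "PW01")
            best = min(groups, key=lambda g: g.final_rank)
            wins += (best.members == [dom])
            S = model.scores_matrix()
            assert abs(stats.pearsonr(S[:, 0], S[:, 1]).statistic) < 1e-8
        assert wins == 5

    def test_decoys_are_collinear(self):
        tr_acts, *_ = make_prioritization_scenario(n_decoys=10, rng_seed=0)
        decoys = tr_acts.drop(index="TR_DOM")
        assert (vif(decoys)["vif"] > 10).all()
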