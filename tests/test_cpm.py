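import numpy as np
import pytest
from scipy import stats
from sklearn.pipeline import Pipeline

from strokecpm import (
    BehaviorArray,
    ConnectivityTransformer,
    CPMRegressor,
    EdgeMask,
    edgewise_correlation,
    fit_model,
    pool_connectivity,
    predict,
    select_edges,
)
from strokecpm.connectome import matrix_from_edges, edge_count
from strokecpm.cpm import EdgeStatMaps


def random_cohort(rng, n, m):
    edges = rng.uniform(-0.9, 0.9, (n, edge_count(m)))
    mats = matrix_from_edges(edges, m)
    scores = rng.uniform(0, 6, n)
    beh = BehaviorArray([f"s{k}" for k in range(n)], scores, "mRS", 2)
    return list(mats), beh


class TestEdgewiseCorrelation:
    def test_behavior_copy_of_one_edge_has_r_one(self, rng):
        mats, beh = random_cohort(rng, 10, 5)
        scores = np.array([m[1, 3] for m in mats]) * 10 + 50
        beh = BehaviorArray(beh.subject_ids, scores.clip(0, 100), "BI", 2)
        st = edgewise_correlation(mats, beh)
        assert st.r[1, 3] == pytest.approx(1.0)
        assert st.p[1, 3] < 1e-6

    def test_constant_behavior_rejected(self, rng):
        mats, beh = random_cohort(rng, 8, 4)
        flat = BehaviorArray(beh.subject_ids, np.full(8, 3.0), "mRS", 2)
        with pytest.raises(ValueError, match="constant"):
            edgewise_correlation(mats, flat)

    def test_matches_per_edge_brute_force(self, rng):
        """Vectorised edge-wise stats equal a scipy.pearsonr loop (N=5 toy)."""
        mats, beh = random_cohort(rng, 5, 4)
        st = edgewise_correlation(mats, beh)
        for i in range(4):
            for j in range(i + 1, 4):
                vals = np.array([m[i, j] for m in mats])
                r, p = stats.pearsonr(vals, beh.scores)
                assert st.r[i, j] == pytest.approx(r, abs=1e-12)
                assert st.p[i, j] == pytest.approx(p, abs=1e-12)

    def test_symmetry_and_diagonal(self, rng):
        mats, beh = random_cohort(rng, 12, 6)
        st = edgewise_correlation(mats, beh)
        np.testing.assert_array_equal(st.r, st.r.T)
        np.testing.assert_array_equal(st.p, st.p.T)
        assert np.all(np.diag(st.r) == 0)
        assert np.all(np.diag(st.p) == 1)
        assert np.all(np.abs(st.r) <= 1)


class TestSelectEdges:
    def test_all_p_one_gives_empty_mask(self):
        m = 5
        st = EdgeStatMaps(r=np.ones((m, m)) * 0.5, p=np.ones((m, m)))
        assert select_edges(st, 0.05, "pos").is_empty

    def test_alpha_one_selects_every_positive_edge(self):
        m = 4
        r = matrix_from_edges(np.full(edge_count(m), 0.3), m)
        st = EdgeStatMaps(r=r, p=np.full((m, m), 0.9))
        pos = select_edges(st, 1.0, "pos")
        neg = select_edges(st, 1.0, "neg")
        assert pos.n_edges == edge_count(m)
        assert neg.is_empty

    def test_pos_neg_masks_disjoint(self, rng):
        mats, beh = random_cohort(rng, 15, 8)
        st = edgewise_correlation(mats, beh)
        for alpha in (0.01, 0.05, 0.5, 0.99):
            pos = select_edges(st, alpha, "pos").mask
            neg = select_edges(st, alpha, "neg").mask
            assert not np.any(pos & neg)

    def test_monotone_in_alpha(self, rng):
        mats, beh = random_cohort(rng, 15, 8)
        st = edgewise_correlation(mats, beh)
        previous = None
        for alpha in (0.01, 0.05, 0.2, 0.5, 0.9):
            mask = select_edges(st, alpha, "pos").mask
            if previous is not None:
                assert np.all(mask >= previous)
            previous = mask

    def test_recovers_planted_edges(self, planted_cohort):
        _, connectomes, behavior, truth = planted_cohort
        st = edgewise_correlation(connectomes, behavior)
        mask = select_edges(st, 0.05, "pos")
        assert set(truth.edges()) <= set(mask.edges())


class TestPoolConnectivity:
    def test_empty_mask_pools_to_zero(self, rng):
        mask = EdgeMask(np.zeros((4, 4)), "pos", 0.05)
        assert pool_connectivity(rng.standard_normal((4, 4)) * 0, mask) == 0.0

    def test_single_edge(self):
        c = matrix_from_edges(np.arange(1, 7, dtype=float) / 10, 4)
        sel = np.zeros((4, 4))
        sel[0, 2] = sel[2, 0] = 1
        mask = EdgeMask(sel, "pos", 0.05)
        assert pool_connectivity(c, mask) == pytest.approx(c[0, 2])

    def test_three_node_hand_sum(self):
        c = np.array([[0, 0.5, 0.2], [0.5, 0, -0.1], [0.2, -0.1, 0]])
        sel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        mask = EdgeMask(sel, "pos", 0.05)
        assert pool_connectivity(c, mask) == pytest.approx(0.4)

    def test_linear_in_connectome(self, rng):
        m = 6
        a = matrix_from_edges(rng.standard_normal(edge_count(m)), m)
        b = matrix_from_edges(rng.standard_normal(edge_count(m)), m)
        sel = matrix_from_edges((rng.random(edge_count(m)) < 0.4).astype(float), m)
        mask = EdgeMask(sel, "pos", 0.05)
        assert pool_connectivity(a + b, mask) == pytest.approx(
            pool_connectivity(a, mask) + pool_connectivity(b, mask), abs=1e-10)


class TestFitAndPredict:
    def _mask(self, m=3):
        sel = np.zeros((m, m))
        sel[0, 1] = sel[1, 0] = 1
        return EdgeMask(sel, "pos", 0.05)

    def test_exact_line_recovered(self):
        pooled = np.array([0.1, 0.4, 0.2, 0.8, 0.6])
        behavior = 2 * pooled + 1
        model = fit_model(pooled, behavior, self._mask())
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.training_r == pytest.approx(1.0)

    def test_orthogonal_behavior_gives_zero_slope(self, rng):
        pooled = rng.standard_normal(30)
        behavior = rng.standard_normal(30)
        design = np.column_stack([np.ones(30), pooled])
        behavior -= design @ np.linalg.lstsq(design, behavior, rcond=None)[0]
        model = fit_model(pooled, behavior, self._mask())
        assert abs(model.slope) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        pooled = rng.standard_normal(25)
        behavior = rng.uniform(0, 6, 25)
        model = fit_model(pooled, behavior, self._mask())
        design = np.column_stack([np.ones(25), pooled])
        beta = np.linalg.solve(design.T @ design, design.T @ behavior)
        assert model.intercept == pytest.approx(beta[0], abs=1e-10)
        assert model.slope == pytest.approx(beta[1], abs=1e-10)

    def test_predict_arithmetic(self):
        model = fit_model(np.array([0.0, 0.5, 1.0, 2.0]),
                          np.array([1.0, 2.0, 3.0, 5.0]), self._mask())
        # fitted exactly: slope 2, intercept 1; single-edge mask -> s = c_01
        c = np.zeros((3, 3))
        c[0, 1] = c[1, 0] = 0.3
        assert predict(model, c) == pytest.approx(1 + 2 * 0.3)

    def test_degenerate_model_falls_back_to_mean(self):
        empty = EdgeMask(np.zeros((3, 3)), "pos", 0.05)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            model = fit_model(np.zeros(5), np.array([1, 2, 3, 4, 5.0]), empty)
        assert model.degenerate
        with pytest.warns(RuntimeWarning):
            assert model.predict(np.zeros((3, 3))) == pytest.approx(3.0)

    def test_scale_equivariance(self, rng):
        """Scaling behavior scales the slope and leaves the mask identical."""
        mats, beh = random_cohort(rng, 20, 6)
        st = edgewise_correlation(mats, beh)
        mask = select_edges(st, 0.5, "pos")
        pooled = np.array([pool_connectivity(m, mask) for m in mats])
        m1 = fit_model(pooled, beh.scores, mask)
        scaled = BehaviorArray(beh.subject_ids, beh.scores * 10, "BI", 2)
        st2 = edgewise_correlation(mats, scaled)
        mask2 = select_edges(st2, 0.5, "pos")
        np.testing.assert_array_equal(mask.mask, mask2.mask)
        m2 = fit_model(pooled, scaled.scores, mask2)
        assert m2.slope == pytest.approx(10 * m1.slope, rel=1e-10)


class TestCPMRegressor:
    def test_fit_predict_matches_functional_route(self, planted_cohort):
        _, connectomes, behavior, _ = planted_cohort
        reg = CPMRegressor(alpha=0.05, polarity="pos").fit(connectomes, behavior)
        st = edgewise_correlation(connectomes, behavior)
        mask = select_edges(st, 0.05, "pos")
        np.testing.assert_array_equal(reg.edge_mask_.mask, mask.mask)
        pooled = np.array([pool_connectivity(c, mask) for c in connectomes])
        model = fit_model(pooled, behavior, mask)
        assert reg.slope_ == pytest.approx(model.slope, abs=1e-10)
        assert reg.intercept_ == pytest.approx(model.intercept, abs=1e-10)
        preds = reg.predict(connectomes)
        manual = np.array([model.predict(c) for c in connectomes])
        np.testing.assert_allclose(preds, manual, atol=1e-10)

    def test_get_set_params_round_trip(self):
        reg = CPMRegressor(alpha=0.01, polarity="neg")
        assert reg.get_params() == {"alpha": 0.01, "polarity": "neg"}
        reg.set_params(alpha=0.1)
        assert reg.alpha == 0.1

    def test_accepts_3d_stack_and_edge_matrix(self, planted_cohort, rng):
        _, connectomes, behavior, _ = planted_cohort
        stack = np.stack([c.matrix for c in connectomes])
        from strokecpm.connectome import vectorize_edges
        edges = np.stack([vectorize_edges(c.matrix) for c in connectomes])
        r1 = CPMRegressor().fit(stack, behavior.scores).predict(stack)
        r2 = CPMRegressor().fit(edges, behavior.scores).predict(edges)
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_pipeline_from_time_series(self, rng):
        from strokecpm import SyntheticSpec, generate_cohort
        spec = SyntheticSpec(n_subjects=12, n_nodes=6, n_timepoints=120,
                             planted_edges=((0, 1), (2, 3)), seed=5)
        subjects, behavior, _ = generate_cohort(spec)
        pipe = Pipeline([
            ("edges", ConnectivityTransformer()),
            ("cpm", CPMRegressor(alpha=0.5)),
        ])
        pipe.fit(subjects, behavior.scores)
        preds = pipe.predict(subjects)
        assert preds.shape == (12,)
        assert np.isfinite(preds).all()

    def test_unfitted_predict_raises(self):
        with pytest.raises(AttributeError):
            CPMRegressor().predict(np.zeros((3, 10)))
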