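import numpy as np
import pytest
from scipy import stats

from strokecpm import (
    SyntheticSpec,
    edgewise_correlation,
    generate_cohort,
    generate_connectomes_direct,
    select_edges,
)
from strokecpm.synthetic import write_behavior, write_ground_truth


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_nodes=2),
        dict(n_subjects=2),
        dict(n_timepoints=10),
        dict(tr_seconds=0),
        dict(planted_edges=()),
        dict(planted_edges=((1, 1),)),
        dict(planted_edges=((3, 2),)),
        dict(planted_edges=((0, 50),), n_nodes=10),
        dict(planted_edges=((0, 1), (0, 1))),
        dict(noise_sd=-1),
        dict(measure="FIM"),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticSpec(**kwargs)

    def test_polarity_follows_effect_sign(self):
        assert SyntheticSpec(effect_size=1.0).polarity == "pos"
        assert SyntheticSpec(effect_size=-1.0).polarity == "neg"


class TestDirectGenerator:
    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_subjects=10, n_nodes=8, n_planted=2, seed=3)
        c1, b1, t1 = generate_connectomes_direct(spec)
        c2, b2, t2 = generate_connectomes_direct(spec)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(b1.scores, b2.scores)
        np.testing.assert_array_equal(t1.mask, t2.mask)

    def test_noiseless_single_edge_correlates_perfectly(self):
        spec = SyntheticSpec(n_subjects=12, n_nodes=5,
                             planted_edges=((1, 3),), effect_size=1.0,
                             noise_sd=0.0, base_connectivity_sd=0.0,
                             discretize=False, seed=11)
        connectomes, behavior, _ = generate_connectomes_direct(spec)
        st = edgewise_correlation(connectomes, behavior)
        assert st.r[1, 3] == pytest.approx(1.0, abs=1e-12)

    def test_behavior_scale_mrs(self):
        spec = SyntheticSpec(n_subjects=60, n_nodes=6, n_planted=1,
                             measure="mRS", seed=4)
        _, behavior, _ = generate_connectomes_direct(spec)
        assert set(np.unique(behavior.scores)) <= set(range(7))

    def test_behavior_scale_bi(self):
        spec = SyntheticSpec(n_subjects=60, n_nodes=6, n_planted=1,
                             measure="BI", seed=4)
        _, behavior, _ = generate_connectomes_direct(spec)
        assert np.all(behavior.scores % 5 == 0)
        assert behavior.scores.min() >= 0 and behavior.scores.max() <= 100

    def test_stage1_mrs_restricted_to_moderate_disability(self):
        spec = SyntheticSpec(n_subjects=80, n_nodes=6, n_planted=1,
                             measure="mRS", stage=1, seed=4)
        _, behavior, _ = generate_connectomes_direct(spec)
        assert set(np.unique(behavior.scores)) <= {2.0, 3.0, 4.0}

    def test_ground_truth_mask_symmetric_both_triangles(self):
        spec = SyntheticSpec(n_subjects=10, n_nodes=9,
                             planted_edges=((0, 3), (2, 7), (4, 8)), seed=0)
        _, _, truth = generate_connectomes_direct(spec)
        np.testing.assert_array_equal(truth.mask, truth.mask.T)
        assert truth.mask.sum() == 2 * 3
        assert truth.n_edges == 3

    def test_three_subject_background_p_matches_brute_force(self):
        """An N=3 cohort runs end-to-end; background p-values are large."""
        spec = SyntheticSpec(n_subjects=3, n_nodes=6, n_planted=1,
                             effect_size=0.0, seed=21)
        connectomes, behavior, truth = generate_connectomes_direct(spec)
        st = edgewise_correlation(connectomes, behavior)
        iu, ju = np.triu_indices(6, k=1)
        for i, j in zip(iu, ju):
            vals = np.array([c.matrix[i, j] for c in connectomes])
            r, p = stats.pearsonr(vals, behavior.scores)
            assert st.p[i, j] == pytest.approx(p, abs=1e-10)
        background = [st.p[i, j] for i, j in zip(iu, ju)
                      if not truth.mask[i, j]]
        assert np.median(background) > 0.2


class TestCohortGenerator:
    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_subjects=4, n_nodes=6, n_timepoints=60,
                             n_planted=2, seed=8)
        s1, b1, _ = generate_cohort(spec)
        s2, b2, _ = generate_cohort(spec)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.data, b.data)
            np.testing.assert_array_equal(a.nuisance, b.nuisance)
        np.testing.assert_array_equal(b1.scores, b2.scores)

    def test_shapes_and_nuisance_columns(self):
        spec = SyntheticSpec(n_subjects=3, n_nodes=7, n_timepoints=80,
                             n_planted=1, seed=2)
        subjects, behavior, _ = generate_cohort(spec)
        assert len(subjects) == 3 and len(behavior) == 3
        for ts in subjects:
            assert ts.data.shape == (80, 7)
            assert ts.nuisance.shape == (80, 9)
            assert np.isfinite(ts.data).all()

    def test_noiseless_behavior_monotone_in_latent(self):
        """With zero noise the behavior is a monotone function of the latent."""
        spec = SyntheticSpec(n_subjects=15, n_nodes=5, n_timepoints=40,
                             planted_edges=((0, 1), (2, 3)), effect_size=1.0,
                             noise_sd=0.0, discretize=False, seed=13)
        _, behavior, _ = generate_cohort(spec)
        rng = np.random.default_rng(13)
        spec.resolve_edges(rng)
        # regenerate the latent stream: it is drawn right after edge choice
        z = rng.standard_normal(15)
        clipped = (behavior.scores > 0) & (behavior.scores < 6)
        order = np.argsort(z[clipped])
        assert np.all(np.diff(behavior.scores[clipped][order]) >= 0)

    def test_planted_correlation_recovered_from_time_series(self):
        """Pearson connectivity of generated series tracks the planted value."""
        spec = SyntheticSpec(n_subjects=25, n_nodes=6, n_timepoints=400,
                             planted_edges=((1, 4),), effect_size=1.0,
                             noise_sd=0.0, base_connectivity_sd=0.0,
                             connectivity_scale=0.4, seed=17)
        subjects, _, _ = generate_cohort(spec)
        rng = np.random.default_rng(17)
        z = rng.standard_normal(25)
        from strokecpm import compute_connectivity
        observed = np.array([
            compute_connectivity(ts.data).matrix[1, 4] for ts in subjects
        ])
        target = np.clip(0.4 * z, -0.9, 0.9)
        # nuisance and drift contaminate the raw series; the correlation
        # should still be strongly positive across subjects
        assert stats.pearsonr(observed, target).statistic > 0.6


def test_selection_rate_matches_alpha_under_null():
    """With no effect, each background edge is selected at rate ~ alpha."""
    alpha = 0.05
    total = selected = 0
    for rep in range(200):
        spec = SyntheticSpec(n_subjects=15, n_nodes=8, n_planted=1,
                             effect_size=0.0, measure="BI", seed=1000 + rep)
        connectomes, behavior, truth = generate_connectomes_direct(spec)
        st = edgewise_correlation(connectomes, behavior)
        pos = select_edges(st, alpha, "pos")
        neg = select_edges(st, alpha, "neg")
        both = pos.mask | neg.mask
        background = ~truth.mask.astype(bool)
        background &= ~np.eye(8, dtype=bool)
        selected += int((both[background]).sum() / 2)
        total += int(background.sum() / 2)
    rate = selected / total
    # binomial 99.9% band around alpha for the pooled count (edges within a
    # cohort are nearly independent here)
    sd = np.sqrt(alpha * (1 - alpha) / total)
    assert abs(rate - alpha) < 4 * sd + 0.005


def test_background_p_values_uniform_under_null():
    """Pooled background p-values over replicates pass a KS uniformity test."""
    pooled = []
    for rep in range(40):
        spec = SyntheticSpec(n_subjects=20, n_nodes=8, n_planted=1,
                             effect_size=0.0, seed=2000 + rep)
        connectomes, behavior, truth = generate_connectomes_direct(spec)
        st = edgewise_correlation(connectomes, behavior)
        iu, ju = np.triu_indices(8, k=1)
        pooled.extend(st.p[i, j] for i, j in zip(iu, ju)
                      if not truth.mask[i, j])
    ks = stats.kstest(np.asarray(pooled), "uniform")
    assert ks.pvalue > 0.01


def test_writers(tmp_path):
    spec = SyntheticSpec(n_subjects=5, n_nodes=6, planted_edges=((1, 2), (3, 4)),
                         seed=1)
    _, behavior, truth = generate_connectomes_direct(spec)
    write_behavior(behavior, tmp_path / "behavior.csv", group="ST")
    write_ground_truth(truth, tmp_path / "gt.tsv")
    import pandas as pd
    table = pd.read_csv(tmp_path / "behavior.csv")
    assert list(table.columns) == ["subject_id", "group", "stage", "measure", "score"]
    assert len(table) == 5
    edges = np.loadtxt(tmp_path / "gt.tsv", dtype=int, ndmin=2)
    assert [tuple(e) for e in edges] == [(1, 2), (3, 4)]
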