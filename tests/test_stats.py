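import numpy as np
import pandas as pd
import pytest

from actomotility import features as ft
from actomotility import stats as st
from actomotility.features import FEATURES, LengthCurveSet


def _curve_set(seed, n_windows=20, B=150, shift=0.0, scale=1.0,
               condition="c", rho=0.0, sd=0.02):
    """Synthetic curve set: smooth base curves + correlated replicate noise."""
    rng = np.random.default_rng(seed)
    centers = np.linspace(0.6, 3.0, n_windows)
    base = np.column_stack([
        scale * (0.4 + 0.1 * centers) + shift,
        np.clip(0.6 + 0.1 * centers, 0, 1),
        1.0 / (1 + centers),
        0.5 + centers,
    ])
    reps = np.empty((B, n_windows, 4))
    for b in range(B):
        eps = rng.normal(0, sd, 4)
        if rho:
            eps[1] = rho * eps[0] + np.sqrt(1 - rho ** 2) * eps[1]
        reps[b] = base * (1 + eps[None, :])
    cs = LengthCurveSet(
        centers=centers, width=0.59,
        est=pd.DataFrame(base, columns=list(FEATURES)),
        counts=np.full(n_windows, 50), replicates=reps,
        condition=condition, seed=seed)
    cs.ci_low = pd.DataFrame(np.percentile(reps, 2.5, axis=0),
                             columns=list(FEATURES))
    cs.ci_high = pd.DataFrame(np.percentile(reps, 97.5, axis=0),
                              columns=list(FEATURES))
    return cs


class TestAssemble:
    def test_row_layout_and_standardisation(self):
        curves = {"a": _curve_set(1), "b": _curve_set(2)}
        m = st.assemble(curves)
        assert m.X.shape[0] == 2 * (1 + 150)
        assert np.allclose(m.X.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(m.X.std(axis=0), 1, atol=1e-9)
        assert m.row_is_main.sum() == 2

    def test_identical_conditions_have_identical_main_rows(self):
        curves = {"a": _curve_set(5), "b": _curve_set(5)}
        m = st.assemble(curves)
        mains = m.X[m.row_is_main]
        np.testing.assert_allclose(mains[0], mains[1])

    def test_windows_missing_anywhere_dropped_globally(self):
        a, b = _curve_set(1), _curve_set(2)
        a.est.iloc[3, 0] = np.nan
        a.replicates[:, 3, 0] = np.nan
        m = st.assemble({"a": a, "b": b})
        assert ("v_mean", 3) in m.dropped_columns
        assert np.all(np.isfinite(m.X))


class TestPCA:
    def test_collinear_data_put_all_variance_on_pc1(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 1, 200)
        X = np.outer(t, rng.normal(0, 1, 8))
        X += rng.normal(0, 1e-6, X.shape)
        m = st.ConditionMatrix(
            X=X, row_condition=np.array(["a"] * 200),
            row_is_main=np.zeros(200, bool),
            col_feature=np.array(["f"] * 8), col_window=np.arange(8),
            col_mean=np.zeros(8), col_sd=np.ones(8))
        emb = st.pca3(m)
        assert emb.explained_var_ratio[0] > 0.999

    def test_orthogonal_rotation_preserves_explained_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (100, 6)) * np.array([3, 2, 1, .5, .3, .1])
        Q, _ = np.linalg.qr(rng.normal(0, 1, (6, 6)))
        meta = dict(row_condition=np.array(["a"] * 100),
                    row_is_main=np.zeros(100, bool),
                    col_feature=np.array(["f"] * 6),
                    col_window=np.arange(6),
                    col_mean=np.zeros(6), col_sd=np.ones(6))
        e1 = st.pca3(st.ConditionMatrix(X=X, **meta))
        e2 = st.pca3(st.ConditionMatrix(X=X @ Q, **meta))
        np.testing.assert_allclose(e1.explained_var_ratio,
                                   e2.explained_var_ratio, rtol=1e-8)

    def test_rank_deficient_matrix_rejected(self):
        X = np.ones((10, 4))
        m = st.ConditionMatrix(
            X=X, row_condition=np.array(["a"] * 10),
            row_is_main=np.zeros(10, bool),
            col_feature=np.array(["f"] * 4), col_window=np.arange(4),
            col_mean=np.zeros(4), col_sd=np.ones(4))
        with pytest.raises(ValueError):
            st.pca3(m)


class TestSeparation:
    def _embedding(self, offset):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (150, 3))
        b = rng.normal(offset, 1, (150, 3))
        scores = np.vstack([a, b])
        return st.PCEmbedding(
            scores=scores, explained_var_ratio=np.array([.6, .3, .1]),
            loadings=np.eye(3),
            row_condition=np.array(["a"] * 150 + ["b"] * 150),
            row_is_main=np.zeros(300, bool))

    def test_same_distribution_not_significant(self):
        assert not st.separation_test(self._embedding(0.0), "a", "b")

    def test_strong_offset_significant(self):
        assert st.separation_test(self._embedding(10.0), "a", "b")

    def test_condition_vs_itself_never_significant(self):
        assert not st.separation_test(self._embedding(10.0), "a", "a")

    def test_pairwise_matrix_is_symmetric(self):
        sig = st.pairwise_separation(self._embedding(10.0))
        assert sig.loc["a", "b"] == sig.loc["b", "a"] == True  # noqa: E712
        assert not sig.loc["a", "a"]


class TestHCluster:
    def _embedding_from_points(self, pts, conds):
        return st.PCEmbedding(
            scores=pts, explained_var_ratio=np.array([.5, .3, .2]),
            loadings=np.eye(3), row_condition=np.array(conds),
            row_is_main=np.zeros(len(pts), bool))

    def test_four_well_separated_blobs_give_k4_pure_composition(self):
        rng = np.random.default_rng(3)
        blobs, conds = [], []
        for i, mu in enumerate([(0, 0, 0), (20, 0, 0), (0, 20, 0),
                                (0, 0, 20)]):
            blobs.append(rng.normal(mu, 0.5, (60, 3)))
            conds += [f"c{i}"] * 60
        emb = self._embedding_from_points(np.vstack(blobs), conds)
        k, assign, prof, comp = st.hcluster(emb)
        assert k == 4
        assert (comp.max(axis=1) == 60).all()

    def test_identical_points_collapse_to_single_cluster(self):
        pts = np.ones((40, 3))
        emb = self._embedding_from_points(pts, ["a"] * 40)
        k, assign, prof, comp = st.hcluster(emb)
        assert k == 1

    def test_assignment_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, .5, (30, 3)),
                         rng.normal(15, .5, (30, 3))])
        conds = ["a"] * 30 + ["b"] * 30
        emb = self._embedding_from_points(pts, conds)
        k1, a1, _, _ = st.hcluster(emb)
        perm = rng.permutation(60)
        emb2 = self._embedding_from_points(pts[perm],
                                           list(np.array(conds)[perm]))
        k2, a2, _, _ = st.hcluster(emb2)
        assert k1 == k2
        # same partition up to label names
        m1 = a1[np.argsort(np.arange(60))]
        pairs1 = {(a1[i] == a1[j]) for i in range(10) for j in range(50, 60)}
        inv = np.empty(60, int)
        inv[perm] = np.arange(60)
        a2u = a2[inv]
        pairs2 = {(a2u[i] == a2u[j]) for i in range(10)
                  for j in range(50, 60)}
        assert pairs1 == pairs2


class TestFoldChanges:
    def test_identical_conditions_fold_one_not_significant(self):
        a = _curve_set(1)
        b = _curve_set(1)
        r = st.fold_changes(a, b, "v_mean")
        assert r.fold == pytest.approx(1.0)
        assert not r.significant
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_velocity_scale_equivariance(self):
        base = _curve_set(2)
        target = _curve_set(3)
        r1 = st.fold_changes(target, base, "v_mean")
        base_s = _curve_set(2, scale=3.0)
        target_s = _curve_set(3, scale=3.0)
        r2 = st.fold_changes(target_s, base_s, "v_mean")
        assert r1.fold == pytest.approx(r2.fold, rel=1e-9)

    def test_known_velocity_inflation_recovered(self):
        base_rec = ft.synthetic_records(400, seed=10)
        infl = base_rec.copy()
        for col in ("v_trace_um_s", "v_f2f_mean_um_s"):
            infl[col] = infl[col] * 1.12
        cs_b = ft.bootstrap_curves(base_rec, B=200, seed=1)
        cs_t = ft.bootstrap_curves(infl, B=200, seed=2)
        r = st.fold_changes(cs_t, cs_b, "v_mean")
        assert r.fold == pytest.approx(1.12, abs=0.03)
        assert r.ci_low <= 1.12 <= r.ci_high

    def test_window_restriction_honoured(self):
        a, b = _curve_set(4), _curve_set(5)
        sel = a.centers < 1.5
        r = st.fold_changes(a, b, "run_time", window_sel=sel)
        manual = a.est.loc[sel, "run_time"].mean() / \
            b.est.loc[sel, "run_time"].mean()
        assert r.fold == pytest.approx(manual)


class TestJointFoldTest:
    def test_identical_conditions_not_significant(self):
        assert not st.joint_fold_test(_curve_set(1), _curve_set(1),
                                      "v_mean", "f_mot")

    def test_aligned_shift_detected_jointly_but_not_marginally(self):
        # anti-correlated replicate noise makes the diagonal the quiet
        # axis: a diagonal shift too small for either marginal CI is
        # resolved by the joint projection
        base = _curve_set(6, rho=-0.9, sd=0.03)
        target = _curve_set(7, rho=-0.9, sd=0.03, shift=0.02)
        target.est["f_mot"] *= 1.045
        target.replicates[:, :, 1] *= 1.045
        r_v = st.fold_changes(target, base, "v_mean")
        r_f = st.fold_changes(target, base, "f_mot")
        assert not (r_v.significant or r_f.significant)
        assert st.joint_fold_test(target, base, "v_mean", "f_mot")

    def test_noise_inflation_without_shift_not_significant(self):
        base = _curve_set(8, sd=0.02)
        target = _curve_set(8, sd=0.06)
        assert not st.joint_fold_test(target, base, "v_mean", "f_mot")


class TestTypeI:
    def test_single_comparison_reproducible(self,
                                            synthetic_baseline_records):
        a = st.type_i_assessment(synthetic_baseline_records, 1, seed=5,
                                 B=60)
        b = st.type_i_assessment(synthetic_baseline_records, 1, seed=5,
                                 B=60)
        pd.testing.assert_frame_equal(a, b)

    def test_margins_locate_below_zero(self, synthetic_baseline_records):
        m = st.type_i_assessment(synthetic_baseline_records, 20, seed=2,
                                 B=100)
        assert (m.mean() < 0).all()
        assert ((-m.mean() / m.std()) > 1.5).all()


class TestIsotropicNoise:
    def test_isotropic_data_spread_variance_evenly(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (4000, 6))
        m = st.ConditionMatrix(
            X=X, row_condition=np.array(["a"] * 4000),
            row_is_main=np.zeros(4000, bool),
            col_feature=np.array(["f"] * 6), col_window=np.arange(6),
            col_mean=np.zeros(6), col_sd=np.ones(6))
        evr = st.pca3(m).explained_var_ratio
        # six isotropic dimensions: each component explains ~1/6
        assert np.all(np.abs(evr - 1 / 6) < 0.02)
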