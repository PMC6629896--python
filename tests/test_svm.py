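import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from cvcoupling import (
    CascadeModel,
    FeatureTable,
    KernelSpec,
    ParameterError,
    kernel_eval,
    kernel_matrix,
    loocv_report,
    train_svm,
)
from cvcoupling.svm import cascade_loocv, loocv_grid_search


class TestKernels:
    def test_zero_distance_values(self):
        x = np.array([1.0, -2.0, 3.0])
        assert kernel_eval(KernelSpec("gaussian", 1.5), x, x) == pytest.approx(1.0)
        assert kernel_eval(KernelSpec("laplace", 0.7), x, x) == pytest.approx(1.0)
        assert kernel_eval(KernelSpec("laplace_printed", 0.7), x, x) == pytest.approx(1.0)
        assert kernel_eval(KernelSpec("anova", 1.0, 2), x, x) == pytest.approx(3.0)

    def test_gaussian_closed_form(self):
        x, y = np.array([0.0, 0.0]), np.array([2.0, 0.0])
        assert kernel_eval(KernelSpec("gaussian", 1.0), x, y) == pytest.approx(np.exp(-2.0))

    def test_laplace_and_printed_variant_differ(self):
        x, y = np.array([0.0]), np.array([2.0])
        assert kernel_eval(KernelSpec("laplace", 1.0), x, y) == pytest.approx(np.exp(-2.0))
        assert kernel_eval(KernelSpec("laplace_printed", 1.0), x, y) == pytest.approx(np.exp(-2.0))
        x, y = np.array([0.0]), np.array([3.0])
        assert kernel_eval(KernelSpec("laplace", 1.0), x, y) == pytest.approx(np.exp(-3.0))
        assert kernel_eval(KernelSpec("laplace_printed", 1.0), x, y) == pytest.approx(np.exp(-4.5))

    def test_anova_1d_degree1_matches_gaussian_scale(self):
        sigma = 0.8
        x, y = np.array([1.2]), np.array([-0.3])
        anova = kernel_eval(KernelSpec("anova", sigma, 1), x, y)
        assert anova == pytest.approx(np.exp(-sigma * (1.2 + 0.3) ** 2))

    def test_dimension_mismatch(self):
        with pytest.raises(ParameterError):
            kernel_eval(KernelSpec("gaussian", 1.0), np.zeros(2), np.zeros(3))

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            KernelSpec("gaussian", -1.0)
        with pytest.raises(ParameterError):
            KernelSpec("rbf", 1.0)


def blobs(rng, n=12, sep=6.0):
    x = np.vstack([rng.standard_normal((n, 2)), rng.standard_normal((n, 2)) + sep])
    y = np.array(["neg"] * n + ["pos"] * n)
    return x, y


class TestTrainSvm:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        x, y = blobs(rng)
        model = train_svm(x, y, C=100.0, kernel=KernelSpec("gaussian", 1.0),
                          positive_label="pos")
        assert (model.predict(x) == y).all()

    def test_alpha_within_box_and_hits_bound_on_contradiction(self, rng):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array(["pos", "neg", "pos", "neg"])  # identical points, opposite labels
        C = 2.5
        model = train_svm(x, y, C=C, kernel=KernelSpec("gaussian", 1.0),
                          positive_label="pos")
        alpha = model.alpha
        assert np.all(alpha <= C + 1e-8)
        assert np.any(np.isclose(alpha, C, atol=1e-6))

    def test_matches_brute_force_qp(self, rng):
        """Dual solution agrees with a direct QP solve on a small instance."""
        x, y = blobs(rng, n=8, sep=2.5)
        spec = KernelSpec("laplace", 1.0)
        C = 2.0
        model = train_svm(x, y, C=C, kernel=spec, positive_label="pos")

        xs = (x - x.mean(axis=0)) / x.std(axis=0)
        k = kernel_matrix(spec, xs, xs)
        ybin = np.where(y == "pos", 1.0, -1.0)
        q = k * np.outer(ybin, ybin)

        def neg_dual(a):
            return -(a.sum() - 0.5 * a @ q @ a)

        n = len(ybin)
        res = minimize(neg_dual, np.full(n, C / 2), method="SLSQP",
                       bounds=[(0, C)] * n,
                       constraints={"type": "eq", "fun": lambda a: a @ ybin},
                       options={"maxiter": 500, "ftol": 1e-12})
        assert res.success
        oracle_obj = -res.fun
        a_impl = np.zeros(n)
        # reconstruct full alpha vector from support vectors
        sv_rows = model.support_vectors
        for coef, sv in zip(model.dual_coef, sv_rows):
            idx = np.argmin(np.abs(xs - sv).sum(axis=1))
            a_impl[idx] = abs(coef)
        impl_obj = a_impl.sum() - 0.5 * a_impl @ q @ a_impl
        assert impl_obj == pytest.approx(oracle_obj, abs=1e-4 * max(1.0, abs(oracle_obj)))

    def test_deterministic(self, rng):
        x, y = blobs(rng)
        m1 = train_svm(x, y, C=1.0, kernel=KernelSpec("gaussian", 1.0), positive_label="pos")
        m2 = train_svm(x, y, C=1.0, kernel=KernelSpec("gaussian", 1.0), positive_label="pos")
        np.testing.assert_array_equal(m1.dual_coef, m2.dual_coef)
        assert m1.intercept == m2.intercept

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((6, 2))
        with pytest.raises(ParameterError):
            train_svm(x, np.array(["a"] * 6), C=1.0,
                      kernel=KernelSpec("gaussian", 1.0), positive_label="a")

    def test_json_round_trip(self, rng, tmp_path):
        x, y = blobs(rng)
        model = train_svm(x, y, C=3.0, kernel=KernelSpec("anova", 0.5, 2),
                          positive_label="pos", feature_names=["f1", "f2"])
        path = tmp_path / "model.json"
        model.to_json(path)
        from cvcoupling.svm import SvmModel
        back = SvmModel.from_json(path)
        probe = rng.standard_normal((5, 2))
        np.testing.assert_allclose(back.decision_function(probe),
                                   model.decision_function(probe))


class TestLoocv:
    def test_shuffled_labels_near_chance(self, rng):
        x = rng.standard_normal((30, 2))
        y = np.array(["pos", "neg"] * 15)
        rep = loocv_report(x, y, C=1.0, kernel=KernelSpec("gaussian", 1.0),
                           positive_label="pos")
        assert 35.0 <= rep.acc <= 65.0

    def test_perfect_ordering_auc_one(self, rng):
        x, y = blobs(rng, n=10, sep=8.0)
        rep = loocv_report(x, y, C=10.0, kernel=KernelSpec("gaussian", 3.0),
                           positive_label="pos")
        assert rep.auc == pytest.approx(1.0)
        assert rep.acc == pytest.approx(100.0)
        assert rep.sn == pytest.approx(100.0)
        assert rep.sp == pytest.approx(100.0)

    def test_grid_search_returns_best_and_report(self, rng):
        x, y = blobs(rng, n=10, sep=5.0)
        df = pd.DataFrame(x, columns=["u", "v"])
        df["noise"] = rng.standard_normal(len(df))
        table = FeatureTable(values=df, labels=pd.Series(y, index=df.index))
        res = loocv_grid_search(table, "neg", "pos", positive_label="pos",
                                candidate_pairs=[("u", "v"), ("u", "noise")],
                                kernels=[KernelSpec("gaussian", 1.0)],
                                C_grid=[1.0])
        assert res.features == ("u", "v")
        assert res.report.acc >= 95.0

    def test_empty_grid_rejected(self, rng):
        x, y = blobs(rng)
        df = pd.DataFrame(x, columns=["u", "v"])
        table = FeatureTable(values=df, labels=pd.Series(y, index=df.index))
        with pytest.raises(ParameterError):
            loocv_grid_search(table, "neg", "pos", positive_label="pos",
                              candidate_pairs=[], kernels=[], C_grid=[])


class TestCascade:
    def _models(self, rng):
        x1 = np.vstack([rng.standard_normal((8, 2)), rng.standard_normal((8, 2)) + 6])
        y1 = np.array(["CON"] * 8 + ["IDC"] * 8)
        stage1 = train_svm(x1, y1, C=5.0, kernel=KernelSpec("gaussian", 1.0),
                           positive_label="IDC", feature_names=["a", "b"])
        x2 = np.vstack([rng.standard_normal((8, 2)), rng.standard_normal((8, 2)) + 6])
        y2 = np.array(["IDC_LR"] * 8 + ["IDC_HR"] * 8)
        stage2 = train_svm(x2, y2, C=5.0, kernel=KernelSpec("gaussian", 1.0),
                           positive_label="IDC_HR", feature_names=["c", "d"])
        return CascadeModel(stage1=stage1, stage2=stage2)

    def test_con_verdict_short_circuits_stage2(self, rng):
        cascade = self._models(rng)
        # stage-2 features deliberately absent: stage 2 must never be scored
        label = cascade.predict_one({"a": -0.1, "b": 0.1})
        assert label == "CON"

    def test_idc_routes_to_stage2(self, rng):
        cascade = self._models(rng)
        label = cascade.predict_one({"a": 6.0, "b": 6.0, "c": 6.0, "d": 6.0})
        assert label == "IDC_HR"

    def test_missing_feature_named(self, rng):
        cascade = self._models(rng)
        with pytest.raises(ParameterError, match="'b'"):
            cascade.predict_one({"a": 0.0})

    def test_cascade_loocv_on_separated_groups(self, rng):
        n = 8
        rows = []
        labels = []
        for grp, centre in (("CON", 0.0), ("IDC_LR", 6.0), ("IDC_HR", 12.0)):
            for _ in range(n):
                rows.append(centre + rng.standard_normal(2))
                labels.append(grp)
        df = pd.DataFrame(rows, columns=["u", "v"])
        table = FeatureTable(values=df, labels=pd.Series(labels, index=df.index))
        acc, per_class = cascade_loocv(table, ("u", "v"), ("u", "v"),
                                       KernelSpec("gaussian", 1.0),
                                       KernelSpec("gaussian", 1.0),
                                       stage1_C=5.0, stage2_C=5.0)
        assert acc >= 90.0
        assert set(per_class) == {"CON", "IDC_LR", "IDC_HR"}
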