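"""Trust-region optimizer with manifold handling."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from foldclust import (
    ParameterVector,
    PenaltySpec,
    check_optimality,
    optimize_regularized,
    pair_terms,
    relabel_reference,
    replicate_model,
)
from foldclust.optimize import (
    OptimizerOptions,
    merge_sensitivities,
    release_pair,
    truncate_step,
)
from foldclust.penalty import PairTerm
from foldclust.simulate import data_residuals


def vec(m, **kw):
    d = {"p": -1.5, "r_p__2": 0.0, "r_p__3": 0.0}
    d.update(kw)
    return ParameterVector.from_dict(m, d)


class TestTruncateStep:
    @pytest.fixture()
    def terms3(self, decay3):
        return pair_terms(decay3, PenaltySpec())

    def test_fold_change_crossing_scales_whole_step(self, decay3, terms3):
        v = vec(decay3, r_p__2=0.2, r_p__3=0.5)
        step = np.array([0.0, -0.5, 0.1])
        t, trunc = truncate_step(v, step, terms3)
        assert t == pytest.approx(0.4)  # 0.2 / 0.5
        assert v.values[1] + trunc[1] == pytest.approx(0.0, abs=1e-15)
        # whole-vector scaling, not per-coordinate clipping
        assert trunc[2] == pytest.approx(0.4 * 0.1)

    def test_no_crossing_keeps_step(self, decay3, terms3):
        v = vec(decay3, r_p__2=0.2, r_p__3=0.5)
        step = np.array([0.3, 0.1, 0.1])
        t, trunc = truncate_step(v, step, terms3)
        assert t == 1.0
        np.testing.assert_array_equal(trunc, step)

    def test_difference_crossing_at_endpoint(self, decay3, terms3):
        # r = (0.3, 0.1), step (-0.1, +0.1): delta = 0.2 reaches 0 at t = 1
        v = vec(decay3, r_p__2=0.3, r_p__3=0.1)
        step = np.array([0.0, -0.1, 0.1])
        t, trunc = truncate_step(v, step, terms3)
        assert t == pytest.approx(1.0)
        d_after = (v.values[1] + trunc[1]) - (v.values[2] + trunc[2])
        assert d_after == pytest.approx(0.0, abs=1e-15)

    def test_active_pairs_do_not_truncate(self, decay3, terms3):
        v = vec(decay3, r_p__2=0.0, r_p__3=0.0)
        step = np.array([0.0, 0.2, -0.1])
        t, _ = truncate_step(v, step, terms3)
        assert t == 1.0


class TestMergeSensitivities:
    def test_mean_of_two_columns(self):
        jac = np.array([[1.0, 0.0, 3.0], [-1.0, 2.0, 5.0]])
        out = merge_sensitivities(jac, [((0, 2), False)], "mean")
        np.testing.assert_allclose(out[:, 0], [2.0, 2.0])
        np.testing.assert_allclose(out[:, 2], [2.0, 2.0])
        np.testing.assert_allclose(out[:, 1], jac[:, 1])

    def test_cluster_of_three_order_invariant(self):
        rng = np.random.default_rng(0)
        jac = rng.normal(size=(4, 3))
        out1 = merge_sensitivities(jac, [((0, 1, 2), False)], "mean")
        out2 = merge_sensitivities(jac, [((2, 0, 1), False)], "mean")
        np.testing.assert_allclose(out1, out2)
        np.testing.assert_allclose(out1[:, 0], jac.mean(axis=1))

    def test_max_rule_keeps_largest_magnitude(self):
        jac = np.array([[1.0, -3.0], [2.0, 1.0]])
        out = merge_sensitivities(jac, [((0, 1), False)], "max")
        np.testing.assert_allclose(out[:, 0], [-3.0, 2.0])

    def test_reference_cluster_is_pinned(self):
        jac = np.array([[1.0, 2.0]])
        out = merge_sensitivities(jac, [((0, 1), True)], "mean")
        np.testing.assert_allclose(out, [[0.0, 0.0]])

    def test_release_zeroes_only_the_pair_row(self):
        jac = np.ones((3, 4))
        term = PairTerm("p", 2, 3, 1, 3)
        out = release_pair(jac, 2, term)
        assert out[2, 1] == 0.0 and out[2, 3] == 0.0
        assert out[:2].sum() == 8.0  # other rows untouched


class TestOptimality:
    def test_unregularized_optimum_converged(self, decay3, toy_data):
        fit = optimize_regularized(
            decay3, toy_data, PenaltySpec(lam=0.0), vec(decay3)
        )
        conv, report = check_optimality(
            decay3, fit.params, toy_data, PenaltySpec(lam=0.0),
            OptimizerOptions(gtol=1e-3),
        )
        assert conv and report["criterion_3"]

    def test_dominated_pair_reported(self, decay3, toy_data):
        # strong regularization at the origin: data slope clearly dominated
        spec = PenaltySpec(q=0.8, lam=1e6)
        v = vec(decay3, r_p__2=0.0, r_p__3=0.0)
        conv, report = check_optimality(decay3, v, toy_data, spec)
        assert report["criterion_3"]
        assert all(report["manifold"].dominated.values())

    def test_weak_regularization_releases_pair(self, decay3, toy_data):
        # at the origin with tiny lambda and q = 1 the data slope wins
        spec = PenaltySpec(q=1.0, lam=1e-6)
        v = vec(decay3, r_p__2=0.0, r_p__3=0.0)
        conv, report = check_optimality(decay3, v, toy_data, spec)
        assert not conv
        assert not all(report["manifold"].dominated.values())


class TestOptimize:
    def test_plain_least_squares_matches_independent_optimizer(
        self, decay3, toy_data
    ):
        """lambda = 0 coincides with a stock least-squares solve."""
        fit = optimize_regularized(decay3, toy_data, PenaltySpec(lam=0.0), vec(decay3))

        def resid(theta):
            v = ParameterVector(decay3.parameter_names, theta)
            return data_residuals(decay3, v, toy_data).values

        ref = least_squares(resid, np.array([-1.0, 0.0, 0.0]), method="lm")
        assert fit.chi2 == pytest.approx(2 * ref.cost, rel=1e-6)
        np.testing.assert_allclose(fit.params.values, ref.x, atol=1e-4)

    def test_huge_lambda_collapses_all_fold_changes(self, decay3, toy_data):
        spec = PenaltySpec(q=0.8, lam=1e6)
        fit = optimize_regularized(
            decay3, toy_data, spec, vec(decay3, r_p__2=0.3, r_p__3=-0.2)
        )
        assert abs(fit.params["r_p__2"]) < spec.epsilon
        assert abs(fit.params["r_p__3"]) < spec.epsilon

    def test_objective_monotone_over_accepted_steps(self, decay3, toy_data):
        rng = np.random.default_rng(5)
        for _ in range(10):
            start = vec(
                decay3,
                p=-1.5 + rng.uniform(-0.7, 0.7),
                r_p__2=rng.uniform(-0.5, 0.5),
                r_p__3=rng.uniform(-0.5, 0.5),
            )
            fit = optimize_regularized(
                decay3, toy_data, PenaltySpec(q=0.8, lam=10.0), start
            )
            obj = [row["objective"] for row in fit.log if row["accepted"]]
            diffs = np.diff(obj)
            assert np.all(diffs <= 1e-7 * (1 + np.abs(obj[:-1])))

    def test_objective_decomposition_consistent(self, decay3, toy_data):
        fit = optimize_regularized(
            decay3, toy_data, PenaltySpec(q=0.8, lam=20.0), vec(decay3)
        )
        assert fit.objective == pytest.approx(
            fit.chi2 + fit.lam * fit.penalty, rel=1e-9
        )

    def test_reference_invariance_of_final_objective(self, decay3, toy_data):
        spec = PenaltySpec(q=0.8, lam=30.0)
        base = optimize_regularized(decay3, toy_data, spec, vec(decay3))
        for ref in (2, 3):
            m2, v2 = relabel_reference(decay3, ref, vec(decay3))
            fit2 = optimize_regularized(m2, toy_data, spec, v2)
            assert fit2.objective == pytest.approx(base.objective, rel=1e-6)

    def test_zero_merge_rule_cannot_leave_nonzero_cluster(self, decay3, toy_data):
        """Ablation: zeroing the columns of a dominated pair freezes the
        cluster at its current (nonzero) value, so the origin is never
        reached; the mean rule moves the cluster jointly to zero."""
        start = vec(decay3, p=-1.5, r_p__2=0.25, r_p__3=0.25)
        spec = PenaltySpec(q=0.8, lam=1e5)
        frozen = optimize_regularized(
            decay3, toy_data, spec, start,
            OptimizerOptions(merge_rule="zero"), fixed=("p",),
        )
        assert frozen.params["r_p__2"] == pytest.approx(0.25)
        assert frozen.params["r_p__3"] == pytest.approx(0.25)
        moving = optimize_regularized(
            decay3, toy_data, spec, start,
            OptimizerOptions(merge_rule="mean"), fixed=("p",),
        )
        assert abs(moving.params["r_p__2"]) < spec.epsilon
        assert abs(moving.params["r_p__3"]) < spec.epsilon

    def test_soft_threshold_for_q1(self, decay_model, toy_data):
        """For q = 1 and a single penalized fold change, the optimum sits at
        r = 0 exactly when lambda exceeds the data slope |d chi2/dr| at 0
        (the soft-threshold condition)."""
        m = replicate_model(decay_model, 2, {"p"})
        data = toy_data[toy_data.cell_type <= 2]
        v0 = ParameterVector.from_dict(m, {"p": -1.5, "r_p__2": 0.0})
        block = data_residuals(m, v0, data)
        slope = abs(2.0 * block.jac[:, 1] @ block.values)
        for lam, expect_zero in ((0.7 * slope, False), (1.5 * slope, True)):
            fit = optimize_regularized(
                m, data, PenaltySpec(q=1.0, lam=lam), v0, fixed=("p",)
            )
            if expect_zero:
                assert abs(fit.params["r_p__2"]) < 1e-10
            else:
                assert abs(fit.params["r_p__2"]) > 1e-4

    def test_deterministic_rerun(self, decay3, toy_data):
        spec = PenaltySpec(q=0.8, lam=25.0)
        f1 = optimize_regularized(decay3, toy_data, spec, vec(decay3))
        f2 = optimize_regularized(decay3, toy_data, spec, vec(decay3))
        np.testing.assert_array_equal(f1.params.values, f2.params.values)
        assert f1.n_iter == f2.n_iter
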