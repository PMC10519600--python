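"""Penalty value, residual representation, and gradient."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldclust import (
    ParameterVector,
    PenaltySpec,
    pair_terms,
    penalty_gradient,
    penalty_residuals,
    penalty_value,
    relabel_reference,
    replicate_model,
)


def vec(m, **kw):
    d = {"p": 0.0}
    d.update(kw)
    return ParameterVector.from_dict(m, d)


@pytest.fixture(scope="module")
def m3(decay_model):
    return replicate_model(decay_model, 3, {"p"})


class TestPairTerms:
    def test_clustered_counts_all_pairs(self, m3):
        terms = pair_terms(m3, PenaltySpec(mode="clustered"))
        assert len(terms) == 3  # n(n-1)/2 with n = 3
        assert {(t.j, t.k) for t in terms} == {(1, 2), (1, 3), (2, 3)}

    def test_standard_counts_reference_pairs_only(self, m3):
        terms = pair_terms(m3, PenaltySpec(mode="standard"))
        assert {(t.j, t.k) for t in terms} == {(1, 2), (1, 3)}


class TestValue:
    def test_worked_example_reference_1(self, m3):
        """log p = (0.5, 0.75, 1.0): standard terms are |0.25|^q and |0.5|^q."""
        v = vec(m3, r_p__2=0.25, r_p__3=0.5)
        for q in (0.8, 1.0):
            nu, br = penalty_value(m3, v, PenaltySpec(q=q, mode="standard"))
            mags = sorted(abs(d) for _, d, _ in br)
            assert mags == pytest.approx([0.25, 0.5])
            assert nu == pytest.approx(0.25 ** q + 0.5 ** q)

    def test_worked_example_reference_2(self, m3):
        """Same point re-referenced to cell type 2: two terms of 0.25 each,
        so the standard penalty depends on the reference choice."""
        v = vec(m3, r_p__2=0.25, r_p__3=0.5)
        m2, v2 = relabel_reference(m3, 2, v)
        for q in (0.8, 1.0):
            nu, br = penalty_value(m2, v2, PenaltySpec(q=q, mode="standard"))
            mags = sorted(abs(d) for _, d, _ in br)
            assert mags == pytest.approx([0.25, 0.25])
            assert nu == pytest.approx(2 * 0.25 ** q)

    def test_all_zero_minimizes_both_modes(self, m3):
        v = vec(m3, r_p__2=0.0, r_p__3=0.0)
        for mode in ("clustered", "standard"):
            nu, _ = penalty_value(m3, v, PenaltySpec(mode=mode))
            assert nu == 0.0

    def test_clustered_l1_value_brute_force(self, m3):
        # pairwise absolute differences of (0, 0.25, 0.5): 0.25 + 0.5 + 0.25
        v = vec(m3, r_p__2=0.25, r_p__3=0.5)
        nu, _ = penalty_value(m3, v, PenaltySpec(q=1.0, mode="clustered"))
        assert nu == pytest.approx(1.0)

    @given(
        r2=st.floats(-2, 2, allow_nan=False),
        r3=st.floats(-2, 2, allow_nan=False),
        ref=st.integers(1, 3),
        q=st.sampled_from([0.8, 1.0]),
    )
    @settings(max_examples=50, deadline=None)
    def test_clustered_value_reference_invariant(self, decay_model, r2, r3, ref, q):
        m = replicate_model(decay_model, 3, {"p"})
        v = vec(m, r_p__2=r2, r_p__3=r3)
        nu, _ = penalty_value(m, v, PenaltySpec(q=q, mode="clustered"))
        m2, v2 = relabel_reference(m, ref, v)
        nu2, _ = penalty_value(m2, v2, PenaltySpec(q=q, mode="clustered"))
        assert nu2 == pytest.approx(nu, abs=1e-12, rel=1e-12)

    def test_zero_iff_all_on_manifold(self, m3):
        spec = PenaltySpec()
        v = vec(m3, r_p__2=4e-11, r_p__3=-4e-11)
        assert penalty_value(m3, v, spec)[0] == 0.0
        v = vec(m3, r_p__2=1e-9, r_p__3=0.0)
        assert penalty_value(m3, v, spec)[0] > 0.0

    def test_monotone_in_each_difference(self, m3):
        spec = PenaltySpec(q=0.8)
        base = penalty_value(m3, vec(m3, r_p__2=0.1, r_p__3=0.5), spec)[0]
        bigger = penalty_value(m3, vec(m3, r_p__2=0.1, r_p__3=0.7), spec)[0]
        assert bigger > base


class TestResiduals:
    def test_lambda_zero_is_empty_block(self, m3):
        v = vec(m3, r_p__2=0.3, r_p__3=-0.1)
        block = penalty_residuals(m3, v, PenaltySpec(lam=0.0))
        assert block.values.shape == (0,)

    def test_q1_substitution_example(self, decay_model):
        # q = 1, lambda = 4, |delta| = 0.25: rho = 2 * 0.5 = 1, rho^2 = lambda*|delta|
        m = replicate_model(decay_model, 2, {"p"})
        v = ParameterVector.from_dict(m, {"p": 0.0, "r_p__2": 0.25})
        block = penalty_residuals(m, v, PenaltySpec(q=1.0, lam=4.0))
        assert block.values[0] == pytest.approx(1.0)

    def test_squared_residuals_reproduce_lambda_nu(self, m3):
        """Sum rho_m^2 = lambda * nu exactly, off-manifold, for random draws."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            q = rng.choice([0.8, 1.0])
            lam = float(rng.uniform(0.1, 100))
            v = vec(m3, r_p__2=float(rng.uniform(-2, 2)), r_p__3=float(rng.uniform(-2, 2)))
            spec = PenaltySpec(q=q, lam=lam)
            nu, _ = penalty_value(m3, v, spec)
            block = penalty_residuals(m3, v, spec)
            assert float(block.values @ block.values) == pytest.approx(lam * nu, rel=1e-12)

    def test_jacobian_rows_antisymmetric(self, m3):
        v = vec(m3, r_p__2=0.3, r_p__3=0.1)
        block = penalty_residuals(m3, v, PenaltySpec(q=0.8, lam=2.0))
        for row, (param, j, k) in zip(block.jac, block.labels):
            nz = row[np.nonzero(row)]
            if len(nz) == 2:  # non-reference pair
                assert nz[0] == pytest.approx(-nz[1])


class TestGradient:
    def test_middle_coordinate_balances_for_q1(self, m3):
        # 0 < a < b with q = 1: the two terms incident to r2 cancel
        v = vec(m3, r_p__2=0.2, r_p__3=0.7)
        g = penalty_gradient(m3, v, PenaltySpec(q=1.0))
        assert g[1] == pytest.approx(0.0, abs=1e-12)  # r_p__2
        assert g[2] == pytest.approx(2.0)  # r_p__3: +1 vs ref, +1 vs r2

    def test_matches_finite_differences(self, m3):
        rng = np.random.default_rng(11)
        for q in (0.8, 1.0):
            spec = PenaltySpec(q=q)
            for _ in range(20):
                r2, r3 = rng.uniform(-1, 1, 2)
                if min(abs(r2), abs(r3), abs(r2 - r3)) < 1e-3:
                    continue
                v = vec(m3, r_p__2=r2, r_p__3=r3)
                g = penalty_gradient(m3, v, spec)
                h = 1e-7
                for i, name in enumerate(("r_p__2", "r_p__3")):
                    up = vec(m3, r_p__2=r2 + (h if i == 0 else 0), r_p__3=r3 + (h if i == 1 else 0))
                    dn = vec(m3, r_p__2=r2 - (h if i == 0 else 0), r_p__3=r3 - (h if i == 1 else 0))
                    fd = (penalty_value(m3, up, spec)[0] - penalty_value(m3, dn, spec)[0]) / (2 * h)
                    assert g[i + 1] == pytest.approx(fd, rel=1e-5, abs=1e-5)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw", [{"q": 0.0}, {"q": 1.5}, {"lam": -1.0}, {"epsilon": 0.0}, {"mode": "x"}]
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            PenaltySpec(**kw)
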