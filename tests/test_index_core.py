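"""Unit and property tests for the selection-index algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selindex.index_core import (
    ConditioningError,
    CovarianceEstimate,
    IndexWeights,
    dg_coefficients,
    esim_coefficients,
    index_parameters,
    index_values,
    selection_intensity,
    smith_coefficients,
    truncate_select,
)

from conftest import random_cov_pair, random_spd


class TestSelectionIntensity:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.10, 1.755),  # standard 10% truncation value
            (1.0, 0.0),  # selecting everyone gives no superiority
            (0.50, 2 * 0.3989422804),  # closed form 2*phi(0)
        ],
    )
    def test_known_values(self, p, expected):
        assert selection_intensity(p) == pytest.approx(expected, abs=5e-4)

    @given(st.floats(min_value=0.01, max_value=0.98))
    @settings(deadline=None, max_examples=30)
    def test_strictly_decreasing(self, p):
        assert selection_intensity(p) > selection_intensity(p + 0.01)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            selection_intensity(p)


class TestSmith:
    def test_worked_example(self, cov2020):
        b = smith_coefficients(cov2020, np.array([-1.0, 1.0]))
        assert b == pytest.approx([-0.42, 0.40], abs=0.02)

    def test_identity_heritability(self, rng):
        P = random_spd(rng, 3)
        cov = CovarianceEstimate(traits=["a", "b", "c"], P=P, C=P)
        w = rng.normal(size=3)
        assert smith_coefficients(cov, w) == pytest.approx(w)

    def test_defining_identity(self, rng):
        # P b = C w, and sigma_IH = sigma_I^2 at the optimum
        for _ in range(10):
            cov = random_cov_pair(rng, 4)
            w = rng.normal(size=4)
            b = smith_coefficients(cov, w)
            assert cov.P @ b == pytest.approx(cov.C @ w, rel=1e-9)
            assert b @ cov.P @ b == pytest.approx(w @ cov.C @ b, rel=1e-10)

    def test_optimality_random_search(self, rng):
        # no random direction beats the closed form's correlation with H
        cov = random_cov_pair(rng, 4)
        w = rng.normal(size=4)
        b_opt = smith_coefficients(cov, w)
        var_H = w @ cov.C @ w
        rho_opt = (w @ cov.C @ b_opt) / np.sqrt(var_H * (b_opt @ cov.P @ b_opt))
        B = rng.normal(size=(100_000, 4))
        num = B @ (cov.C @ w)
        den = np.sqrt(var_H * np.einsum("ij,jk,ik->i", B, cov.P, B))
        assert (num / den).max() <= rho_opt + 1e-6

    def test_conditioning_error(self):
        P = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-14]])
        cov = CovarianceEstimate.__new__(CovarianceEstimate)
        cov.traits = ["a", "b"]
        cov.P = P
        cov.C = np.eye(2)
        with pytest.raises(ConditioningError):
            smith_coefficients(cov, np.ones(2))

    def test_scale_equivariance(self, cov2020):
        # scaling w leaves rho unchanged and scales b (hence R) linearly
        w = np.array([-1.0, 1.0])
        k = selection_intensity(0.10)
        r1 = index_parameters(
            cov2020, IndexWeights("SIM", cov2020.traits, w=w),
            smith_coefficients(cov2020, w), k,
        )
        r2 = index_parameters(
            cov2020, IndexWeights("SIM", cov2020.traits, w=3.0 * w),
            smith_coefficients(cov2020, 3.0 * w), k,
        )
        assert r2.correlation == pytest.approx(r1.correlation, rel=1e-12)
        assert r2.response == pytest.approx(3.0 * r1.response, rel=1e-12)
        assert r2.expected_gain == pytest.approx(r1.expected_gain, rel=1e-12)


class TestESIM:
    def test_worked_example(self, cov2020):
        beta, lam, w_E = esim_coefficients(cov2020, np.ones(2))
        assert beta == pytest.approx([0.07, 1.0], abs=0.02)
        assert lam == pytest.approx(0.5105, abs=1e-3)

    def test_diagonal_case(self):
        cov = CovarianceEstimate(["a", "b"], P=np.eye(2), C=np.diag([0.9, 0.1]))
        beta, lam, _ = esim_coefficients(cov, np.ones(2))
        assert lam == pytest.approx(0.9)
        assert beta == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_eigen_residual_and_F_invariance(self, rng):
        for _ in range(10):
            cov = random_cov_pair(rng, 4)
            F = rng.choice([-2.0, -1.0, 1.0, 3.0], size=4)
            beta, lam, _ = esim_coefficients(cov, F)
            _, lam_id, b_E = esim_coefficients(cov, np.ones(4))
            # eigenvalue invariant to the transforming matrix
            assert lam == pytest.approx(lam_id, rel=1e-10)
            # beta is F times the (sign-fixed) eigenvector
            bE = beta / F
            resid = np.linalg.solve(cov.P, cov.C @ bE) - lam * bE
            assert np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(bE)

    def test_canonical_correlation_oracle(self, rng):
        # lambda^2 is the max of (w'Cb)^2 / (w'Cw b'Pb) over directions
        cov = random_cov_pair(rng, 3)
        _, lam, _ = esim_coefficients(cov, np.ones(3))
        B = rng.normal(size=(100_000, 3))
        W = rng.normal(size=(100_000, 3))
        num = np.einsum("ij,jk,ik->i", W, cov.C, B) ** 2
        den = np.einsum("ij,jk,ik->i", W, cov.C, W) * np.einsum(
            "ij,jk,ik->i", B, cov.P, B
        )
        assert (num / den).max() <= lam + 1e-4
        # and the (b_E, w_E) pair attains it
        bE, _, w_E = esim_coefficients(cov, np.ones(3))
        attained = (w_E @ cov.C @ bE) ** 2 / (
            (w_E @ cov.C @ w_E) * (bE @ cov.P @ bE)
        )
        assert attained == pytest.approx(lam, rel=1e-8)

    def test_zero_F_rejected(self, cov2020):
        with pytest.raises(ValueError):
            esim_coefficients(cov2020, np.array([0.0, 1.0]))


class TestDG:
    def test_identity(self):
        cov = CovarianceEstimate(["a", "b"], P=np.eye(2), C=np.eye(2))
        assert dg_coefficients(cov, np.array([-1.0, 1.0])) == pytest.approx([-1, 1])

    def test_worked_example(self, cov2020):
        d = np.array([-1.0, 1.0])
        b = dg_coefficients(cov2020, d)
        assert b == pytest.approx([-0.699, 3.380], abs=2e-3)
        assert cov2020.C @ b == pytest.approx(d, abs=1e-10)

    def test_constraint_and_minimum_variance(self, rng, cov2020):
        d = np.array([-1.0, 1.0])
        b = dg_coefficients(cov2020, d)
        base = b @ cov2020.P @ b
        # project random perturbations back onto {C b = d} via least squares
        for _ in range(1000):
            pert = b + rng.normal(size=2)
            corr = np.linalg.lstsq(cov2020.C, cov2020.C @ pert - d, rcond=None)[0]
            feas = pert - corr
            assert np.allclose(cov2020.C @ feas, d, atol=1e-8)
            assert feas @ cov2020.P @ feas >= base - 1e-9


class TestIndexParameters:
    def test_sim_worked_example(self, cov2020):
        w = np.array([-1.0, 1.0])
        b = smith_coefficients(cov2020, w)
        res = index_parameters(
            cov2020, IndexWeights("SIM", cov2020.traits, w=w), b, 1.755
        )
        assert res.response == pytest.approx(1.87, abs=0.02)
        assert res.correlation == pytest.approx(0.65, abs=0.02)
        assert res.expected_gain == pytest.approx([-1.85, 0.02], abs=0.02)

    def test_dg_worked_example(self, cov2020):
        d = np.array([-1.0, 1.0])
        b = dg_coefficients(cov2020, d)
        res = index_parameters(
            cov2020, IndexWeights("DG", cov2020.traits, d=d), b, 1.755
        )
        assert res.expected_gain == pytest.approx([-0.60, 0.60], abs=0.02)
        assert res.correlation is None

    def test_zero_intensity(self, cov2020):
        w = np.array([-1.0, 1.0])
        b = smith_coefficients(cov2020, w)
        res = index_parameters(
            cov2020, IndexWeights("SIM", cov2020.traits, w=w), b, 0.0
        )
        assert res.response == 0.0
        assert res.expected_gain == pytest.approx([0.0, 0.0])

    def test_json_round_trip(self, cov2020):
        import json

        w = np.array([-1.0, 1.0])
        b = smith_coefficients(cov2020, w)
        res = index_parameters(
            cov2020, IndexWeights("SIM", cov2020.traits, w=w), b, 1.755
        )
        rec = json.loads(res.to_json())
        assert rec["method"] == "SIM"
        assert rec["R"] == pytest.approx(res.response)


class TestIndexValues:
    def test_centered_input(self):
        b = np.array([-0.42, 0.40])
        mu = np.array([10.0, 5.0])
        assert index_values(b, mu[None, :], mu)[0] == 0.0

    def test_univariate_identity(self):
        I = index_values(np.array([1.0]), np.array([[2.0], [4.0], [6.0]]))
        assert I == pytest.approx([-2.0, 0.0, 2.0])

    def test_missing_flagged(self):
        Y = np.array([[1.0, 2.0], [np.nan, 3.0]])
        I = index_values(np.array([1.0, 1.0]), Y, mu=np.zeros(2))
        assert np.isnan(I[1]) and not np.isnan(I[0])

    def test_monte_carlo_variance(self, rng, cov2020):
        b = smith_coefficients(cov2020, np.array([-1.0, 1.0]))
        Y = rng.multivariate_normal(np.zeros(2), cov2020.P, size=500)
        I = index_values(b, Y)
        assert np.var(I) == pytest.approx(b @ cov2020.P @ b, rel=0.15)


class TestTruncateSelect:
    def test_top_third(self):
        assert truncate_select(np.array([3.0, 1.0, 2.0]), 1 / 3) == [0]

    def test_tie_break_by_id(self):
        assert truncate_select(np.array([1.0, 1.0, 1.0]), 2 / 3) == [0, 1]

    def test_empty_error(self):
        with pytest.raises(ValueError):
            truncate_select(np.array([]), 0.5)

    def test_selection_differential_matches_k(self, rng):
        # mean standardized superiority of the selected tail ~ k
        I = rng.normal(size=100_000)
        sel = truncate_select(I, 0.10)
        k = selection_intensity(0.10)
        assert np.mean(I[sel]) == pytest.approx(k, abs=3 * 1.0 / np.sqrt(len(sel)))


class TestCovarianceEstimate:
    def test_bending_repairs_indefinite(self):
        C = np.array([[1.0, 1.2], [1.2, 1.0]])  # indefinite
        with pytest.warns(UserWarning, match="bending"):
            cov = CovarianceEstimate(["a", "b"], P=2 * np.eye(2), C=C)
        vals = np.linalg.eigvalsh(cov.C)
        assert vals[0] >= 1e-6 * vals[-1] * 0.999

    def test_heritability_flagging(self, cov2020):
        h2 = cov2020.heritabilities()
        assert h2[0] == pytest.approx(2.93 / 6.67, abs=1e-12)

    def test_subset_preserves_order(self, cov2020):
        sub = cov2020.subset(["Yield"])
        assert sub.P[0, 0] == 0.71 and sub.C[0, 0] == 0.36

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            IndexWeights("SIM", ["a"], d=np.array([1.0]))
        with pytest.raises(ValueError):
            IndexWeights("ESIM", ["a"], F_diag=np.array([0.0]))
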