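import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize

from conftest import random_trajectory
from wfdms.frequencies import FrequencyTrajectory
from wfdms.io import ConfigError
from wfdms.model import (
    InferenceConfig,
    IntegratedStatistics,
    NumericalError,
    SelectionModel,
    gauge_to_reference,
    infer_selection,
    integrated_covariance,
    select_gamma,
)

FIXED = InferenceConfig(gamma=0.25, gamma_mode="fixed")


class TestIntegratedCovariance:
    def test_trapezoid_two_allele_example(self, two_allele_traj):
        stats = integrated_covariance(two_allele_traj)
        # variance 0.09 at t0, 0.16 at t1 -> trapezoid average 0.125
        assert stats.A == pytest.approx(
            np.array([[0.125, -0.125], [-0.125, 0.125]]), abs=1e-15)
        assert stats.b == pytest.approx([-0.1, 0.1], abs=1e-15)

    def test_absent_allele_gives_zero_row_and_b(self):
        z = np.array([[0.9, 0.8], [0.1, 0.2], [0.0, 0.0]])
        traj = FrequencyTrajectory(
            replicate_id="r", times=np.array([0.0, 1.0]), sites=[1],
            alleles={1: ["A", "G", "C"]}, wildtype={1: "A"},
            z={1: z}, depth={1: np.array([10.0, 10.0])})
        stats = integrated_covariance(traj)
        assert np.all(stats.A[2] == 0) and np.all(stats.A[:, 2] == 0)
        assert stats.b[2] == 0

    def test_integral_additive_over_intervals(self):
        rng = np.random.default_rng(5)
        traj = random_trajectory(rng, 3, 2)
        whole = integrated_covariance(traj).A
        z = traj.z[1]
        parts = []
        for k in range(2):
            sub = FrequencyTrajectory(
                replicate_id="r", times=traj.times[k:k + 2], sites=[1],
                alleles=traj.alleles, wildtype=traj.wildtype,
                z={1: z[:, k:k + 2]}, depth={1: traj.depth[1][k:k + 2]})
            parts.append(integrated_covariance(sub).A)
        assert whole == pytest.approx(parts[0] + parts[1], abs=1e-14)

    def test_site_blocks_rows_sum_to_zero(self):
        stats = integrated_covariance(random_trajectory(np.random.default_rng(1), 4, 3))
        assert stats.A.sum(axis=1) == pytest.approx(np.zeros(4), abs=1e-12)

    def test_haplotype_mode_without_variant_tables_is_config_error(self, two_allele_traj):
        with pytest.raises(ConfigError):
            integrated_covariance(two_allele_traj,
                                  InferenceConfig(linkage_mode="haplotype"))


class TestInferSelection:
    def test_two_allele_closed_form(self, two_allele_traj):
        stats = integrated_covariance(two_allele_traj)
        res = infer_selection([stats], FIXED)
        assert res.params[(1, "G")] == pytest.approx(0.2, abs=1e-12)
        assert res.params[(1, "A")] == pytest.approx(-0.2, abs=1e-12)

    def test_zero_change_gives_zero_coefficients(self):
        z = np.array([[0.7, 0.7], [0.3, 0.3]])
        traj = FrequencyTrajectory(
            replicate_id="r", times=np.array([0.0, 1.0]), sites=[1],
            alleles={1: ["A", "G"]}, wildtype={1: "A"},
            z={1: z}, depth={1: np.array([10.0, 10.0])})
        res = infer_selection([integrated_covariance(traj)], FIXED)
        assert np.all(res.params.to_numpy() == 0.0)

    def test_replicates_pool_evidence_not_averages(self, two_allele_traj):
        stats = integrated_covariance(two_allele_traj)
        res = infer_selection([stats, stats], FIXED)
        assert res.params[(1, "G")] == pytest.approx(0.2 / 0.75, abs=1e-12)
        assert res.scope == "joint"

    def test_antisymmetry_two_allele(self):
        traj = random_trajectory(np.random.default_rng(9), 2, 3)
        res = infer_selection([integrated_covariance(traj)], FIXED)
        s = res.params.to_numpy()
        assert s[0] == pytest.approx(-s[1], abs=1e-14)

    def test_pooling_identity_gamma_over_r(self):
        stats = integrated_covariance(random_trajectory(np.random.default_rng(3), 4, 2))
        pooled = infer_selection([stats] * 3, gamma=0.3).params.to_numpy()
        single = infer_selection([stats], gamma=0.1).params.to_numpy()
        assert pooled == pytest.approx(single, abs=1e-12)

    def test_permutation_equivariance(self):
        stats = integrated_covariance(random_trajectory(np.random.default_rng(7), 4, 2))
        perm = [2, 0, 3, 1]
        permuted = IntegratedStatistics(
            index=[stats.index[i] for i in perm],
            A=stats.A[np.ix_(perm, perm)], b=stats.b[perm],
            replicate_id=stats.replicate_id)
        s0 = infer_selection([stats], gamma=0.2).params
        s1 = infer_selection([permuted], gamma=0.2).params
        for i, key in enumerate(permuted.index):
            assert s1[key] == pytest.approx(s0[key], abs=1e-13)

    @given(st.integers(0, 50))
    def test_shrinkage_monotone_in_gamma(self, seed):
        stats = integrated_covariance(
            random_trajectory(np.random.default_rng(seed), 4, 3))
        norms = [np.linalg.norm(infer_selection([stats], gamma=g).params.to_numpy())
                 for g in (0.01, 0.1, 1.0, 10.0)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_singular_system_advises_regularization(self):
        stats = integrated_covariance(
            random_trajectory(np.random.default_rng(0), 3, 2))
        with pytest.raises(NumericalError, match="gamma > 0"):
            infer_selection([stats], gamma=0.0)

    def test_matches_numerical_optimizer(self):
        """Closed form equals direct maximization of the regularized objective."""
        rng = np.random.default_rng(123)
        for trial in range(10):
            stats = integrated_covariance(
                random_trajectory(rng, int(rng.integers(2, 6)),
                                  int(rng.integers(1, 4))))
            gamma = [0.01, 0.1, 1.0][trial % 3]
            closed = infer_selection([stats], gamma=gamma).params.to_numpy()
            n = len(stats.b)
            M = stats.A + gamma * np.eye(n)
            opt = minimize(lambda s: 0.5 * s @ M @ s - s @ stats.b,
                           np.zeros(n), jac=lambda s: M @ s - stats.b,
                           method="BFGS", options={"gtol": 1e-12})
            assert np.max(np.abs(opt.x - closed)) < 1e-6


class TestSelectGamma:
    def test_fixed_mode_returns_config_value(self, two_allele_traj):
        stats = integrated_covariance(two_allele_traj)
        assert select_gamma([stats], InferenceConfig(gamma=0.3, gamma_mode="fixed")) == 0.3

    def test_adaptive_mode_is_mean_diagonal(self, two_allele_traj):
        stats = integrated_covariance(two_allele_traj)
        assert select_gamma([stats], InferenceConfig()) == pytest.approx(0.125)

    def test_all_zero_statistics_fall_back_with_warning(self):
        z = np.array([[1.0, 1.0], [0.0, 0.0]])
        traj = FrequencyTrajectory(
            replicate_id="r", times=np.array([0.0, 1.0]), sites=[1],
            alleles={1: ["A", "G"]}, wildtype={1: "A"},
            z={1: z}, depth={1: np.array([10.0, 10.0])})
        stats = integrated_covariance(traj)
        with pytest.warns(UserWarning, match="gamma = 1"):
            assert select_gamma([stats], InferenceConfig()) == 1.0


class TestGauge:
    def test_wt_zero_shifts_per_site(self, two_allele_traj):
        res = infer_selection([integrated_covariance(two_allele_traj)], FIXED)
        res.params[(1, "A")] = 0.1
        res.params[(1, "G")] = 0.3
        gauged = gauge_to_reference(res, {1: "A"})
        assert gauged.params[(1, "A")] == 0.0
        assert gauged.params[(1, "G")] == pytest.approx(0.2)
        assert gauged.params_raw[(1, "G")] == 0.3

    def test_gauging_twice_is_rejected(self, two_allele_traj):
        res = infer_selection([integrated_covariance(two_allele_traj)], FIXED)
        gauged = gauge_to_reference(res, {1: "A"})
        with pytest.raises(ValueError, match="raw"):
            gauge_to_reference(gauged, {1: "A"})

    def test_missing_wildtype_allele_is_key_error(self, two_allele_traj):
        res = infer_selection([integrated_covariance(two_allele_traj)], FIXED)
        with pytest.raises(KeyError):
            gauge_to_reference(res, {1: "X"})


class TestSelectionModel:
    def test_fit_and_summary(self, two_allele_traj):
        model = SelectionModel([two_allele_traj], FIXED)
        res = model.fit()
        assert "ridge penalty" in res.summary()
        assert res.wildtype == {1: "A"}
        gauged = res.gauge_to_reference()
        assert gauged.params[(1, "A")] == 0.0

    def test_fit_single_selects_replicate(self, two_allele_traj):
        model = SelectionModel([two_allele_traj], FIXED)
        res = model.fit_single("rep1")
        assert res.scope == "rep1"
        with pytest.raises(KeyError):
            model.fit_single("nope")
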