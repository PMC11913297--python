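"""Tests for importance weights, the ACE, normalizing-constant estimators,
the CIC value, and effective sample size."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cicfit as cf
from cicfit.errors import (
    DegenerateSupportError,
    InvalidArgumentError,
    InvalidTargetError,
)


def _one_stage_archive(points, r_values, proposal_log_density, p=1):
    archive = cf.SampleArchive(p)
    archive.add(
        cf.StageRecord.from_r(0, np.asarray(points, float).reshape(-1, p),
                              np.asarray(r_values, float),
                              np.asarray(proposal_log_density, float))
    )
    return archive


class TestImportanceWeights:
    def test_unit_proposal_density(self):
        w = cf.importance_weights(np.array([2.0, 2.0]), np.zeros(2))
        np.testing.assert_allclose(w, [2.0, 2.0])

    def test_optimal_proposal_gives_constant_rho(self, two_comp_1d):
        """With proposal = q* and r = rho*q*, every weight equals rho."""
        rho = 3.0
        x = cf.gmm_sample(two_comp_1d, 500, seed=0)
        lq = cf.gmm_log_density(two_comp_1d, x)
        r = rho * np.exp(lq)
        w = cf.importance_weights(r, lq)
        np.testing.assert_allclose(w, rho, rtol=1e-12)

    def test_all_zero_r_is_degenerate(self):
        with pytest.raises(DegenerateSupportError):
            cf.importance_weights(np.zeros(4), np.zeros(4))

    def test_negative_r_rejected(self):
        with pytest.raises(InvalidTargetError):
            cf.importance_weights(np.array([1.0, -0.1]), np.zeros(2))


class TestAce:
    def test_single_point_closed_form(self, std_normal_1d):
        """One point at the mode with r = 2*phi and proposal phi: weight 2,
        ACE = 2 * (-log phi(0)) = log(2 pi)."""
        phi0 = np.exp(-0.5 * np.log(2 * np.pi))
        archive = _one_stage_archive([0.0], [2 * phi0], [np.log(phi0)])
        val = cf.ace(archive, std_normal_1d)
        assert val == pytest.approx(np.log(2 * np.pi), rel=1e-12)

    def test_zero_log_density_candidate_scores_zero(self):
        """A candidate with log q = 0 at every point gives ACE 0 whatever
        the weights are."""
        sigma2 = 1.0 / (2 * np.pi)  # N(0, 1/(2 pi)) has log-density 0 at 0
        candidate = cf.GaussianMixtureParams.single(0.0, sigma2)
        archive = _one_stage_archive([0.0, 0.0], [3.0, 5.0], [0.0, 0.0])
        assert cf.ace(archive, candidate) == pytest.approx(0.0, abs=1e-12)

    def test_unsupported_candidate_returns_inf(self, std_normal_1d):
        # a positively weighted point where the candidate density underflows
        # past what the log-space evaluation can represent
        archive = _one_stage_archive([1e200], [1.0], [0.0])
        assert cf.ace(archive, std_normal_1d) == np.inf

    def test_matches_quadrature_oracle_within_mc_error(self, std_normal_1d):
        """ACE on 200 points from a fixed proposal is within 4 Monte-Carlo
        standard errors of the quadrature value of C(theta)."""
        rho, n = 2.0, 200
        target = cf.make_gmm_target(std_normal_1d, rho)
        proposal = cf.GaussianMixtureParams.single(0.0, 2.25)
        candidate = cf.GaussianMixtureParams.single(0.3, 1.2)
        x = cf.gmm_sample(proposal, n, seed=3)
        lq = cf.gmm_log_density(proposal, x)
        r = target(x)
        archive = _one_stage_archive(x, r, lq)
        val = cf.ace(archive, candidate)
        w = archive.stages[0].weights
        terms = -w * cf.gmm_log_density(candidate, x)
        se = terms.std(ddof=1) / np.sqrt(n)
        oracle = cf.oracle_cross_entropy(target, candidate)
        assert abs(val - oracle.value) < 4 * se

    def test_cumulative_pools_per_observation(self, std_normal_1d):
        """Pooling two stages equals the observation-weighted combination of
        the per-stage values."""
        archive = cf.SampleArchive(1)
        rng = np.random.default_rng(0)
        for s, n in enumerate([30, 70]):
            x = rng.normal(size=(n, 1))
            lq = cf.gmm_log_density(std_normal_1d, x)
            archive.add(cf.StageRecord.from_r(s, x, np.exp(lq) * 2, lq))
        a0 = cf.ace(archive, std_normal_1d, stages=[0])
        a1 = cf.ace(archive, std_normal_1d, stages=[1])
        pooled = cf.ace(archive, std_normal_1d)
        assert pooled == pytest.approx((30 * a0 + 70 * a1) / 100, rel=1e-12)


class TestRhoHat:
    def test_zero_variance_at_optimum(self, two_comp_1d):
        rho = 3.0
        x = cf.gmm_sample(two_comp_1d, 200, seed=1)
        lq = cf.gmm_log_density(two_comp_1d, x)
        archive = cf.SampleArchive(1)
        archive.add(cf.StageRecord.from_r(0, x, rho * np.exp(lq), lq))
        assert cf.rho_hat(archive) == pytest.approx(rho, rel=1e-12)

    def test_simple_mean(self):
        archive = _one_stage_archive([0.0, 1.0], [1.0, 3.0], [0.0, 0.0])
        assert cf.rho_hat(archive) == pytest.approx(2.0, rel=1e-12)

    def test_initial_stage_exclusion(self):
        archive = cf.SampleArchive(1)
        x = np.zeros((2, 1))
        archive.add(cf.StageRecord.from_r(0, x, np.array([10.0, 10.0]), np.zeros(2)))
        archive.add(cf.StageRecord.from_r(1, x, np.array([2.0, 2.0]), np.zeros(2)))
        assert cf.rho_hat(archive, include_initial=False) == pytest.approx(2.0)
        assert cf.rho_hat(archive, include_initial=True) == pytest.approx(6.0)

    def test_exclusion_requires_later_stage(self):
        archive = _one_stage_archive([0.0], [1.0], [0.0])
        with pytest.raises(InvalidArgumentError):
            cf.rho_hat(archive, include_initial=False)


class TestCicValue:
    @pytest.mark.parametrize(
        "ace_val,rho,d,n,expected",
        [(1.0, 2.0, 5, 100, 1.1), (3.7, 9.9, 0, 10, 3.7), (0.0, 2.0, 17, 1000, 0.034)],
    )
    def test_formula(self, ace_val, rho, d, n, expected):
        assert cf.cic_value(ace_val, rho, d, n) == pytest.approx(expected, rel=1e-12)

    def test_requires_positive_rho(self):
        with pytest.raises(InvalidArgumentError):
            cf.cic_value(1.0, 0.0, 2, 10)

    @settings(max_examples=50, derandomize=True)
    @given(d=st.integers(0, 50), rho=st.floats(0.1, 10), a=st.floats(-5, 5))
    def test_strictly_increasing_in_d(self, d, rho, a):
        assert cf.cic_value(a, rho, d + 1, 100) > cf.cic_value(a, rho, d, 100)


class TestEss:
    def test_equal_weights(self):
        assert cf.ess(np.full(10, 0.37)) == pytest.approx(10.0)

    def test_single_positive_weight(self):
        assert cf.ess(np.array([1.0, 0, 0, 0])) == pytest.approx(1.0)

    def test_mixed_weights(self):
        assert cf.ess(np.array([1.0, 1.0, 2.0])) == pytest.approx(16 / 6)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateSupportError):
            cf.ess(np.zeros(3))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(1e-6, 100.0)), min_size=1, max_size=30
        ).filter(lambda w: sum(w) > 0)
    )
    def test_bounded_by_n(self, w):
        val = cf.ess(np.array(w))
        assert 0 < val <= len(w) + 1e-9


class TestStageRecordAndArchive:
    def test_inconsistent_weights_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cf.StageRecord(0, np.zeros((1, 1)), np.array([1.0]), np.array([0.0]),
                           np.array([2.0]))

    def test_stage_indices_contiguous(self):
        archive = cf.SampleArchive(1)
        rec = cf.StageRecord.from_r(1, np.zeros((1, 1)), np.array([1.0]), np.array([0.0]))
        with pytest.raises(InvalidArgumentError):
            archive.add(rec)

    def test_npz_round_trip(self, tmp_path, two_comp_1d):
        archive = cf.SampleArchive(1)
        for s in range(2):
            x = cf.gmm_sample(two_comp_1d, 20, seed=s)
            lq = cf.gmm_log_density(two_comp_1d, x)
            archive.add(cf.StageRecord.from_r(s, x, 3 * np.exp(lq), lq))
        path = tmp_path / "arch.npz"
        archive.to_npz(path)
        back = cf.SampleArchive.from_npz(path)
        assert len(back) == 2
        np.testing.assert_allclose(back.stages[1].weights, archive.stages[1].weights)

    def test_csv_row_count(self, tmp_path, two_comp_1d):
        import pandas as pd

        archive = cf.SampleArchive(1)
        for s, n in enumerate([15, 25]):
            x = cf.gmm_sample(two_comp_1d, n, seed=s)
            lq = cf.gmm_log_density(two_comp_1d, x)
            archive.add(cf.StageRecord.from_r(s, x, 3 * np.exp(lq), lq))
        path = tmp_path / "arch.csv"
        archive.to_csv(path)
        df = pd.read_csv(path)
        assert len(df) == 40
        assert list(df.columns) == ["stage", "x_1", "r_value", "proposal_log_density", "weight"]


class TestUnbiasedness:
    """The ACE and rho_hat are unbiased for C(theta) and rho: replicate-mean
    checks against quadrature oracles (smaller-M versions; the full-size runs
    live in the acceptance suite)."""

    def test_ace_and_rho_means(self, two_comp_1d, wide_proposal_1d):
        rho, n, M = 3.0, 300, 200
        target = cf.make_gmm_target(two_comp_1d, rho)
        candidate = cf.GaussianMixtureParams(
            weights=np.array([0.4, 0.6]),
            means=np.array([[-2.5], [2.5]]),
            covariances=np.array([[[1.5]], [[1.5]]]),
        )
        oracle = cf.oracle_cross_entropy(target, candidate)
        aces, rhos = [], []
        for j in range(M):
            x = cf.gmm_sample(wide_proposal_1d, n, seed=j)
            lq = cf.gmm_log_density(wide_proposal_1d, x)
            archive = cf.SampleArchive(1)
            archive.add(cf.StageRecord.from_r(0, x, target(x), lq))
            aces.append(cf.ace(archive, candidate))
            rhos.append(cf.rho_hat(archive))
        aces, rhos = np.asarray(aces), np.asarray(rhos)
        assert abs(aces.mean() - oracle.value) < 4 * aces.std(ddof=1) / np.sqrt(M)
        assert abs(rhos.mean() - rho) < 4 * rhos.std(ddof=1) / np.sqrt(M)
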