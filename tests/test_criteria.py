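import numpy as np
import pytest
from conftest import as_estimate, block_corr, random_pd_corr

from factorretain.arms import ARMS
from factorretain.criteria import (EigenSpectrum, _implied_pca_matrix,
                                   _sequential_count, acceleration_factor,
                                   combine_with_kaiser, eigen_spectrum,
                                   kaiser_count, map_count, map_statistic,
                                   parallel_analysis,
                                   revised_parallel_analysis)
from factorretain.sampling import SampleMatrix, draw_from_corr

CONT = ARMS["cont_pearson"]


def map_statistic_brute(R, m):
    """Velicer's f_m by explicit elementwise loops (independent oracle)."""
    J = R.shape[0]
    if m == 0:
        A = R
    else:
        vals, vecs = np.linalg.eigh(R)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        lam = vecs[:, :m] * np.sqrt(vals[:m])
        C = R - lam @ lam.T
        A = np.empty_like(C)
        for v in range(J):
            for w in range(J):
                A[v, w] = C[v, w] / np.sqrt(C[v, v] * C[w, w])
    total = 0.0
    for v in range(J):
        for w in range(J):
            if v != w:
                total += A[v, w] ** 2
    return total / (J * (J - 1))


class TestSpectrum:
    def test_identity_spectrum(self):
        s = eigen_spectrum(np.eye(5))
        np.testing.assert_allclose(s.values, 1.0)

    def test_equicorrelation_closed_form(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        np.testing.assert_allclose(eigen_spectrum(R).values, [2.0, 0.5, 0.5],
                                   atol=1e-12)

    def test_trace_identity(self, rng):
        R = random_pd_corr(rng, n_items=12)
        assert eigen_spectrum(R).values.sum() == pytest.approx(12, abs=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            eigen_spectrum(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestKaiserAndScree:
    @pytest.mark.parametrize("values, expected", [
        ((1.0, 1.0, 1.0), 0),             # exactly 1 is not counted
        ((2.0, 0.5, 0.5), 1),
        ((3.0, 1.2, 1.0001, 0.5), 3),
    ])
    def test_kaiser_strictly_greater_than_one(self, values, expected):
        assert kaiser_count(EigenSpectrum(np.array(values))) == expected

    @pytest.mark.parametrize("values, expected", [
        ((4, 2, 0.5, 0.45, 0.4), 2),
        ((3, 2.9, 2.8, 0.2, 0.1, 0.05), 3),
        ((5, 4, 3, 2, 1), 1),             # linear scree: first-index tie-break
    ])
    def test_acceleration_factor(self, values, expected):
        assert acceleration_factor(EigenSpectrum(np.array(values, float))) == expected

    def test_acceleration_factor_needs_three_eigenvalues(self):
        with pytest.raises(ValueError):
            acceleration_factor(EigenSpectrum(np.array([2.0, 1.0])))

    @pytest.mark.parametrize("pair, expected", [((2, 1), 1), ((3, 5), 3),
                                                ((0, 4), 0)])
    def test_combined_with_kaiser_is_minimum(self, pair, expected):
        assert combine_with_kaiser(*pair) == expected


class TestMap:
    def test_identity_has_zero_f0_and_retains_nothing(self):
        from factorretain.criteria import CriterionFailure
        assert map_statistic(np.eye(4), 0) == 0.0
        # partialing a component out of exact independence leaves an item
        # with zero residual variance: flagged, and the count stays 0
        with pytest.raises(CriterionFailure):
            map_statistic(np.eye(4), 1)
        assert map_count(np.eye(4)) == 0
        # near-independence: the spurious component induces nonzero partials
        R = np.full((4, 4), 0.01)
        np.fill_diagonal(R, 1.0)
        assert map_statistic(R, 1) > map_statistic(R, 0) > 0
        assert map_count(R) == 0

    def test_equicorrelation_f0(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        assert map_statistic(R, 0) == pytest.approx(0.25)

    def test_three_block_population_retains_three(self, three_block_corr):
        assert map_count(three_block_corr) == 3

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            R = random_pd_corr(rng, n_items=6)
            for m in range(0, 5):
                assert map_statistic(R, m) == pytest.approx(
                    map_statistic_brute(R, m), abs=1e-12)

    def test_count_within_search_range(self, rng):
        for _ in range(10):
            R = random_pd_corr(rng, n_items=8)
            assert 0 <= map_count(R) <= 6


class TestParallelAnalysis:
    def test_sequential_count_strict_boundary(self):
        obs = np.array([2.0, 1.5, 1.0])
        assert _sequential_count(obs, obs.copy()) == 0  # ties fail
        assert _sequential_count(obs, np.array([1.9, 1.6, 0.9])) == 1
        assert _sequential_count(obs, np.array([1.0, 1.0, 0.5])) == 3

    def test_strong_single_factor_detected(self, rng):
        R = block_corr([6], 0.9)
        hits = 0
        for r in range(40):
            Z = SampleMatrix(draw_from_corr(R, 1000, rng))
            m = parallel_analysis(Z, CONT, reference="p95", k=100,
                                  rng=np.random.default_rng(r))
            hits += m == 1
        assert hits >= 36  # expect ~>=95%

    def test_pure_noise_rarely_retains(self, rng):
        false_pos = 0
        for r in range(40):
            Z = SampleMatrix(rng.standard_normal((500, 20)))
            m = parallel_analysis(Z, CONT, reference="p95", k=100,
                                  rng=np.random.default_rng(r))
            false_pos += m > 0
        assert false_pos <= 8  # ~5% expected

    def test_mean_reference_less_conservative_than_p95(self, rng):
        R = block_corr([5, 5], 0.6, phi=0.3)
        Z = SampleMatrix(draw_from_corr(R, 300, rng))
        m_mean = parallel_analysis(Z, CONT, "mean", k=100,
                                   rng=np.random.default_rng(1))
        m_95 = parallel_analysis(Z, CONT, "p95", k=100,
                                 rng=np.random.default_rng(1))
        assert m_mean >= m_95

    def test_binary_arm_pipeline_runs(self, rng):
        R = block_corr([5, 5], 0.8)
        Z = SampleMatrix(draw_from_corr(R, 400, rng))
        m = parallel_analysis(Z, ARMS["d50_pearson"], "p95", k=30,
                              rng=np.random.default_rng(2))
        assert 0 <= m <= 10


class TestRevisedParallelAnalysis:
    def test_stage_zero_matches_traditional_first_eigenvalue(self, rng):
        # identical seeds => identical identity-null comparison draws
        Z = SampleMatrix(rng.standard_normal((200, 8)))
        pa = parallel_analysis(Z, CONT, "p95", k=50,
                               rng=np.random.default_rng(7))
        rpa = revised_parallel_analysis(Z, CONT, k=50,
                                        rng=np.random.default_rng(7))
        assert (pa >= 1) == (rpa >= 1)

    def test_strong_single_factor_detected(self, rng):
        R = block_corr([6], 0.9)
        hits = 0
        for r in range(30):
            Z = SampleMatrix(draw_from_corr(R, 1000, rng))
            m = revised_parallel_analysis(Z, CONT, k=100,
                                          rng=np.random.default_rng(r))
            hits += m == 1
        assert hits >= 27

    def test_kaiser_cap_never_exceeds_plain_count(self, rng):
        R = block_corr([4, 4], 0.7, phi=0.2)
        Z = SampleMatrix(draw_from_corr(R, 150, rng))
        plain = revised_parallel_analysis(Z, CONT, k=50,
                                          rng=np.random.default_rng(3))
        capped = revised_parallel_analysis(Z, CONT, k=50, with_kaiser=True,
                                           rng=np.random.default_rng(3))
        est = CONT.correlation_of(Z.values)
        assert capped <= kaiser_count(eigen_spectrum(est))
        assert capped <= plain

    def test_implied_matrix_constructions(self, rng):
        R = random_pd_corr(rng, n_items=6)
        np.testing.assert_array_equal(_implied_pca_matrix(R, 0), np.eye(6))
        for kind in ("unit_error", "diag_reset"):
            M = _implied_pca_matrix(R, 2, kind)
            np.testing.assert_allclose(np.diag(M), 1.0, atol=1e-12)
            assert np.linalg.eigvalsh(M)[0] > 0
        # unit-error residual dimensions keep near-noise variance
        unit = _implied_pca_matrix(R, 2, "unit_error")
        reset = _implied_pca_matrix(R, 2, "diag_reset")
        assert np.linalg.eigvalsh(unit)[2] >= np.linalg.eigvalsh(reset)[2]
        with pytest.raises(ValueError):
            _implied_pca_matrix(R, 2, "bogus")
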