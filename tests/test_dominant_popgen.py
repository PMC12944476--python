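import numpy as np
import pytest

from pstfst import (
    AlleleFrequencySet,
    BetaPrior,
    MarkerMatrix,
    diversity_partition,
    estimate_allele_frequencies,
    fit_beta_prior,
    fst_permutation_test,
    pairwise_fst,
)
from pstfst.dominant_popgen import _posterior_mean

from conftest import toy_marker_matrix


def freqs(q, n):
    """AlleleFrequencySet from plain arrays, auto-naming pops and loci."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    n = np.full_like(q, float(n)) if np.isscalar(n) else np.asarray(n, dtype=float)
    return AlleleFrequencySet(
        [f"pop{i}" for i in range(q.shape[0])],
        [f"L{j}" for j in range(q.shape[1])], q, n,
    )


class TestBetaPrior:
    def test_method_of_moments_algebra(self):
        # mean 0.3, variance 0.03 -> m(1-m)/v = 7 -> (1.8, 4.2)
        d = np.sqrt(0.03)
        prior = fit_beta_prior(np.array([0.3 - d, 0.3 + d]))
        assert prior.a == pytest.approx(1.8, abs=1e-6)
        assert prior.b == pytest.approx(4.2, abs=1e-6)

    def test_zero_variance_degenerates_to_flat(self):
        prior = fit_beta_prior(np.full(50, 0.4))
        assert prior.degenerate
        assert (prior.a, prior.b) == (1.0, 1.0)

    def test_too_few_loci(self):
        with pytest.raises(ValueError):
            fit_beta_prior(np.array([0.5]))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(123)
        f = rng.beta(2.0, 5.0, size=10_000)
        prior = fit_beta_prior(f)
        assert prior.a == pytest.approx(2.0, rel=0.15)
        assert prior.b == pytest.approx(5.0, rel=0.15)


class TestAlleleFrequencies:
    def test_sqrt_estimator(self, rng):
        mm = toy_marker_matrix([[0.5], [0.0]], 16, rng)
        # force known counts: 4 absent of 16 in pop1, 0 in pop2
        bands = np.ones((32, 1))
        bands[:4, 0] = 0.0
        mm = MarkerMatrix(mm.individual_ids, mm.population_labels, mm.locus_ids, bands)
        est = estimate_allele_frequencies(mm, method="sqrt")
        assert est.q[0, 0] == pytest.approx(0.5)
        assert est.q[1, 0] == 0.0

    def test_bayesian_matches_riemann_oracle(self):
        # flat prior, x=4 of n=16: posterior mean of q with likelihood
        # (q^2)^4 (1-q^2)^12 against a 1e6-point Riemann sum
        q = (np.arange(1_000_000) + 0.5) / 1_000_000
        f = q**8 * (1 - q**2) ** 12
        oracle = np.sum(q * f) / np.sum(f)
        value = _posterior_mean(4, 16, BetaPrior(1.0, 1.0))
        assert value == pytest.approx(oracle, abs=1e-6)

    def test_estimators_converge_at_large_n(self):
        # fixed x/n = 0.25: |bayes - sqrt| shrinks as n grows
        prior = BetaPrior(1.5, 2.5)
        gaps = [
            abs(_posterior_mean(n // 4, n, prior) - np.sqrt(0.25))
            for n in (10, 100, 1000)
        ]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.01

    def test_no_scored_individuals_gives_nan(self):
        bands = np.array([[1.0, np.nan], [0.0, np.nan], [1.0, 1.0], [1.0, 0.0]])
        mm = MarkerMatrix(["a", "b", "c", "d"], ["A", "A", "B", "B"],
                          ["L1", "L2"], bands)
        est = estimate_allele_frequencies(mm, method="sqrt")
        assert np.isnan(est.q[0, 1])
        assert est.n[0, 1] == 0


class TestDiversityPartition:
    def test_two_population_hand_arithmetic(self):
        # q = 0.2 / 0.8, huge n so the n/(n-1) correction vanishes
        part = diversity_partition(freqs([[0.2], [0.8]], 1e12))
        assert part.hw == pytest.approx(0.32, abs=1e-9)
        assert part.ht == pytest.approx(0.50, abs=1e-9)
        assert part.hb == pytest.approx(0.18, abs=1e-9)
        assert part.fst == pytest.approx(0.36, abs=1e-9)

    def test_identical_populations_undifferentiated(self):
        q = np.tile(np.linspace(0.1, 0.9, 12), (2, 1))
        part = diversity_partition(freqs(q, 1e12))
        assert part.hb == pytest.approx(0.0, abs=1e-12)
        assert part.fst == pytest.approx(0.0, abs=1e-12)

    def test_ht_is_hw_plus_hb_pre_flooring(self, rng):
        for _ in range(20):
            q = rng.random((4, 30))
            part = diversity_partition(freqs(q, rng.integers(5, 30)))
            assert part.ht == pytest.approx(part.hw + part.hb_raw, abs=1e-12)

    def test_invariant_to_relabelling(self, rng):
        mm = toy_marker_matrix(rng.random((4, 40)), 12, rng)
        base = diversity_partition(estimate_allele_frequencies(mm))
        perm = rng.permutation(mm.n_loci)
        shuffled = mm.subset_loci(list(perm))
        renamed = shuffled.relabelled({"pop1": "zz", "pop3": "aa"})
        again = diversity_partition(estimate_allele_frequencies(renamed))
        assert again.fst == pytest.approx(base.fst, abs=1e-12)
        assert again.hw == pytest.approx(base.hw, abs=1e-12)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            diversity_partition(freqs([[0.2, 0.3]], 10))


class TestPermutationTest:
    def test_fixed_opposite_bands_minimal_p(self, opposite_fixed_markers):
        part = fst_permutation_test(opposite_fixed_markers, n_perm=1000, seed=4)
        assert part.fst == pytest.approx(1.0)
        assert part.p_value == pytest.approx(1 / 1001)

    def test_null_labels_not_significant(self, rng):
        # one panmictic pool arbitrarily split in two
        mm = toy_marker_matrix([list(rng.random(40))] * 2, 15, rng)
        part = fst_permutation_test(mm, n_perm=200, seed=9)
        assert part.p_value > 0.05

    def test_zero_permutations_rejected(self, opposite_fixed_markers):
        with pytest.raises(ValueError):
            fst_permutation_test(opposite_fixed_markers, n_perm=0)

    def test_super_uniform_under_null(self):
        # rejection rate at alpha = 0.05 stays in [0.01, 0.10]
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(200):
            q = rng.uniform(0.2, 0.8, size=25)
            bands = (rng.random((36, 25)) >= q**2).astype(float)
            mm = MarkerMatrix([f"i{i}" for i in range(36)],
                              [f"p{i % 3}" for i in range(36)],
                              [f"L{j}" for j in range(25)], bands)
            part = fst_permutation_test(mm, n_perm=99,
                                        seed=int(rng.integers(2**31)))
            rejections += part.p_value <= 0.05
        assert 0.01 <= rejections / 200 <= 0.10


class TestPairwiseFst:
    def test_identical_populations_all_zero(self, rng):
        q = np.tile(rng.random(30), (3, 1))
        mm = toy_marker_matrix(q, 1000, rng)
        # use the exact frequencies rather than sampled data
        pw_freqs = freqs(q, 1e12)
        from pstfst.dominant_popgen import diversity_partition as dp
        for i in range(3):
            for j in range(i + 1, 3):
                sub = freqs(q[[i, j]], 1e12)
                assert dp(sub).fst == pytest.approx(0.0, abs=1e-12)

    def test_toy_pair_value(self):
        sub = freqs([[0.2], [0.8]], 1e12)
        assert diversity_partition(sub).fst == pytest.approx(0.36, abs=1e-9)

    def test_simulated_pairwise_spread_around_target(self):
        from pstfst import SimulationConfig, simulate_markers

        config = SimulationConfig(n_individuals=15, n_loci=500, target_fst=0.33)
        mm = simulate_markers(config, seed=77)
        pw = pairwise_fst(mm)
        off = pw.matrix[np.triu_indices(len(pw.populations), 1)]
        # a two-population Nei partition captures half the among-population
        # variance: E[F_ST_pair] ~ F/(2 - F) under the island model
        expected = 0.33 / (2 - 0.33)
        assert abs(off.mean() - expected) < 0.07
        assert np.allclose(pw.matrix, pw.matrix.T)
        assert np.allclose(np.diag(pw.matrix), 0.0)
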