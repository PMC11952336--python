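import numpy as np
import pytest

from gplandscape import (DeltaPrior, GaussianObservations, Landscape,
                         SequenceSpace, VCPrior, expand_pattern,
                         fit_variance_components, gaussian_posterior,
                         mean_squared_epistatic_coefficient, mei,
                         mutation_contrast_weights, posterior_contrast,
                         sample_prior, simulate_counts, simulate_observations,
                         variance_components, vc_regression,
                         empirical_distance_correlation)
from gplandscape.gp import order_distance_basis

from .oracles import dense_gp_posterior


class TestObservationValidation:
    def test_duplicate_indices_rejected(self, binary2):
        with pytest.raises(ValueError, match="unique"):
            GaussianObservations(binary2, [0, 0], [1.0, 2.0], [0.1, 0.1])

    def test_negative_noise_rejected(self, binary2):
        with pytest.raises(ValueError):
            GaussianObservations(binary2, [0], [1.0], [-0.1])


class TestGaussianPosterior:
    def test_two_genotype_conditioning(self):
        # observe one genotype noiselessly: the other shrinks by the prior
        # correlation (which is -lambda_1 on a single binary site)
        space = SequenceSpace(["01"])
        lam1 = 0.8
        obs = GaussianObservations(space, [0], [1.0], [0.0])
        post = gaussian_posterior(VCPrior((0.0, lam1)), obs, center=False)
        rho = -1.0  # b_1(1) for two alleles
        assert np.allclose(post.mean, [1.0, rho], atol=1e-4)

    def test_huge_noise_returns_prior_mean(self, acg2, rng):
        obs = GaussianObservations(acg2, np.arange(9),
                                   rng.standard_normal(9), np.full(9, 1e8))
        post = gaussian_posterior(VCPrior((0.0, 1.0, 0.5)), obs, center=False)
        assert np.abs(post.mean).max() < 1e-5

    def test_matches_dense_oracle(self, acg2, rng):
        prior = VCPrior((0.0, 1.0, 0.4))
        K = prior.kernel_operator(acg2).to_dense()
        idx = np.array([0, 2, 3, 5, 7])
        y = rng.standard_normal(5)
        nv = np.full(5, 0.1)
        obs = GaussianObservations(acg2, idx, y, nv)
        post = gaussian_posterior(prior, obs, center=False)
        mean_d, cov_d = dense_gp_posterior(K, idx, y, nv)
        assert np.allclose(post.mean, mean_d, atol=1e-7)
        assert np.allclose(post.variances(np.arange(9)), np.diag(cov_d),
                           atol=1e-7)
        w = rng.standard_normal(9)
        w2 = rng.standard_normal(9)
        assert np.isclose(post.cov_query(w, w2), w @ cov_d @ w2, atol=1e-7)

    def test_precision_form_matches_dense(self, acg2, rng):
        prior = DeltaPrior(P=2, a=3.0)
        idx = np.arange(9)
        y = rng.standard_normal(9)
        nv = np.full(9, 0.2)
        obs = GaussianObservations(acg2, idx, y, nv)
        post = gaussian_posterior(prior, obs)
        C = prior.precision_operator(acg2).to_dense()
        H = C + np.diag(1.0 / nv)
        mean_d = np.linalg.solve(H, y / nv)
        assert np.allclose(post.mean, mean_d, atol=1e-6)
        w = rng.standard_normal(9)
        assert np.isclose(post.cov_query(w), w @ np.linalg.solve(H, w),
                          atol=1e-6)


class TestMEI:
    def test_full_observation_is_identity(self, binary2, rng):
        y = rng.standard_normal(4)
        obs = GaussianObservations(binary2, np.arange(4), y, np.zeros(4))
        assert np.allclose(mei(obs).mean, y)

    def test_parallelogram_completion(self, binary2):
        obs = GaussianObservations(binary2, [0, 1, 2],
                                   [0.0, 1.0, 2.0], np.zeros(3))
        post = mei(obs)
        assert np.isclose(post.mean[3], 3.0)

    def test_additive_truth_recovered_from_half(self, rng):
        space = SequenceSpace(["ACGT"] * 3)
        effects = [rng.standard_normal(4) for _ in range(3)]
        f = sum(e.reshape([4 if p == q else 1 for q in range(3)])
                for p, e in enumerate(effects)) + np.zeros((4, 4, 4))
        truth = Landscape(space, f.reshape(-1))
        obs = simulate_observations(truth, 0.0, 0.5, rng)
        post = mei(obs)
        assert np.allclose(post.mean, truth.values, atol=1e-5)
        eps2, _ = mean_squared_epistatic_coefficient(post.to_landscape(), 2)
        assert eps2 < 1e-10

    def test_beats_random_completions(self, rng):
        space = SequenceSpace(["01"] * 3)
        truth = rng.standard_normal(8)
        idx = np.array([0, 3, 5, 6])
        obs = GaussianObservations(space, idx, truth[idx], np.zeros(4))
        post = mei(obs)
        from gplandscape import delta_operator
        D = delta_operator(space, 2)
        best = D.quad(post.mean)
        for _ in range(50):
            other = post.mean.copy()
            mask = np.ones(8, bool)
            mask[idx] = False
            other[mask] += 0.3 * rng.standard_normal(mask.sum())
            assert D.quad(other) >= best - 1e-10


class TestDistanceCorrelation:
    def test_additive_profile(self, rng):
        # complete additive noiseless landscape: cov follows the order-1 basis
        space = SequenceSpace(["ACGT"] * 4)
        f = sample_prior(space, VCPrior((0, 1.0, 0, 0, 0)), rng)
        obs = GaussianObservations(space, np.arange(256), f.values,
                                   np.zeros(256))
        table = empirical_distance_correlation(obs)
        b1 = order_distance_basis(space)[:, 1]
        got = table["covariance"].to_numpy()
        assert np.allclose(got / got[0], b1, atol=1e-10)
        assert got[-1] < 0  # anticorrelation at maximal distance

    def test_constant_data_flagged(self, binary2):
        obs = GaussianObservations(binary2, np.arange(4), np.ones(4),
                                   np.zeros(4))
        table = empirical_distance_correlation(obs)
        assert table["correlation"].isna().all()

    def test_operator_path_matches_pairwise_enumeration(self, rng):
        # the complete-data spectral shortcut must agree with brute-force
        # averaging over all ordered pairs at each distance
        space = SequenceSpace(["ACG"] * 2)
        y = rng.standard_normal(9)
        obs = GaussianObservations(space, np.arange(9), y, np.zeros(9))
        fast = empirical_distance_correlation(obs)
        yc = y - y.mean()
        idx = np.arange(9)
        d = space.hamming_distances(np.repeat(idx, 9), np.tile(idx, 9))
        prod = np.outer(yc, yc).reshape(-1)
        for dd in range(3):
            mask = d == dd
            assert fast["n_pairs"][dd] == mask.sum()
            assert np.isclose(fast["covariance"][dd], prod[mask].mean())


class TestKernelAlignment:
    def test_additive_data_yields_additive_prior(self, rng):
        space = SequenceSpace(["ACGT"] * 4)
        f = sample_prior(space, VCPrior((0, 1.0, 0, 0, 0)), rng)
        obs = GaussianObservations(space, np.arange(256), f.values,
                                   np.zeros(256))
        prior = fit_variance_components(obs)
        lam = np.array(prior.lambdas)
        assert lam[2:].max() < 1e-8 * lam[1]

    def test_recovers_planted_lambdas(self, rng):
        # realized per-order variances fluctuate chi^2-style around the
        # planted values; averaging replicates isolates the estimator's bias
        space = SequenceSpace(["ACGT"] * 5)
        planted = np.array([0.0, 1.0, 0.5, 0.0, 0.0, 0.0])
        acc = np.zeros(6)
        reps = 100
        for _ in range(reps):
            f = sample_prior(space, VCPrior(planted), rng)
            obs = GaussianObservations(space, np.arange(1024), f.values,
                                       np.zeros(1024))
            acc += np.array(fit_variance_components(obs).lambdas)
        acc /= reps
        nz = planted > 0
        assert np.abs(acc[nz] - planted[nz]).max() / planted[nz].min() < 0.1

    def test_noise_correction_keeps_lambdas_unbiased(self, rng):
        space = SequenceSpace(["ACGT"] * 4)
        planted = np.array([0.0, 1.0, 0.5, 0.0, 0.0])
        sigma = 0.5
        acc = np.zeros(5)
        reps = 20
        for _ in range(reps):
            f = sample_prior(space, VCPrior(planted), rng)
            obs = simulate_observations(f, sigma, 0.0, rng)
            acc += np.array(fit_variance_components(obs).lambdas)
        acc /= reps
        nz = planted > 0
        assert np.abs(acc[nz] - planted[nz]).max() / planted[nz].min() < 0.15


class TestVCRegression:
    def test_complete_noiseless_reproduces_data(self, rng):
        space = SequenceSpace(["ACGT"] * 3)
        f = sample_prior(space, VCPrior((0, 1.0, 0.5, 0.2)), rng)
        obs = GaussianObservations(space, np.arange(64), f.values,
                                   np.zeros(64))
        post = vc_regression(obs)
        assert np.allclose(post.mean, f.values, atol=1e-4)

    def test_small_instance_matches_dense(self, acg2, rng):
        prior = VCPrior((0.0, 0.7, 0.3))
        K = prior.kernel_operator(acg2).to_dense()
        idx = np.array([1, 2, 4, 8])
        y = rng.standard_normal(4)
        nv = np.full(4, 0.05)
        obs = GaussianObservations(acg2, idx, y, nv)
        post = gaussian_posterior(prior, obs, center=False)
        mean_d, _ = dense_gp_posterior(K, idx, y, nv)
        assert np.allclose(post.mean, mean_d, atol=1e-7)


class TestContrasts:
    def test_pattern_weights_uniform(self, binary2):
        w = expand_pattern(binary2, "NN")
        assert np.allclose(w, 0.25)

    def test_pattern_restricts(self, dna3):
        w = expand_pattern(dna3, "ANG")
        seqs = dna3.genotype_strings()
        assert np.allclose(w.sum(), 1.0)
        assert all((x[0] == "A" and x[2] == "G") == (wi > 0)
                   for x, wi in zip(seqs, w))

    def test_no_match_raises(self, binary2):
        with pytest.raises(ValueError, match="matches nothing"):
            expand_pattern(binary2, "AN")

    def test_noiseless_difference_has_zero_sd(self, acg2, rng):
        prior = VCPrior((0.0, 1.0, 0.5))
        idx = np.arange(9)
        y = rng.standard_normal(9)
        obs = GaussianObservations(acg2, idx, y, np.zeros(9))
        post = gaussian_posterior(prior, obs, center=False)
        w = np.zeros(9)
        w[2], w[5] = 1.0, -1.0
        res = posterior_contrast(post, weights=w)
        assert np.isclose(res["mean"], y[2] - y[5], atol=1e-5)
        assert res["sd"] < 1e-3

    def test_mutation_weights(self, dna3):
        w = mutation_contrast_weights(dna3, "ACG", 1, "C", "G")
        assert w[dna3.encode("AGG")] == 1.0
        assert w[dna3.encode("ACG")] == -1.0
        assert np.count_nonzero(w) == 2


class TestSimulators:
    def test_additive_prior_sample_has_no_epistasis(self, rng):
        space = SequenceSpace(["01"] * 3)
        f = sample_prior(space, VCPrior((0, 1.0, 0, 0)), rng)
        eps2, _ = mean_squared_epistatic_coefficient(f, 2)
        assert eps2 < 1e-12

    def test_vc_sampling_variances_match(self, rng):
        space = SequenceSpace(["01"] * 3)
        planted = np.array([0.0, 1.0, 0.5, 0.25])
        acc = np.zeros(4)
        n_samp = 1000
        for _ in range(n_samp):
            f = sample_prior(space, VCPrior(planted), rng)
            acc += variance_components(f).by_order
        acc /= n_samp
        assert np.abs(acc[1:] - planted[1:]).max() / planted[1:].min() < 0.1

    def test_delta_prior_sample_scale(self, rng):
        space = SequenceSpace(["ACGT"] * 3)
        prior = DeltaPrior(P=2, a=10.0)
        s = prior.coefficient_count(space)
        acc = 0.0
        for _ in range(200):
            f = sample_prior(space, prior, rng)
            from gplandscape import delta_operator
            acc += delta_operator(space, 2).quad(f.values) / s
        # E[f' Delta f] = rank(Delta) * s / a / s ... check via dense trace
        C = (prior.a / s) * delta_operator(space, 2).to_dense()
        rank = np.linalg.matrix_rank(C, tol=1e-8)
        assert np.isclose(acc / 200 * prior.a, rank, rtol=0.15)

    def test_count_simulation_totals(self, binary2, rng):
        data = simulate_counts(binary2, np.full(4, 0.25), 100, rng)
        assert data.n_total == 100

    def test_zero_total_rejected(self, binary2, rng):
        with pytest.raises(ValueError):
            simulate_counts(binary2, np.full(4, 0.25), 0, rng)

    def test_bad_missing_fraction(self, binary2, rng):
        ls = Landscape(binary2, np.zeros(4))
        with pytest.raises(ValueError):
            simulate_observations(ls, 0.1, 1.0, rng)
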