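"""Allocation softmax, Gumbel-Softmax sampling, soft progeny and the
multi-generation differentiable forward pass."""

import numpy as np
import pytest

from softbreed import (
    AllocationParams,
    SchemeConfig,
    allocation_probs,
    draw_noise,
    draw_noise_bank,
    expected_merit,
    forward_scheme,
    gumbel_softmax_sample,
    merit_topk,
    simulate_scheme_hard,
    soft_progeny,
)
from softbreed.autodiff import Tensor
from softbreed.meiosis import progeny_batch
from softbreed.metrics import assemble_features
from softbreed.selection import select


class TestAllocationProbs:
    def test_zero_weights_give_uniform(self, rng):
        omega = rng.normal(size=(10, 2))
        pi = allocation_probs(omega, np.zeros(2))
        np.testing.assert_allclose(pi, 0.1)

    def test_softmax_closed_form(self):
        omega = np.array([[np.log(2.0)], [0.0]])
        pi = allocation_probs(omega, np.ones(1))
        np.testing.assert_allclose(pi, [2 / 3, 1 / 3])

    def test_shift_invariance(self, rng):
        omega = rng.normal(size=(6, 2))
        theta = np.array([0.7, 1.3])
        # shifting every pair's score by the same constant leaves pi unchanged
        pi1 = allocation_probs(omega @ theta[:, None], np.ones(1))
        pi2 = allocation_probs(omega @ theta[:, None] + 123.4, np.ones(1))
        np.testing.assert_allclose(pi1, pi2, atol=1e-12)

    def test_nan_features_rejected(self):
        omega = np.array([[np.nan, 0.0]])
        with pytest.raises(FloatingPointError):
            allocation_probs(omega, np.ones(2))


class TestGumbelSoftmax:
    def test_rows_sum_to_one(self, rng):
        pi = rng.dirichlet(np.ones(8))
        g = rng.gumbel(size=(30, 8))
        y = gumbel_softmax_sample(pi, g, c=0.7)
        np.testing.assert_allclose(y.sum(axis=-1), 1.0, atol=1e-9)

    def test_collapses_to_one_hot_at_tiny_temperature(self):
        pi = np.array([0.5, 0.5])
        y = gumbel_softmax_sample(pi, np.array([0.1, -0.2]), c=1e-6)
        np.testing.assert_allclose(y, [1.0, 0.0], atol=1e-9)

    def test_symmetric_inputs_split_evenly(self):
        y = gumbel_softmax_sample(np.array([0.5, 0.5]), np.zeros(2), c=1.0)
        np.testing.assert_allclose(y, [0.5, 0.5])

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            gumbel_softmax_sample(np.array([1.0]), np.zeros(1), c=0.0)


class TestSoftProgeny:
    def test_one_hot_selects_candidate(self, rng):
        cand = rng.integers(0, 2, size=(4, 6)).astype(float)
        y = np.eye(4)[2]
        np.testing.assert_allclose(soft_progeny(y, cand), cand[2])

    def test_uniform_mix_of_two(self):
        cand = np.array([[1, 0, 1, 1], [0, 1, 1, 1]], dtype=float)
        got = soft_progeny(np.array([0.5, 0.5]), cand)
        np.testing.assert_allclose(got, [0.5, 0.5, 1.0, 1.0])

    def test_identical_candidates_ignore_weights(self, rng):
        cand = np.tile(rng.integers(0, 2, size=6).astype(float), (5, 1))
        y = rng.dirichlet(np.ones(5))
        np.testing.assert_allclose(soft_progeny(y, cand), cand[0])


class TestMeritTopK:
    def test_small_example(self):
        assert merit_topk(np.array([3.0, 1.0, 2.0]), 2) == pytest.approx(2.5)

    def test_k_equals_n_is_mean(self, rng):
        v = rng.normal(size=9)
        assert merit_topk(v, 9) == pytest.approx(v.mean())

    def test_matches_sort_oracle(self, rng):
        v = rng.normal(size=40)
        assert merit_topk(v, 5) == pytest.approx(np.sort(v)[-5:].mean())

    @pytest.mark.parametrize("K", [0, 41])
    def test_out_of_range_k(self, rng, K):
        with pytest.raises(ValueError):
            merit_topk(rng.normal(size=40), K)


class TestForwardScheme:
    def test_soft_allele_scores_stay_in_unit_interval(
        self, tiny_founders, tiny_trait, tiny_map, tiny_config
    ):
        params = AllocationParams(nu=np.ones((2, 2)))
        noise = draw_noise(tiny_map, tiny_config, tiny_founders.n, seed=5)
        res = forward_scheme(
            tiny_founders, params, tiny_trait, tiny_map, noise, tiny_config
        )
        w = res.final_w.data
        assert np.all((w >= -1e-12) & (w <= 1 + 1e-12))
        assert res.grads.shape == (2, 2)

    def test_temperature_limit_recovers_hard_argmax_progeny(
        self, tiny_founders, tiny_trait, tiny_map
    ):
        """As c -> 0 the soft scheme equals a hard scheme whose pair choices
        are the Gumbel argmaxes, generation by generation."""
        config = SchemeConfig(
            generations=2, top_k=5, selection="SI1", n_selected=5, temperature=1e-6
        )
        params = AllocationParams(nu=np.zeros((2, 2)))
        noise = draw_noise(tiny_map, config, tiny_founders.n, seed=8)
        res = forward_scheme(
            tiny_founders, params, tiny_trait, tiny_map, noise, config,
            compute_grads=False,
        )
        # replay discretely with the same noise
        theta = params.theta
        w = np.asarray(tiny_founders.w, dtype=float)
        for tau in range(2):
            sel = select(w, tiny_trait, "SI1", 5)
            feats = assemble_features(w, sel.indices, tiny_trait, tiny_map)
            pi = allocation_probs(feats.omega, theta[tau])
            choice = np.argmax(np.log(pi) + noise.gumbel[tau], axis=-1)
            etaM = noise.eta[tau, 0][np.arange(w.shape[0]), choice]
            etaP = noise.eta[tau, 1][np.arange(w.shape[0]), choice]
            w = progeny_batch(
                w[sel.indices], feats.kM[choice], feats.kP[choice], etaM, etaP
            )
        np.testing.assert_allclose(res.final_w.data, w, atol=1e-9)

    def test_gradients_match_finite_differences(
        self, tiny_founders, tiny_trait, tiny_map, tiny_config
    ):
        nu0 = np.array([[0.3, -0.4], [0.1, 0.6]])
        bank = draw_noise_bank(tiny_map, tiny_config, tiny_founders.n, 17, 5)
        base = expected_merit(
            tiny_founders, AllocationParams(nu=nu0), tiny_trait, tiny_map, 5, 17,
            tiny_config, noise_bank=bank,
        )
        h = 1e-4
        for idx in np.ndindex(2, 2):
            fp, fm = [], []
            for sign, acc in ((+h, fp), (-h, fm)):
                nu = nu0.copy()
                nu[idx] += sign
                acc.append(
                    expected_merit(
                        tiny_founders, AllocationParams(nu=nu), tiny_trait,
                        tiny_map, 5, 17, tiny_config, noise_bank=bank,
                        compute_grads=False,
                    ).F
                )
            fd = (fp[0] - fm[0]) / (2 * h)
            assert base.grads_nu[idx] == pytest.approx(fd, rel=1e-3, abs=1e-8)

    def test_mismatched_generations_rejected(
        self, tiny_founders, tiny_trait, tiny_map, tiny_config
    ):
        noise = draw_noise(tiny_map, tiny_config, tiny_founders.n, seed=1)
        with pytest.raises(ValueError):
            forward_scheme(
                tiny_founders, AllocationParams(nu=np.zeros((3, 2))), tiny_trait,
                tiny_map, noise, tiny_config,
            )


class TestExpectedMerit:
    def test_single_rep_reduces_to_forward(self, tiny_founders, tiny_trait, tiny_map,
                                           tiny_config):
        params = AllocationParams(nu=np.zeros((2, 2)))
        bank = draw_noise_bank(tiny_map, tiny_config, tiny_founders.n, 3, 1)
        a = expected_merit(tiny_founders, params, tiny_trait, tiny_map, 1, 3,
                           tiny_config, noise_bank=bank)
        b = forward_scheme(tiny_founders, params, tiny_trait, tiny_map, bank[0],
                           tiny_config)
        assert a.F == pytest.approx(b.F)
        np.testing.assert_allclose(a.grads_nu, b.grads_nu)

    def test_same_seed_reproducible(self, tiny_founders, tiny_trait, tiny_map,
                                    tiny_config):
        params = AllocationParams(nu=np.full((2, 2), 0.2))
        a = expected_merit(tiny_founders, params, tiny_trait, tiny_map, 4, 21,
                           tiny_config, compute_grads=False)
        b = expected_merit(tiny_founders, params, tiny_trait, tiny_map, 4, 21,
                           tiny_config, compute_grads=False)
        assert a.F == b.F

    def test_mc_variance_shrinks_with_reps(self, tiny_founders, tiny_trait, tiny_map,
                                           tiny_config):
        params = AllocationParams(nu=np.zeros((2, 2)))

        def batch_var(n_mc, n_batches, seed0):
            vals = [
                expected_merit(
                    tiny_founders, params, tiny_trait, tiny_map, n_mc,
                    seed0 + i, tiny_config, compute_grads=False,
                ).F
                for i in range(n_batches)
            ]
            return np.var(vals)

        v10 = batch_var(10, 12, 100)
        v40 = batch_var(40, 12, 300)
        assert v40 < v10  # ~1/n shrinkage, checked directionally


def test_soft_theta_zero_matches_hard_equal_allocation_distribution(
    tiny_founders, tiny_trait, tiny_map
):
    """With theta = 0 and a tiny temperature, the relaxed simulator's merit
    distribution agrees with the discrete equal-allocation simulator within
    Monte-Carlo error (the two integerize uniform allocation differently:
    per-slot categorical draws versus largest-remainder counts)."""
    config = SchemeConfig(
        generations=2, top_k=5, selection="SI1", n_selected=5, temperature=1e-6
    )
    eq = AllocationParams.equal_allocation(2)
    soft_params = AllocationParams(fixed_theta=np.zeros((2, 2)))
    n_reps = 500
    soft_F = np.empty(n_reps)
    hard_F = np.empty(n_reps)
    for r in range(n_reps):
        noise = draw_noise(tiny_map, config, tiny_founders.n, seed=5000 + r)
        soft_F[r] = forward_scheme(
            tiny_founders, soft_params, tiny_trait, tiny_map, noise, config,
            compute_grads=False,
        ).F
        pops = simulate_scheme_hard(
            tiny_founders, eq, tiny_trait, tiny_map, config, seed=5000 + r
        )
        hard_F[r] = merit_topk(
            pops[-1].w @ np.concatenate([tiny_trait.beta, tiny_trait.beta]), 5
        )
    se = np.sqrt(soft_F.var() / n_reps + hard_F.var() / n_reps)
    assert abs(soft_F.mean() - hard_F.mean()) < 4 * se
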