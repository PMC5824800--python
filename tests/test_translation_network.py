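import math

import numpy as np
import pytest

from protocode.codon_space import CODON_ENCODINGS
from protocode.translation_network import (
    N_HIDDEN,
    N_INPUT,
    N_OUTPUT,
    PerceptronTranslator,
    forward,
    forward_batch,
    init_network,
    sample_loss,
    train_on_pairs,
)


def zero_net(lr=0.1):
    return PerceptronTranslator(
        np.zeros((N_INPUT, N_HIDDEN)),
        np.zeros(N_HIDDEN),
        np.zeros((N_HIDDEN, N_OUTPUT)),
        np.zeros(N_OUTPUT),
        lr,
    )


def all_params(net):
    return np.concatenate(
        [
            net.w_input_hidden.ravel(),
            net.b_hidden,
            net.w_hidden_output.ravel(),
            net.b_output,
        ]
    )


class TestInit:
    def test_moments_of_initial_weights(self):
        rng = np.random.default_rng(0)
        samples = np.concatenate(
            [all_params(init_network(rng)) for _ in range(1000)]
        )
        assert samples.size >= 100_000
        n = samples.size
        se_mean = 0.1 / math.sqrt(n)
        assert abs(samples.mean()) < 3 * se_mean
        se_sd = 0.1 / math.sqrt(2 * n)
        assert abs(samples.std() - 0.1) < 3 * se_sd

    def test_uniform_support_bounds(self):
        rng = np.random.default_rng(0)
        samples = np.concatenate([all_params(init_network(rng)) for _ in range(200)])
        half_width = 0.1 * math.sqrt(3)
        assert samples.min() >= -half_width and samples.max() <= half_width

    def test_same_seed_bitwise_identical(self):
        a = init_network(np.random.default_rng(99))
        b = init_network(np.random.default_rng(99))
        assert np.array_equal(all_params(a), all_params(b))

    def test_normal_init_variant(self):
        rng = np.random.default_rng(0)
        samples = np.concatenate(
            [all_params(init_network(rng, init="normal")) for _ in range(1000)]
        )
        assert abs(samples.std() - 0.1) < 3 * 0.1 / math.sqrt(2 * samples.size)
        half_width = 0.1 * math.sqrt(3)
        assert samples.min() < -half_width  # gaussian tails exceed the uniform box

    def test_unknown_init_rejected(self):
        with pytest.raises(ValueError):
            init_network(np.random.default_rng(0), init="cauchy")


class TestForward:
    def test_zero_network_outputs_half(self, rng):
        net = zero_net()
        for _ in range(5):
            assert np.allclose(forward(net, rng.random(3)), 0.5)

    def test_output_strictly_inside_unit_interval(self, rng):
        net = init_network(rng)
        for x in CODON_ENCODINGS:
            y = forward(net, x)
            assert np.all(y > 0) and np.all(y < 1)

    def test_logistic_monotone_in_drive(self):
        # single path: scale the output bias and watch the output rise
        outs = []
        for b in (-2.0, -1.0, 0.0, 1.0, 2.0):
            net = zero_net()
            net.b_output[:] = b
            outs.append(forward(net, np.zeros(3))[0])
        assert outs == sorted(outs)
        assert outs[2] == pytest.approx(0.5)

    def test_independent_hand_rolled_oracle(self, rng):
        # scalar re-implementation with math.exp, no numpy linear algebra
        def oracle(net, x):
            hidden = []
            for j in range(N_HIDDEN):
                v = net.b_hidden[j]
                for i in range(N_INPUT):
                    v += net.w_input_hidden[i, j] * x[i]
                hidden.append(1.0 / (1.0 + math.exp(-v)))
            out = []
            for j in range(N_OUTPUT):
                v = net.b_output[j]
                for i in range(N_HIDDEN):
                    v += net.w_hidden_output[i, j] * hidden[i]
                out.append(1.0 / (1.0 + math.exp(-v)))
            return np.array(out)

        for _ in range(100):
            net = init_network(rng)
            x = rng.random(3)
            assert np.allclose(forward(net, x), oracle(net, x), atol=1e-12)

    def test_batch_matches_single(self, rng):
        net = init_network(rng)
        X = rng.random((10, 3))
        batch = forward_batch(net, X)
        for k in range(10):
            assert np.allclose(batch[k], forward(net, X[k]), atol=1e-12)

    def test_non_finite_input_rejected(self, rng):
        net = init_network(rng)
        with pytest.raises(ValueError):
            forward(net, np.array([0.1, np.inf, 0.3]))


def _finite_difference_update(net, x, d, h=1e-5):
    """Expected weight change -eta * dEps/dtheta via central differences."""
    eta = net.learning_rate
    ref = net.copy()
    arrays = ("w_input_hidden", "b_hidden", "w_hidden_output", "b_output")
    deltas = {}
    for name in arrays:
        arr = getattr(ref, name)
        grad = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            probe = ref.copy()
            getattr(probe, name)[idx] += h
            up = sample_loss(probe, x, d)
            probe = ref.copy()
            getattr(probe, name)[idx] -= h
            down = sample_loss(probe, x, d)
            grad[idx] = (up - down) / (2 * h)
        deltas[name] = -eta * grad
    return deltas


class TestTraining:
    def test_gradient_matches_central_differences(self, rng):
        for _ in range(5):
            net = init_network(rng)
            x, d = rng.random(3), rng.random(11)
            expected = _finite_difference_update(net, x, d)
            before = net.copy()
            train_on_pairs(net, [(x, d)], epochs=1, rng=rng)
            for name, exp in expected.items():
                actual = getattr(net, name) - getattr(before, name)
                scale = np.maximum(np.abs(exp), 1e-8)
                assert np.all(np.abs(actual - exp) / scale < 1e-6), name

    def test_zero_learning_rate_leaves_network_unchanged(self, rng):
        net = init_network(rng, learning_rate=0.0)
        before = all_params(net).copy()
        train_on_pairs(net, [(rng.random(3), rng.random(11))], 50, rng)
        assert np.array_equal(all_params(net), before)

    def test_zero_epochs_leaves_network_unchanged(self, rng):
        net = init_network(rng)
        before = all_params(net).copy()
        train_on_pairs(net, [(rng.random(3), rng.random(11))], 0, rng)
        assert np.array_equal(all_params(net), before)

    def test_single_pair_loss_decreases(self, rng):
        net = init_network(rng)
        x, d = rng.random(3), rng.random(11)
        start = sample_loss(net, x, d)
        train_on_pairs(net, [(x, d)], epochs=200, rng=rng)
        assert sample_loss(net, x, d) < start

    def test_empty_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            train_on_pairs(init_network(rng), [], 10, rng)

    def test_dimension_mismatch_rejected(self, rng):
        net = init_network(rng)
        with pytest.raises(ValueError, match="mismatch"):
            train_on_pairs(net, [(rng.random(4), rng.random(11))], 1, rng)

    def test_capacity_64_codons_to_20_amino_acids(self, aa_table):
        # six hidden nodes suffice to map 64 codons onto all 20 amino
        # acids: backprop training during a short communal run produces a
        # network whose read-out encodes every amino acid (its own
        # read-out is then a fully matched 64->20 target table)
        from protocode.simulation import RunConfig, run_simulation

        cfg = RunConfig(
            total_transfers=2000, master_seed=3, n_runs=1, recording_interval=500
        )
        result = run_simulation(cfg, aa_table)
        assert (result.receiver_expressivity == 20).any()


class TestSerialization:
    def test_json_round_trip_exact(self, rng):
        net = init_network(rng)
        back = PerceptronTranslator.from_json(net.to_json())
        assert np.array_equal(all_params(net), all_params(back))
        assert back.learning_rate == net.learning_rate
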