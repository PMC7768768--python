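"""The bilateral SRN: initialization, forward dynamics, gradients, updates."""

import numpy as np
import pytest

import bilatnet as bn
from bilatnet.network import (
    _block_diag_mask,
    compute_gradients,
    cross_entropy_loss,
    forward_batch,
    train_step,
)
from conftest import make_toy_state


def random_features(seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, (3, 25)).astype(float)


def scrambled_state(seed=3, **kw):
    """A toy state pushed out of the near-linear regime, with gains/lesions."""
    state = make_toy_state(seed=seed, **kw)
    rng = np.random.default_rng(100 + seed)
    for v in state.weight_blocks().values():
        v += rng.normal(0, 0.5, v.shape)
    diag = _block_diag_mask(state.config.n_left, state.config.n_right)
    state.C_ctx *= diag
    state.W_mid *= diag
    state.C_cross *= state.M_cross1
    state.X_cross *= state.M_cross2
    return state


class TestInit:
    def test_capacity_split(self):
        state = bn.init_network(bn.NetworkConfig(n_left=60, n_right=30))
        assert state.layer_slice("LH1") == slice(0, 60)
        assert state.layer_slice("RH2") == slice(60, 90)
        assert state.W_in.shape == (90, 25)

    def test_unilateral_configuration_runs(self, lexicon):
        # single-pathway models (used for capacity-minimum probes) work
        state = bn.init_network(bn.NetworkConfig(n_left=30, n_right=0, seed=1))
        state, log = bn.train(state, lexicon, 200, eval_every=0, rng=0)
        acts = bn.forward_trial(
            state, bn.encode(lexicon.words[0].phonemes, lexicon.inventory))
        assert acts.rh1.shape == (6, 0)
        assert acts.output.shape == (6, 25)

    def test_zero_density_means_no_cross(self, toy_state):
        assert not toy_state.M_cross1.any()
        assert not toy_state.M_cross2.any()
        assert not toy_state.C_cross.any()

    def test_deterministic(self):
        a = bn.init_network(bn.NetworkConfig(seed=7, cross_density=0.5))
        b = bn.init_network(bn.NetworkConfig(seed=7, cross_density=0.5))
        for k, v in a.weight_blocks().items():
            assert np.array_equal(v, b.weight_blocks()[k])
        assert np.array_equal(a.M_cross1, b.M_cross1)

    def test_init_range_uniform(self):
        state = bn.init_network(bn.NetworkConfig(seed=1, init_range=0.2))
        w = state.W_in
        assert w.min() >= -0.2 and w.max() <= 0.2
        # mean |w| of a fresh init is close to init_range / 2
        assert abs(np.abs(w).mean() - 0.1) < 0.01

    def test_negative_only_at_init(self):
        state = bn.init_network(bn.NetworkConfig(
            cross_density=0.5, cross_constraint="negative_only", seed=2))
        assert state.C_cross.max() <= 0
        assert state.X_cross.max() <= 0

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            bn.NetworkConfig(cross_density=1.5)
        with pytest.raises(ValueError):
            bn.NetworkConfig(n_left=-1)
        with pytest.raises(ValueError):
            bn.NetworkConfig(backprop="bogus")


class TestForward:
    def test_six_ticks_and_ranges(self, toy_state):
        acts = bn.forward_trial(toy_state, random_features())
        for arr in (acts.lh1, acts.rh1, acts.lh2, acts.rh2, acts.output):
            assert arr.shape[0] == 6
            assert np.all((arr > 0) & (arr < 1))

    def test_wrong_shape_raises(self, toy_state):
        with pytest.raises(ValueError, match="features"):
            bn.forward_trial(toy_state, np.zeros((2, 25)))

    def test_gain_zero_saturates_at_half(self, toy_state):
        bn.set_layer_gain(toy_state, "LH1", 0.0)
        acts = bn.forward_trial(toy_state, random_features())
        assert np.allclose(acts.lh1, 0.5)

    def test_gain_compresses_toward_half(self):
        # compared at the first tick, where both runs share a zero context
        state = scrambled_state()
        a1 = bn.forward_trial(state, random_features()).lh1[0]
        bn.set_layer_gain(state, "LH1", 0.5)
        a05 = bn.forward_trial(state, random_features()).lh1[0]
        assert np.all(np.abs(a05 - 0.5) < np.abs(a1 - 0.5) + 1e-12)

    def test_gain_one_is_plain_logistic(self):
        state = scrambled_state()
        ref = bn.forward_trial(state, random_features()).output
        bn.set_layer_gain(state, "RH2", 1.0)
        assert np.array_equal(bn.forward_trial(state, random_features()).output, ref)

    def test_out_of_range_gain_raises(self, toy_state):
        with pytest.raises(ValueError):
            bn.set_layer_gain(toy_state, "LH1", 1.2)

    def test_silencing_changes_output(self):
        state = scrambled_state()
        F = random_features()
        full = bn.forward_trial(state, F).output
        left = bn.forward_trial(state, F, silence="right").output
        right = bn.forward_trial(state, F, silence="left").output
        assert not np.allclose(full, left)
        assert not np.allclose(full, right)
        assert not np.allclose(left, right)

    def test_pathway_independence_without_cross(self):
        # with no cross-connections, left H1/H2 ignore right-pathway weights
        state = scrambled_state(seed=9)
        F = random_features()
        before = forward_batch(state, F[None])
        state.W_in[state.right, :] += 1.0
        state.C_ctx[state.right, state.right] += 0.5
        after = forward_batch(state, F[None])
        L = state.left
        assert np.array_equal(before[0][:, :, L], after[0][:, :, L])
        assert np.array_equal(before[1][:, :, L], after[1][:, :, L])
        assert not np.array_equal(before[2], after[2])  # output does change


class TestGradients:
    @pytest.mark.parametrize("cross_density,constraint,lesion,gains", [
        (0.0, "free", False, False),
        (0.5, "free", False, False),
        (0.5, "negative_only", False, False),
        (0.4, "free", True, True),
    ])
    def test_matches_finite_differences(self, cross_density, constraint,
                                        lesion, gains):
        """Analytic gradients agree with central differences on toy nets."""
        state = scrambled_state(cross_density=cross_density,
                                cross_constraint=constraint)
        if gains:
            bn.set_layer_gain(state, "LH1", 0.7)
            bn.set_layer_gain(state, "RH2", 0.3)
        if lesion:
            state.alive1[1] = 0.0
            state.alive2[4] = 0.0
        F = random_features(5)
        _, grads = compute_gradients(state, F)

        diag = _block_diag_mask(state.config.n_left, state.config.n_right)
        allowed = {"C_ctx": diag, "W_mid": diag,
                   "C_cross": state.M_cross1, "X_cross": state.M_cross2}

        def loss_of(s):
            _, _, out = forward_batch(s, F[None])
            return cross_entropy_loss(out[3:, 0], F)

        rng = np.random.default_rng(0)
        eps = 1e-5  # balances truncation against roundoff on a ~50-scale loss
        for name, g in grads.items():
            W = state.weight_blocks()[name]
            mask = allowed.get(name, np.ones(W.shape, bool))
            idx = [ij for ij in np.ndindex(W.shape) if mask[ij]]
            if not idx:
                continue
            sel = [idx[i] for i in
                   rng.choice(len(idx), size=min(12, len(idx)), replace=False)]
            for ij in sel:
                sp, sm = state.copy(), state.copy()
                sp.weight_blocks()[name][ij] += eps
                sm.weight_blocks()[name][ij] -= eps
                fd = (loss_of(sp) - loss_of(sm)) / (2 * eps)
                rel = abs(g[ij] - fd) / max(1e-4, abs(fd), abs(g[ij]))
                assert rel < 1e-5, (name, ij, g[ij], fd)

    def test_dead_units_get_zero_gradient(self):
        state = scrambled_state()
        state.alive1[2] = 0.0
        _, grads = compute_gradients(state, random_features())
        assert np.allclose(grads["W_in"][2, :], 0)
        assert np.allclose(grads["C_ctx"][2, :], 0)
        assert np.allclose(grads["b1"][2], 0)
        assert np.allclose(grads["W_mid"][:, 2], 0)

    def test_gain_zero_layer_unlearnable(self):
        state = scrambled_state()
        bn.set_layer_gain(state, "LH1", 0.0)
        _, grads = compute_gradients(state, random_features())
        L = state.left
        assert np.allclose(grads["W_in"][L, :], 0)
        assert np.allclose(grads["b1"][L], 0)


class TestTrainStep:
    def test_fresh_loss_near_chance(self, toy_state):
        loss = train_step(toy_state, random_features())
        # outputs near 0.5: loss per output unit per tick is about ln 2
        assert 0.5 * 75 * np.log(2) < loss < 2.0 * 75 * np.log(2)

    def test_single_pattern_descent(self):
        state = make_toy_state(n_left=5, n_right=5, seed=2)
        F = random_features(1)
        losses = [train_step(state, F, lr=0.05) for _ in range(50)]
        assert np.all(np.diff(losses) < 0)

    def test_negative_only_never_positive(self):
        state = make_toy_state(cross_density=0.6, seed=4,
                               cross_constraint="negative_only")
        rng = np.random.default_rng(0)
        for _ in range(30):
            train_step(state, rng.integers(0, 2, (3, 25)).astype(float),
                       lr=0.5)
        assert state.C_cross.max() <= 0
        assert state.X_cross.max() <= 0

    def test_masks_preserved_through_updates(self):
        state = make_toy_state(cross_density=0.5, seed=4)
        rng = np.random.default_rng(1)
        for _ in range(10):
            train_step(state, rng.integers(0, 2, (3, 25)).astype(float),
                       lr=0.2)
        diag = _block_diag_mask(state.config.n_left, state.config.n_right)
        assert not state.C_ctx[~diag].any()
        assert not state.W_mid[~diag].any()
        assert not state.C_cross[~state.M_cross1].any()
        assert not state.X_cross[~state.M_cross2].any()

    def test_truncated_mode_backprops_production_ticks_only(self):
        state = scrambled_state(backprop="truncated")
        _, grads = compute_gradients(state, random_features())
        # no error signal reaches the input ticks in truncated mode
        assert np.allclose(grads["W_in"], 0)
        assert not np.allclose(grads["C_ctx"], 0)


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tmp_path, lexicon):
        state = make_toy_state(cross_density=0.3, seed=6)
        feats = bn.encode_words(lexicon.word_triples(), lexicon.inventory)
        for i in range(5):
            train_step(state, feats[i])
        state.alive1[0] = 0.0
        state.lesioned_layers["LH1"] = np.array([0])
        bn.set_layer_gain(state, "LH1", 0.4)
        p = tmp_path / "ckpt.npz"
        bn.save_checkpoint(state, p)
        back = bn.load_checkpoint(p)
        assert back.config == state.config
        for k, v in state.weight_blocks().items():
            assert np.array_equal(v, back.weight_blocks()[k])
        assert np.array_equal(back.alive1, state.alive1)
        assert np.array_equal(back.g1, state.g1)
        assert np.array_equal(back.lesioned_layers["LH1"],
                              state.lesioned_layers["LH1"])


class TestDeterminism:
    def test_identical_seed_and_sequence_bit_identical(self, lexicon):
        feats = bn.encode_words(lexicon.word_triples(), lexicon.inventory)
        from bilatnet._kernels import train_block
        final = []
        for _ in range(2):
            state = make_toy_state(n_left=6, n_right=4, seed=11)
            idx = np.random.default_rng(5).choice(
                200, size=200, p=lexicon.presentation_probs)
            train_block(state, idx, feats)
            final.append(state)
        for k, v in final[0].weight_blocks().items():
            assert np.array_equal(v, final[1].weight_blocks()[k])

    def test_kernel_matches_reference(self, lexicon):
        """The compiled kernel reproduces the numpy reference numerics."""
        from bilatnet._kernels import train_block
        feats = bn.encode_words(lexicon.word_triples(), lexicon.inventory)
        s1 = make_toy_state(n_left=6, n_right=4, cross_density=0.4, seed=5,
                            learning_rate=0.05)
        s2 = s1.copy()
        idx = np.random.default_rng(0).choice(
            200, size=150, p=lexicon.presentation_probs)
        l1 = train_block(s1, idx, feats)
        l2 = sum(train_step(s2, feats[i]) for i in idx)
        assert l1 == pytest.approx(l2, rel=1e-9)
        for k, v in s1.weight_blocks().items():
            assert np.allclose(v, s2.weight_blocks()[k], atol=1e-12)
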