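"""Aggregator contracts: per-arch forward semantics, attention arithmetic,
additive decomposition, permutation invariance, and gradient correctness
of every architecture's training loss."""

import numpy as np
import pytest

import milrel.autodiff as ad
from milrel.autodiff import Tensor
from milrel.bagcore import InstanceBag, ScoreChannel
from milrel.milmodels import ModelConfig, build_model, config_from_name
from milrel.milmodels.archs import _selection_scores
from milrel.milmodels.layers import GatedAttention, Linear

SMALL = dict(input_dim=12, embed_dim=8, attn_dim=4, heads=2, pseudo_bags=3)

ALL_MODELS = [
    "mean_pool", "max_pool", "mean_pool_ins", "max_pool_ins", "abmil",
    "clam", "madmil/2", "acmil/2", "dtfd", "abmil-add", "clam-add", "acmil/2-add",
]


def _bag(rng, n=7, d=12, label=1, seed_coords=None):
    cells = rng.choice(64, size=n, replace=False)
    coords = np.stack([cells % 8, cells // 8], axis=1) * 256
    return InstanceBag("s", rng.normal(size=(n, d)).astype(np.float32), coords,
                       bag_label=label)


@pytest.fixture(autouse=True)
def float64_mode():
    prev = ad.get_default_dtype()
    ad.set_default_dtype(np.float64)
    yield
    ad.set_default_dtype(prev)


class TestCompressor:
    def test_zero_weights_zero_output(self):
        model = build_model(ModelConfig(arch="mean_pool", **SMALL))
        for p in model.compress.parameters():
            p.data[...] = 0.0
        out = model.compress(Tensor(np.zeros((3, 12))))
        assert np.all(out.data == 0)

    def test_instance_wise_independence(self, rng):
        model = build_model(ModelConfig(arch="mean_pool", **SMALL))
        x = rng.normal(size=(5, 12))
        one = model.compress(Tensor(x[:1])).data
        five = model.compress(Tensor(x)).data
        np.testing.assert_allclose(five[0], one[0], rtol=1e-12)

    def test_default_layer_parameter_count(self):
        model = build_model(ModelConfig(arch="mean_pool"))
        n = sum(p.data.size for p in model.compress.parameters())
        assert n == 1024 * 512 + 512 == 524_800


class TestGatedAttention:
    def test_singleton_bag(self, rng):
        attn = GatedAttention(4, 3, rng)
        w = attn(Tensor(rng.normal(size=(1, 4))))
        np.testing.assert_allclose(w.data, [1.0])

    def test_identical_embeddings_uniform(self, rng):
        attn = GatedAttention(4, 3, rng)
        H = np.tile(rng.normal(size=4), (4, 1))
        np.testing.assert_allclose(attn(Tensor(H)).data, np.full(4, 0.25), rtol=1e-9)

    def test_hand_set_weights(self):
        """D=2, attn_dim=1, hand-set V, U, w on 2 instances: the weights
        equal the softmax of w*(tanh(Vh) * sigmoid(Uh)) + b computed by
        hand."""
        attn = GatedAttention(2, 1, np.random.default_rng(0))
        attn.V.W.data[...] = [[1.0], [0.5]]
        attn.V.b.data[...] = 0.0
        attn.U.W.data[...] = [[-1.0], [2.0]]
        attn.U.b.data[...] = 0.1
        attn.w.W.data[...] = [[2.0]]
        attn.w.b.data[...] = -0.3
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        gate = np.tanh(H @ [[1.0], [0.5]]) / (1 + np.exp(-(H @ [[-1.0], [2.0]] + 0.1)))
        logits = (gate * 2.0 - 0.3).ravel()
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(attn(Tensor(H)).data, expected, rtol=1e-12)

    def test_weights_on_simplex(self, rng):
        attn = GatedAttention(6, 4, rng)
        w = attn(Tensor(rng.normal(size=(9, 6)))).data
        assert np.all(w >= 0) and np.isclose(w.sum(), 1.0)


class TestForwardContracts:
    def test_mean_pool_emits_no_scores(self, rng):
        out = build_model(ModelConfig(arch="mean_pool", **SMALL)).forward(_bag(rng))
        assert out.score_sets == []

    def test_selection_scores_argmax_fraction(self):
        # two instances with embeddings (1,0) and (0,1): each wins half the dims
        np.testing.assert_allclose(
            _selection_scores(np.array([[1.0, 0.0], [0.0, 1.0]])), [0.5, 0.5])
        # ties split equally
        np.testing.assert_allclose(
            _selection_scores(np.array([[1.0, 2.0], [1.0, 0.0]])), [0.75, 0.25])

    def test_max_pool_selection_sums_to_one(self, rng):
        out = build_model(ModelConfig(arch="max_pool", **SMALL)).forward(_bag(rng))
        (sel,) = out.score_sets
        assert sel.channel is ScoreChannel.selection
        assert sel.scores.sum() == pytest.approx(1.0)

    def test_mean_pool_ins_bag_prob_is_instance_mean(self, rng):
        model = build_model(ModelConfig(arch="mean_pool_ins", **SMALL))
        bag = _bag(rng)
        out = model.forward(bag)
        (pp,) = out.score_sets
        H = model.compress(Tensor(bag.features)).data
        L = H @ model.clf.W.data + model.clf.b.data
        P = np.exp(L) / np.exp(L).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out.probs, P.mean(axis=0), rtol=1e-9)
        np.testing.assert_allclose(pp.scores, P[:, 1], rtol=1e-9)

    def test_mean_pool_ins_two_instance_example(self, rng):
        """Instances with positive-class probabilities 0.2 and 0.8 pool to
        a bag positive probability of 0.5."""
        model = build_model(ModelConfig(arch="mean_pool_ins", **SMALL))
        bag = _bag(rng, n=2)
        # rig classifier so instance probs are exactly (0.2, 0.8)
        H = model.compress(Tensor(bag.features)).data
        target = np.log(np.array([[0.8, 0.2], [0.2, 0.8]]))
        model.clf.W.data[...] = np.linalg.lstsq(H, target, rcond=None)[0]
        model.clf.b.data[...] = target[0] - H[0] @ model.clf.W.data
        out = model.forward(bag)
        assert out.probs[1] == pytest.approx(0.5, abs=1e-6)

    def test_max_pool_ins_emits_both_channels(self, rng):
        out = build_model(ModelConfig(arch="max_pool_ins", **SMALL)).forward(_bag(rng))
        channels = [s.channel for s in out.score_sets]
        assert channels == [ScoreChannel.selection, ScoreChannel.patch_prob]

    def test_abmil_on_identical_instances_equals_mean_pool(self, rng):
        """With all-equal instances attention is uniform, so abmil's
        prediction coincides with mean pooling under shared weights."""
        abmil = build_model(ModelConfig(arch="abmil", **SMALL))
        meanp = build_model(ModelConfig(arch="mean_pool", **SMALL))
        for src, dst in zip(abmil.compress.parameters() + abmil.clf.parameters(),
                            meanp.compress.parameters() + meanp.clf.parameters()):
            dst.data[...] = src.data
        feats = np.tile(rng.normal(size=12).astype(np.float32), (5, 1))
        coords = np.stack([np.arange(5), np.zeros(5, int)], axis=1) * 256
        bag = InstanceBag("s", feats, coords, bag_label=1)
        np.testing.assert_allclose(abmil.forward(bag).logits,
                                   meanp.forward(bag).logits, rtol=1e-6)

    def test_attention_channels_on_simplex(self, rng):
        bag = _bag(rng, n=9)
        for name in ["abmil", "clam", "madmil/2", "acmil/2"]:
            out = build_model(config_from_name(name, **SMALL)).forward(bag)
            a = out.score_sets[0]
            assert a.channel is ScoreChannel.attention
            assert a.scores.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(a.scores >= 0)

    def test_dtfd_patch_prob_in_unit_interval(self, rng):
        out = build_model(ModelConfig(arch="dtfd", **SMALL)).forward(_bag(rng, n=8))
        (pp,) = out.score_sets
        assert pp.channel is ScoreChannel.patch_prob
        assert pp.scores.min() >= 0 and pp.scores.max() <= 1

    def test_additive_logit_decomposition(self, rng):
        """The additive reformulation's bag logit equals the exact sum of
        per-instance contributions."""
        bag = _bag(rng, n=6)
        for name in ["abmil-add", "clam-add", "acmil/2-add"]:
            model = build_model(config_from_name(name, **SMALL))
            logits, _, info = model._run(Tensor(bag.features), bag)
            np.testing.assert_allclose(
                logits.data, info["contrib"].sum(axis=0), atol=1e-5)
            out = model.forward(bag)
            assert len(out.score_sets) == 2
            assert out.score_sets[1].channel is ScoreChannel.patch_prob

    def test_dim_mismatch_raises(self, rng):
        model = build_model(ModelConfig(arch="abmil", **SMALL))
        bag = _bag(rng, d=12)
        bad = InstanceBag("s", np.ones((3, 5), np.float32),
                          np.array([[0, 0], [256, 0], [512, 0]]))
        model.forward(bag)
        with pytest.raises(ValueError):
            model.forward(bad)


class TestPermutationInvariance:
    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_permuting_instances_permutes_scores_only(self, name, rng):
        model = build_model(config_from_name(name, **SMALL))
        bag = _bag(rng, n=8)
        perm = rng.permutation(8)
        permuted = InstanceBag("s", bag.features[perm], bag.coords[perm],
                               bag_label=bag.bag_label)
        out1, out2 = model.forward(bag), model.forward(permuted)
        np.testing.assert_allclose(out2.logits, out1.logits, atol=1e-9)
        for s1, s2 in zip(out1.score_sets, out2.score_sets):
            np.testing.assert_allclose(s2.scores, s1.scores[perm], atol=1e-9)


class TestLossGradients:
    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_loss_gradient_matches_finite_differences(self, name, rng):
        model = build_model(config_from_name(name, **SMALL))
        bag = _bag(rng, n=6)
        loss = model.loss(bag)
        loss.backward()
        # spot-check a handful of coordinates in every parameter tensor
        for p in model.parameters():
            flat = p.data.reshape(-1)
            grad = (p.grad if p.grad is not None else np.zeros_like(p.data)).reshape(-1)
            idx = rng.choice(flat.size, size=min(4, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                eps = 1e-5
                flat[i] = orig + eps
                hi = model.loss(bag).item()
                flat[i] = orig - eps
                lo = model.loss(bag).item()
                flat[i] = orig
                num = (hi - lo) / (2 * eps)
                assert grad[i] == pytest.approx(num, rel=5e-4, abs=1e-7), (name, i)

    def test_loss_decreases_under_adam(self, rng):
        from milrel.autodiff import Adam

        model = build_model(ModelConfig(arch="abmil", **SMALL))
        bags = [_bag(rng, label=i % 2) for i in range(6)]
        opt = Adam(model.parameters(), lr=1e-2)
        def total():
            return sum(model.loss(b).item() for b in bags)
        before = total()
        for _ in range(30):
            for b in bags:
                opt.zero_grad()
                model.loss(b).backward()
                opt.step()
        assert total() < before
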