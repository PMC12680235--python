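"""The MIL aggregator family.

Every architecture shares one contract: a bag of patch features goes in,
slide-level class logits come out, together with zero or more per-patch
score sets (attention weights, patch probabilities, or max-selection
indicators) that downstream reliability evaluation consumes.

All aggregators start with the same instance-wise feature compressor
(input_dim -> D affine + ReLU) and differ only in how instance embeddings
are pooled into a slide representation:

* ``mean_pool`` / ``max_pool`` — element-wise mean / max of embeddings,
  then a linear classifier. Mean pooling yields no patch scores; max
  pooling scores each instance by the fraction of embedding dimensions it
  wins in the element-wise max (ties split equally).
* ``mean_pool_ins`` / ``max_pool_ins`` — instance-level variants: a linear
  classifier scores every instance, and instance class probabilities are
  mean-pooled (or class logits max-pooled) into the slide prediction.
* ``abmil`` — gated-attention pooling; the attention weights are the patch
  scores.
* ``clam_lite`` — abmil plus per-class instance-scoring heads trained with
  an auxiliary top-k/bottom-k instance loss.
* ``madmil`` — multi-head attention over contiguous slices of the
  embedding; patch score = head-mean attention.
* ``acmil_lite`` — multiple attention branches sharing the gate, averaged
  bag representations, with a branch-diversity penalty.
* ``dtfd`` — two-tier pooling over pseudo-bags with gradient-based
  instance attribution as the patch-probability channel.

Setting ``additive=True`` on an attention architecture reformulates the
classifier as an additive function of instances: the bag logit is the
exact sum of per-instance contributions, which yields a second,
contribution-based score channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..autodiff import Parameter, Tensor, concat, cross_entropy, stack
from ..bagcore import InstanceBag, PatchScoreSet, ScoreChannel
from .layers import Compressor, GatedAttention, Linear

ARCHS = (
    "mean_pool", "max_pool", "mean_pool_ins", "max_pool_ins",
    "abmil", "clam_lite", "madmil", "dtfd", "acmil_lite",
)

_ATTENTION_ARCHS = ("abmil", "clam_lite", "acmil_lite", "madmil")


@dataclass
class ModelConfig:
    arch: str = "abmil"
    additive: bool = False
    n_classes: int = 2
    input_dim: int = 1024
    embed_dim: int = 512        # D
    attn_dim: int = 256
    heads: int = 2              # madmil / acmil_lite
    pseudo_bags: int = 8        # dtfd: M
    instance_loss_weight: float = 0.3   # clam_lite
    instance_topk: int = 8              # clam_lite
    diversity_weight: float = 0.1       # acmil_lite
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.arch == "madmil" and (self.embed_dim % self.heads or self.attn_dim % self.heads):
            raise ValueError("madmil requires embed_dim and attn_dim divisible by heads")
        if self.arch == "dtfd" and self.pseudo_bags < 2:
            raise ValueError("dtfd requires pseudo_bags >= 2")
        if self.additive and self.arch not in _ATTENTION_ARCHS:
            raise ValueError("additive form applies to attention architectures only")


@dataclass
class ModelOutput:
    logits: np.ndarray
    score_sets: list[PatchScoreSet] = field(default_factory=list)

    @property
    def probs(self) -> np.ndarray:
        z = self.logits - self.logits.max()
        e = np.exp(z)
        return e / e.sum()


def _np(t: Tensor) -> np.ndarray:
    return np.asarray(t.data)


class MILModel:
    """Base class: owns the compressor, the classifier and the seed."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.compress = Compressor(cfg.input_dim, cfg.embed_dim, rng)
        self._build(cfg, rng)

    def _build(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        raise NotImplementedError

    # Subclasses return (bag logits Tensor, aux-loss Tensor or None, eval dict).
    def _run(self, X: Tensor, bag: InstanceBag):
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        params = list(self.compress.parameters())
        for layer in self._layers():
            params.extend(layer.parameters())
        return params

    def _layers(self):
        return []

    def forward(self, bag: InstanceBag) -> ModelOutput:
        if bag.features.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"bag feature dim {bag.features.shape[1]} != input_dim {self.cfg.input_dim}")
        logits, _, info = self._run(Tensor(bag.features), bag)
        return ModelOutput(logits=_np(logits).copy(),
                           score_sets=self._score_sets(bag, _np(logits), info))

    def loss(self, bag: InstanceBag) -> Tensor:
        logits, aux, _ = self._run(Tensor(bag.features), bag)
        ce = cross_entropy(logits, bag.bag_label)
        return ce + aux if aux is not None else ce

    def _score_sets(self, bag: InstanceBag, logits: np.ndarray, info: dict) -> list[PatchScoreSet]:
        return []

    def _context(self, logits: np.ndarray) -> int:
        """Class whose score channel is reported: positive class for binary
        tasks, the bag's predicted class otherwise."""
        return 1 if self.cfg.n_classes == 2 else int(np.argmax(logits))


def _selection_scores(values: np.ndarray) -> np.ndarray:
    """Fraction of columns won by each row under column-wise max, ties split."""
    n, d = values.shape
    top = values.max(axis=0, keepdims=True)
    winners = values == top
    share = winners / winners.sum(axis=0, keepdims=True)
    return share.sum(axis=1) / d


def _renorm(a: np.ndarray) -> np.ndarray:
    s = a.sum()
    return a / s if s > 0 else np.full_like(a, 1.0 / len(a))


# ---------------------------------------------------------------------------


class MeanPool(MILModel):
    def _build(self, cfg, rng):
        self.clf = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def _layers(self):
        return [self.clf]

    def _run(self, X, bag):
        H = self.compress(X)
        logits = self.clf(H.mean(axis=0))
        return logits, None, {}


class MaxPool(MILModel):
    def _build(self, cfg, rng):
        self.clf = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def _layers(self):
        return [self.clf]

    def _run(self, X, bag):
        H = self.compress(X)
        logits = self.clf(H.max(axis=0))
        return logits, None, {"H": _np(H)}

    def _score_sets(self, bag, logits, info):
        return [PatchScoreSet(bag.slide_id, _selection_scores(info["H"]),
                              ScoreChannel.selection, self._context(logits))]


class MeanPoolIns(MILModel):
    """Instance-level classifier; the bag probability is the instance mean."""

    def _build(self, cfg, rng):
        self.clf = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def _layers(self):
        return [self.clf]

    def _run(self, X, bag):
        H = self.compress(X)
        P = self.clf(H).softmax(axis=-1)          # (N, C) instance probabilities
        logits = P.mean(axis=0).log()             # log of mean prob; CE gives -log p_y
        return logits, None, {"P": _np(P)}

    def _score_sets(self, bag, logits, info):
        ctx = self._context(logits)
        return [PatchScoreSet(bag.slide_id, info["P"][:, ctx],
                              ScoreChannel.patch_prob, ctx)]


class MaxPoolIns(MILModel):
    """Per-class bag logit = max over instance logits; emits a selection
    channel (class-winning instances) and a patch-probability channel."""

    def _build(self, cfg, rng):
        self.clf = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def _layers(self):
        return [self.clf]

    def _run(self, X, bag):
        H = self.compress(X)
        L = self.clf(H)                           # (N, C) instance logits
        logits = L.max(axis=0)
        P = L.softmax(axis=-1)
        return logits, None, {"L": _np(L), "P": _np(P)}

    def _score_sets(self, bag, logits, info):
        ctx = self._context(logits)
        sel = _selection_scores(info["L"])
        return [
            PatchScoreSet(bag.slide_id, sel, ScoreChannel.selection, ctx),
            PatchScoreSet(bag.slide_id, info["P"][:, ctx], ScoreChannel.patch_prob, ctx),
        ]


class _AttentionBase(MILModel):
    """Shared logic for single-attention-vector architectures (abmil and
    clam_lite), including the additive reformulation."""

    def _build(self, cfg, rng):
        self.attention = GatedAttention(cfg.embed_dim, cfg.attn_dim, rng)
        self.clf = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def _layers(self):
        return [self.attention, self.clf]

    def _pool(self, X):
        H = self.compress(X)
        a = self.attention(H)
        if self.cfg.additive:
            contrib = self.clf(a.reshape(-1, 1) * H)   # (N, C) instance contributions
            logits = contrib.sum(axis=0)
            return H, a, logits, contrib
        logits = self.clf(a @ H)
        return H, a, logits, None

    def _run(self, X, bag):
        H, a, logits, contrib = self._pool(X)
        aux = self._aux_loss(H, a, bag)
        info = {"a": _np(a)}
        if contrib is not None:
            info["contrib"] = _np(contrib)
        return logits, aux, info

    def _aux_loss(self, H, a, bag):
        return None

    def _score_sets(self, bag, logits, info):
        ctx = self._context(logits)
        sets = [PatchScoreSet(bag.slide_id, _renorm(info["a"]),
                              ScoreChannel.attention, ctx)]
        if "contrib" in info:
            c = info["contrib"]
            e = np.exp(c - c.max(axis=1, keepdims=True))
            probs = e / e.sum(axis=1, keepdims=True)
            sets.append(PatchScoreSet(bag.slide_id, probs[:, ctx],
                                      ScoreChannel.patch_prob, ctx))
        return sets


class ABMIL(_AttentionBase):
    pass


class CLAMLite(_AttentionBase):
    """Attention pooling with per-class instance heads and an auxiliary
    instance loss on the top-k / bottom-k attention patches."""

    def _build(self, cfg, rng):
        super()._build(cfg, rng)
        self.instance_heads = [
            Linear(cfg.embed_dim, cfg.n_classes, rng) for _ in range(cfg.n_classes)
        ]

    def _layers(self):
        return [self.attention, self.clf] + self.instance_heads

    def _aux_loss(self, H, a, bag):
        n = H.shape[0]
        k = min(self.cfg.instance_topk, n // 2)
        if k < 1:
            return None
        order = np.argsort(_np(a))
        top, bottom = order[-k:], order[:k]
        head = self.instance_heads[bag.bag_label]
        loss = None
        for idx, target in [(top, bag.bag_label), (bottom, 0)]:
            sel = head(H[np.sort(idx)]).log_softmax(axis=-1)
            term = -sel[:, target].mean()
            loss = term if loss is None else loss + term
        return loss * (self.cfg.instance_loss_weight / 2.0)


class MADMIL(MILModel):
    """Multi-head attention over contiguous embedding slices; each head runs
    gated attention on its D/heads sub-embedding with attn_dim/heads gate
    width, and the per-head weighted sums are concatenated."""

    def _build(self, cfg, rng):
        self.sub = cfg.embed_dim // cfg.heads
        self.head_attn = [
            GatedAttention(self.sub, cfg.attn_dim // cfg.heads, rng)
            for _ in range(cfg.heads)
        ]
        self.clf = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def _layers(self):
        return self.head_attn + [self.clf]

    def _run(self, X, bag):
        H = self.compress(X)
        reps, attns = [], []
        for k, attn in enumerate(self.head_attn):
            Hk = H[:, k * self.sub:(k + 1) * self.sub]
            ak = attn(Hk)
            reps.append(ak @ Hk)
            attns.append(_np(ak))
        logits = self.clf(concat(reps, axis=0))
        return logits, None, {"attns": np.array(attns)}

    def _score_sets(self, bag, logits, info):
        mean_a = _renorm(info["attns"].mean(axis=0))
        return [PatchScoreSet(bag.slide_id, mean_a, ScoreChannel.attention,
                              self._context(logits))]


class ACMILLite(MILModel):
    """Multiple attention branches sharing the gate projections (separate
    scoring vectors); bag representation is the branch mean, trained with a
    penalty on pairwise cosine similarity of branch attention vectors."""

    def _build(self, cfg, rng):
        self.attention = GatedAttention(cfg.embed_dim, cfg.attn_dim, rng)
        self.branch_w = [Linear(cfg.attn_dim, 1, rng) for _ in range(cfg.heads - 1)]
        self.clf = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def _layers(self):
        return [self.attention] + self.branch_w + [self.clf]

    def _branch_attentions(self, H):
        gate = self.attention.gate(H)
        branches = [self.attention.w(gate).reshape(-1).softmax(axis=-1)]
        branches += [w(gate).reshape(-1).softmax(axis=-1) for w in self.branch_w]
        return branches

    def _run(self, X, bag):
        H = self.compress(X)
        branches = self._branch_attentions(H)
        A = stack(branches, axis=0)               # (heads, N)
        mean_a = A.mean(axis=0)
        if self.cfg.additive:
            contrib = self.clf(mean_a.reshape(-1, 1) * H)
            logits = contrib.sum(axis=0)
        else:
            contrib = None
            reps = stack([a @ H for a in branches], axis=0)
            logits = self.clf(reps.mean(axis=0))
        aux = self._diversity(branches) if len(branches) > 1 else None
        info = {"a": _np(mean_a)}
        if contrib is not None:
            info["contrib"] = _np(contrib)
        return logits, aux, info

    def _diversity(self, branches):
        total, pairs = None, 0
        for i in range(len(branches)):
            for j in range(i + 1, len(branches)):
                ai, aj = branches[i], branches[j]
                cos = (ai * aj).sum() * ((ai * ai).sum() * (aj * aj).sum()) ** -0.5
                total = cos if total is None else total + cos
                pairs += 1
        return total * (self.cfg.diversity_weight / pairs)

    def _score_sets(self, bag, logits, info):
        ctx = self._context(logits)
        sets = [PatchScoreSet(bag.slide_id, _renorm(info["a"]),
                              ScoreChannel.attention, ctx)]
        if "contrib" in info:
            c = info["contrib"]
            e = np.exp(c - c.max(axis=1, keepdims=True))
            probs = e / e.sum(axis=1, keepdims=True)
            sets.append(PatchScoreSet(bag.slide_id, probs[:, ctx],
                                      ScoreChannel.patch_prob, ctx))
        return sets


class DTFD(MILModel):
    """Two-tier pooling: instances are partitioned into M pseudo-bags; a
    shared tier-1 attention + classifier summarizes each pseudo-bag (with a
    pseudo-bag-level loss on the slide label), and a tier-2 attention +
    classifier aggregates the M pseudo-bag features into the slide logits.

    The patch-probability channel is a gradient-times-input attribution of
    the tier-1 predicted-class logit with respect to each instance
    embedding (a_i * (w_c . h_i) for the linear head), min-max mapped to
    [0, 1]. The partition is a spatial round-robin over the canonical
    coordinate order, so it is deterministic and permutation-invariant.
    """

    def _build(self, cfg, rng):
        self.attn1 = GatedAttention(cfg.embed_dim, cfg.attn_dim, rng)
        self.clf1 = Linear(cfg.embed_dim, cfg.n_classes, rng)
        self.attn2 = GatedAttention(cfg.embed_dim, cfg.attn_dim, rng)
        self.clf2 = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def _layers(self):
        return [self.attn1, self.clf1, self.attn2, self.clf2]

    def _partition(self, bag: InstanceBag) -> list[np.ndarray]:
        order = np.lexsort((bag.coords[:, 0], bag.coords[:, 1]))
        m = min(self.cfg.pseudo_bags, bag.n_instances)
        return [order[j::m] for j in range(m)]

    def _run(self, X, bag):
        H = self.compress(X)
        groups = self._partition(bag)
        feats, t1_loss = [], None
        attn_full = np.zeros(bag.n_instances)
        for idx in groups:
            idx = np.sort(idx)
            Hj = H[idx]
            aj = self.attn1(Hj)
            fj = aj @ Hj
            feats.append(fj)
            lj = cross_entropy(self.clf1(fj), bag.bag_label)
            t1_loss = lj if t1_loss is None else t1_loss + lj
            attn_full[idx] = _np(aj)
        F = stack(feats, axis=0)                  # (M, D)
        a2 = self.attn2(F)
        logits = self.clf2(a2 @ F)
        aux = t1_loss * (1.0 / len(groups))
        return logits, aux, {"H": _np(H), "attn1": attn_full}

    def _score_sets(self, bag, logits, info):
        ctx = self._context(logits)
        wc = self.clf1.W.data[:, ctx]
        attribution = info["attn1"] * (info["H"] @ wc)
        lo, hi = attribution.min(), attribution.max()
        scores = (attribution - lo) / (hi - lo) if hi > lo else np.full_like(attribution, 0.5)
        return [PatchScoreSet(bag.slide_id, scores, ScoreChannel.patch_prob, ctx)]


_BUILDERS: dict[str, Callable[[ModelConfig], MILModel]] = {
    "mean_pool": MeanPool,
    "max_pool": MaxPool,
    "mean_pool_ins": MeanPoolIns,
    "max_pool_ins": MaxPoolIns,
    "abmil": ABMIL,
    "clam_lite": CLAMLite,
    "madmil": MADMIL,
    "dtfd": DTFD,
    "acmil_lite": ACMILLite,
}


def build_model(cfg: ModelConfig) -> MILModel:
    return _BUILDERS[cfg.arch](cfg)
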