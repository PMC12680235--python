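"""Exact parameter and FLOPs accounting for the aggregator family.

Parameter counts enumerate every trainable scalar (weights and biases).
FLOPs are reported as multiply-accumulate (MAC) counts for one inference
forward pass at a given bag size: only weight multiplications are counted
(biases, nonlinearities and activation-activation products such as the
attention-weighted sum are excluded), instance-wise layers count once per
instance, and bag-level layers once per bag. Training-only components
(e.g. the clam_lite instance heads) do not contribute to FLOPs.
"""

from __future__ import annotations

from .archs import MILModel, ModelConfig


def count_params(model: MILModel) -> int:
    """Exact number of trainable scalars in a built model."""
    return sum(p.data.size for p in model.parameters())


def _attention_macs(d: int, attn: int) -> int:
    # V and U projections plus the scoring vector, per application
    return 2 * d * attn + attn


def count_flops(model_or_cfg: MILModel | ModelConfig, n_instances: int = 120) -> int:
    """MAC count of one forward pass at ``n_instances`` instances per bag.

    ``n_instances=0`` returns the bag-level (classifier-only) count.
    """
    cfg = model_or_cfg.cfg if isinstance(model_or_cfg, MILModel) else model_or_cfg
    d_in, d, attn, c = cfg.input_dim, cfg.embed_dim, cfg.attn_dim, cfg.n_classes
    per_instance = d_in * d     # feature compression
    per_bag = 0

    if cfg.arch in ("mean_pool", "max_pool"):
        per_bag = d * c
    elif cfg.arch in ("mean_pool_ins", "max_pool_ins"):
        per_instance += d * c
    elif cfg.arch in ("abmil", "clam_lite"):
        per_instance += _attention_macs(d, attn)
        if cfg.additive:
            per_instance += d * c
        else:
            per_bag = d * c
    elif cfg.arch == "acmil_lite":
        # shared V/U gate, one scoring vector per branch
        per_instance += 2 * d * attn + cfg.heads * attn
        if cfg.additive:
            per_instance += d * c
        else:
            per_bag = d * c
    elif cfg.arch == "madmil":
        sub, sub_attn = d // cfg.heads, attn // cfg.heads
        per_instance += cfg.heads * _attention_macs(sub, sub_attn)
        per_bag = d * c
    elif cfg.arch == "dtfd":
        per_instance += _attention_macs(d, attn)          # tier-1 attention
        m = cfg.pseudo_bags
        per_bag = m * d * c                               # tier-1 classifiers
        per_bag += m * _attention_macs(d, attn)           # tier-2 attention
        per_bag += d * c                                  # tier-2 classifier
    else:  # pragma: no cover
        raise ValueError(f"unknown arch {cfg.arch!r}")

    return n_instances * per_instance + per_bag


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def format_params(n: int) -> str:
    """Parameter count in the conventional thousands notation, e.g. '526 K'."""
    return f"{_round_half_up(n / 1000)} K"


def format_flops(n: int) -> str:
    """MAC count in the conventional millions notation, e.g. '63 M'."""
    return f"{_round_half_up(n / 1e6)} M"
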