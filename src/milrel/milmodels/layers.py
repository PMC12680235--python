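"""Building blocks shared by the MIL aggregators."""

from __future__ import annotations

import numpy as np

from ..autodiff import Parameter, Tensor


class Linear:
    """Affine map ``x @ W + b`` with ``W: (d_in, d_out)``."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(d_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))
        self.d_in, self.d_out = d_in, d_out

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class Compressor:
    """The feature-compression layer: input_dim -> D affine map + ReLU.

    Applied instance-wise; every aggregator starts with it.
    """

    def __init__(self, input_dim: int, embed_dim: int, rng: np.random.Generator):
        self.lin = Linear(input_dim, embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin(x).relu()

    def parameters(self) -> list[Parameter]:
        return self.lin.parameters()


class GatedAttention:
    """Gated attention scoring over a bag of embeddings.

    ``a = softmax_i( w . ( tanh(V h_i) * sigmoid(U h_i) ) )`` with
    ``V, U: D -> attn_dim`` (with bias) and ``w: attn_dim -> 1`` (with
    bias); the output is a convex weight vector over the bag.
    """

    def __init__(self, embed_dim: int, attn_dim: int, rng: np.random.Generator):
        self.V = Linear(embed_dim, attn_dim, rng)
        self.U = Linear(embed_dim, attn_dim, rng)
        self.w = Linear(attn_dim, 1, rng)

    def gate(self, H: Tensor) -> Tensor:
        return self.V(H).tanh() * self.U(H).sigmoid()

    def logits(self, H: Tensor) -> Tensor:
        return self.w(self.gate(H)).reshape(-1)

    def __call__(self, H: Tensor) -> Tensor:
        return self.logits(H).softmax(axis=-1)

    def parameters(self) -> list[Parameter]:
        return self.V.parameters() + self.U.parameters() + self.w.parameters()
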