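"""Multi-head graph attention layer.

For each head k with projection ``H_k`` and attention vector
``a_k = [a_src ; a_dst]`` the unnormalized score of neighbour j for node i is

    e_ij = LeakyReLU( a_src . H_k x_i  +  a_dst . H_k x_j )

restricted to the first-order neighbourhood ``N_i = {j : adj[i, j] > 0}``.
Scores are softmax-normalized over ``N_i`` (rows of the attention matrix are
stochastic on the neighbourhood, zero elsewhere), the neighbourhood features
are averaged with those coefficients, passed through ELU, and the K head
outputs are concatenated.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .layers import Layer, Param, glorot_uniform

_NEG = -1e30  # additive mask for non-neighbours before the softmax


class GATLayer(Layer):
    def __init__(
        self,
        d_in: int,
        d_head: int,
        heads: int,
        rng: np.random.Generator,
        leaky_slope: float = 0.2,
        activation: str = "elu",
        dtype=np.float32,
    ):
        if heads < 1 or d_head < 1:
            raise ValueError("need at least one head and one output dim per head")
        self.W = glorot_uniform(rng, (heads, d_head, d_in), d_in, d_head, dtype)
        self.a_src = glorot_uniform(rng, (heads, d_head), 2 * d_head, 1, dtype)
        self.a_dst = glorot_uniform(rng, (heads, d_head), 2 * d_head, 1, dtype)
        self.dW = np.zeros_like(self.W)
        self.da_src = np.zeros_like(self.a_src)
        self.da_dst = np.zeros_like(self.a_dst)
        self.heads, self.d_head, self.d_in = heads, d_head, d_in
        self.leaky_slope = leaky_slope
        self.activation = activation
        self.attention: Optional[np.ndarray] = None  # (B, K, n, n) of the last forward
        self._cache = None

    @property
    def d_out(self) -> int:
        return self.heads * self.d_head

    def forward(self, x: np.ndarray, adj: np.ndarray, training: bool = True) -> np.ndarray:
        """(B, n, d_in) + (n, n) adjacency -> (B, n, K*d_head)."""
        B, n, _ = x.shape
        mask = np.asarray(adj) > 0
        if not mask.any(axis=1).all():
            isolated = np.where(~mask.any(axis=1))[0]
            raise ValueError(f"isolated nodes (empty neighbourhood): {isolated.tolist()}")
        # Z[b,k,i,:] = H_k x_i
        Z = np.matmul(x[:, None, :, :], self.W.transpose(0, 2, 1)[None])
        s = (Z * self.a_src[None, :, None, :]).sum(-1)  # (B,K,n) source terms
        t = (Z * self.a_dst[None, :, None, :]).sum(-1)  # (B,K,n) neighbour terms
        E = s[..., :, None] + t[..., None, :]  # (B,K,n,n), e_ij before LeakyReLU
        pos = E > 0
        Eact = np.where(pos, E, self.leaky_slope * E)
        Eact = np.where(mask, Eact, np.array(_NEG, dtype=Eact.dtype))
        Eact = Eact - Eact.max(axis=-1, keepdims=True)
        A = np.exp(Eact)
        A = np.where(mask, A, 0)
        A /= A.sum(axis=-1, keepdims=True)
        M = np.matmul(A, Z)  # (B,K,n,d_head) aggregated neighbourhood features
        if self.activation == "elu":
            mpos = M > 0
            expm1 = np.expm1(np.minimum(M, 0))
            out_h = np.where(mpos, M, expm1)
        else:
            mpos = expm1 = None
            out_h = M
        self.attention = A
        self._cache = (x, Z, A, pos, mask, mpos, expm1)
        # concatenate heads: (B,K,n,d) -> (B,n,K*d)
        return out_h.transpose(0, 2, 1, 3).reshape(B, n, self.d_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, Z, A, pos, mask, mpos, expm1 = self._cache
        B, n, _ = x.shape
        dH = dout.reshape(B, n, self.heads, self.d_head).transpose(0, 2, 1, 3)
        if self.activation == "elu":
            dM = dH * np.where(mpos, 1.0, expm1 + 1.0).astype(dH.dtype)
        else:
            dM = dH
        dA = np.matmul(dM, Z.transpose(0, 1, 3, 2))
        dA = np.where(mask, dA, 0)
        dZ = np.matmul(A.transpose(0, 1, 3, 2), dM)
        # softmax backward per row
        dE = A * (dA - (A * dA).sum(axis=-1, keepdims=True))
        dE = np.where(pos, dE, self.leaky_slope * dE)
        ds = dE.sum(axis=-1)  # (B,K,n)
        dt = dE.sum(axis=-2)
        dZ += ds[..., None] * self.a_src[None, :, None, :]
        dZ += dt[..., None] * self.a_dst[None, :, None, :]
        self.da_src += (Z * ds[..., None]).sum(axis=(0, 2))
        self.da_dst += (Z * dt[..., None]).sum(axis=(0, 2))
        self.dW += np.einsum("bknd,bni->kdi", dZ, x)
        return np.einsum("bknd,kdi->bni", dZ, self.W)

    def params(self) -> List[Param]:
        return [(self.W, self.dW), (self.a_src, self.da_src), (self.a_dst, self.da_dst)]
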