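"""Self-attention and external-attention on 3D feature maps.

Both mechanisms operate on a feature map F with C channels and
N = D*H*W spatial positions ("pixels").

Self-attention (SA) projects F through three 1x1x1 convolutions f, g, h,
forms the N x N score matrix s_ij = f(x_i)^T g(x_j), normalizes with a
softmax over i (so each attention row sums to 1), aggregates h with those
weights, integrates through a fourth 1x1x1 convolution v, and adds the
result back through a learnable gain: y = gamma * O + x.  Cost is
quadratic in N.

External attention (EA) replaces the sample-internal key/value pair with
two small learnable memories Mk, Mv of k units shared across samples:
scores A = F' Mk^T (N x k), normalized either by a plain column softmax or
by double normalization (column softmax followed by row-wise L1), then
F_out = A Mv, wrapped by 1x1x1 input/output transformations.  Cost is
linear in N at fixed k.  Double normalization guards the attention map
against domination by extreme feature values.

The functional entry points (`sa_attention_matrix`, `ea_scores`, ...)
operate on single feature maps and are the reference semantics; the
`SelfAttention3d` / `ExternalAttention3d` layers wrap the same math over a
batch with hand-written gradients so the blocks can sit inside the FCN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import DEFAULT_DTYPE, Param, _Layer, softmax, uniform_fan_in_init

__all__ = [
    "SelfAttentionParams",
    "ExternalAttentionParams",
    "init_self_attention",
    "init_external_attention",
    "sa_attention_matrix",
    "sa_forward",
    "ea_scores",
    "softmax_normalize",
    "double_normalize",
    "ea_forward",
    "sa_mac_count",
    "ea_mac_count",
    "SelfAttention3d",
    "ExternalAttention3d",
]


def _flatten_map(F):
    F = np.asarray(F)
    if F.ndim != 4:
        raise ValueError(f"feature map must be (C, D, H, W), got shape {F.shape}")
    if not np.all(np.isfinite(F)):
        raise ValueError("feature map contains non-finite values")
    C = F.shape[0]
    return F.reshape(C, -1), F.shape


@dataclass
class SelfAttentionParams:
    """Weights of the self-attention block.

    Wf, Wg, Wh: (C', C) query/key/value projections (1x1x1 convs, no bias);
    Wv: (C, C') output integration; gamma: scalar residual gain.
    """

    Wf: np.ndarray
    Wg: np.ndarray
    Wh: np.ndarray
    Wv: np.ndarray
    gamma: float = 0.0

    def __post_init__(self):
        if self.Wf.shape != self.Wg.shape:
            raise ValueError("Wf and Wg must share the reduced channel count")
        if self.Wv.shape[::-1] != self.Wh.shape:
            raise ValueError("Wv must map the h-branch channels back to C")


@dataclass
class ExternalAttentionParams:
    """Weights of the external-attention block.

    Win: (C', C) input transformation; Wout: (C, C') output transformation
    (1x1x1 convs with bias); Mk, Mv: (k, C') external memories (linear
    layers without bias); norm_mode: 'softmax' or 'double'.
    """

    Win: np.ndarray
    Wout: np.ndarray
    Mk: np.ndarray
    Mv: np.ndarray
    bin: np.ndarray | None = None
    bout: np.ndarray | None = None
    norm_mode: str = "double"

    def __post_init__(self):
        if self.Mk.shape != self.Mv.shape:
            raise ValueError("Mk and Mv must have the same number of memory units")
        if self.Mk.shape[0] < 1:
            raise ValueError("need at least one memory unit")
        if self.norm_mode not in ("softmax", "double"):
            raise ValueError(f"norm_mode must be 'softmax' or 'double', got {self.norm_mode!r}")

    @property
    def k(self):
        return self.Mk.shape[0]


def reduced_channels(C: int) -> int:
    """Default branch-channel reduction C' = ceil(C / 8)."""
    return max(1, -(-C // 8))


def init_self_attention(C, c_reduced=None, rng=None, dtype=DEFAULT_DTYPE) -> SelfAttentionParams:
    rng = rng if rng is not None else np.random.default_rng(0)
    cr = c_reduced if c_reduced is not None else reduced_channels(C)
    return SelfAttentionParams(
        Wf=uniform_fan_in_init((cr, C), C, rng, dtype),
        Wg=uniform_fan_in_init((cr, C), C, rng, dtype),
        Wh=uniform_fan_in_init((cr, C), C, rng, dtype),
        Wv=uniform_fan_in_init((C, cr), cr, rng, dtype),
        gamma=0.0,
    )


def init_external_attention(C, k=64, c_reduced=None, norm_mode="double",
                            rng=None, dtype=DEFAULT_DTYPE) -> ExternalAttentionParams:
    rng = rng if rng is not None else np.random.default_rng(0)
    cr = c_reduced if c_reduced is not None else C
    return ExternalAttentionParams(
        Win=uniform_fan_in_init((cr, C), C, rng, dtype),
        Wout=uniform_fan_in_init((C, cr), cr, rng, dtype),
        Mk=uniform_fan_in_init((k, cr), cr, rng, dtype),
        Mv=uniform_fan_in_init((k, cr), cr, rng, dtype),
        bin=np.zeros(cr, dtype=dtype),
        bout=np.zeros(C, dtype=dtype),
        norm_mode=norm_mode,
    )


# ---------------------------------------------------------------------------
# functional reference semantics (single feature map)
# ---------------------------------------------------------------------------

def sa_attention_matrix(F, p: SelfAttentionParams) -> np.ndarray:
    """The N x N self-attention matrix beta[j, i] (each row sums to 1).

    beta[j, i] is the attention paid to pixel i when synthesizing pixel j:
    a softmax over i of the scores s_ij = f(x_i)^T g(x_j).
    """
    x, _ = _flatten_map(F)
    f = p.Wf @ x                      # (C', N)
    g = p.Wg @ x
    S = f.T @ g                       # S[i, j]
    return softmax(S, axis=0).T       # beta[j, i], normalized over i


def sa_forward(F, p: SelfAttentionParams) -> np.ndarray:
    """Self-attention output y = gamma * O + x, same shape as F."""
    x, shape = _flatten_map(F)
    beta = sa_attention_matrix(F, p)  # (N, N) rows j
    h = p.Wh @ x                      # (C', N)
    Z = h @ beta.T                    # Z[:, j] = sum_i beta[j, i] h[:, i]
    O = p.Wv @ Z                      # (C, N)
    return (p.gamma * O + x).reshape(shape)


def ea_scores(F, p: ExternalAttentionParams) -> np.ndarray:
    """Raw N x k score matrix of transformed features against the memories."""
    x, _ = _flatten_map(F)
    fin = p.Win @ x
    if p.bin is not None:
        fin = fin + p.bin[:, None]
    return fin.T @ p.Mk.T             # (N, k)


def softmax_normalize(A) -> np.ndarray:
    """Column-wise softmax of the attention scores (single normalization)."""
    A = np.asarray(A, dtype=float)
    return softmax(A, axis=0)


def double_normalize(A) -> np.ndarray:
    """Column softmax then row-wise L1 normalization.

    The softmax output is strictly positive, so every row sum is positive
    and the result has non-negative entries with rows summing to 1.
    """
    Ahat = softmax_normalize(A)
    return Ahat / np.sum(np.abs(Ahat), axis=1, keepdims=True)


def ea_forward(F, p: ExternalAttentionParams) -> np.ndarray:
    """External-attention output, same shape as F (no residual add)."""
    x, shape = _flatten_map(F)
    A = ea_scores(F, p)
    An = double_normalize(A) if p.norm_mode == "double" else softmax_normalize(A)
    U = (An @ p.Mv).T                 # (C', N)
    y = p.Wout @ U
    if p.bout is not None:
        y = y + p.bout[:, None]
    return y.reshape((p.Wout.shape[0],) + shape[1:])


# ---------------------------------------------------------------------------
# multiply-accumulate counts (complexity accounting)
# ---------------------------------------------------------------------------

def sa_mac_count(N: int, C: int, c_reduced: int | None = None) -> int:
    """MACs for the full self-attention block, dominated by the two
    N^2-sized products (score matrix and weighted aggregation)."""
    cr = c_reduced if c_reduced is not None else reduced_channels(C)
    proj = 3 * cr * C * N + C * cr * N     # f, g, h branches + v integration
    scores = N * N * cr                    # f^T g
    aggregate = N * N * cr                 # beta-weighted sum of h
    return proj + scores + aggregate


def ea_mac_count(N: int, C: int, k: int, c_reduced: int | None = None) -> int:
    """MACs for the external-attention block: linear in N at fixed k."""
    cr = c_reduced if c_reduced is not None else C
    transforms = 2 * cr * C * N            # Win, Wout
    scores = N * k * cr                    # F' Mk^T
    aggregate = N * k * cr                 # A Mv
    return transforms + scores + aggregate


# ---------------------------------------------------------------------------
# trainable batch layers
# ---------------------------------------------------------------------------

class SelfAttention3d(_Layer):
    """Batched self-attention block with a learnable residual gain.

    gamma is initialized to 0 so the block starts as the identity, which
    stabilizes early training and pins down the initial forward pass.
    """

    def __init__(self, channels, c_reduced=None, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng if rng is not None else np.random.default_rng(0)
        C = channels
        cr = c_reduced if c_reduced is not None else reduced_channels(C)
        self.C, self.cr = C, cr
        self.Wf = Param(uniform_fan_in_init((cr, C), C, rng, dtype), "sa.Wf")
        self.Wg = Param(uniform_fan_in_init((cr, C), C, rng, dtype), "sa.Wg")
        self.Wh = Param(uniform_fan_in_init((cr, C), C, rng, dtype), "sa.Wh")
        self.Wv = Param(uniform_fan_in_init((C, cr), cr, rng, dtype), "sa.Wv")
        self.gamma = Param(np.zeros((), dtype=dtype), "sa.gamma")
        self._cache = None

    def params(self):
        return [self.Wf, self.Wg, self.Wh, self.Wv, self.gamma]

    def as_params(self) -> SelfAttentionParams:
        return SelfAttentionParams(Wf=self.Wf.data, Wg=self.Wg.data, Wh=self.Wh.data,
                                   Wv=self.Wv.data, gamma=float(self.gamma.data))

    def forward(self, x, training=False, rng=None):
        B, C = x.shape[0], x.shape[1]
        shape = x.shape
        xm = x.reshape(B, C, -1)
        f = np.einsum("rc,bcn->brn", self.Wf.data, xm)
        g = np.einsum("rc,bcn->brn", self.Wg.data, xm)
        h = np.einsum("rc,bcn->brn", self.Wh.data, xm)
        S = np.einsum("bri,brj->bij", f, g)          # S[b, i, j]
        beta_t = softmax(S, axis=1)                  # over i: beta_t[b, i, j] = beta[j, i]
        Z = np.matmul(h, beta_t)                     # Z[b, :, j] = sum_i beta[j, i] h[b, :, i]
        O = np.einsum("cr,brn->bcn", self.Wv.data, Z)
        y = float(self.gamma.data) * O + xm
        if training:
            self._cache = (xm, f, g, h, beta_t, Z, O, shape)
        return y.reshape(shape)

    def backward(self, dout):
        xm, f, g, h, beta_t, Z, O, shape = self._cache
        B, C = xm.shape[0], xm.shape[1]
        dy = dout.reshape(B, C, -1)
        gamma = float(self.gamma.data)
        self.gamma.grad += np.sum(dy * O)
        dO = gamma * dy
        dx = dy.copy()
        self.Wv.grad += np.einsum("bcn,brn->cr", dO, Z)
        dZ = np.einsum("cr,bcn->brn", self.Wv.data, dO)
        # Z = h @ beta_t
        dh = np.matmul(dZ, beta_t.transpose(0, 2, 1))
        dbeta_t = np.matmul(h.transpose(0, 2, 1), dZ)   # (B, N_i, N_j)
        # softmax over axis 1 (i) per column j
        tmp = np.sum(dbeta_t * beta_t, axis=1, keepdims=True)
        dS = beta_t * (dbeta_t - tmp)
        df = np.matmul(g, dS.transpose(0, 2, 1))        # df[b,:,i] = sum_j dS[b,i,j] g[b,:,j]
        dg = np.matmul(f, dS)
        for W, d in ((self.Wf, df), (self.Wg, dg), (self.Wh, dh)):
            W.grad += np.einsum("brn,bcn->rc", d, xm)
            dx += np.einsum("rc,brn->bcn", W.data, d)
        self._cache = None
        return dx.reshape(shape)


class ExternalAttention3d(_Layer):
    """Batched external-attention block (no residual add by default,
    matching the block diagram; enable ``residual=True`` to experiment)."""

    def __init__(self, channels, k=64, c_reduced=None, norm_mode="double",
                 residual=False, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng if rng is not None else np.random.default_rng(0)
        C = channels
        cr = c_reduced if c_reduced is not None else C
        if norm_mode not in ("softmax", "double"):
            raise ValueError(f"norm_mode must be 'softmax' or 'double', got {norm_mode!r}")
        self.C, self.cr, self.k = C, cr, k
        self.norm_mode = norm_mode
        self.residual = residual
        self.Win = Param(uniform_fan_in_init((cr, C), C, rng, dtype), "ea.Win")
        self.bin = Param(np.zeros(cr, dtype=dtype), "ea.bin")
        self.Mk = Param(uniform_fan_in_init((k, cr), cr, rng, dtype), "ea.Mk")
        self.Mv = Param(uniform_fan_in_init((k, cr), cr, rng, dtype), "ea.Mv")
        self.Wout = Param(uniform_fan_in_init((C, cr), cr, rng, dtype), "ea.Wout")
        self.bout = Param(np.zeros(C, dtype=dtype), "ea.bout")
        self._cache = None

    def params(self):
        return [self.Win, self.bin, self.Mk, self.Mv, self.Wout, self.bout]

    def as_params(self) -> ExternalAttentionParams:
        return ExternalAttentionParams(Win=self.Win.data, Wout=self.Wout.data,
                                       Mk=self.Mk.data, Mv=self.Mv.data,
                                       bin=self.bin.data, bout=self.bout.data,
                                       norm_mode=self.norm_mode)

    def forward(self, x, training=False, rng=None):
        B, C = x.shape[0], x.shape[1]
        shape = x.shape
        xm = x.reshape(B, C, -1)
        fin = np.einsum("rc,bcn->brn", self.Win.data, xm) + self.bin.data[None, :, None]
        A = np.einsum("brn,kr->bnk", fin, self.Mk.data)         # (B, N, k)
        Ahat = softmax(A, axis=1)                               # column softmax over pixels
        if self.norm_mode == "double":
            r = np.sum(Ahat, axis=2, keepdims=True)
            An = Ahat / r
        else:
            r = None
            An = Ahat
        U = np.einsum("bnk,kr->brn", An, self.Mv.data)          # (B, C', N)
        y = np.einsum("cr,brn->bcn", self.Wout.data, U) + self.bout.data[None, :, None]
        if self.residual:
            y = y + xm
        if training:
            self._cache = (xm, fin, Ahat, r, An, U, shape)
        return y.reshape((B, self.Wout.data.shape[0]) + shape[2:])

    def backward(self, dout):
        xm, fin, Ahat, r, An, U, shape = self._cache
        B, C = xm.shape[0], xm.shape[1]
        dy = dout.reshape(B, dout.shape[1], -1)
        self.bout.grad += dy.sum(axis=(0, 2))
        self.Wout.grad += np.einsum("bcn,brn->cr", dy, U)
        dU = np.einsum("cr,bcn->brn", self.Wout.data, dy)
        dAn = np.einsum("brn,kr->bnk", dU, self.Mv.data)
        self.Mv.grad += np.einsum("bnk,brn->kr", An, dU)
        if self.norm_mode == "double":
            inner = np.sum(dAn * Ahat, axis=2, keepdims=True)
            dAhat = dAn / r - inner / (r * r)
        else:
            dAhat = dAn
        tmp = np.sum(dAhat * Ahat, axis=1, keepdims=True)
        dA = Ahat * (dAhat - tmp)
        dfin = np.einsum("bnk,kr->brn", dA, self.Mk.data)
        self.Mk.grad += np.einsum("bnk,brn->kr", dA, fin)
        self.bin.grad += dfin.sum(axis=(0, 2))
        self.Win.grad += np.einsum("brn,bcn->rc", dfin, xm)
        dx = np.einsum("rc,brn->bcn", self.Win.data, dfin)
        if self.residual:
            dx = dx + dy
        self._cache = None
        return dx.reshape(shape)
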