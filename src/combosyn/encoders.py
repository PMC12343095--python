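"""Graph neural-network layers for molecular graphs.

Three encoder families are provided, matching the model variants:

* **GCN** — symmetric degree-normalised neighbourhood averaging,
  ``H' = sigma(D^-1/2 (A+I) D^-1/2 H W)``.
* **GAT** — attention-weighted aggregation with softmax-normalised
  coefficients ``alpha_uw`` computed from a shared linear map and a
  single-layer additive attention scored through LeakyReLU.
* **Attentive FP** — K rounds of attention-gated message passing, each
  followed by a gated-recurrent-unit state update, with a sum readout
  over final node states.

Self-loops are always inserted before attention so every node has a
well-defined softmax neighbourhood.  All layers operate on
:class:`combosyn.nn.Tensor` and are therefore differentiable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, concat, glorot, row_softmax, stack_rows

__all__ = [
    "GcnLayerParams",
    "GatLayerParams",
    "AttFpParams",
    "ACTIVATIONS",
    "gcn_layer",
    "gat_attention",
    "gat_layer",
    "attfp_encode",
    "global_pool",
]

ACTIVATIONS = {
    "identity": lambda t: t,
    "relu": lambda t: t.relu(),
    "leaky_relu": lambda t: t.leaky_relu(),
    "sigmoid": lambda t: t.sigmoid(),
    "tanh": lambda t: t.tanh(),
}


def _act(name: str):
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


def _check_width(H: Tensor, expected: int, who: str):
    if H.shape[1] != expected:
        raise ValueError(
            f"{who}: feature width {H.shape[1]} does not match parameter fan-in {expected}"
        )


# --------------------------------------------------------------------------
# GCN
# --------------------------------------------------------------------------


@dataclass
class GcnLayerParams:
    W: Tensor
    activation: str = "relu"

    @classmethod
    def init(cls, rng: np.random.Generator, d_in: int, d_out: int,
             activation: str = "relu") -> "GcnLayerParams":
        return cls(W=Tensor(glorot(rng, d_in, d_out), requires_grad=True),
                   activation=activation)

    def tensors(self):
        return [self.W]


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """D^-1/2 (A+I) D^-1/2 with D the degree matrix of A+I."""
    A_hat = np.asarray(A, dtype=np.float64) + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(H: Tensor, A: np.ndarray, params: GcnLayerParams) -> Tensor:
    """One graph-convolution propagation step."""
    _check_width(H, params.W.shape[0], "gcn_layer")
    norm = Tensor(normalized_adjacency(A))
    return _act(params.activation)(norm @ H @ params.W)


# --------------------------------------------------------------------------
# GAT
# --------------------------------------------------------------------------


@dataclass
class GatLayerParams:
    """Multi-head attention layer parameters.

    The attention score for edge (u, w) is
    ``e_uw = LeakyReLU(a^T [W h_u || W h_w])`` with ``a`` split into its
    source and destination halves (`a_src`, `a_dst`), the standard
    additive single-layer attention without bias.
    """

    Ws: list                      # one (d_in x d_out) Tensor per head
    a_src: list                   # one (d_out x 1) Tensor per head
    a_dst: list
    negative_slope: float = 0.2
    activation: str = "relu"
    combine: str = "concat"       # "concat" (hidden layers) or "mean" (final)

    @property
    def heads(self) -> int:
        return len(self.Ws)

    @classmethod
    def init(cls, rng: np.random.Generator, d_in: int, d_out: int,
             heads: int = 1, activation: str = "relu",
             combine: str = "concat", negative_slope: float = 0.2) -> "GatLayerParams":
        if heads < 1:
            raise ValueError("heads must be >= 1")
        return cls(
            Ws=[Tensor(glorot(rng, d_in, d_out), requires_grad=True) for _ in range(heads)],
            a_src=[Tensor(glorot(rng, d_out, 1), requires_grad=True) for _ in range(heads)],
            a_dst=[Tensor(glorot(rng, d_out, 1), requires_grad=True) for _ in range(heads)],
            negative_slope=negative_slope,
            activation=activation,
            combine=combine,
        )

    def tensors(self):
        return [*self.Ws, *self.a_src, *self.a_dst]


def _self_loop_mask(A: np.ndarray) -> np.ndarray:
    return (np.asarray(A) + np.eye(A.shape[0])) > 0


def gat_attention(H: Tensor, A: np.ndarray, params: GatLayerParams,
                  head: int = 0) -> Tensor:
    """Softmax-normalised attention matrix alpha for one head.

    Row u holds node u's attention over its neighbourhood (self-loop
    included); masked entries are exactly 0 and each row sums to 1.
    """
    _check_width(H, params.Ws[head].shape[0], "gat_attention")
    Wh = H @ params.Ws[head]
    s_src = Wh @ params.a_src[head]       # n x 1
    s_dst = Wh @ params.a_dst[head]       # n x 1
    logits = (s_src + s_dst.T).leaky_relu(params.negative_slope)
    return row_softmax(logits, _self_loop_mask(A))


def gat_layer(H: Tensor, A: np.ndarray, params: GatLayerParams,
              collect_attention=None) -> Tensor:
    """Attention-weighted neighbour aggregation, multi-head.

    ``h'_u = sigma(sum_w alpha_uw W h_w)``; head outputs are concatenated
    when ``params.combine == "concat"`` and averaged when ``"mean"``.
    """
    outs = []
    for head in range(params.heads):
        alpha = gat_attention(H, A, params, head=head)
        if collect_attention is not None:
            collect_attention.append(alpha.data.copy())
        outs.append(alpha @ (H @ params.Ws[head]))
    if params.combine == "concat":
        out = outs[0] if len(outs) == 1 else concat(outs, axis=1)
    elif params.combine == "mean":
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        out = acc * (1.0 / len(outs))
    else:
        raise ValueError(f"unknown head combine mode {params.combine!r}")
    return _act(params.activation)(out)


# --------------------------------------------------------------------------
# Attentive FP
# --------------------------------------------------------------------------


@dataclass
class AttFpParams:
    """Attention-gated message passing with GRU state updates.

    ``W_in`` projects raw atom features into the hidden width; each of the
    K steps has its own alignment vectors, message map and GRU gates.
    """

    W_in: Tensor
    align_src: list
    align_dst: list
    W_msg: list
    gru: list                     # per step: dict of Wz,Uz,bz,Wr,Ur,br,Wh,Uh,bh
    steps: int = 2
    negative_slope: float = 0.2

    @classmethod
    def init(cls, rng: np.random.Generator, d_in: int, d_hidden: int,
             steps: int = 2) -> "AttFpParams":
        if steps < 1:
            raise ValueError("steps K must be >= 1")

        def mat(a, b):
            return Tensor(glorot(rng, a, b), requires_grad=True)

        def vec(b):
            return Tensor(np.zeros((1, b)), requires_grad=True)

        return cls(
            W_in=mat(d_in, d_hidden),
            align_src=[mat(d_hidden, 1) for _ in range(steps)],
            align_dst=[mat(d_hidden, 1) for _ in range(steps)],
            W_msg=[mat(d_hidden, d_hidden) for _ in range(steps)],
            gru=[
                {
                    "Wz": mat(d_hidden, d_hidden), "Uz": mat(d_hidden, d_hidden), "bz": vec(d_hidden),
                    "Wr": mat(d_hidden, d_hidden), "Ur": mat(d_hidden, d_hidden), "br": vec(d_hidden),
                    "Wh": mat(d_hidden, d_hidden), "Uh": mat(d_hidden, d_hidden), "bh": vec(d_hidden),
                }
                for _ in range(steps)
            ],
            steps=steps,
        )

    def tensors(self):
        out = [self.W_in, *self.align_src, *self.align_dst, *self.W_msg]
        for g in self.gru:
            out.extend(g.values())
        return out


def attfp_encode(graph, params: AttFpParams, collect_attention=None) -> Tensor:
    """Encode a molecular graph to a (1 x d) embedding.

    Runs K attention + GRU rounds over node states initialised by the
    input projection, then sums final node states (permutation-invariant
    readout).
    """
    H = Tensor(graph.node_features) @ params.W_in
    mask = _self_loop_mask(graph.adjacency)
    for k in range(params.steps):
        s_src = H @ params.align_src[k]
        s_dst = H @ params.align_dst[k]
        logits = (s_src + s_dst.T).leaky_relu(params.negative_slope)
        alpha = row_softmax(logits, mask)
        if collect_attention is not None:
            collect_attention.append(alpha.data.copy())
        m = alpha @ (H @ params.W_msg[k])
        g = params.gru[k]
        z = (m @ g["Wz"] + H @ g["Uz"] + g["bz"]).sigmoid()
        r = (m @ g["Wr"] + H @ g["Ur"] + g["br"]).sigmoid()
        h_tilde = (m @ g["Wh"] + (r * H) @ g["Uh"] + g["bh"]).tanh()
        H = (1.0 - z) * H + z * h_tilde
    return H.sum(axis=0, keepdims=True)


# --------------------------------------------------------------------------
# Pooling
# --------------------------------------------------------------------------


def global_pool(H: Tensor, mode: str = "mean") -> Tensor:
    """Pool node embeddings to a (1 x d) graph vector (mean/sum/max)."""
    if H.shape[0] < 1:
        raise ValueError("cannot pool an empty graph")
    if mode == "mean":
        return H.mean(axis=0, keepdims=True)
    if mode == "sum":
        return H.sum(axis=0, keepdims=True)
    if mode == "max":
        idx = np.argmax(H.data, axis=0)
        cols = np.arange(H.shape[1])
        out = Tensor(H.data[idx, cols][None, :], parents=(H,))

        def bwd(g):
            acc = np.zeros_like(H.data)
            acc[idx, cols] = g[0]
            return [(H, acc)]

        out._backward = bwd
        return out
    raise ValueError(f"unknown pooling mode {mode!r}")
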