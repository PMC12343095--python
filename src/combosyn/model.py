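"""Multi-modal synergy model: graph encoder + fingerprint + omics fusion.

Four variants share one architecture skeleton and differ in the drug
encoder:

* ``gatfp`` — GAT over the molecular graph, concatenated with a linear
  embedding of the ECFP6 fingerprint (the full model);
* ``gat`` / ``gcn`` / ``attfp`` — the respective graph encoder alone,
  with no fingerprint branch.

Per combination <A, B, cell line>, the per-drug embeddings h_A, h_B are
concatenated with linear embeddings of the cell line's gene- and
protein-expression vectors into h_AB = Concat(h_A, h_B, g_exp, p_exp),
which a three-layer fully connected head maps to either a real synergy
score (regression) or a synergism probability through a sigmoid
(classification).  Ablation flags drop a branch entirely: the fusion
vector shrinks and the head's first weight matrix is built at the
reduced width.

Drug order (A, B) is not symmetrised by default; ``symmetrize="average"``
averages the two orderings at prediction time, making the output exactly
swap-invariant, and ``symmetrize="augment"`` duplicates training records
in both orders.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import encoders
from .chem import ATOM_FEATURE_DIM
from .nn import Tensor, concat, glorot, stack_rows

__all__ = ["ModelConfig", "ConfigError", "NumericError", "Prediction", "SynergyModel"]

VARIANTS = ("gatfp", "gat", "gcn", "attfp")
TASKS = ("regression", "classification")


class ConfigError(ValueError):
    """Inconsistent or unknown model configuration."""


class NumericError(FloatingPointError):
    """Non-finite values produced in the forward pass."""


@dataclass
class ModelConfig:
    """All architecture hyperparameters of one model variant.

    Defaults: graph and fingerprint embeddings 128 wide, omics embeddings
    256, head 1024 -> 512 -> 1, dropout 0.2 after each hidden head layer,
    ReLU activations, mean graph pooling, 4 attention heads on hidden GAT
    layers and 1 on the final layer.
    """

    variant: str = "gatfp"
    task: str = "classification"
    n_genes: int = 0
    n_proteins: int = 0
    fingerprint_dim: int = 2048
    graph_dim: int = 128
    fp_dim: int = 128
    omics_dim: int = 256
    head_dims: tuple = (1024, 512)
    dropout: float = 0.2
    gat_heads: int = 4
    n_graph_layers: int = 2
    attfp_steps: int = 2
    pooling: str = "mean"
    activation: str = "relu"
    use_protein: bool = True
    use_gene: bool = True
    use_fingerprint: bool = True
    symmetrize: str = "none"          # none | augment | average
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.symmetrize not in ("none", "augment", "average"):
            raise ConfigError(f"unknown symmetrize mode {self.symmetrize!r}")
        if self.variant == "gatfp" and self.use_fingerprint and self.fp_dim < 1:
            raise ConfigError("fingerprint branch enabled but fp_dim < 1")
        if self.variant in ("gat", "gatfp") and self.graph_dim % self.gat_heads:
            raise ConfigError("graph_dim must be divisible by gat_heads")

    @property
    def fingerprint_enabled(self) -> bool:
        # only the GATFP variant carries the fingerprint branch
        return self.variant == "gatfp" and self.use_fingerprint

    @property
    def per_drug_dim(self) -> int:
        return self.graph_dim + (self.fp_dim if self.fingerprint_enabled else 0)

    @property
    def fusion_dim(self) -> int:
        d = 2 * self.per_drug_dim
        if self.use_gene:
            d += self.omics_dim
        if self.use_protein:
            d += self.omics_dim
        return d


@dataclass
class Prediction:
    """Model output for one record: score y (regression) or probability p."""

    value: float
    task: str
    record: object = None

    @property
    def y(self):
        return self.value if self.task == "regression" else None

    @property
    def p(self):
        return self.value if self.task == "classification" else None


class SynergyModel:
    """One parameterised model variant with forward, save and load."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._params: dict[str, Tensor] = {}
        self._build(rng)

    # -- construction --------------------------------------------------------

    def _reg(self, name: str, t: Tensor) -> Tensor:
        self._params[name] = t
        return t

    def _linear(self, rng, name, d_in, d_out):
        W = self._reg(f"{name}.W", Tensor(glorot(rng, d_in, d_out), requires_grad=True))
        b = self._reg(f"{name}.b", Tensor(np.zeros((1, d_out)), requires_grad=True))
        return W, b

    def _build(self, rng):
        cfg = self.config
        self.encoder_layers = []
        if cfg.variant in ("gat", "gatfp"):
            widths = [ATOM_FEATURE_DIM] + [cfg.graph_dim] * cfg.n_graph_layers
            for layer in range(cfg.n_graph_layers):
                final = layer == cfg.n_graph_layers - 1
                heads = 1 if final else cfg.gat_heads
                d_out = widths[layer + 1] // heads
                p = encoders.GatLayerParams.init(
                    rng, widths[layer], d_out, heads=heads,
                    activation=cfg.activation,
                    combine="mean" if final else "concat",
                )
                self.encoder_layers.append(p)
        elif cfg.variant == "gcn":
            widths = [ATOM_FEATURE_DIM] + [cfg.graph_dim] * cfg.n_graph_layers
            for layer in range(cfg.n_graph_layers):
                self.encoder_layers.append(
                    encoders.GcnLayerParams.init(rng, widths[layer], widths[layer + 1],
                                                 activation=cfg.activation)
                )
        else:  # attfp
            self.encoder_layers.append(
                encoders.AttFpParams.init(rng, ATOM_FEATURE_DIM, cfg.graph_dim,
                                          steps=cfg.attfp_steps)
            )
        for i, layer in enumerate(self.encoder_layers):
            for j, t in enumerate(layer.tensors()):
                self._reg(f"enc{i}.{j}", t)

        if cfg.fingerprint_enabled:
            self.W_f, self.b_f = self._linear(rng, "fp", cfg.fingerprint_dim, cfg.fp_dim)
        if cfg.use_gene:
            if cfg.n_genes < 1:
                raise ConfigError("use_gene=True requires n_genes >= 1")
            self.W_g, self.b_g = self._linear(rng, "gene", cfg.n_genes, cfg.omics_dim)
        if cfg.use_protein:
            if cfg.n_proteins < 1:
                raise ConfigError("use_protein=True requires n_proteins >= 1")
            self.W_p, self.b_p = self._linear(rng, "protein", cfg.n_proteins, cfg.omics_dim)

        h1, h2 = cfg.head_dims
        self.W_1, self.b_1 = self._linear(rng, "head1", cfg.fusion_dim, h1)
        self.W_2, self.b_2 = self._linear(rng, "head2", h1, h2)
        self.W_3, self.b_3 = self._linear(rng, "head3", h2, 1)

    def parameters(self):
        return list(self._params.values())

    # -- forward -------------------------------------------------------------

    def encode_graph(self, graph, collect_attention=None) -> Tensor:
        """Pooled (1 x graph_dim) embedding of one molecular graph."""
        cfg = self.config
        if cfg.variant == "attfp":
            return encoders.attfp_encode(graph, self.encoder_layers[0],
                                         collect_attention=collect_attention)
        H = Tensor(graph.node_features)
        for layer in self.encoder_layers:
            if cfg.variant == "gcn":
                H = encoders.gcn_layer(H, graph.adjacency, layer)
            else:
                H = encoders.gat_layer(H, graph.adjacency, layer,
                                       collect_attention=collect_attention)
        return encoders.global_pool(H, cfg.pooling)

    def encode_drug(self, graph, fingerprint=None, collect_attention=None) -> Tensor:
        """Per-drug embedding h: graph embedding, plus the linear
        fingerprint embedding for the GATFP variant."""
        z = self.encode_graph(graph, collect_attention=collect_attention)
        if not self.config.fingerprint_enabled:
            return z
        if fingerprint is None:
            raise ConfigError("variant gatfp requires a fingerprint per drug")
        f = Tensor(fingerprint.bits[None, :]) @ self.W_f + self.b_f
        return concat([z, f], axis=1)

    def encode_omics(self, G: Tensor, P: Tensor):
        """Linear omics embeddings (g_exp, p_exp); disabled branches -> None."""
        cfg = self.config
        g_exp = (G @ self.W_g + self.b_g) if cfg.use_gene else None
        p_exp = (P @ self.W_p + self.b_p) if cfg.use_protein else None
        return g_exp, p_exp

    def fusion_slices(self) -> dict:
        """Row ranges of the first head weight matrix per fusion segment."""
        cfg = self.config
        spans, pos = {}, 0
        for name, width in (
            ("h_A", cfg.per_drug_dim),
            ("h_B", cfg.per_drug_dim),
            ("g_exp", cfg.omics_dim if cfg.use_gene else 0),
            ("p_exp", cfg.omics_dim if cfg.use_protein else 0),
        ):
            spans[name] = (pos, pos + width)
            pos += width
        return spans

    def fuse_and_predict(self, h_A: Tensor, h_B: Tensor, G: Tensor, P: Tensor,
                         train: bool = False, rng=None) -> Tensor:
        """Fusion head on batched segments; returns a (n,) output Tensor.

        Output is the raw score for regression and the sigmoid probability
        for classification.
        """
        cfg = self.config
        g_exp, p_exp = self.encode_omics(G, P)
        segments = [h_A, h_B] + [s for s in (g_exp, p_exp) if s is not None]
        h = concat(segments, axis=1)
        act = encoders.ACTIVATIONS[cfg.activation]
        layers = [(self.W_1, self.b_1), (self.W_2, self.b_2)]
        for i, (W, b) in enumerate(layers):
            h = act(h @ W + b)
            if train and cfg.dropout > 0:
                if rng is None:
                    raise ValueError("training forward with dropout requires an rng")
                keep = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                h = h * Tensor(keep)
            if not np.all(np.isfinite(h.data)):
                raise NumericError(f"non-finite activations in head layer {i + 1}")
        out = h @ self.W_3 + self.b_3
        if not np.all(np.isfinite(out.data)):
            raise NumericError("non-finite activations in head layer 3")
        if cfg.task == "classification":
            out = out.sigmoid()
        return out.reshape(-1)

    # -- batched application over a dataset bundle ----------------------------

    def drug_embedding_matrix(self, bundle, drug_ids) -> Tensor:
        rows = []
        for did in drug_ids:
            if did not in bundle.graphs:
                raise KeyError(f"no featurization for drug id {did!r}")
            fp = bundle.fingerprints.get(did) if self.config.fingerprint_enabled else None
            if self.config.fingerprint_enabled and fp is None:
                raise KeyError(f"no fingerprint for drug id {did!r}")
            rows.append(self.encode_drug(bundle.graphs[did], fp))
        return stack_rows(rows)

    def forward_records(self, bundle, records, train: bool = False, rng=None,
                        _swap: bool = False) -> Tensor:
        """Vectorised forward pass over records; deterministic given
        parameters, inputs and (when training with dropout) the rng."""
        for r in records:
            if r.cell_line_id not in bundle.omics:
                raise KeyError(f"no omics profile for cell line {r.cell_line_id!r}")
        drug_ids = sorted({d for r in records for d in (r.drug_a_id, r.drug_b_id)})
        index = {d: i for i, d in enumerate(drug_ids)}
        D = self.drug_embedding_matrix(bundle, drug_ids)
        a_idx = [index[r.drug_b_id if _swap else r.drug_a_id] for r in records]
        b_idx = [index[r.drug_a_id if _swap else r.drug_b_id] for r in records]
        h_A = D.take_rows(a_idx)
        h_B = D.take_rows(b_idx)
        G = Tensor(np.vstack([bundle.omics[r.cell_line_id].gene_expr for r in records]))
        P = Tensor(np.vstack([bundle.omics[r.cell_line_id].protein_expr for r in records]))
        out = self.fuse_and_predict(h_A, h_B, G, P, train=train, rng=rng)
        if self.config.symmetrize == "average" and not _swap and not train:
            out = (out + self.forward_records(bundle, records, _swap=True)) * 0.5
        return out

    def predict(self, bundle, records) -> list:
        values = self.forward_records(bundle, records).data
        return [Prediction(value=float(v), task=self.config.task, record=r)
                for v, r in zip(values, records)]

    # -- persistence ----------------------------------------------------------

    def save(self, path_prefix: str) -> None:
        """Write `<prefix>.npz` (weights) and `<prefix>.json` (manifest)."""
        np.savez(f"{path_prefix}.npz",
                 **{k: v.data for k, v in self._params.items()})
        manifest = {
            "config": asdict(self.config),
            "param_shapes": {k: list(v.shape) for k, v in self._params.items()},
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "SynergyModel":
        with open(f"{path_prefix}.json") as fh:
            manifest = json.load(fh)
        cfg_dict = manifest["config"]
        cfg_dict["head_dims"] = tuple(cfg_dict["head_dims"])
        model = cls(ModelConfig(**cfg_dict))
        arrays = np.load(f"{path_prefix}.npz")
        for k, t in model._params.items():
            t.data = np.asarray(arrays[k], dtype=np.float64)
        return model
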