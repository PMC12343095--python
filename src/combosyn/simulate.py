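"""Synthetic drug-combination fixtures with planted, known ground truth.

The generator emits exactly the input formats the preprocessing pipeline
consumes — a combination table (drug pair, SMILES, cell line, Loewe-like
score) plus cell-line x gene and cell-line x protein expression matrices
— from a fully specified additive model, so that training, ablation,
cold-start and attribution behaviour can be tested against known truth.

Planted structure:

* **Molecules** are drug-like decorated ring systems; a designated
  synergy substructure (a chlorinated aromatic ring) is carried by a
  known subset of drugs.
* **Omics profiles** have cluster structure (shared between the gene and
  protein matrices, emulating tissue-of-origin clustering).  A responder
  signature of protein features has low baseline abundance and is
  strongly elevated in a known subset of cell lines; the gene matrix
  carries no responder information, only cluster structure and a mild
  gene signature.
* **Scores** follow the additive planted model

  ``score = beta_sub * 1[both drugs planted]
          + beta_prot * mean(responder-signature proteins of the line)
          + beta_gene * mean(gene-signature genes of the line)
          + Normal(0, noise_sd)``,

  clipped to the retained Loewe interval [-75, 50].

Defaults are sized so a full train+evaluate cycle runs in minutes on one
CPU: 2,000 combinations over 40 drugs and 24 cell lines, 200 genes and
400 proteins in 4 clusters.  All generation is bit-reproducible given
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chem import canonical_smiles, smiles_to_graph

__all__ = [
    "SynthConfig",
    "gen_molecules",
    "gen_omics",
    "gen_synergy",
    "make_fixture",
    "analytic_prevalence",
]

SCORE_MIN, SCORE_MAX = -75.0, 50.0

# decorated-scaffold vocabulary; every (substituent, core) product parses
_SUBSTITUENTS = ["C", "CC", "CCC", "CCO", "CO", "O", "N", "CN", "OCC", "C(C)C"]
_PLAIN_CORES = [
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1ccc2ccccc2c1",      # naphthalene
    "C1CCCCC1",            # cyclohexane
    "c1ccsc1",             # thiophene
    "C1CCNCC1",            # piperidine
]
# the planted synergy substructure: a chlorinated aromatic ring
_CHLORO_CORES = [
    "c1ccc(Cl)cc1",
    "c1cccc(Cl)c1",
    "c1ccc(Cl)c(Cl)c1",
]


@dataclass
class SynthConfig:
    """Study conditions of the planted-signal benchmark."""

    n_drugs: int = 40
    n_cell_lines: int = 24
    n_combinations: int = 2000
    n_genes: int = 200
    n_proteins: int = 400
    n_clusters: int = 4
    signature_size: int = 15          # responder-signature proteins
    gene_signature_size: int = 15
    planted_fraction: float = 1 / 3   # drugs carrying the synergy substructure
    responder_fraction: float = 0.5   # cell lines with the elevated signature
    beta_sub: float = 12.0
    beta_prot: float = 12.0
    beta_gene: float = 4.0
    noise_sd: float = 5.0
    line_noise_sd: float = 0.5
    signature_baseline: float = -1.0  # baseline shift of signature proteins
    elevation: float = 3.0            # responder elevation of signature proteins
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_cell_lines, self.n_combinations,
               self.n_genes, self.n_proteins, self.n_clusters) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_clusters > self.n_cell_lines:
            raise ValueError("n_clusters cannot exceed n_cell_lines")


def gen_molecules(n_drugs: int, seed: int = 0, planted_fraction: float = 1 / 3):
    """Seeded drug-like molecules; a known subset carries the planted ring.

    Returns ``(molecules, planted_ids)`` where molecules is a list of
    (drug_id, SMILES).  Every emitted SMILES parses and featurizes.
    """
    if n_drugs < 2:
        raise ValueError("need at least two drugs")
    rng = np.random.default_rng(seed)
    n_planted = max(1, int(round(planted_fraction * n_drugs)))
    if n_planted >= n_drugs:
        n_planted = n_drugs - 1

    def combos(cores):
        out = [(r, c) for c in cores for r in _SUBSTITUENTS]
        rng.shuffle(out)
        return out

    planted_pool = combos(_CHLORO_CORES)
    plain_pool = combos(_PLAIN_CORES)
    if n_planted > len(planted_pool) or n_drugs - n_planted > len(plain_pool):
        raise ValueError("vocabulary too small for requested n_drugs")
    molecules, planted_ids = [], []
    for i in range(n_drugs):
        drug_id = f"D{i:03d}"
        if i < n_planted:
            r, core = planted_pool[i]
            planted_ids.append(drug_id)
        else:
            r, core = plain_pool[i - n_planted]
        smiles = canonical_smiles(r + core)
        smiles_to_graph(smiles)  # validity contract
        molecules.append((drug_id, smiles))
    return molecules, planted_ids


def gen_omics(n_cell_lines: int, n_genes: int, n_proteins: int,
              n_clusters: int = 4, seed: int = 0, line_noise_sd: float = 0.5,
              signature_size: int = 15, gene_signature_size: int = 15,
              responder_fraction: float = 0.5,
              signature_baseline: float = -1.0, elevation: float = 3.0):
    """Cluster-structured omics matrices with a planted protein signature.

    Returns ``(gene_df, protein_df, meta)``; meta records cluster
    assignments, responder cell lines and the signature feature names.
    Cluster means are drawn once per cluster; per-line Gaussian noise is
    added on top.  Signature proteins sit ``signature_baseline`` below
    the bulk and are raised by ``elevation`` in responder lines.
    """
    if n_clusters > n_cell_lines:
        raise ValueError("n_clusters cannot exceed n_cell_lines")
    rng = np.random.default_rng(seed)
    lines = [f"CL{i:03d}" for i in range(n_cell_lines)]
    clusters = rng.integers(n_clusters, size=n_cell_lines)
    # guarantee every cluster id occurs
    clusters[:n_clusters] = np.arange(n_clusters)

    def matrix(n_feat):
        means = rng.normal(0.0, 1.0, size=(n_clusters, n_feat))
        return means[clusters] + rng.normal(0.0, line_noise_sd,
                                            size=(n_cell_lines, n_feat))

    genes = matrix(n_genes)
    proteins = matrix(n_proteins)
    # responder status is stratified within clusters so that cluster
    # (tissue) identity alone carries no information about response --
    # the responder signal lives in the protein signature only
    responders = []
    for c in range(n_clusters):
        members = np.flatnonzero(clusters == c)
        rng.shuffle(members)
        responders.extend(members[: int(round(responder_fraction * len(members)))])
    responders = np.asarray(sorted(responders), dtype=np.intp)
    sig = rng.choice(n_proteins, size=min(signature_size, n_proteins), replace=False)
    gene_sig = rng.choice(n_genes, size=min(gene_signature_size, n_genes), replace=False)
    proteins[:, sig] += signature_baseline
    proteins[np.ix_(responders, sig)] += elevation

    gene_names = [f"G{j:04d}" for j in range(n_genes)]
    protein_names = [f"P{j:04d}" for j in range(n_proteins)]
    gene_df = pd.DataFrame(genes, index=lines, columns=gene_names)
    protein_df = pd.DataFrame(proteins, index=lines, columns=protein_names)
    meta = {
        "clusters": {ln: int(c) for ln, c in zip(lines, clusters)},
        "responder_lines": sorted(lines[i] for i in responders),
        "protein_signature": sorted(protein_names[j] for j in sig),
        "gene_signature": sorted(gene_names[j] for j in gene_sig),
    }
    return gene_df, protein_df, meta


def gen_synergy(records, planted_ids, gene_df, protein_df, meta,
                cfg: SynthConfig):
    """Score <drug_a, drug_b, cell_line> triples under the planted model.

    ``records`` is a list of (drug_a, drug_b, cell_line) id triples.
    Returns a DataFrame with the scores and their ground-truth components
    (sub/prot/gene effects and the noise draw) per record; scores are
    clipped to the retained interval [-75, 50].
    """
    rng = np.random.default_rng(cfg.seed + 1)
    planted = set(planted_ids)
    sig = meta["protein_signature"]
    gene_sig = meta["gene_signature"]
    prot_mean = protein_df[sig].mean(axis=1)
    gene_mean = gene_df[gene_sig].mean(axis=1)
    rows = []
    for drug_a, drug_b, line in records:
        sub = cfg.beta_sub * float(drug_a in planted and drug_b in planted)
        prot = cfg.beta_prot * float(prot_mean[line])
        gene = cfg.beta_gene * float(gene_mean[line])
        noise = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
        score = float(np.clip(sub + prot + gene + noise, SCORE_MIN, SCORE_MAX))
        rows.append({
            "drug_a": drug_a, "drug_b": drug_b, "cell_line": line,
            "loewe": score, "sub_effect": sub, "prot_effect": prot,
            "gene_effect": gene, "noise": noise,
        })
    return pd.DataFrame(rows)


def analytic_prevalence(truth: pd.DataFrame, noise_sd: float) -> float:
    """Expected fraction of synergistic labels under the planted model.

    Uses the Gaussian noise distribution around each record's
    deterministic component (clipping at the retained interval never
    moves a score across zero, so it does not change the label).
    """
    mu = (truth["sub_effect"] + truth["prot_effect"] + truth["gene_effect"]).to_numpy()
    if noise_sd == 0:
        return float(np.mean(mu > 0))
    return float(np.mean(norm.cdf(mu / noise_sd)))


def make_fixture(cfg: SynthConfig | None = None, out_dir=None):
    """Generate one complete fixture dataset.

    Returns ``(comb_df, gene_df, protein_df, truth)`` where ``comb_df``
    follows the combination-table schema the preprocessing expects and
    ``truth`` is the ground-truth manifest (planted drugs, responder
    lines, signature features, effect sizes, seed, per-record
    components).  With ``out_dir``, writes combinations.csv, genes.csv,
    proteins.csv and truth.json.
    """
    cfg = cfg or SynthConfig()
    molecules, planted_ids = gen_molecules(cfg.n_drugs, seed=cfg.seed,
                                           planted_fraction=cfg.planted_fraction)
    gene_df, protein_df, meta = gen_omics(
        cfg.n_cell_lines, cfg.n_genes, cfg.n_proteins, cfg.n_clusters,
        seed=cfg.seed, line_noise_sd=cfg.line_noise_sd,
        signature_size=cfg.signature_size,
        gene_signature_size=cfg.gene_signature_size,
        responder_fraction=cfg.responder_fraction,
        signature_baseline=cfg.signature_baseline, elevation=cfg.elevation,
    )
    smiles = dict(molecules)
    drug_ids = [d for d, _ in molecules]
    lines = list(gene_df.index)
    rng = np.random.default_rng(cfg.seed + 2)
    pairs = [(a, b) for i, a in enumerate(drug_ids) for b in drug_ids[i + 1:]]
    n_possible = len(pairs) * len(lines)
    n_comb = min(cfg.n_combinations, n_possible)
    chosen = rng.choice(n_possible, size=n_comb, replace=False)
    triples = [(pairs[c // len(lines)][0], pairs[c // len(lines)][1],
                lines[c % len(lines)]) for c in chosen]
    truth_df = gen_synergy(triples, planted_ids, gene_df, protein_df, meta, cfg)
    comb_df = truth_df[["drug_a", "drug_b", "cell_line", "loewe"]].copy()
    comb_df.insert(2, "smiles_a", comb_df["drug_a"].map(smiles))
    comb_df.insert(3, "smiles_b", comb_df["drug_b"].map(smiles))
    comb_df["study"] = "SYNTH"
    comb_df["tissue"] = comb_df["cell_line"].map(
        lambda ln: f"cluster{meta['clusters'][ln]}")
    truth = {
        "config": asdict(cfg),
        "planted_drugs": planted_ids,
        "smiles": smiles,
        **meta,
        "analytic_prevalence": analytic_prevalence(truth_df, cfg.noise_sd),
        "components": truth_df[["sub_effect", "prot_effect", "gene_effect",
                                "noise"]].to_dict(orient="list"),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comb_df.to_csv(out / "combinations.csv", index=False)
        gene_df.to_csv(out / "genes.csv")
        protein_df.to_csv(out / "proteins.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return comb_df, gene_df, protein_df, truth
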