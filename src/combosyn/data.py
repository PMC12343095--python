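"""Combination-table preprocessing and omics alignment.

Implements the filtering protocol used to assemble a drug-combination
synergy dataset: drop invalid rows (blank or non-numeric cells), discard
Loewe-score outliers (scores above 50 or below -75), optionally restrict
drugs to an allow-list, and deduplicate on the triplet (cell line,
unordered drug-name pair).  Records are then restricted to cell lines
present in BOTH the gene- and protein-expression matrices, and omics
features are z-scored against training cell lines only.

Synergism labels follow Loewe additivity: a positive score (observed
combination effect above the dose-additive expectation) is synergistic
(label 1); zero or negative is not (label 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CombinationRecord",
    "DoseResponsePoint",
    "OmicsProfile",
    "DatasetBundle",
    "SchemaError",
    "EmptyDatasetError",
    "REQUIRED_COLUMNS",
    "read_combination_table",
    "read_omics_matrix",
    "filter_records",
    "assemble_bundle",
    "label_synergy",
    "loewe_score",
    "align_omics",
    "standardize_omics",
]

REQUIRED_COLUMNS = ("drug_a", "drug_b", "smiles_a", "smiles_b", "cell_line", "loewe")


class SchemaError(ValueError):
    """A combination table is missing required columns."""


class EmptyDatasetError(ValueError):
    """No records survive alignment/filtering."""


@dataclass(frozen=True)
class CombinationRecord:
    """One <drug A, drug B, cell line> synergy experiment."""

    drug_a_id: str
    drug_b_id: str
    smiles_a: str
    smiles_b: str
    cell_line_id: str
    loewe: float
    study: str = ""
    tissue: str = ""
    label: int = 0

    @property
    def pair_key(self):
        """Unordered drug-name pair (deduplication key component)."""
        return tuple(sorted((self.drug_a_id, self.drug_b_id)))


@dataclass(frozen=True)
class DoseResponsePoint:
    """Concentrations and efficacies entering the Loewe-score helper."""

    x1: float
    x2: float
    y1: float
    y2: float
    yc: float


@dataclass
class OmicsProfile:
    """Gene- and protein-expression vectors for one cell line."""

    cell_line_id: str
    gene_expr: np.ndarray
    protein_expr: np.ndarray
    gene_names: list
    protein_names: list

    def __post_init__(self):
        if len(self.gene_expr) != len(self.gene_names):
            raise ValueError("gene vector/name length mismatch")
        if len(self.protein_expr) != len(self.protein_names):
            raise ValueError("protein vector/name length mismatch")


@dataclass
class DatasetBundle:
    """Filtered records plus their featurizations and omics profiles."""

    records: list = field(default_factory=list)
    graphs: dict = field(default_factory=dict)          # drug_id -> MolecularGraph
    fingerprints: dict = field(default_factory=dict)    # drug_id -> Fingerprint
    omics: dict = field(default_factory=dict)           # cell_line_id -> OmicsProfile
    audit: dict = field(default_factory=dict)

    @property
    def cell_line_ids(self):
        return sorted({r.cell_line_id for r in self.records})

    @property
    def drug_ids(self):
        out = set()
        for r in self.records:
            out.add(r.drug_a_id)
            out.add(r.drug_b_id)
        return sorted(out)


def label_synergy(loewe: float) -> int:
    """1 if the Loewe score is strictly positive (synergistic), else 0."""
    if not math.isfinite(loewe):
        raise ValueError(f"non-finite Loewe score: {loewe}")
    return 1 if loewe > 0 else 0


def loewe_score(p: DoseResponsePoint) -> float:
    """Loewe synergy score y_c - y_1 (x_1 + x_2).

    The textbook identity also writes this as y_c - y_2 (x_1 + x_2),
    which coincides only when the two single-agent efficacies are equal;
    this helper evaluates the first expression.
    """
    for name in ("x1", "x2", "y1", "y2", "yc"):
        if not math.isfinite(getattr(p, name)):
            raise ValueError(f"non-finite dose-response field {name}")
    return p.yc - p.y1 * (p.x1 + p.x2)


def read_combination_table(path) -> pd.DataFrame:
    """Read a combination CSV/TSV by extension (default comma)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_omics_matrix(path) -> pd.DataFrame:
    """Read a cell-line x feature matrix (first column = cell-line id)."""
    p = str(path)
    if p.endswith(".parquet"):
        df = pd.read_parquet(p)
        return df.set_index(df.columns[0])
    sep = "\t" if p.endswith((".tsv", ".txt")) else ","
    return pd.read_csv(p, sep=sep, index_col=0)


def filter_records(
    table: pd.DataFrame,
    score_max: float = 50.0,
    score_min: float = -75.0,
    drug_allowlist=None,
) -> tuple[list, dict]:
    """Apply the preprocessing filters to a raw combination table.

    Returns (records, audit).  Removal order per row: invalid entry
    (blank/non-numeric cell) -> allow-list -> score out of range ->
    duplicate triplet; each row is counted under the first rule it
    violates so input rows = output records + sum(audit values).
    Boundary scores exactly at ``score_max`` / ``score_min`` are kept
    (the outlier rule is a strict inequality).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"combination table is missing columns: {missing}")

    audit = {
        "invalid_entry": 0,
        "not_in_allowlist": 0,
        "score_out_of_range": 0,
        "duplicate_triplet": 0,
    }
    records: list[CombinationRecord] = []
    seen = set()
    for _, row in table.iterrows():
        cells = {c: row[c] for c in REQUIRED_COLUMNS}
        if any(pd.isna(v) or (isinstance(v, str) and not v.strip()) for v in cells.values()):
            audit["invalid_entry"] += 1
            continue
        try:
            loewe = float(cells["loewe"])
        except (TypeError, ValueError):
            audit["invalid_entry"] += 1
            continue
        if not math.isfinite(loewe):
            audit["invalid_entry"] += 1
            continue
        drug_a, drug_b = str(cells["drug_a"]), str(cells["drug_b"])
        if drug_allowlist is not None and (
            drug_a not in drug_allowlist or drug_b not in drug_allowlist
        ):
            audit["not_in_allowlist"] += 1
            continue
        if loewe > score_max or loewe < score_min:
            audit["score_out_of_range"] += 1
            continue
        key = (str(cells["cell_line"]), tuple(sorted((drug_a, drug_b))))
        if key in seen:
            audit["duplicate_triplet"] += 1
            continue
        seen.add(key)
        records.append(
            CombinationRecord(
                drug_a_id=drug_a,
                drug_b_id=drug_b,
                smiles_a=str(cells["smiles_a"]),
                smiles_b=str(cells["smiles_b"]),
                cell_line_id=str(cells["cell_line"]),
                loewe=loewe,
                study=str(row.get("study", "") or ""),
                tissue=str(row.get("tissue", "") or ""),
                label=label_synergy(loewe),
            )
        )
    return records, audit


def align_omics(
    records: list,
    gene_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
) -> DatasetBundle:
    """Keep records whose cell line has BOTH gene and protein profiles.

    Raises :class:`EmptyDatasetError` if the gene/protein cell-line
    intersection (restricted to the records) is empty.
    """
    shared = set(gene_matrix.index) & set(protein_matrix.index)
    kept = [r for r in records if r.cell_line_id in shared]
    if not kept:
        raise EmptyDatasetError(
            "no records remain: gene/protein cell-line overlap does not cover the table"
        )
    audit = {"cell_line_not_in_both_omics": len(records) - len(kept)}
    gene_names = list(gene_matrix.columns)
    protein_names = list(protein_matrix.columns)
    omics = {}
    for cl in sorted({r.cell_line_id for r in kept}):
        omics[cl] = OmicsProfile(
            cell_line_id=cl,
            gene_expr=gene_matrix.loc[cl].to_numpy(dtype=np.float64),
            protein_expr=protein_matrix.loc[cl].to_numpy(dtype=np.float64),
            gene_names=gene_names,
            protein_names=protein_names,
        )
    return DatasetBundle(records=kept, omics=omics, audit=audit)


def assemble_bundle(
    table: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    drug_allowlist=None,
) -> DatasetBundle:
    """Full preprocessing: filter, align omics, featurize every drug.

    The returned bundle resolves every record's drugs to a molecular
    graph and fingerprint and every cell line to an omics profile; the
    audit merges the removal counts of both stages.
    """
    from . import chem  # local import keeps data-table utilities RDKit-free

    records, audit = filter_records(table, drug_allowlist=drug_allowlist)
    bundle = align_omics(records, gene_matrix, protein_matrix)
    bundle.audit = {**audit, **bundle.audit}
    for r in bundle.records:
        for drug_id, smiles in ((r.drug_a_id, r.smiles_a), (r.drug_b_id, r.smiles_b)):
            if drug_id not in bundle.graphs:
                bundle.graphs[drug_id] = chem.smiles_to_graph(smiles, drug_id=drug_id)
                bundle.fingerprints[drug_id] = chem.smiles_to_fingerprint(
                    smiles, drug_id=drug_id)
    return bundle


def _fit_scaler(matrix: np.ndarray):
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    return mean, sd


def _apply_scaler(vec: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    out = np.where(sd > 0, (vec - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def standardize_omics(bundle: DatasetBundle, training_line_ids) -> DatasetBundle:
    """Per-feature z-score using statistics from training cell lines only.

    Constant (sd = 0) features map to 0 everywhere; missing (NaN) entries
    are imputed to the training mean before scaling, which is the neutral
    value 0 after z-scoring.  Validation/test profiles receive the same
    transform.
    """
    train_ids = [cl for cl in training_line_ids if cl in bundle.omics]
    if not train_ids:
        raise ValueError("training_line_ids must overlap the bundle's cell lines")
    for attr in ("gene_expr", "protein_expr"):
        train_mat = np.vstack([getattr(bundle.omics[cl], attr) for cl in train_ids])
        col_mean = np.nanmean(train_mat, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        imputed = np.where(np.isfinite(train_mat), train_mat, col_mean)
        mean, sd = _fit_scaler(imputed)
        for profile in bundle.omics.values():
            vec = getattr(profile, attr)
            vec = np.where(np.isfinite(vec), vec, col_mean)
            setattr(profile, attr, _apply_scaler(vec, mean, sd))
    return bundle
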