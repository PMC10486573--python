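"""Reading molecular-network inputs and assembling per-sample graphs.

A sample is a *molecular network*: the genes of the curated signaling
interactome (e.g. KEGG pathway edges), plus one or two drug nodes wired to
their target genes (e.g. DrugBank drug–target links).  Gene node features are
``[expression, hit-by-drug-A, hit-by-drug-B]``; drug node features are all
−1.  Every gene carries a *global id* from a shared lexicographically sorted
vocabulary, so the same gene has the same index in every network — this is
what makes the trainable global edge-weight matrix of the pooling layers
meaningful across samples.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneVocabulary",
    "MolecularNetwork",
    "SynergyRecord",
    "load_edge_list",
    "write_edge_list",
    "build_vocabulary",
    "read_expression",
    "write_expression",
    "read_synergy",
    "write_synergy",
    "assemble_network",
    "swap_drug_order",
]

# tokens that mark a first row as a header rather than data
_HEADER_TOKENS = {
    "source", "target", "gene", "gene1", "gene2", "gene_a", "gene_b",
    "drug", "drug_a", "drug_b", "from", "to", "node1", "node2", "name",
}


@dataclasses.dataclass(frozen=True)
class GeneVocabulary:
    """Shared gene-name → integer index map (lexicographically sorted).

    The sorted order is the pre-defined node index used by the pooling
    layers' global edge-weight matrices; two additional slots (``len(names)``
    and ``len(names)+1``) are reserved for the first and second drug node.
    """

    names: tuple[str, ...]

    def __post_init__(self):
        if not self.names:
            raise ValueError("gene vocabulary cannot be empty")
        if list(self.names) != sorted(set(self.names)):
            raise ValueError("vocabulary names must be sorted and unique")
        object.__setattr__(
            self, "_index", {name: i for i, name in enumerate(self.names)}
        )

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index_of(self, name: str) -> int:
        return self._index[name]

    @property
    def n_slots(self) -> int:
        """Vocabulary size plus the two reserved drug slots."""
        return len(self.names) + 2

    @property
    def drug_slots(self) -> tuple[int, int]:
        return (len(self.names), len(self.names) + 1)


@dataclasses.dataclass(frozen=True)
class SynergyRecord:
    """One assay: a drug (pair) applied to a cell line with a measured score."""

    drug_a: str
    drug_b: str | None
    cell_line: str
    score: float | None

    def __post_init__(self):
        if self.score is not None and not np.isfinite(self.score):
            raise ValueError("synergy score must be finite")

    @property
    def pair_key(self) -> tuple[str, str]:
        """Unordered drug-pair identity (grouping key for inductive splits)."""
        b = self.drug_b or ""
        return tuple(sorted((self.drug_a, b)))


@dataclasses.dataclass
class MolecularNetwork:
    """One sample graph: gene nodes followed by 1–2 drug nodes."""

    node_features: np.ndarray          # n×3
    adjacency: np.ndarray              # n×n symmetric binary, zero diagonal
    gene_global_ids: np.ndarray        # ids into the vocabulary, one per gene
    drug_positions: tuple[int, ...]    # node positions of the drug nodes
    drug_slots: tuple[int, ...]        # global ids of the drug nodes
    cell_line: str
    synergy: float | None = None
    drug_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.gene_global_ids = np.asarray(self.gene_global_ids, dtype=np.intp)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_global_ids)

    @property
    def global_node_ids(self) -> np.ndarray:
        """Global vocabulary ids for every node (genes, then drug slots)."""
        return np.concatenate(
            [self.gene_global_ids, np.asarray(self.drug_slots, dtype=np.intp)]
        )

    def validate(self) -> None:
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if self.node_features.shape != (n, 3):
            raise ValueError("node features must be n×3")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if n != self.n_genes + len(self.drug_positions):
            raise ValueError("node count must equal genes + drugs")
        drugs = list(self.drug_positions)
        if not np.all(self.node_features[drugs] == -1.0):
            raise ValueError("drug node features must all be -1")


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def _split_line(line: str) -> list[str]:
    delim = "\t" if "\t" in line else ","
    return [f.strip() for f in line.split(delim)]


def load_edge_list(path, kind: str) -> set[tuple[str, str]]:
    """Read a two-column edge list (TSV or CSV, optional header).

    ``kind="gene_gene"`` canonicalises pairs as unordered (sorted tuples) and
    drops self-loops; ``kind="drug_gene"`` keeps (drug, gene) order.
    """
    if kind not in ("gene_gene", "drug_gene"):
        raise ValueError(f"unknown edge-list kind: {kind!r}")
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    rows: list[tuple[int, list[str]]] = [
        (i + 1, _split_line(ln)) for i, ln in enumerate(lines) if ln.strip()
    ]
    if not rows:
        raise ValueError(f"empty edge-list file: {path}")
    first = rows[0][1]
    if any(f.lower() in _HEADER_TOKENS for f in first):
        rows = rows[1:]
        if not rows:
            raise ValueError(f"edge-list file has a header but no data: {path}")
    edges: set[tuple[str, str]] = set()
    for lineno, fields in rows:
        usable = [f for f in fields[:2] if f]
        if len(fields) < 2 or len(usable) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 usable fields, got {fields!r}"
            )
        a, b = usable
        if kind == "gene_gene":
            if a == b:
                continue  # zero-diagonal invariant: no self-interactions
            edges.add(tuple(sorted((a, b))))
        else:
            edges.add((a, b))
    if not edges:
        raise ValueError(f"no usable edges in {path}")
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path, header=None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


def build_vocabulary(gene_names: Iterable[str]) -> GeneVocabulary:
    """Sort unique gene names lexicographically into the shared index."""
    names = sorted(set(gene_names))
    if not names:
        raise ValueError("cannot build a vocabulary from an empty collection")
    return GeneVocabulary(tuple(names))


def read_expression(path) -> pd.DataFrame:
    """Gene × cell-line expression table (row index = gene name)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip()
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep)


def read_synergy(path) -> list[SynergyRecord]:
    df = pd.read_csv(path)
    required = {"drug_a", "drug_b", "cell_line", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"synergy table must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        drug_b = None if pd.isna(row.drug_b) or row.drug_b == "" else str(row.drug_b).strip()
        score = None if pd.isna(row.score) else float(row.score)
        records.append(
            SynergyRecord(str(row.drug_a).strip(), drug_b,
                          str(row.cell_line).strip(), score)
        )
    return records


def write_synergy(records: Sequence[SynergyRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "drug_a": r.drug_a,
                "drug_b": "" if r.drug_b is None else r.drug_b,
                "cell_line": r.cell_line,
                "score": r.score,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def assemble_network(
    record: SynergyRecord,
    expression: pd.DataFrame,
    gene_edges: set[tuple[str, str]],
    drug_edges: set[tuple[str, str]],
    vocab: GeneVocabulary,
    zscore: bool = False,
) -> MolecularNetwork:
    """Build the per-sample graph for one synergy record.

    A gene enters the network iff it is in the vocabulary and has expression
    data for the record's cell line.  Genes keep the vocabulary order, so
    ``gene_global_ids`` is identical across networks sharing a gene set.
    Isolated genes are retained (degree 0; the propagation rule adds
    self-loops).  Setting ``zscore`` standardises expression per gene across
    cell lines before slicing.
    """
    if record.cell_line not in expression.columns:
        raise ValueError(f"unknown cell line: {record.cell_line!r}")
    expr = expression
    if zscore:
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1).replace(0.0, 1.0)
        expr = expr.sub(mu, axis=0).div(sd, axis=0)
    col = expr[record.cell_line]

    genes = [g for g in vocab.names if g in col.index and np.isfinite(col[g])]
    if not genes:
        raise ValueError("no genes with expression data available")
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    drugs = [record.drug_a] + ([record.drug_b] if record.drug_b else [])
    n = n_genes + len(drugs)

    targets: dict[str, set[str]] = {d: set() for d in drugs}
    for drug, gene in drug_edges:
        if drug in targets and gene in gene_pos:
            targets[drug].add(gene)

    X = np.zeros((n, 3))
    X[:n_genes, 0] = [col[g] for g in genes]
    for j, drug in enumerate(drugs):
        for g in targets[drug]:
            X[gene_pos[g], 1 + j] = 1.0
    X[n_genes:, :] = -1.0

    A = np.zeros((n, n))
    for a, b in gene_edges:
        if a in gene_pos and b in gene_pos:
            i, j = gene_pos[a], gene_pos[b]
            A[i, j] = A[j, i] = 1.0
    for j, drug in enumerate(drugs):
        dpos = n_genes + j
        if not targets[drug]:
            logger.warning(
                "drug %r has no targets in the network for cell line %s",
                drug, record.cell_line,
            )
        for g in targets[drug]:
            A[dpos, gene_pos[g]] = A[gene_pos[g], dpos] = 1.0

    slots = vocab.drug_slots[: len(drugs)]
    return MolecularNetwork(
        node_features=X,
        adjacency=A,
        gene_global_ids=np.array([vocab.index_of(g) for g in genes], dtype=np.intp),
        drug_positions=tuple(range(n_genes, n)),
        drug_slots=tuple(slots),
        cell_line=record.cell_line,
        synergy=record.score,
        drug_names=tuple(drugs),
    )


def swap_drug_order(net: MolecularNetwork) -> MolecularNetwork:
    """Relabel drug A as drug B and vice versa (two-drug networks only).

    Part of the drug-order input contract: the two drug node rows exchange
    positions and the gene indicator columns (features 1 and 2) swap.  The
    drug *slots* stay attached to positions (first drug → first slot), so a
    caller testing order invariance must also swap the model's drug slots in
    its global edge-weight matrices.
    """
    if len(net.drug_positions) != 2:
        raise ValueError("swap_drug_order requires a two-drug network")
    pa, pb = net.drug_positions
    perm = np.arange(net.n_nodes)
    perm[[pa, pb]] = [pb, pa]
    X = net.node_features[perm].copy()
    gene_rows = slice(0, net.n_genes)
    X[gene_rows, 1], X[gene_rows, 2] = (
        net.node_features[gene_rows, 2].copy(),
        net.node_features[gene_rows, 1].copy(),
    )
    A = net.adjacency[np.ix_(perm, perm)]
    return MolecularNetwork(
        node_features=X,
        adjacency=A,
        gene_global_ids=net.gene_global_ids.copy(),
        drug_positions=net.drug_positions,
        drug_slots=net.drug_slots,
        cell_line=net.cell_line,
        synergy=net.synergy,
        drug_names=tuple(reversed(net.drug_names)),
    )
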