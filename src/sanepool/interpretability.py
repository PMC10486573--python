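"""From pooling traces to gene-importance statistics and core sub-networks.

A trained model's pooling decisions are an interpretable by-product: the
genes that survive to the final pooled layer are the ones actually feeding
the readout.  Per cell line, a gene's *synergic importance* is the
proportion of synergistic samples (synergy > 0) in which it survives, and
its *non-synergic importance* the analogue over synergy < 0 samples.  A
two-sample Kolmogorov–Smirnov test compares the two per-cell-line importance
distributions, and the genes whose synergic-minus-non-synergic difference
exceeds a threshold (default 0.1) form the core gene sub-network together
with their induced interactions.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelConfig, ModelParams, forward
from .network_io import GeneVocabulary, MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionEntry",
    "SelectionLog",
    "build_selection_log",
    "importance_scores",
    "ks_test",
    "ks_by_cell_line",
    "core_subnetwork",
    "export_reports",
]

ALPHA = 0.05


@dataclasses.dataclass(frozen=True)
class SelectionEntry:
    """One evaluated sample: which genes reached the final pooled layer."""

    cell_line: str
    synergy: float
    kept_genes: tuple[str, ...]


@dataclasses.dataclass
class SelectionLog:
    entries: list[SelectionEntry]

    def __len__(self):
        return len(self.entries)

    def cell_lines(self) -> list[str]:
        return sorted({e.cell_line for e in self.entries})


def build_selection_log(networks: Sequence[MolecularNetwork],
                        params: ModelParams, cfg: ModelConfig,
                        vocab: GeneVocabulary) -> SelectionLog:
    """Run the model over samples and record the final-layer gene sets."""
    entries = []
    for net in networks:
        if net.synergy is None:
            continue
        _, trace = forward(net, params, cfg)
        gids = trace[-1].kept_global_ids
        genes = tuple(vocab.names[int(g)] for g in sorted(gids)
                      if g < len(vocab))
        entries.append(SelectionEntry(net.cell_line, float(net.synergy), genes))
    return SelectionLog(entries)


def importance_scores(log: SelectionLog,
                      vocab: GeneVocabulary) -> pd.DataFrame:
    """Per (cell line, gene) selection proportions.

    ``syn_importance`` = fraction of synergy>0 samples of the cell line whose
    final pooled layer contains the gene; ``nonsyn_importance`` analogous for
    synergy<0; samples with synergy exactly 0 are excluded.  Cell lines
    without both classes are skipped with a warning.
    Columns: cell_line, gene, syn_importance, nonsyn_importance, diff.
    """
    if not log.entries:
        raise ValueError("selection log is empty")
    rows = []
    for cell in log.cell_lines():
        syn = [e for e in log.entries if e.cell_line == cell and e.synergy > 0]
        non = [e for e in log.entries if e.cell_line == cell and e.synergy < 0]
        if not syn or not non:
            logger.warning(
                "cell line %s lacks synergic and/or non-synergic samples; skipped",
                cell,
            )
            continue
        syn_counts = np.zeros(len(vocab))
        non_counts = np.zeros(len(vocab))
        for e in syn:
            for g in e.kept_genes:
                syn_counts[vocab.index_of(g)] += 1
        for e in non:
            for g in e.kept_genes:
                non_counts[vocab.index_of(g)] += 1
        s = syn_counts / len(syn)
        q = non_counts / len(non)
        for i, gene in enumerate(vocab.names):
            rows.append({"cell_line": cell, "gene": gene,
                         "syn_importance": s[i], "nonsyn_importance": q[i],
                         "diff": s[i] - q[i]})
    if not rows:
        raise ValueError("no cell line had both synergic and non-synergic samples")
    return pd.DataFrame(rows)


def ks_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value).

    D is the supremum distance between the two empirical CDFs; the p-value
    uses the asymptotic two-sample distribution (no exact small-sample
    enumeration).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("K-S test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_by_cell_line(table: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """K-S test of syn vs non-syn importance distributions per cell line."""
    rows = []
    for cell, sub in table.groupby("cell_line", sort=True):
        D, p = ks_test(sub["syn_importance"].to_numpy(),
                       sub["nonsyn_importance"].to_numpy())
        rows.append({"cell_line": cell, "D": D, "p_value": p,
                     "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def core_subnetwork(table: pd.DataFrame, cell_line: str,
                    gene_edges: Iterable[tuple[str, str]],
                    threshold: float = 0.1):
    """Genes with diff > threshold plus their induced gene–gene edges.

    The inequality is strict, so a zero-difference gene never enters even at
    threshold 0.  Returns ``(genes, edges)`` sorted.
    """
    sub = table[table["cell_line"] == cell_line]
    if sub.empty:
        raise ValueError(f"cell line {cell_line!r} not present in the table")
    genes = sorted(sub.loc[sub["diff"] > threshold, "gene"])
    gene_set = set(genes)
    edges = sorted(
        tuple(sorted((a, b))) for a, b in gene_edges
        if a in gene_set and b in gene_set
    )
    return genes, edges


def export_reports(table: pd.DataFrame, ks_df: pd.DataFrame,
                   subnetworks: dict[str, tuple], out_dir,
                   plots: bool = False) -> list[Path]:
    """Write importance.csv, ks_tests.csv and per-cell-line edge lists.

    With ``plots=True`` an importance heatmap per cell line is also written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    imp = out / "importance.csv"
    table.to_csv(imp, index=False,
                 columns=["cell_line", "gene", "syn_importance",
                          "nonsyn_importance", "diff"])
    written.append(imp)
    ks = out / "ks_tests.csv"
    ks_df.to_csv(ks, index=False,
                 columns=["cell_line", "D", "p_value", "significant"])
    written.append(ks)
    for cell, (genes, edges) in sorted(subnetworks.items()):
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in cell)
        path = out / f"core_{safe}.edges"
        with path.open("w", encoding="utf-8") as fh:
            for a, b in edges:
                fh.write(f"{a}\t{b}\n")
        written.append(path)
    if plots:
        written.append(_heatmap(table, out))
    return written


def _heatmap(table: pd.DataFrame, out: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = table["cell_line"].unique()
    fig, axes = plt.subplots(len(cells), 1, figsize=(10, 2 * len(cells)),
                             squeeze=False)
    for ax, cell in zip(axes.ravel(), cells):
        sub = table[table["cell_line"] == cell]
        ax.imshow(sub[["syn_importance", "nonsyn_importance"]].to_numpy().T,
                  aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_yticks([0, 1], ["syn > 0", "syn < 0"])
        ax.set_title(str(cell))
        ax.set_xlabel("gene index")
    fig.tight_layout()
    path = out / "importance_heatmap.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
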