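"""Inductive cross-validated training and evaluation.

Evaluation is *inductive*: in the default grouping, every sample sharing an
unordered drug pair lands in the same fold, so tested combinations are never
seen during training.  Metrics are Pearson correlation and MSE/RMSE on the
predicted synergy scores, reported per fold and as mean ± s.d. over the five
folds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Adam, Tensor
from .model import ModelConfig, ModelParams, forward, init_params
from .network_io import MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "EvalReport",
    "make_folds",
    "train_model",
    "cross_validate",
    "pearson_r",
    "mse_rmse",
]

N_FOLDS = 5


@dataclasses.dataclass
class FoldPlan:
    """Sample-index → fold assignment."""

    fold_assignments: dict[int, int]
    grouping: str
    seed: int

    def fold_of(self, sample_idx: int) -> int:
        return self.fold_assignments[sample_idx]

    def test_indices(self, fold: int) -> list[int]:
        return [i for i, f in self.fold_assignments.items() if f == fold]

    def train_indices(self, fold: int) -> list[int]:
        return [i for i, f in self.fold_assignments.items() if f != fold]


def _group_key(record) -> tuple:
    return record.pair_key


def make_folds(records, grouping: str = "by_drug_pair", seed: int = 0,
               n_folds: int = N_FOLDS) -> FoldPlan:
    """Deterministic balanced fold assignment.

    ``by_drug_pair`` shuffles the distinct unordered drug pairs with the seed
    and deals them round-robin into folds, so group counts differ by at most
    one and no pair straddles folds.  ``random`` deals individual samples.
    """
    if grouping not in ("by_drug_pair", "random"):
        raise ValueError(f"unknown grouping: {grouping!r}")
    rng = np.random.default_rng(seed)
    assignments: dict[int, int] = {}
    if grouping == "by_drug_pair":
        groups = sorted({_group_key(r) for r in records})
        if len(groups) < n_folds:
            raise ValueError(
                f"need at least {n_folds} distinct drug pairs, got {len(groups)}"
            )
        order = rng.permutation(len(groups))
        fold_of_group = {groups[g]: i % n_folds for i, g in enumerate(order)}
        for i, r in enumerate(records):
            assignments[i] = fold_of_group[_group_key(r)]
    else:
        if len(records) < n_folds:
            raise ValueError(f"need at least {n_folds} samples")
        order = rng.permutation(len(records))
        for i, s in enumerate(order):
            assignments[int(s)] = i % n_folds
    return FoldPlan(assignments, grouping, seed)


def train_model(networks: list[MolecularNetwork], cfg: ModelConfig,
                n_vocab: int, params: ModelParams | None = None,
                epochs: int = 100, lr: float = 5e-3, batch_size: int = 4,
                seed: int = 0, shuffle: bool = True,
                lr_decay: bool = True):
    """Minimise MSE on synergy scores with Adam; returns (params, history).

    The default schedule anneals the learning rate with a cosine curve to
    10% of its peak.  ``history`` is the per-epoch mean training MSE
    (computed from the predictions made during that epoch, before each
    update).  Divergence to non-finite loss raises with the epoch index.
    """
    if not networks:
        raise ValueError("empty training set")
    if any(n.synergy is None for n in networks):
        raise ValueError("all training networks need a synergy label")
    rng = np.random.default_rng(seed)
    if params is None:
        params = init_params(cfg, n_vocab, rng)
    opt = Adam(params.all(), lr=lr)
    history: list[float] = []
    n = len(networks)
    for epoch in range(epochs):
        if lr_decay:
            opt.lr = lr * (0.1 + 0.45 * (1 + np.cos(np.pi * epoch / epochs)))
        order = rng.permutation(n) if shuffle else np.arange(n)
        sq_errors = []
        for start in range(0, n, batch_size):
            batch = order[start:start + batch_size]
            opt.zero_grad()
            for s in batch:
                net = networks[s]
                score, _ = forward(net, params, cfg)
                err = score - Tensor(np.array(net.synergy))
                loss = (err * err) * (1.0 / len(batch))
                loss.backward()
                sq_errors.append(float(err.data) ** 2)
            opt.step()
        epoch_mse = float(np.mean(sq_errors))
        if not np.isfinite(epoch_mse):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        history.append(epoch_mse)
    return params, history


def pearson_r(pred, truth) -> float:
    """Sample Pearson correlation; rejects constant inputs."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    return float(stats.pearsonr(pred, truth).statistic)


def mse_rmse(pred, truth) -> tuple[float, float]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("need two equal-length non-empty vectors")
    mse = float(np.mean((pred - truth) ** 2))
    return mse, float(np.sqrt(mse))


@dataclasses.dataclass
class EvalReport:
    """Per-fold metrics and their mean ± s.d."""

    folds: list[dict]
    grouping: str
    seed: int
    config_hash: str

    def _col(self, key):
        return np.array([f[key] for f in self.folds])

    def summary(self) -> dict:
        out = {}
        for key in ("pearson_r", "mse", "rmse"):
            vals = self._col(key)
            out[f"{key}_mean"] = float(vals.mean())
            out[f"{key}_std"] = float(vals.std(ddof=0))
        return out

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "summary": self.summary(),
            "grouping": self.grouping,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _config_hash(cfg: ModelConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def cross_validate(networks: list[MolecularNetwork], records, cfg: ModelConfig,
                   n_vocab: int, grouping: str = "by_drug_pair", seed: int = 0,
                   epochs: int = 100, lr: float = 1e-3, batch_size: int = 16,
                   collect_selections: bool = False):
    """5-fold inductive evaluation.

    Returns ``(report, predictions_df)`` and, with ``collect_selections``,
    additionally the held-out selection log entries
    ``(sample_index, cell_line, synergy, kept gene global ids)`` from the
    final pooling layer — the raw material for held-out importance scores.
    """
    plan = make_folds(records, grouping=grouping, seed=seed)
    folds, rows, selections = [], [], []
    for fold in range(N_FOLDS):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        if grouping == "by_drug_pair":
            seen = {_group_key(records[i]) for i in tr}
            leaked = [i for i in te if _group_key(records[i]) in seen]
            assert not leaked, "drug pair leaked across the inductive split"
        params, _ = train_model([networks[i] for i in tr], cfg, n_vocab,
                                epochs=epochs, lr=lr, batch_size=batch_size,
                                seed=seed + fold)
        preds, truths = [], []
        for i in te:
            score, trace = forward(networks[i], params, cfg)
            preds.append(float(score.data))
            truths.append(networks[i].synergy)
            rows.append({"sample_id": i, "fold": fold,
                         "truth": networks[i].synergy,
                         "pred": float(score.data)})
            if collect_selections:
                gids = trace[-1].kept_global_ids
                genes = tuple(int(g) for g in gids if g < n_vocab)
                selections.append((i, networks[i].cell_line,
                                   networks[i].synergy, genes))
        m, r = mse_rmse(preds, truths)
        folds.append({"fold": fold, "n": len(te),
                      "pearson_r": pearson_r(preds, truths),
                      "mse": m, "rmse": r})
        logger.info("fold %d: r=%.3f mse=%.3f (n=%d)", fold,
                    folds[-1]["pearson_r"], m, len(te))
    report = EvalReport(folds, grouping, seed, _config_hash(cfg))
    pred_df = pd.DataFrame(rows)
    if collect_selections:
        return report, pred_df, selections
    return report, pred_df
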