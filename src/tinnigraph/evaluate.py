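"""Classifier evaluation: confusion matrix, metric suite, cross-validated
training, and PCA projection of model activations.

Confusion rates are reported row-normalized (per true class) alongside the
raw counts, so either convention can be audited. "Recall" and
"sensitivity" are the same quantity and are echoed under both keys.
Ratios with zero denominators are reported as None with a reason, never
silently coerced to 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .graph import FeatureGraph, FoldSpec, make_fold_masks, normalize_adjacency
from .model import ModelConfig, train, predict

__all__ = [
    "ConfusionResult",
    "EvalReport",
    "confusion",
    "metrics",
    "cross_validate",
    "CVReport",
    "pca_projection",
    "ProjectionResult",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionResult:
    """Counts use class 1 as positive: tp = true 1 predicted 1."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def rates(self) -> dict[str, float | None]:
        """Row-normalized proportions: each true-class row sums to 1."""
        pos = self.tp + self.fn
        neg = self.tn + self.fp
        return {
            "tp": self.tp / pos if pos else None,
            "fn": self.fn / pos if pos else None,
            "tn": self.tn / neg if neg else None,
            "fp": self.fp / neg if neg else None,
        }


def _check_binary(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return y


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionResult:
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionResult(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


@dataclass
class EvalReport:
    counts: ConfusionResult
    rates: dict[str, float | None]
    accuracy: float
    precision: float | None
    recall: float | None
    sensitivity: float | None
    f1: float | None
    kappa: float | None
    auc: float | None
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def metrics(y_true: np.ndarray, y_pred: np.ndarray,
            scores: np.ndarray | None = None) -> EvalReport:
    """Full metric suite from the confusion counts.

    accuracy = (TP+TN)/N; precision = TP/(TP+FP);
    recall = sensitivity = TP/(TP+FN); F1 = 2PR/(P+R);
    kappa = (p_o - p_e)/(1 - p_e) with chance agreement from the marginals;
    AUC from ``scores`` (class-1 probabilities) as a rank statistic.
    """
    cm = confusion(y_true, y_pred)
    undefined: dict[str, str] = {}
    n = cm.n
    if n == 0:
        raise ValueError("empty prediction set")
    accuracy = (cm.tp + cm.tn) / n

    precision = recall = f1 = None
    if cm.tp + cm.fp:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        undefined["precision"] = "no positive predictions (TP+FP = 0)"
    if cm.tp + cm.fn:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        undefined["recall"] = "no positive ground truth (TP+FN = 0)"
    if precision is not None and recall is not None:
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            undefined["f1"] = "precision + recall = 0"
    else:
        undefined["f1"] = "precision or recall undefined"

    p_o = accuracy
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    kappa = None
    if abs(1.0 - p_e) > 1e-15:
        kappa = (p_o - p_e) / (1.0 - p_e)
    else:
        undefined["kappa"] = "chance agreement = 1 (single marginal class)"

    auc = None
    y_true_arr = _check_binary(y_true, "y_true")
    if scores is None:
        undefined["auc"] = "no scores provided"
        logger.debug("AUC omitted: no scores")
    elif len(np.unique(y_true_arr)) < 2:
        undefined["auc"] = "only one class present"
    else:
        auc = float(roc_auc_score(y_true_arr, np.asarray(scores, dtype=float)))

    return EvalReport(counts=cm, rates=cm.rates(), accuracy=accuracy,
                      precision=precision, recall=recall, sensitivity=recall,
                      f1=f1, kappa=kappa, auc=auc, undefined=undefined)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    pooled: EvalReport
    fold_accuracy: list[float]
    fold_best_epoch: list[int]
    mode: str
    n_folds: int
    seed: int
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    activations: np.ndarray

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "fold_accuracy": self.fold_accuracy,
            "fold_best_epoch": self.fold_best_epoch,
            "mode": self.mode,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def _run_fold(g: FeatureGraph, fold: FoldSpec, cfg: ModelConfig, mode: str,
              global_na) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    if mode == "transductive":
        tm = train(g, fold.train_idx, fold.val_idx, cfg, norm_adj=global_na)
        labels, probs, acts = predict(tm, g, mask=fold.test_idx,
                                      norm_adj=global_na)
        return labels, probs[:, 1], acts, tm.best_epoch
    # Inductive: fit on the training subgraph, then evaluate on the full
    # graph (test nodes attach through their own distances only at this
    # point); the trained weights never saw a test row.
    sub = fold.train_graph
    local = {int(gidx): i for i, gidx in enumerate(fold.train_index)}
    tr = np.array([local[int(i)] for i in fold.train_idx])
    va = np.array([local[int(i)] for i in fold.val_idx])
    tm = train(sub, tr, va, cfg)
    labels, probs, acts = predict(tm, g, mask=fold.test_idx,
                                  norm_adj=global_na)
    return labels, probs[:, 1], acts, tm.best_epoch


def cross_validate(g: FeatureGraph, model_config: ModelConfig | None = None,
                   n_folds: int = 10, mode: str = "transductive",
                   seed: int = 0,
                   groups: np.ndarray | None = None) -> CVReport:
    """Train one model per fold and pool the held-out predictions.

    Every node is predicted exactly once (folds partition the graph);
    metrics are computed on the pooled predictions and per-fold accuracy
    is reported alongside. The per-fold model seed derives from ``seed``.
    """
    base = model_config or ModelConfig()
    folds = make_fold_masks(g, n_folds=n_folds, mode=mode, seed=seed,
                            groups=groups)
    global_na = normalize_adjacency(g)
    n = g.n_nodes
    y_pred = np.full(n, -1, dtype=int)
    scores = np.full(n, np.nan)
    acts = np.zeros((n, base.lstm_hidden))
    fold_acc: list[float] = []
    fold_best: list[int] = []
    for fold in folds:
        cfg = ModelConfig(**{**asdict(base), "seed": base.seed + 1000 * (fold.fold + 1)})
        try:
            labels, s1, a, best = _run_fold(g, fold, cfg, mode, global_na)
        except Exception as exc:  # noqa: BLE001 - re-raise with fold context
            raise RuntimeError(f"fold {fold.fold} failed: {exc}") from exc
        y_pred[fold.test_idx] = labels
        scores[fold.test_idx] = s1
        acts[fold.test_idx] = a
        fold_acc.append(float((labels == g.y[fold.test_idx]).mean()))
        fold_best.append(int(best))
    assert (y_pred >= 0).all(), "folds did not cover every node"
    pooled = metrics(g.y, y_pred, scores=scores)
    return CVReport(pooled=pooled, fold_accuracy=fold_acc,
                    fold_best_epoch=fold_best, mode=mode, n_folds=n_folds,
                    seed=seed, y_true=g.y.copy(), y_pred=y_pred,
                    scores=scores, activations=acts)


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectionResult:
    coordinates: np.ndarray            # (n, 2)
    explained_variance_ratio: np.ndarray
    components: np.ndarray             # (2, d), orthonormal rows


def pca_projection(activations: np.ndarray) -> ProjectionResult:
    """Top-2 principal components of mean-centered activations.

    Deterministic sign convention: within each component, the loading of
    largest magnitude is made positive. Rank-1 input gets a zero second
    component with a warning.
    """
    A = np.asarray(activations, dtype=float)
    if A.shape[0] < 3 or A.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 dimensions")
    rank = np.linalg.matrix_rank(A - A.mean(axis=0))
    n_comp = min(2, max(1, rank))
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(A)
    comps = pca.components_
    evr = pca.explained_variance_ratio_
    if n_comp < 2:
        logger.warning("activations have rank < 2: second component is zero")
        coords = np.column_stack([coords, np.zeros(A.shape[0])])
        comps = np.vstack([comps, np.zeros(A.shape[1])])
        evr = np.append(evr, 0.0)
    for k in range(2):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            coords[:, k] = -coords[:, k]
    return ProjectionResult(coordinates=coords, explained_variance_ratio=evr,
                            components=comps)


def plot_projection(proj: ProjectionResult, labels: np.ndarray,
                    path: str | Path) -> Path:
    """Scatter of the 2-D projection colored by class (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for cls, color in ((0, "tab:blue"), (1, "tab:red")):
        m = labels == cls
        ax.scatter(proj.coordinates[m, 0], proj.coordinates[m, 1],
                   s=8, alpha=0.6, c=color, label=f"class {cls}")
    ax.set_xlabel(f"PC1 ({proj.explained_variance_ratio[0]:.1%})")
    ax.set_ylabel(f"PC2 ({proj.explained_variance_ratio[1]:.1%})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
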