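"""Case/control prediction from expression matrices.

Implements the supervised half of the pipeline: an architecture zoo (two
dense networks, two 1-D convolutional networks, one recurrent LSTM
network), gene-list feature filtering, stratified k-fold cross-validated
training with an Adam/softmax-cross-entropy loop, tissue-specific
evaluation, cross-tissue transfer (a train-tissue x test-tissue AUC
matrix), shallow baselines, and a paired test comparing per-tissue AUCs
with and without a feature filter.

The flat gene vector feeds the LSTM as a sequence of fixed-length chunks
(zero-padded); a single-timestep mode (one step carrying the whole vector)
is available as a config alternative. AUC is computed with the rank
(Mann-Whitney) formulation so ties are handled exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_rel
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import nn
from .prioritization import TissueGeneLists

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "MetricsReport",
    "FilterList",
    "CrossTissueMatrix",
    "ClassifierRun",
    "apply_gene_filter",
    "filter_from_gene_lists",
    "train_classifier",
    "evaluate_metrics",
    "predict_scores",
    "cross_tissue_eval",
    "compare_filters",
    "shallow_baselines",
    "majority_baseline",
    "auc_mann_whitney",
]

logger = logging.getLogger(__name__)

ARCHITECTURES = ("dense-1", "dense-2", "conv-1", "conv-2", "recurrent")

#: full-scale layer widths; ``reduced=True`` swaps in desk-scale widths
FULL_LSTM_UNITS = (150, 10)
REDUCED_LSTM_UNITS = (16, 4)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan of one classifier network.

    ``kind`` selects the plan: dense-1 (800/500/400/200/40/2), dense-2
    (800/200/2), conv-1 (10- and 5-filter convolutions with dropout, dense
    200/100/2), conv-2 (10- and 5-filter convolutions, dense 2), recurrent
    (LSTM 150 -> batch norm -> LSTM 10 -> batch norm -> dense 2; reduced
    widths 16/4 for desk-scale runs). Convolution kernel/stride and the LSTM
    chunking of the gene vector are package choices, the sources never fix
    them.
    """

    kind: str
    input_width: int
    reduced: bool = False
    lstm_units: tuple[int, int] | None = None
    chunk: int = 64
    single_timestep: bool = False
    conv_kernel: int = 8
    conv_stride: int = 4
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.kind!r}; choose from {ARCHITECTURES}")
        if self.input_width <= 0:
            raise ValueError("input_width must be positive")

    def resolved_lstm_units(self) -> tuple[int, int]:
        if self.lstm_units is not None:
            return self.lstm_units
        return REDUCED_LSTM_UNITS if self.reduced else FULL_LSTM_UNITS

    def _dense_plan(self) -> list[int]:
        full = {"dense-1": [800, 500, 400, 200, 40], "dense-2": [800, 200]}[self.kind]
        if not self.reduced:
            return full
        return [max(4, w // 16) for w in full]

    def build(self, rng: np.random.Generator) -> nn.Sequential:
        layers: list[nn.Layer] = []
        if self.kind in ("dense-1", "dense-2"):
            width = self.input_width
            for w in self._dense_plan():
                layers += [nn.Dense(width, w, rng), nn.ReLU()]
                width = w
            layers.append(nn.Dense(width, 2, rng))
        elif self.kind in ("conv-1", "conv-2"):
            length = self.input_width

            def conv(in_ch: int, out_ch: int) -> nn.Conv1D:
                # clamp kernel/stride so short sequences survive deep stacks
                nonlocal length
                k = min(self.conv_kernel, length)
                s = min(self.conv_stride, k)
                layer = nn.Conv1D(in_ch, out_ch, k, rng, s)
                length = (length - k) // s + 1
                return layer

            layers.append(nn.ToChannels())
            if self.kind == "conv-1":
                layers += [conv(1, 10), nn.ReLU()]
                layers += [conv(10, 5), nn.ReLU(), nn.Dropout(self.dropout, rng)]
                layers += [conv(5, 5), nn.ReLU()]
                flat = 5 * length
                d1, d2 = (200, 100) if not self.reduced else (32, 16)
                layers += [
                    nn.Flatten(),
                    nn.Dense(flat, d1, rng),
                    nn.ReLU(),
                    nn.Dropout(self.dropout, rng),
                    nn.Dense(d1, d2, rng),
                    nn.ReLU(),
                    nn.Dense(d2, 2, rng),
                ]
            else:
                layers += [conv(1, 10), nn.ReLU(), nn.Dropout(self.dropout, rng)]
                layers += [conv(10, 5), nn.ReLU()]
                layers += [nn.Flatten(), nn.Dense(5 * length, 2, rng)]
        else:  # recurrent
            u1, u2 = self.resolved_lstm_units()
            chunk = self.input_width if self.single_timestep else min(self.chunk, self.input_width)
            layers += [
                nn.ToSequence(chunk),
                nn.LSTM(chunk, u1, rng, return_sequences=True),
                nn.BatchNorm(u1),
                nn.LSTM(u1, u2, rng, return_sequences=False),
                nn.BatchNorm(u2),
                nn.Dense(u2, 2, rng),
            ]
        return nn.Sequential(layers)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 100
    learning_rate: float = 0.001
    n_folds: int = 10
    balanced: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "n_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MetricsReport:
    """Accuracy, AUC, precision, recall, F1 on one named evaluation partition."""

    partition: str
    accuracy: float
    auc: float  # NaN when the partition has a single class
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class FilterList:
    """A named feature-selection gene list (per tissue or global)."""

    name: str
    provenance: str  # unsupervised | association | external
    per_tissue: dict[str, list[str]] | None = None
    global_genes: list[str] | None = None

    def genes_for(self, tissue: str | None = None) -> list[str]:
        if self.per_tissue is not None:
            if tissue is None or tissue not in self.per_tissue:
                raise ValueError(f"filter {self.name!r} has no list for tissue {tissue!r}")
            return self.per_tissue[tissue]
        if self.global_genes is None:
            raise ValueError(f"filter {self.name!r} carries no genes")
        return self.global_genes


def filter_from_gene_lists(lists: TissueGeneLists, name: str = "List-unsupervised") -> FilterList:
    """Per-tissue filter = union of a tissue's retained up and down genes."""
    per_tissue = {t: lists.combined_retained(t) for t in lists.tissues}
    global_genes = sorted({g for genes in per_tissue.values() for g in genes})
    return FilterList(
        name=name, provenance="unsupervised", per_tissue=per_tissue, global_genes=global_genes
    )


def apply_gene_filter(
    matrix: pd.DataFrame, gene_filter: FilterList, tissue: str | None = None
) -> pd.DataFrame:
    """Restrict matrix columns to the filter's genes, preserving column order.

    Filter genes absent from the matrix are dropped silently with a logged
    count; an empty intersection is an error.
    """
    wanted = set(
        gene_filter.genes_for(tissue) if gene_filter.per_tissue else gene_filter.genes_for()
    )
    keep = [g for g in matrix.columns if g in wanted]
    dropped = len(wanted) - len(keep)
    if dropped:
        logger.info("filter %s: %d genes absent from the matrix", gene_filter.name, dropped)
    if not keep:
        raise ValueError(f"filter {gene_filter.name!r} shares no genes with the matrix")
    return matrix[keep]


@dataclass
class ClassifierRun:
    """A trained classifier plus its cross-validated training metrics."""

    model: nn.Sequential
    arch: ArchitectureSpec
    config: TrainConfig
    fold_metrics: list[MetricsReport]
    train_auc: float  # fold-mean AUC, the "training AUC" reported on diagonals
    train_accuracy: float


def _fit(
    model: nn.Sequential,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> None:
    loss_fn = nn.SoftmaxCrossEntropy()
    optimizer = nn.Adam(model.params(), learning_rate=config.learning_rate)
    weights = None
    if config.balanced:
        counts = np.bincount(y, minlength=2).astype(float)
        class_w = counts.sum() / (2.0 * np.maximum(counts, 1.0))
        weights = class_w[y]
    batch = min(config.batch_size, x.shape[0])
    for _ in range(config.epochs):
        order = rng.permutation(x.shape[0])
        for start in range(0, x.shape[0], batch):
            idx = order[start : start + batch]
            logits = model.forward(x[idx], train=True)
            loss, grad = loss_fn.forward(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError("non-finite training loss")
            if weights is not None:
                w = weights[idx][:, None]
                grad = grad * w / w.mean()
            optimizer.zero_grad()
            model.backward(grad)
            optimizer.step()


def predict_scores(model: nn.Sequential, x: np.ndarray) -> np.ndarray:
    """Positive-class softmax probability per row (evaluation mode)."""
    logits = model.forward(np.asarray(x, dtype=np.float64), train=False)
    return nn.SoftmaxCrossEntropy.probabilities(logits)[:, 1]


def auc_mann_whitney(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank-statistic formulation (exact under ties)."""
    y = np.asarray(y_true).astype(int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _metrics_from_scores(y: np.ndarray, scores: np.ndarray, partition: str) -> MetricsReport:
    pred = (scores >= 0.5).astype(int)
    tp = float(np.sum((y == 1) & (pred == 1)))
    fp = float(np.sum((y == 0) & (pred == 1)))
    fn = float(np.sum((y == 1) & (pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsReport(
        partition=partition,
        accuracy=float(np.mean(pred == y)),
        auc=auc_mann_whitney(y, scores),
        precision=precision,
        recall=recall,
        f1=f1,
    )


def evaluate_metrics(model: nn.Sequential, x: np.ndarray, y: np.ndarray,
                     partition: str = "test") -> MetricsReport:
    """All five monitored scores; the predicted class is the softmax argmax."""
    y = np.asarray(y).astype(int)
    if y.size == 0:
        raise ValueError("empty evaluation partition")
    return _metrics_from_scores(y, predict_scores(model, x), partition)


def train_classifier(
    x: np.ndarray,
    y: np.ndarray,
    arch: ArchitectureSpec,
    config: TrainConfig = TrainConfig(),
) -> ClassifierRun:
    """Stratified k-fold cross-validated training, then a refit on all rows.

    Each fold trains a fresh network and is scored on its held-out rows; the
    fold-mean AUC/accuracy summarize the training phase. Deterministic given
    ``config.seed``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training rows contain a single class")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    fold_metrics: list[MetricsReport] = []
    for fold, (tr, va) in enumerate(skf.split(x, y)):
        rng = np.random.default_rng(config.seed + 1000 + fold)
        model = arch.build(rng)
        _fit(model, x[tr], y[tr], config, rng)
        fold_metrics.append(evaluate_metrics(model, x[va], y[va], partition=f"fold{fold}"))
    rng = np.random.default_rng(config.seed)
    final = arch.build(rng)
    _fit(final, x, y, config, rng)
    aucs = [m.auc for m in fold_metrics if np.isfinite(m.auc)]
    return ClassifierRun(
        model=final,
        arch=arch,
        config=config,
        fold_metrics=fold_metrics,
        train_auc=float(np.mean(aucs)) if aucs else float("nan"),
        train_accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
    )


@dataclass
class CrossTissueMatrix:
    """Train-tissue x test-tissue AUC matrix; diagonal = training-phase AUC."""

    auc: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.auc.index) != list(self.auc.columns):
            raise ValueError("cross-tissue matrix must be square over one tissue set")


def cross_tissue_eval(
    runs: dict[str, ClassifierRun],
    test_data: dict[str, tuple[np.ndarray, np.ndarray]],
) -> CrossTissueMatrix:
    """Evaluate every tissue's model on every other tissue's test rows.

    All models must share the zero-filled union gene representation (equal
    input width). Entry (i, j) is the AUC of the model trained on tissue i
    applied to tissue j's held-out rows; the diagonal reports each model's
    training-phase (cross-validated) AUC.
    """
    tissues = sorted(runs)
    if sorted(test_data) != tissues:
        raise ValueError("models and test matrices cover different tissue sets")
    widths = {runs[t].arch.input_width for t in tissues}
    widths.update(test_data[t][0].shape[1] for t in tissues)
    if len(widths) != 1:
        raise ValueError(f"gene-universe mismatch across tissues: widths {sorted(widths)}")
    matrix = pd.DataFrame(index=tissues, columns=tissues, dtype=float)
    for i in tissues:
        for j in tissues:
            if i == j:
                matrix.loc[i, j] = runs[i].train_auc
            else:
                xj, yj = test_data[j]
                matrix.loc[i, j] = auc_mann_whitney(
                    np.asarray(yj).astype(int), predict_scores(runs[i].model, xj)
                )
    return CrossTissueMatrix(auc=matrix)


@dataclass
class FilterComparison:
    statistic: float
    pvalue: float  # NaN when the paired differences have zero variance
    mean_difference: float
    note: str = ""


def compare_filters(
    auc_no_filter: np.ndarray, auc_filtered: np.ndarray
) -> FilterComparison:
    """Paired t-test on per-tissue AUC differences (filtered minus unfiltered)."""
    a = np.asarray(auc_no_filter, dtype=float)
    b = np.asarray(auc_filtered, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired AUC vectors of length >= 3")
    diff = b - a
    if np.allclose(diff.var(), 0.0):
        return FilterComparison(
            statistic=float("nan"),
            pvalue=float("nan"),
            mean_difference=float(diff.mean()),
            note="zero-variance paired differences; test undefined",
        )
    stat, pval = ttest_rel(b, a)
    return FilterComparison(
        statistic=float(stat), pvalue=float(pval), mean_difference=float(diff.mean())
    )


def shallow_baselines(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
) -> dict[str, MetricsReport]:
    """Logistic regression, SVM and random-forest baselines on one split."""
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)
    models = {
        "logistic-regression": LogisticRegression(max_iter=2000),
        "svm": SVC(random_state=seed),
        "random-forest": RandomForestClassifier(n_estimators=200, random_state=seed),
    }
    reports = {}
    for name, clf in models.items():
        clf.fit(x_train, y_train)
        if hasattr(clf, "predict_proba"):
            scores = clf.predict_proba(x_test)[:, 1]
        else:  # margin scores rank identically for AUC; squash for thresholding
            from scipy.special import expit

            scores = expit(clf.decision_function(x_test))
        reports[name] = _metrics_from_scores(y_test, scores, partition=f"test:{name}")
    return reports


def majority_baseline(y_train: np.ndarray, y_test: np.ndarray) -> MetricsReport:
    """Constant majority-class predictor: accuracy = majority fraction, AUC = 0.5.

    Scored through the same metric code as real models (constant scores tie
    every pair, so the rank AUC is exactly 0.5), reproducing the degenerate
    pattern of collapsed shallow classifiers.
    """
    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)
    majority = int(np.bincount(y_train, minlength=2).argmax())
    scores = np.full(y_test.shape, 1.0 if majority == 1 else 0.0)
    return _metrics_from_scores(y_test, scores, partition="test:majority")
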