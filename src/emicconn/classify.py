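"""Leave-one-out cross-validated linear-SVM classification.

In every fold the Kendall-tau edge ranking is recomputed on the N-1
training subjects only, the top-k edges are selected, features are
standardized with training-fold statistics, and a linear SVM (libsvm
C-SVC, C = 1) predicts the held-out subject.  Scores exactly on the
decision boundary resolve to +1 (control) — a fixed rule instead of
platform-dependent behaviour.  The whole procedure is deterministic: there
is no random state anywhere in the pipeline.

Performance is summarized by the generalization rate GR (all subjects
correct), sensitivity SS (patients correct) and specificity SC (controls
correct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .connectivity import FeatureTable
from .ranking import RankedEdges, rank_edges, select_top_k

__all__ = [
    "FoldResult",
    "ClassificationReport",
    "metrics",
    "loocv_classify",
    "accuracy_sweep",
    "DEFAULT_SWEEP",
]

#: the standard accuracy-vs-k sweep: 50, 100, ..., 1000 selected connections
DEFAULT_SWEEP = tuple(range(50, 1001, 50))


@dataclass(frozen=True)
class FoldResult:
    """Outcome of one leave-one-out fold."""

    held_out_subject: str
    true_label: int
    predicted_label: int
    selected_edges: np.ndarray       # training-only top-k edge indices
    fold_ranking: RankedEdges        # full training-only ranking


@dataclass(frozen=True)
class ClassificationReport:
    """LOOCV summary: rates plus the per-fold details consensus needs."""

    gr: float
    ss: float
    sc: float
    k: int
    measure: str
    folds: tuple[FoldResult, ...] = field(repr=False)

    @property
    def fold_selections(self) -> list[np.ndarray]:
        return [f.selected_edges for f in self.folds]

    @property
    def fold_rankings(self) -> list[RankedEdges]:
        return [f.fold_ranking for f in self.folds]

    def to_dict(self) -> dict:
        return {
            "gr": self.gr,
            "ss": self.ss,
            "sc": self.sc,
            "k": self.k,
            "measure": self.measure,
            "folds": [
                {
                    "held_out_subject": f.held_out_subject,
                    "true_label": int(f.true_label),
                    "predicted_label": int(f.predicted_label),
                    "selected_edges": [int(e) for e in f.selected_edges],
                }
                for f in self.folds
            ],
        }


def metrics(predictions, truths) -> tuple[float, float, float]:
    """(GR, SS, SC): overall, patient (-1), and control (+1) accuracy."""
    predictions = np.asarray(predictions, dtype=int)
    truths = np.asarray(truths, dtype=int)
    if predictions.size == 0:
        raise ValueError("empty input")
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    correct = predictions == truths
    gr = float(correct.mean())
    patients = truths == -1
    controls = truths == 1
    ss = float(correct[patients].mean()) if patients.any() else float("nan")
    sc = float(correct[controls].mean()) if controls.any() else float("nan")
    return gr, ss, sc


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def loocv_classify(table: FeatureTable, k: int = 200, *, C: float = 1.0,
                   standardize: bool = True) -> ClassificationReport:
    """Leave-one-out classification with fold-internal top-k tau selection."""
    X, y = table.matrix, table.labels
    N = table.n_subjects
    if N < 4:
        raise ValueError("need at least 4 subjects")
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    if not 1 <= k <= table.n_edges:
        raise ValueError(f"k={k} out of range 1..{table.n_edges}")
    folds = []
    predictions = np.empty(N, dtype=int)
    for i in range(N):
        train = np.ones(N, dtype=bool)
        train[i] = False
        ranking = rank_edges(X[train], y[train])
        sel = select_top_k(ranking, k)
        Xtr, Xte = X[train][:, sel], X[i:i + 1, sel]
        if standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        svm = SVC(kernel="linear", C=C)
        svm.fit(Xtr, y[train])
        # classes_ is sorted [-1, +1]; positive score -> +1.  Exact zero -> +1.
        score = float(svm.decision_function(Xte)[0])
        predictions[i] = 1 if score >= 0 else -1
        folds.append(FoldResult(
            held_out_subject=table.subject_ids[i],
            true_label=int(y[i]),
            predicted_label=int(predictions[i]),
            selected_edges=sel,
            fold_ranking=ranking,
        ))
    gr, ss, sc = metrics(predictions, y)
    return ClassificationReport(gr=gr, ss=ss, sc=sc, k=k,
                                measure=table.measure, folds=tuple(folds))


def accuracy_sweep(table: FeatureTable, ks=DEFAULT_SWEEP, *, C: float = 1.0,
                   standardize: bool = True) -> dict[int, ClassificationReport]:
    """One LOOCV report per feature count k (deterministic given the table)."""
    ks = [int(k) for k in ks]
    bad = [k for k in ks if k > table.n_edges]
    if bad:
        raise ValueError(f"k values {bad} exceed the {table.n_edges} edges")
    return {
        k: loocv_classify(table, k, C=C, standardize=standardize) for k in ks
    }
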