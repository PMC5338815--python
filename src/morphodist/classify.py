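"""Linear C-SVM classification on the embedded space with k-fold CV.

The cross-validation operates directly on a pairwise distance matrix: in the
default ``fold_honest`` mode each fold refits the MDS embedding on the
training-subject submatrix only, projects the held-out subjects in via the
Nystrom extension, trains a soft-margin linear SVM (C = 1) on the training
embedding and predicts the held-out subjects.  No held-out distance ever
touches the training eigendecomposition.  ``transductive`` mode embeds the
whole cohort once and cross-validates only the classifier — an optimistic
protocol kept for leakage audits.

Predictions and signed decision values are pooled over folds into a single
confusion table (micro-average); SEN/SPE/PPV/NPV/ACCU are reported as
percentages rounded to two decimals and the ROC/AUC is computed from the
pooled decision values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .embedding import ClassicalMDS

__all__ = [
    "CONTRASTS",
    "FoldAssignment",
    "ConfusionCounts",
    "MetricsReport",
    "DistanceSVMClassifier",
    "make_folds",
    "train_svm",
    "cross_validate",
    "compute_metrics",
    "roc_auc",
]

# contrast name -> (negative/control class, positive/disease class)
CONTRASTS = {
    "NCvsAD": ("NC", "AD"),
    "NCvsPMCI": ("NC", "pMCI"),
    "sMCIvsPMCI": ("sMCI", "pMCI"),
}


@dataclass
class FoldAssignment:
    k: int
    assignments: dict[str, int]
    seed: int
    stratified: bool

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    contrast: str
    roi: str
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    roc_points: list[tuple[float, float]]
    auc: float
    per_fold: list[ConfusionCounts] = field(default_factory=list)
    mode: str = "fold_honest"


def _round2(x: float) -> float:
    return round(float(x), 2)


def compute_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """SEN/SPE/PPV/NPV/ACCU as percentages rounded to 2 decimals.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return _round2(100.0 * num / den) if den > 0 else None

    c = counts
    return {
        "SEN": ratio(c.tp, c.tp + c.fn),
        "SPE": ratio(c.tn, c.tn + c.fp),
        "PPV": ratio(c.tp, c.tp + c.fp),
        "NPV": ratio(c.tn, c.tn + c.fn),
        "ACCU": ratio(c.tp + c.tn, c.total),
    }


def roc_auc(decision_values, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    The trapezoidal area equals the tie-corrected concordance statistic over
    positive-negative pairs; all-tied scores give AUC = 0.5.
    """
    scores = np.asarray(decision_values, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points, auc


def make_folds(labels: dict[str, str], k: int, seed: int, stratified: bool = True) -> FoldAssignment:
    """Random partition of subjects into k near-equal folds.

    Stratified mode balances class proportions per fold.  Deterministic for
    a fixed seed; fold sizes differ by at most two.
    """
    ids = list(labels.keys())
    y = np.asarray([labels[s] for s in ids])
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of subjects ({n})")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if (counts < k).any():
            raise ValueError("each class needs at least k members for stratified folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        for i in test_idx:
            assignments[ids[i]] = fold
    return FoldAssignment(k, assignments, seed, stratified)


def train_svm(points: np.ndarray, labels: np.ndarray, C: float = 1.0) -> SVC:
    """Soft-margin linear SVM; exposes signed decision values for ROC."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(np.asarray(points, dtype=np.float64), y)
    return clf


class DistanceSVMClassifier(ClassifierMixin, BaseEstimator):
    """MDS embedding + linear SVM operating on precomputed distances.

    ``fit`` takes the training-subject square distance matrix and binary
    labels; ``predict`` / ``decision_function`` take (m, n_train) distances
    from new subjects to the training subjects, which are embedded via the
    Nystrom extension before classification.  Decision values are oriented
    so that positive means the positive (disease) class.
    """

    def __init__(self, n_components: int = 3, C: float = 1.0, positive_label=1):
        self.n_components = n_components
        self.C = C
        self.positive_label = positive_label

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.mds_ = ClassicalMDS(self.n_components).fit(X)
        emb = self.mds_.embedding_
        ybin = (y == self.positive_label).astype(int)
        if len(np.unique(ybin)) < 2:
            raise ValueError("training labels contain a single class")
        self.svm_ = SVC(kernel="linear", C=self.C)
        self.svm_.fit(emb, ybin)
        self.classes_ = np.unique(y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svm_")
        emb = self.mds_.transform(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        return self.svm_.decision_function(emb)

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def _folds_ok(fold_of: np.ndarray, ybin: np.ndarray, k: int) -> bool:
    for f in range(k):
        train = ybin[fold_of != f]
        if len(train) == 0 or len(np.unique(train)) < 2:
            return False
        if (fold_of == f).sum() == 0:
            return False
    return True


def cross_validate(
    D,
    labels: dict[str, str],
    positive: str | None = None,
    k: int = 10,
    seed: int = 0,
    mode: str = "fold_honest",
    n_components: int = 3,
    C: float = 1.0,
    stratified: bool = True,
    contrast: str | None = None,
) -> MetricsReport:
    """k-fold cross-validated classification of a pairwise distance matrix.

    D may be a DistanceMatrix or a square ndarray (then subject order must
    match the iteration order of ``labels``).  Folds with a single training
    class trigger a re-draw with a derived seed, up to 10 times.
    """
    if mode not in ("fold_honest", "transductive"):
        raise ValueError(f"unknown mode {mode!r}")
    if hasattr(D, "values") and hasattr(D, "subject_ids"):
        ids = list(D.subject_ids)
        values = D.values
        roi_name = D.roi.name
    else:
        ids = list(labels.keys())
        values = np.asarray(D, dtype=np.float64)
        roi_name = "?"
    keep = [i for i, s in enumerate(ids) if s in labels]
    ids = [ids[i] for i in keep]
    values = values[np.ix_(keep, keep)]
    y = np.asarray([labels[s] for s in ids])
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"binary contrast required, got classes {classes}")
    if positive is None:
        for cand in ("AD", "pMCI", "sMCI"):
            if cand in classes:
                positive = cand
                break
        else:
            positive = classes[1]
    ybin = (y == positive).astype(int)
    n = len(ids)
    if n < k:
        raise ValueError(f"need at least k = {k} subjects, got {n}")

    label_map = {s: labels[s] for s in ids}
    folds = None
    for attempt in range(10):
        cand = make_folds(label_map, k, seed + attempt * 1000003, stratified)
        fold_of = np.asarray([cand.assignments[s] for s in ids])
        if _folds_ok(fold_of, ybin, k):
            folds = cand
            break
    if folds is None:
        raise RuntimeError("could not draw folds with both classes in every training set")
    fold_of = np.asarray([folds.assignments[s] for s in ids])

    decision = np.zeros(n)
    pred = np.zeros(n, dtype=int)
    per_fold: list[ConfusionCounts] = []
    if mode == "transductive":
        emb_all = ClassicalMDS(n_components).fit(values).embedding_
    for f in range(k):
        test = fold_of == f
        train = ~test
        if mode == "fold_honest":
            clf = DistanceSVMClassifier(n_components, C, positive_label=1)
            clf.fit(values[np.ix_(train, train)], ybin[train])
            dv = clf.decision_function(values[np.ix_(test, train)])
        else:
            svm = train_svm(emb_all[train], ybin[train], C)
            dv = svm.decision_function(emb_all[test])
        decision[test] = dv
        pred[test] = (dv > 0).astype(int)
        per_fold.append(
            ConfusionCounts(
                tp=int(((pred[test] == 1) & (ybin[test] == 1)).sum()),
                fp=int(((pred[test] == 1) & (ybin[test] == 0)).sum()),
                tn=int(((pred[test] == 0) & (ybin[test] == 0)).sum()),
                fn=int(((pred[test] == 0) & (ybin[test] == 1)).sum()),
            )
        )
    counts = ConfusionCounts(
        tp=sum(c.tp for c in per_fold),
        fp=sum(c.fp for c in per_fold),
        tn=sum(c.tn for c in per_fold),
        fn=sum(c.fn for c in per_fold),
    )
    points, auc = roc_auc(decision, ybin)
    if contrast is None:
        contrast = next(
            (name for name, (neg, pos) in CONTRASTS.items()
             if {neg, pos} == set(classes)), f"{classes[0]}vs{classes[1]}"
        )
    return MetricsReport(
        contrast=contrast,
        roi=roi_name,
        counts=counts,
        metrics=compute_metrics(counts),
        roc_points=points,
        auc=auc,
        per_fold=per_fold,
        mode=mode,
    )
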