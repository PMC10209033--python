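"""Allergenicity prediction from pattern features with a sparse linear SVM.

Feature construction
--------------------
Proteins are encoded either by binary indicators x_ij = 1 iff pattern Q_j
is a substring of sequence z_i (used for mined ASP/non-ASP features and
for thresholded 6-mers), or by k-mer ratios x_ij = (#occurrences of k-mer
j) / (len(z_i) - k + 1) for k in {1, 2}.

Model
-----
A soft-margin linear SVM: minimize (1/2) w.w + C sum_i max{0, 1 - y_i
(w.x_i + b)}.  The decision value f(x) = w.x + b is the prediction score;
the weight on each pattern feature is directly interpretable as that
pattern's contribution to allergenicity.

Evaluation
----------
Leave-category-out cross-validation (LCO-CV): each fold holds out every
protein of one paired biological category; ASP/non-ASP (or k-mer) features
are re-derived from the training portion only, so no information from the
held-out category leaks into feature selection.  The regularization
trade-off C is chosen by a nested LCO-CV inside the training categories
over the grid log10 C in {-27/9, -23/9, ..., 9/9}, extended by steps of
4/9 while a boundary value remains best (ties resolved toward the smallest
C).  Reported metrics: ROC/AUC, AUC-10% (ROC integral over FPR in [0, 0.1]
times 10), and F1 / MCC at the decision threshold 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .dataset import ProteinDataset, classify_categories
from .significance import generate_permutations, wy_calibrate
from .asp import find_significant_patterns, select_asps, select_non_asps

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "LinearModel",
    "MetricsReport",
    "CVResult",
    "build_feature_matrix",
    "kmer_feature_spec",
    "asp_feature_spec",
    "train_linear_svm",
    "select_C",
    "leave_category_out_cv",
    "compute_metrics",
    "DEFAULT_LOG10_C_GRID",
]

#: 10-point default grid for log10 C, step 4/9.
DEFAULT_LOG10_C_GRID = tuple(np.arange(-27, 10, 4) / 9.0)


@dataclass
class FeatureSpec:
    patterns: list[str]
    kind: str = "binary_indicator"  # or "kmer_ratio"
    k: Optional[int] = None
    support_threshold: Optional[int] = None

    def __post_init__(self):
        if len(set(self.patterns)) != len(self.patterns):
            raise ValueError("feature patterns must be unique")
        if self.kind == "kmer_ratio" and self.k is None:
            raise ValueError("kmer_ratio requires k")
        if self.kind not in ("binary_indicator", "kmer_ratio"):
            raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class FeatureMatrix:
    X: np.ndarray
    ids: list[str]
    labels: Optional[np.ndarray]
    spec: FeatureSpec


@dataclass
class LinearModel:
    weights: np.ndarray
    intercept: float
    C: float
    feature_patterns: list[str] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.intercept


def build_feature_matrix(
    sequences: Sequence[tuple[str, str]] | ProteinDataset,
    spec: FeatureSpec,
) -> FeatureMatrix:
    """Encode sequences as indicator or k-mer-ratio features."""
    if isinstance(sequences, ProteinDataset):
        items = [(r.id, r.sequence) for r in sequences]
        labels = sequences.labels
    else:
        items = list(sequences)
        labels = None
    n, d = len(items), len(spec.patterns)
    X = np.zeros((n, d))
    if spec.kind == "binary_indicator":
        for i, (_, seq) in enumerate(items):
            for j, q in enumerate(spec.patterns):
                if q in seq:
                    X[i, j] = 1.0
    else:
        k = spec.k
        col = {q: j for j, q in enumerate(spec.patterns)}
        for i, (rid, seq) in enumerate(items):
            total = len(seq) - k + 1
            if total <= 0:
                warnings.warn(f"sequence {rid!r} shorter than k={k}; all-zero feature row")
                continue
            for s in range(total):
                j = col.get(seq[s : s + k])
                if j is not None:
                    X[i, j] += 1.0
            X[i] /= total
    return FeatureMatrix(X, [rid for rid, _ in items], labels, spec)


def kmer_feature_spec(
    training_set: ProteinDataset, k: int, support_threshold: Optional[int] = None
) -> FeatureSpec:
    """k-mer features from a training set.

    k <= 2: ratio features over every observed k-mer, no support threshold.
    k >= 3 (the 6-mer baseline): binary indicators over k-mers contained in
    at least ``support_threshold`` proteins (default 15).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k <= 2:
        observed: set[str] = set()
        for r in training_set:
            s = r.sequence
            observed.update(s[i : i + k] for i in range(len(s) - k + 1))
        return FeatureSpec(sorted(observed), kind="kmer_ratio", k=k)
    threshold = 15 if support_threshold is None else support_threshold
    doc_freq: dict[str, int] = {}
    for r in training_set:
        s = r.sequence
        for kmer in {s[i : i + k] for i in range(len(s) - k + 1)}:
            doc_freq[kmer] = doc_freq.get(kmer, 0) + 1
    patterns = sorted(q for q, c in doc_freq.items() if c >= threshold)
    if not patterns:
        warnings.warn(f"no {k}-mers reach support threshold {threshold}; empty feature spec")
    return FeatureSpec(patterns, kind="binary_indicator", k=k, support_threshold=threshold)


def asp_feature_spec(
    training_set: ProteinDataset,
    alpha: float = 0.05,
    m_perms: int = 100,
    seed: int = 0,
    min_support: int = 1,
) -> FeatureSpec:
    """Mine ASPs and non-ASPs on the training set and use them as indicators."""
    profile = classify_categories(training_set)
    plan = generate_permutations(training_set, m_perms, seed)
    calibration = wy_calibrate(training_set, plan, alpha=alpha, min_support=min_support)
    delta = calibration.delta
    pos_cands, _ = find_significant_patterns(training_set, delta, "allergen", min_support)
    neg_cands, _ = find_significant_patterns(training_set, delta, "nonallergen", min_support)
    asps = select_asps(pos_cands, training_set, profile, calibration)
    non_asps = select_non_asps(neg_cands, training_set, profile, calibration)
    patterns = sorted({r.pattern for r in asps} | {r.pattern for r in non_asps})
    if not patterns:
        warnings.warn("no significant patterns survived the screen; empty feature spec")
    return FeatureSpec(patterns, kind="binary_indicator")


def train_linear_svm(X: FeatureMatrix | np.ndarray, C: float, y=None) -> LinearModel:
    """Fit the soft-margin linear SVM (1/2)w.w + C sum hinge via libsvm."""
    from sklearn.svm import SVC

    if isinstance(X, FeatureMatrix):
        y = X.labels
        patterns = X.spec.patterns
        X_arr = X.X
    else:
        patterns = []
        X_arr = np.asarray(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X_arr, y)
    return LinearModel(svc.coef_.ravel().copy(), float(svc.intercept_[0]), C, list(patterns))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc10: float
    f1: float
    mcc: float
    confusion: dict


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve over all distinct thresholds, from (0,0) to (1,1)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = (labels[order] == 1).astype(float)
    neg = 1.0 - pos
    tp = np.cumsum(pos)
    fp = np.cumsum(neg)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    n_pos, n_neg = pos.sum(), neg.sum()
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return fpr, tpr


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pairwise-comparison (rank) statistic, ties counted 1/2."""
    from scipy.stats import rankdata

    pos = labels == 1
    ranks = rankdata(scores)
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(scores, labels) -> MetricsReport:
    """ROC/AUC/AUC-10% plus F1 and MCC at decision threshold 0.

    A test protein is predicted allergenic when its score is >= the
    threshold.  AUC is the rank statistic (exactly the step-integrated ROC
    area); AUC-10% integrates the ROC curve over FPR in [0, 0.1] and
    multiplies by 10.  MCC is defined as 0 when any confusion marginal
    vanishes.  AUC is NaN (with a warning) when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred_pos = scores >= 0
    tp = int(np.sum(pred_pos & (labels == 1)))
    fp = int(np.sum(pred_pos & (labels == -1)))
    tn = int(np.sum(~pred_pos & (labels == -1)))
    fn = int(np.sum(~pred_pos & (labels == 1)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    if len(np.unique(labels)) < 2:
        warnings.warn("AUC undefined with a single class in the test labels")
        nan = float("nan")
        return MetricsReport(
            np.array([0.0, 1.0]), np.array([0.0, 1.0]), nan, nan, f1, float(mcc),
            {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        )
    fpr, tpr = _roc_points(scores, labels)
    auc = _mann_whitney_auc(scores, labels)
    # piecewise-linear ROC restricted to FPR <= 0.1
    cut = 0.1
    tpr_at_cut = float(np.interp(cut, fpr, tpr))
    mask = fpr <= cut
    fx = np.r_[fpr[mask], cut]
    fy = np.r_[tpr[mask], tpr_at_cut]
    auc10 = float(np.trapezoid(fy, fx) * 10.0)
    return MetricsReport(
        fpr, tpr, auc, auc10, float(f1), float(mcc),
        {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _feature_builder(
    feature_source: str,
    alpha: float,
    m_perms: int,
    min_support: int,
    external_spec: Optional[FeatureSpec],
) -> Callable[[ProteinDataset, int], FeatureSpec]:
    if feature_source == "asp":
        return lambda ds, seed: asp_feature_spec(
            ds, alpha=alpha, m_perms=m_perms, seed=seed, min_support=min_support
        )
    if feature_source.startswith("kmer"):
        k = int(feature_source[4:])
        return lambda ds, seed: kmer_feature_spec(ds, k)
    if feature_source == "external":
        if external_spec is None:
            raise ValueError("external feature source requires external_spec")
        return lambda ds, seed: external_spec
    raise ValueError(f"unknown feature source {feature_source!r}")


def _metric_value(report: MetricsReport, metric: str) -> float:
    return {"auc": report.auc, "auc10": report.auc10, "f1": report.f1, "mcc": report.mcc}[metric]


def select_C(
    train_set: ProteinDataset,
    build_spec: Callable[[ProteinDataset, int], FeatureSpec],
    metric: str = "auc",
    seed: int = 0,
    log10_grid: Sequence[float] = DEFAULT_LOG10_C_GRID,
    grid_step: float = 4.0 / 9.0,
    max_extensions: int = 6,
) -> float:
    """Choose C by nested leave-category-out CV inside the training categories.

    The grid is extended outward in steps of ``grid_step`` (log10) while a
    boundary value stays best; ties are broken toward the smallest C.
    """
    profile = classify_categories(train_set)
    inner_cats = sorted(profile.paired)
    if len(inner_cats) < 2:
        raise ValueError("C selection needs >= 2 paired categories in the training set")

    folds = []
    for fold_idx, cat in enumerate(inner_cats):
        test_idx = [i for i, r in enumerate(train_set) if r.category == cat]
        tr_idx = [i for i, r in enumerate(train_set) if r.category != cat]
        tr = train_set.subset(tr_idx)
        te = train_set.subset(test_idx)
        spec = build_spec(tr, seed + 1000 + fold_idx)
        if not spec.patterns:
            continue
        folds.append(
            (build_feature_matrix(tr, spec), build_feature_matrix(te, spec), te.labels)
        )
    if not folds:
        return 1.0  # no usable features anywhere; C is immaterial

    def mean_score(log10_c: float) -> float:
        c = 10.0**log10_c
        vals = []
        for fm_tr, fm_te, y_te in folds:
            model = train_linear_svm(fm_tr, c)
            vals.append(_metric_value(compute_metrics(model.decision(fm_te.X), y_te), metric))
        return float(np.mean(vals))

    grid = sorted(log10_grid)
    scores = {g: mean_score(g) for g in grid}

    def best(gs):
        return max(gs, key=lambda g: (scores[g], -g))  # ties -> smallest C

    for _ in range(max_extensions):
        b = best(grid)
        if b == grid[0]:
            new = grid[0] - grid_step
        elif b == grid[-1]:
            new = grid[-1] + grid_step
        else:
            break
        scores[new] = mean_score(new)
        grid = sorted(grid + [new])
    return float(10.0 ** best(grid))


@dataclass
class FoldResult:
    category: str
    C: float
    n_features: int
    ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    metrics: MetricsReport
    model: LinearModel


@dataclass
class CVResult:
    folds: list[FoldResult]
    pooled: MetricsReport

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean([f.metrics.auc for f in self.folds]))

    def metrics_json(self) -> dict:
        return {
            "folds": {
                f.category: {
                    "auc": f.metrics.auc,
                    "auc10": f.metrics.auc10,
                    "f1": f.metrics.f1,
                    "mcc": f.metrics.mcc,
                    "C": f.C,
                    "n_features": f.n_features,
                }
                for f in self.folds
            },
            "mean_auc": self.mean_auc,
            "pooled": {
                "auc": self.pooled.auc,
                "auc10": self.pooled.auc10,
                "f1": self.pooled.f1,
                "mcc": self.pooled.mcc,
            },
        }


def leave_category_out_cv(
    dataset: ProteinDataset,
    feature_source: str = "asp",
    alpha: float = 0.05,
    m_perms: int = 100,
    seed: int = 0,
    min_support: int = 1,
    select_c_metric: Optional[str] = "auc",
    fixed_C: float = 1.0,
    external_spec: Optional[FeatureSpec] = None,
) -> CVResult:
    """One fold per paired category; features re-mined on the training side.

    ``select_c_metric=None`` skips the nested C search and uses ``fixed_C``.
    The pooled report concatenates held-out scores across folds
    ("pooled-concatenated"); per-fold reports are kept alongside.
    """
    profile = classify_categories(dataset)
    paired = sorted(profile.paired)
    if len(paired) < 2:
        raise ValueError("LCO-CV needs >= 2 paired categories")
    build_spec = _feature_builder(feature_source, alpha, m_perms, min_support, external_spec)

    folds: list[FoldResult] = []
    for fold_idx, cat in enumerate(paired):
        test_idx = [i for i, r in enumerate(dataset) if r.category == cat]
        train_idx = [i for i, r in enumerate(dataset) if r.category != cat]
        train_ds = dataset.subset(train_idx)
        test_ds = dataset.subset(test_idx)
        fold_seed = seed + 17 * (fold_idx + 1)
        spec = build_spec(train_ds, fold_seed)
        if not spec.patterns:
            warnings.warn(f"fold {cat!r}: empty feature set; scoring all zeros")
            scores = np.zeros(len(test_ds))
            model = LinearModel(np.zeros(0), 0.0, fixed_C)
            c_used = fixed_C
        else:
            if select_c_metric is not None:
                c_used = select_C(train_ds, build_spec, metric=select_c_metric, seed=fold_seed)
            else:
                c_used = fixed_C
            fm_tr = build_feature_matrix(train_ds, spec)
            model = train_linear_svm(fm_tr, c_used)
            fm_te = build_feature_matrix(test_ds, spec)
            scores = model.decision(fm_te.X)
        folds.append(
            FoldResult(
                cat,
                c_used,
                len(spec.patterns),
                [r.id for r in test_ds],
                scores,
                test_ds.labels,
                compute_metrics(scores, test_ds.labels),
                model,
            )
        )
    all_scores = np.concatenate([f.scores for f in folds])
    all_labels = np.concatenate([f.labels for f in folds])
    return CVResult(folds, compute_metrics(all_scores, all_labels))
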