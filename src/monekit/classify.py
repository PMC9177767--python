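"""Linear phenotype classifiers over slide-level features.

Multi-class linear discriminant analysis (MLDA) projects slides into the
(k-1)-dimensional discriminant space and classifies by Gaussian
equal-covariance posteriors; LR-LASSO is multinomial logistic regression
with an L1 penalty (inverse strength C, default 100), yielding sparse,
directly interpretable coefficients.  Evaluation uses Monte Carlo
cross-validation with patient-level, class-stratified splits, one-vs-rest
AUC per class, and row-normalized confusion matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score, rand_score, roc_auc_score

from .data import MoneMatrix, SlideMeta

__all__ = [
    "SplitPlan",
    "ClassifierReport",
    "make_splits",
    "fit_mlda",
    "fit_lr_lasso",
    "evaluate",
    "macro_ovr_auc",
    "universal_tumor_score",
    "cross_classification",
    "clustermap_metrics",
    "embed_mlda_tsne",
    "class_labels",
]


def class_labels(meta: Sequence[SlideMeta], scheme: str = "38class") -> np.ndarray:
    """Class label per slide: ``"38class"`` = cancer:lesion, ``"lesion"`` = tumor/normal."""
    if scheme == "38class":
        return np.array([f"{m.cancer_type}:{m.lesion}" for m in meta])
    if scheme == "lesion":
        return np.array([m.lesion for m in meta])
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class SplitPlan:
    """Patient-grouped, class-stratified Monte Carlo splits."""

    splits: list[tuple[np.ndarray, np.ndarray]]  # (train idx, test idx)
    seed: int
    test_fraction: float

    def __iter__(self):
        return iter(self.splits)


def make_splits(
    meta: Sequence[SlideMeta],
    n_reps: int = 10,
    test_fraction: float = 0.25,
    seed: int = 0,
    scheme: str = "38class",
) -> SplitPlan:
    """Random train/test splits at the patient level, preserving class ratios.

    A patient's slides (possibly spanning tumor and normal classes) always
    land on the same side.  Patients are allocated greedily per cancer so
    each class's test share tracks ``test_fraction``.
    """
    labels = class_labels(meta, scheme)
    classes, counts = np.unique(labels, return_counts=True)
    patient_class_counts: dict[str, dict[str, int]] = {}
    for m, lab in zip(meta, labels):
        patient_class_counts.setdefault(m.patient_id, {}).setdefault(lab, 0)
        patient_class_counts[m.patient_id][lab] += 1
    for cls in classes:
        patients = {p for p, cc in patient_class_counts.items() if cls in cc}
        if len(patients) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 patients")

    rng = np.random.default_rng(seed)
    target = {cls: test_fraction * cnt for cls, cnt in zip(classes, counts)}

    # group patients by their class-contribution signature; allocating whole
    # signature groups keeps every class's test share within rounding of the
    # target even when a patient's slides span two classes
    groups: dict[tuple, list[str]] = {}
    for p, cc in patient_class_counts.items():
        sig = tuple(sorted(cc.items()))
        groups.setdefault(sig, []).append(p)
    # multi-class signatures first: they constrain two deficits at once
    sig_order = sorted(groups, key=lambda s: (-len(s), s))

    splits = []
    for _ in range(n_reps):
        deficit = dict(target)
        test_patients: set[str] = set()
        for sig in sig_order:
            members = sorted(groups[sig])
            # patients of this signature to place in test: bounded by the
            # tightest per-class deficit
            n_take = int(np.floor(min(deficit[c] / k for c, k in sig) + 0.5))
            n_take = max(0, min(n_take, len(members)))
            chosen = rng.choice(len(members), size=n_take, replace=False)
            for i in chosen:
                test_patients.add(members[i])
            for c, k in sig:
                deficit[c] -= n_take * k
        test_idx = np.array(
            [i for i, m in enumerate(meta) if m.patient_id in test_patients],
            dtype=int,
        )
        train_idx = np.array(
            [i for i, m in enumerate(meta) if m.patient_id not in test_patients],
            dtype=int,
        )
        splits.append((train_idx, test_idx))
    return SplitPlan(splits=splits, seed=seed, test_fraction=test_fraction)


@dataclass
class FittedClassifier:
    model: object
    classes: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def fit_mlda(X: np.ndarray, y: np.ndarray) -> FittedClassifier:
    """Multi-class LDA (SVD solver; min(k-1, M)-dimensional projection)."""
    model = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Variables are collinear")
        model.fit(X, y)
    return FittedClassifier(model=model, classes=model.classes_)


def fit_lr_lasso(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 100.0,
    max_iter: int = 2000,
    tol: float = 1e-3,
    seed: int = 0,
) -> FittedClassifier:
    """Multinomial logistic regression with L1 penalty (saga solver).

    Coefficients with magnitude below 1e-8 are zeroed.  Non-convergence at
    ``max_iter`` raises a warning, never silent failure.
    """
    model = LogisticRegression(
        penalty="l1", C=C, solver="saga", max_iter=max_iter, tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            warnings.warn(
                f"LR-LASSO did not fully converge within {max_iter} iterations "
                f"(tol={tol}); coefficients may be slightly off",
                ConvergenceWarning,
                stacklevel=2,
            )
    model.coef_[np.abs(model.coef_) < 1e-8] = 0.0
    return FittedClassifier(model=model, classes=model.classes_)


def nonzero_features(clf: FittedClassifier, feature_ids: Sequence[int] | None = None):
    """Feature ids with a nonzero coefficient in any class (L1 model)."""
    coef = np.atleast_2d(clf.model.coef_)
    nz = np.flatnonzero(np.any(coef != 0.0, axis=0))
    if feature_ids is None:
        return nz
    return np.asarray(feature_ids)[nz]


@dataclass
class ClassifierReport:
    """Per-class OVR-AUC and row-normalized confusion matrix for one test set."""

    ovr_auc: dict[str, float | None]
    confusion: np.ndarray
    classes: np.ndarray

    @property
    def macro_auc(self) -> float:
        vals = [v for v in self.ovr_auc.values() if v is not None]
        return float(np.mean(vals))


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """OVR-AUC as the normalized Mann-Whitney rank statistic (ties -> 0.5)."""
    from scipy.stats import rankdata

    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate(clf: FittedClassifier, X: np.ndarray, y: np.ndarray) -> ClassifierReport:
    """Per-class OVR-AUC and confusion matrix on a test set.

    Classes absent from the test set get AUC None (reported missing).
    Confusion rows (true classes present in the test set) sum to 1.
    """
    if len(y) == 0:
        raise ValueError("empty test set")
    proba = clf.predict_proba(X)
    pred = clf.classes[np.argmax(proba, axis=1)]
    aucs: dict[str, float | None] = {}
    for k, cls in enumerate(clf.classes):
        pos = y == cls
        if pos.sum() == 0 or pos.sum() == len(y):
            aucs[str(cls)] = None
            continue
        aucs[str(cls)] = _rank_auc(proba[:, k], pos)
    k = len(clf.classes)
    cls_pos = {c: i for i, c in enumerate(clf.classes)}
    confusion = np.zeros((k, k))
    for yt, yp in zip(y, pred):
        confusion[cls_pos[yt], cls_pos[yp]] += 1
    row_sums = confusion.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        confusion = np.where(row_sums > 0, confusion / row_sums, 0.0)
    return ClassifierReport(ovr_auc=aucs, confusion=confusion, classes=clf.classes)


def macro_ovr_auc(reports: list[ClassifierReport]) -> tuple[float, float]:
    """Mean and sd of macro OVR-AUC across Monte Carlo repetitions."""
    vals = np.array([r.macro_auc for r in reports])
    return float(vals.mean()), float(vals.std())


def universal_tumor_score(
    clf: FittedClassifier, X: np.ndarray
) -> np.ndarray:
    """Per-slide tumor probability from a cancer:lesion multi-class model.

    Sums the predicted probabilities of all ``*:tumor`` classes; the class
    scheme must be the 2-per-cancer (tumor, normal) labeling.
    """
    tumor_cols = [i for i, c in enumerate(clf.classes) if str(c).endswith(":tumor")]
    normal_cols = [i for i, c in enumerate(clf.classes) if str(c).endswith(":normal")]
    if not tumor_cols or not normal_cols:
        raise ValueError(
            "classifier was not trained on the cancer:lesion class scheme"
        )
    proba = clf.predict_proba(X)
    return proba[:, tumor_cols].sum(axis=1)


def cross_classification(
    cohorts: dict[str, tuple[np.ndarray, np.ndarray]],
    train_test: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] | None = None,
    C: float = 100.0,
    seed: int = 0,
) -> "np.ndarray":
    """Tumor/normal AUC matrix: classifiers trained per cancer, applied to all.

    ``cohorts`` maps cancer -> (X, binary tumor labels).  The diagonal uses a
    held-out split of the same cancer (provided via ``train_test`` as
    (X_train, y_train, X_test, y_test), else a deterministic 75/25 split);
    off-diagonal entries apply the trained model to the full other cohort.
    Returns the AUC matrix in the sorted-cancer order.
    """
    cancers = sorted(cohorts)
    models = {}
    held_out = {}
    for c in cancers:
        X, y = cohorts[c]
        if train_test and c in train_test:
            X_tr, y_tr, X_te, y_te = train_test[c]
        else:
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(y))
            n_te = max(2, int(0.25 * len(y)))
            te, tr = idx[:n_te], idx[n_te:]
            X_tr, y_tr, X_te, y_te = X[tr], y[tr], X[te], y[te]
        models[c] = fit_lr_lasso(X_tr, y_tr.astype(int), C=C, seed=seed)
        held_out[c] = (X_te, y_te)
    k = len(cancers)
    auc = np.full((k, k), np.nan)
    for i, ci in enumerate(cancers):
        for j, cj in enumerate(cancers):
            if i == j:
                X_te, y_te = held_out[cj]
            else:
                X_te, y_te = cohorts[cj]
            if len(np.unique(y_te)) < 2:
                continue
            proba = models[ci].predict_proba(X_te)
            pos_col = list(models[ci].classes).index(1)
            auc[i, j] = _rank_auc(proba[:, pos_col], y_te.astype(bool))
    return auc


def clustermap_metrics(
    values: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """(AUC, rand score, adjusted rand score) of a 2-cluster average-linkage cut.

    Slides are clustered hierarchically (average linkage, Euclidean) on the
    selected features and cut at 2 clusters; rand/ARI compare clusters with
    the binary labels; the AUC scores each slide by its cluster's positive
    fraction.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 slides per class")
    Z = linkage(values, method="average", metric="euclidean")
    clusters = fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(clusters)) < 2:
        warnings.warn("degenerate single-cluster cut")
    scores = np.zeros(len(labels))
    for c in np.unique(clusters):
        mask = clusters == c
        scores[mask] = labels[mask].mean()
    auc = _rank_auc(scores, labels)
    return auc, float(rand_score(labels, clusters)), float(
        adjusted_rand_score(labels, clusters)
    )


def embed_mlda_tsne(
    projected: np.ndarray, perplexity: float = 50.0, seed: int = 0
) -> np.ndarray:
    """2-D t-SNE of the MLDA discriminant space (PCA init, fixed seed)."""
    n = projected.shape[0]
    if n < 3 * perplexity:
        warnings.warn(
            f"{n} samples is below the recommended 3 x perplexity "
            f"({3 * perplexity:.0f}); consider lowering perplexity"
        )
    perplexity = min(perplexity, max(2.0, (n - 1) / 3.0))
    projected = np.asarray(projected, dtype=float)
    if projected.ndim == 1:
        projected = projected[:, None]
    init = "pca" if projected.shape[1] > 1 else "random"
    ts = TSNE(
        n_components=2, perplexity=perplexity, init=init, random_state=seed
    )
    return ts.fit_transform(projected)
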