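"""Feature selection and recurrence classifiers.

Selection is a two-stage scheme: a minimum-redundancy-maximum-relevance
(mRMR) ranking retains the top 3 features within each of the 5 feature
categories (15 candidates), then an exhaustive search over all C(15, 7) = 6435
seven-feature subsets picks the one with the best quadratic-discriminant
cross-validated accuracy, the folds being shared across subsets.

Classifiers: Gaussian quadratic/linear discriminants (implemented here, with
JSON-serialisable parameters; scikit-learn's discriminants serve as an
independent cross-check in the test suite) and a degree-2 polynomial-kernel
SVM (trained with scikit-learn, predictions reproduced from the serialised
support vectors).  Features are standardised by training mean/sd stored in
the model bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core_io import CATEGORIES, feature_names

__all__ = [
    "mutual_information",
    "mrmr_rank_per_category",
    "select_candidates",
    "SelectionResult",
    "qda_subset_search",
    "GaussianDiscriminant",
    "ModelBundle",
    "train_classifier",
    "predict",
    "save_model",
    "load_model",
    "EvalReport",
    "evaluate",
    "metrics_from_confusion",
]


# ---------------------------------------------------------------------------
# Mutual information and mRMR
# ---------------------------------------------------------------------------

def _discretize(x: np.ndarray, bins: int = 8) -> np.ndarray:
    """Equal-frequency discretisation; constant features map to one bin."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 8) -> float:
    """MI (bits) between a real feature and a discrete label, the feature
    discretised into ``bins`` equal-frequency bins."""
    xd = _discretize(np.asarray(x, dtype=float), bins)
    return _mi_discrete(xd, np.asarray(y))


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((len(ua), len(ub)))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank_per_category(
    table: pd.DataFrame,
    labels: np.ndarray,
    category: str,
    k: int = 3,
    bins: int = 8,
    variant: str = "difference",
) -> list[str]:
    """Greedy mRMR ranking of one category's features; top-k in selection order.

    Criterion: relevance MI(f; y) minus (difference variant, default) or
    divided by (quotient variant) the mean pairwise MI with already-selected
    features.  Features are discretised into equal-frequency bins; ties break
    by registry order.  Non-finite columns are excluded.
    """
    if variant not in ("difference", "quotient"):
        raise ValueError("variant must be 'difference' or 'quotient'")
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("mRMR needs binary labels with both classes present")
    cand = [
        n for n in feature_names(category)
        if n in table.columns and np.isfinite(table[n].to_numpy(dtype=float)).all()
    ]
    if len(cand) < k:
        raise ValueError(f"category {category}: fewer than k={k} usable features")

    disc = {n: _discretize(table[n].to_numpy(dtype=float), bins) for n in cand}
    relevance = {n: _mi_discrete(disc[n], y) for n in cand}

    selected: list[str] = []
    remaining = list(cand)
    while len(selected) < k:
        best_name, best_score = None, -np.inf
        for n in remaining:  # registry order -> first max wins ties
            if not selected:
                score = relevance[n]
            else:
                red = float(np.mean([_mi_discrete(disc[n], disc[s]) for s in selected]))
                if variant == "difference":
                    score = relevance[n] - red
                else:
                    score = relevance[n] / (red + 1e-12)
            if score > best_score:
                best_name, best_score = n, score
        selected.append(best_name)
        remaining.remove(best_name)
    return selected


def select_candidates(
    table: pd.DataFrame, labels: np.ndarray, k: int = 3, bins: int = 8,
    variant: str = "difference",
) -> dict[str, list[str]]:
    """Top-k mRMR features per category: 5 categories x k (default 15 names)."""
    return {
        cat: mrmr_rank_per_category(table, labels, cat, k=k, bins=bins, variant=variant)
        for cat in CATEGORIES
    }


# ---------------------------------------------------------------------------
# Gaussian discriminants (QDA / LDA)
# ---------------------------------------------------------------------------

def _regularize(cov: np.ndarray, lam_scale: float = 1e-4) -> np.ndarray:
    d = cov.shape[-1]
    lam = lam_scale * np.trace(cov) / d
    return cov + lam * np.eye(d)


@dataclass
class GaussianDiscriminant:
    """Two-class Gaussian discriminant; ``kind`` 'QDA' (class covariances) or
    'LDA' (pooled covariance).  Singular covariances are ridge-regularised by
    1e-4 * trace/d."""

    kind: str = "QDA"
    classes_: np.ndarray | None = None
    means_: np.ndarray | None = None       # (2, d)
    covs_: np.ndarray | None = None        # (2, d, d) or (1, d, d) pooled
    priors_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianDiscriminant":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("needs exactly two classes")
        means, covs, ns = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            means.append(Xc.mean(axis=0))
            covs.append(np.cov(Xc, rowvar=False, ddof=0) if len(Xc) > 1
                        else np.zeros((X.shape[1], X.shape[1])))
            ns.append(len(Xc))
        self.means_ = np.asarray(means)
        self.priors_ = np.asarray(ns, dtype=float) / len(y)
        if self.kind == "QDA":
            self.covs_ = np.stack([_regularize(np.atleast_2d(c)) for c in covs])
        else:
            pooled = sum(n * np.atleast_2d(c) for n, c in zip(ns, covs)) / len(y)
            self.covs_ = _regularize(pooled)[None]
        return self

    def _log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), 2))
        for c in range(2):
            cov = self.covs_[c if self.kind == "QDA" else 0]
            L = np.linalg.cholesky(cov)
            diff = X - self.means_[c]
            z = np.linalg.solve(L, diff.T)
            maha = (z**2).sum(axis=0)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            out[:, c] = -0.5 * (maha + logdet) + np.log(self.priors_[c])
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        ll = self._log_likelihoods(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self._log_likelihoods(X).argmax(axis=1)]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "classes": self.classes_.tolist(),
            "means": self.means_.tolist(),
            "covs": self.covs_.tolist(),
            "priors": self.priors_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianDiscriminant":
        obj = cls(kind=d["kind"])
        obj.classes_ = np.asarray(d["classes"])
        obj.means_ = np.asarray(d["means"])
        obj.covs_ = np.asarray(d["covs"])
        obj.priors_ = np.asarray(d["priors"])
        return obj


# ---------------------------------------------------------------------------
# Exhaustive QDA subset search
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    per_category: dict[str, list[str]]      # top-k per category, rank order
    candidates: list[str]                    # flattened, category order
    selected: list[str]                      # the winning subset, candidate order
    cv_accuracy: float                       # mean CV accuracy of the winner
    subset_size: int
    n_iter: int
    n_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "per_category": self.per_category,
            "candidates": self.candidates,
            "selected": self.selected,
            "cv_accuracy": self.cv_accuracy,
            "subset_size": self.subset_size,
            "n_iter": self.n_iter,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def _fold_subset_scores(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, yte: np.ndarray,
    subsets: np.ndarray, lam_scale: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """(correct counts, log-odds scores) of QDA for every subset on one fold.

    Class means/covariances are estimated once on the full candidate space;
    each subset's model is the corresponding slice, evaluated with batched
    Cholesky factorisations over all subsets simultaneously.
    Returns (n_subsets,) correct-prediction counts and (n_te, n_subsets)
    class-1 log-odds for AUC tie-breaking.
    """
    classes = np.unique(ytr)
    S, d = subsets.shape
    n_te = len(Xte)
    ll = np.empty((2, n_te, S))
    for ci, c in enumerate(classes):
        Xc = Xtr[ytr == c]
        mean = Xc.mean(axis=0)
        cov = np.cov(Xc, rowvar=False, ddof=0)
        cov_s = cov[subsets[:, :, None], subsets[:, None, :]]          # (S, d, d)
        tr = np.trace(cov_s, axis1=1, axis2=2)
        cov_s = cov_s + (lam_scale * tr / d)[:, None, None] * np.eye(d)
        L = np.linalg.cholesky(cov_s)                                   # (S, d, d)
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
        diff = Xte[:, subsets] - mean[subsets]                          # (n_te, S, d)
        z = np.linalg.solve(L[None], diff[..., None])[..., 0]          # (n_te, S, d)
        maha = (z**2).sum(axis=-1)
        prior = (ytr == c).mean()
        ll[ci] = -0.5 * (maha + logdet[None, :]) + np.log(prior)
    pred = ll[1] > ll[0]   # class order = sorted unique = (0, 1)
    correct = (pred == (yte[:, None] == classes[1])).sum(axis=0)
    return correct, ll[1] - ll[0]


def qda_subset_search(
    candidates: list[str],
    table: pd.DataFrame,
    labels: np.ndarray,
    subset_size: int = 7,
    n_iter: int = 100,
    n_folds: int = 3,
    seed: int = 0,
    per_category: dict[str, list[str]] | None = None,
) -> SelectionResult:
    """Exhaustive search over all C(len(candidates), subset_size) subsets.

    Every subset is scored by mean QDA accuracy over the same ``n_iter``
    repeats of stratified ``n_folds``-fold cross-validation (one seed stream,
    folds shared across subsets).  Ties break by higher mean AUC, then lower
    mRMR rank-sum, then lexicographic subset order.
    """
    y = np.asarray(labels).astype(int)
    X = table[candidates].to_numpy(dtype=float)
    n = len(y)
    if n < 3 * subset_size:
        warnings.warn(
            f"n={n} is small for subset_size={subset_size}; CV estimates will be noisy"
        )
    subsets = np.array(list(combinations(range(len(candidates)), subset_size)))
    rng = np.random.default_rng(seed)

    correct = np.zeros(len(subsets))
    total = 0
    auc_sum = np.zeros(len(subsets))
    n_auc = 0
    for _ in range(n_iter):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        for tr_idx, te_idx in skf.split(X, y):
            c, scores = _fold_subset_scores(
                X[tr_idx], y[tr_idx], X[te_idx], y[te_idx], subsets
            )
            correct += c
            total += len(te_idx)
            yte = y[te_idx]
            if len(np.unique(yte)) == 2:
                # midrank AUC per subset, for tie-breaking
                from scipy.stats import rankdata

                ranks = rankdata(scores, axis=0)
                n_pos = int((yte == 1).sum())
                n_neg = len(yte) - n_pos
                auc_sum += (ranks[yte == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (
                    n_pos * n_neg
                )
                n_auc += 1

    acc = correct / total
    best_acc = acc.max()
    tied = np.where(acc == best_acc)[0]
    if len(tied) > 1 and n_auc > 0:
        aucs = auc_sum[tied] / n_auc
        tied = tied[aucs == aucs.max()]
    if len(tied) > 1:
        rank_sums = subsets[tied].sum(axis=1)  # candidate index = mRMR rank order
        tied = tied[rank_sums == rank_sums.min()]
    best = tied[0]  # subsets are generated in lexicographic order

    selected = [candidates[i] for i in subsets[best]]
    return SelectionResult(
        per_category=per_category or {},
        candidates=list(candidates),
        selected=selected,
        cv_accuracy=float(acc[best]),
        subset_size=subset_size,
        n_iter=n_iter,
        n_folds=n_folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Classifier training / prediction / serialisation
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    classifier_kind: str            # "QDA" | "LDA" | "SVM"
    selected_features: list[str]
    params: dict                    # serialisable fitted parameters
    feature_means: np.ndarray
    feature_scales: np.ndarray
    training_seed: int = 0

    def standardize(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in table.columns]
        if missing:
            raise ValueError(f"missing feature column at predict time: {missing[0]}")
        X = table[self.selected_features].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in selected feature columns")
        return (X - self.feature_means) / self.feature_scales


def train_classifier(
    kind: str,
    table: pd.DataFrame,
    labels: np.ndarray,
    selected: list[str],
    seed: int = 0,
) -> ModelBundle:
    """Fit QDA/LDA (Gaussian discriminants) or a degree-2 polynomial SVM on
    standardised selected features."""
    kind = kind.upper()
    if kind not in ("QDA", "LDA", "SVM"):
        raise ValueError("kind must be QDA, LDA or SVM")
    y = np.asarray(labels).astype(int)
    X = table[selected].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in selected feature columns")
    means = X.mean(axis=0)
    scales = X.std(ddof=0, axis=0)
    scales[scales == 0] = 1.0
    Xs = (X - means) / scales

    if kind in ("QDA", "LDA"):
        clf = GaussianDiscriminant(kind=kind).fit(Xs, y)
        params = clf.to_dict()
    else:
        svc = SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", random_state=seed)
        svc.fit(Xs, y)
        params = {
            "support_vectors": svc.support_vectors_.tolist(),
            "dual_coef": svc.dual_coef_.tolist(),
            "intercept": svc.intercept_.tolist(),
            "gamma": float(svc._gamma),
            "coef0": 1.0,
            "degree": 2,
            "classes": svc.classes_.tolist(),
        }
    return ModelBundle(
        classifier_kind=kind,
        selected_features=list(selected),
        params=params,
        feature_means=means,
        feature_scales=scales,
        training_seed=seed,
    )


def _svm_decision(params: dict, Xs: np.ndarray) -> np.ndarray:
    sv = np.asarray(params["support_vectors"])
    dual = np.asarray(params["dual_coef"])[0]
    K = (params["gamma"] * (Xs @ sv.T) + params["coef0"]) ** params["degree"]
    return K @ dual + params["intercept"][0]


def predict(bundle: ModelBundle, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(scores, binary calls).  Scores are class-1 posteriors (QDA/LDA,
    threshold 0.5) or the SVM margin (threshold 0)."""
    Xs = bundle.standardize(table)
    if bundle.classifier_kind in ("QDA", "LDA"):
        clf = GaussianDiscriminant.from_dict(bundle.params)
        scores = clf.predict_proba(Xs)[:, 1]
        calls = scores > 0.5
    else:
        scores = _svm_decision(bundle.params, Xs)
        calls = scores > 0.0
    return scores, calls.astype(bool)


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    payload = {
        "classifier_kind": bundle.classifier_kind,
        "selected_features": bundle.selected_features,
        "params": bundle.params,
        "feature_means": np.asarray(bundle.feature_means).tolist(),
        "feature_scales": np.asarray(bundle.feature_scales).tolist(),
        "training_seed": bundle.training_seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ModelBundle:
    d = json.loads(Path(path).read_text())
    return ModelBundle(
        classifier_kind=d["classifier_kind"],
        selected_features=d["selected_features"],
        params=d["params"],
        feature_means=np.asarray(d["feature_means"]),
        feature_scales=np.asarray(d["feature_scales"]),
        training_seed=d["training_seed"],
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    recall: float
    ppv: float
    specificity: float
    auc: float
    roc_fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def confusion(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """accuracy / recall (sensitivity) / PPV / specificity from counts."""
    n = tp + fp + fn + tn
    return {
        "accuracy": (tp + tn) / n,
        "recall": tp / (tp + fn) if tp + fn else np.nan,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }


def evaluate(calls: np.ndarray, scores: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Confusion counts, accuracy/recall/PPV/specificity, ROC points and the
    trapezoidal (midrank-equivalent) AUC."""
    calls = np.asarray(calls).astype(bool)
    truth = np.asarray(truth).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if not (len(calls) == len(scores) == len(truth)):
        raise ValueError("calls, scores, truth must have equal lengths")
    tp = int((calls & truth).sum())
    fp = int((calls & ~truth).sum())
    fn = int((~calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    m = metrics_from_confusion(tp, fp, fn, tn)
    if len(np.unique(truth)) == 2:
        auc = float(roc_auc_score(truth, scores))
        fpr, tpr, _ = roc_curve(truth, scores)
    else:
        warnings.warn("one-class truth: AUC undefined")
        auc, fpr, tpr = np.nan, np.array([]), np.array([])
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=m["accuracy"], recall=m["recall"], ppv=m["ppv"],
        specificity=m["specificity"], auc=auc, roc_fpr=fpr, roc_tpr=tpr,
    )
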