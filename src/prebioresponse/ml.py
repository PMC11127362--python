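"""Responder classification and permutation feature ranking.

Per-substrate RBF-kernel SVM classifiers are trained on baseline
target-gene copy numbers (log10(x+1)-transformed, z-scored with
training statistics only).  Hyperparameters (cost C, kernel width
sigma) are grid-searched by repeated stratified k-fold cross-validated
AUC; features are ranked by permutation importance: the mean drop in
held-out AUC when one feature's column is shuffled, averaged over many
independently split and trained models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

POSITIVE_LABEL = "R"


@dataclass(frozen=True)
class SvmConfig:
    """Grid-search and resampling settings.

    ``sigma_scales`` multiply the median-heuristic kernel width; the
    RBF gamma is 1/(2 sigma^2).  ``n_models`` independent split/train
    cycles feed the permutation ranking with ``n_permutations``
    shuffles per feature per model.
    """

    c_grid: tuple[float, ...] = tuple(2.0**k for k in range(-2, 7))
    sigma_scales: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    cv_folds: int = 5
    cv_repeats: int = 10
    split_fraction: float = 0.5
    n_models: int = 100
    n_permutations: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.sigma_scales:
            raise ValueError("hyperparameter grids must be nonempty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class TrainedModel:
    """A fitted RBF SVM plus the preprocessing statistics it needs."""

    svc: SVC
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    C: float
    sigma: float
    cv_auc: float

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing: {missing}")
        Z = (X[self.feature_names].to_numpy(dtype=float) - self.scale_mean) / self.scale_std
        return self.svc.decision_function(Z)


def build_feature_matrix(
    copies: pd.DataFrame, labels: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series | None]:
    """log10(copy number + 1) feature encoding; non-detects (NaN) -> 0."""
    X = np.log10(copies.fillna(0.0).clip(lower=0.0) + 1.0)
    if labels is not None:
        labels = labels.reindex(X.index)
        if labels.isna().any():
            raise ValueError("labels missing for some subjects")
    return X, labels


def split_train_test(
    X: pd.DataFrame, y: pd.Series, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Stratified random partition into train and held-out test sets."""
    rng = np.random.default_rng(seed)
    train_idx: list = []
    for label in sorted(y.unique()):
        members = y.index[y == label].to_numpy()
        if members.size < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members")
        perm = rng.permutation(members)
        n_train = int(round(fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
    train_mask = X.index.isin(train_idx)
    return (
        X[train_mask], y[train_mask], X[~train_mask], y[~train_mask],
    )


def auc(labels, scores) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity.

    Probability that a random positive outscores a random negative,
    with ties counting one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == POSITIVE_LABEL if labels.dtype.kind in "UO" else labels.astype(bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _median_heuristic_sigma(Z: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the standardized matrix."""
    if Z.shape[0] < 2:
        return 1.0
    d = pdist(Z)
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return med if med > 0 else 1.0


def train_svm(
    X: pd.DataFrame, y: pd.Series, config: SvmConfig | None = None, seed: int | None = None
) -> TrainedModel:
    """Grid-searched RBF SVM with repeated stratified k-fold CV.

    Selects (C, sigma) maximizing mean cross-validated AUC, then refits
    on the full training set.  Features are z-scored with training
    statistics; constant features get unit scale.
    """
    config = config or SvmConfig()
    seed = config.seed if seed is None else seed
    Xa = X.to_numpy(dtype=float)
    ya = (y == POSITIVE_LABEL).to_numpy()
    mean = Xa.mean(axis=0)
    std = Xa.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    Z = (Xa - mean) / std

    sigma0 = _median_heuristic_sigma(Z)
    sigmas = [sigma0 * s for s in config.sigma_scales]
    folds = int(min(config.cv_folds, ya.sum(), (~ya).sum()))
    if folds < 2:
        raise ValueError("need >= 2 members per class for cross-validation")
    cv = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=config.cv_repeats, random_state=seed % 2**31
    )
    splits = list(cv.split(Z, ya))

    best = None
    for C in config.c_grid:
        for sigma in sigmas:
            gamma = 1.0 / (2.0 * sigma**2)
            fold_aucs = []
            for tr, te in splits:
                if ya[te].all() or not ya[te].any():
                    continue
                clf = SVC(C=C, kernel="rbf", gamma=gamma)
                clf.fit(Z[tr], ya[tr])
                fold_aucs.append(auc(ya[te], clf.decision_function(Z[te])))
            score = float(np.mean(fold_aucs)) if fold_aucs else 0.5
            if best is None or score > best[0]:
                best = (score, C, sigma, gamma)
    cv_auc, C, sigma, gamma = best
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    svc.fit(Z, ya)
    return TrainedModel(
        svc=svc,
        feature_names=list(X.columns),
        scale_mean=mean,
        scale_std=std,
        C=float(C),
        sigma=float(sigma),
        cv_auc=cv_auc,
    )


def predict_phenotype(model: TrainedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Label new subjects by decision-score sign (threshold 0)."""
    scores = model.decision_scores(X)
    return pd.DataFrame(
        {
            "label": np.where(scores > 0, "R", "NR"),
            "decision_score": scores,
        },
        index=X.index,
    )


def permutation_importance(
    X: pd.DataFrame, y: pd.Series, config: SvmConfig | None = None
) -> pd.DataFrame:
    """Rank features by mean test-AUC drop under column permutation.

    For each of ``n_models`` models (independent 50:50 splits and CV
    seeds), compute the held-out AUC, then for every feature the mean
    AUC over ``n_permutations`` shuffles of that feature's test column;
    the feature's per-model importance is the difference.  Output is
    sorted by mean importance, descending.
    """
    config = config or SvmConfig()
    deltas = {f: [] for f in X.columns}
    for m in range(config.n_models):
        seed_m = (config.seed + 7919 * m) % 2**31
        X_tr, y_tr, X_te, y_te = split_train_test(
            X, y, fraction=config.split_fraction, seed=seed_m
        )
        model = train_svm(X_tr, y_tr, config=config, seed=seed_m)
        base_auc = auc(y_te, model.decision_scores(X_te))
        rng = np.random.default_rng(seed_m)
        for f in X.columns:
            col = X_te[f].to_numpy().copy()
            perm_aucs = []
            for _ in range(config.n_permutations):
                Xp = X_te.copy()
                Xp[f] = rng.permutation(col)
                perm_aucs.append(auc(y_te, model.decision_scores(Xp)))
            deltas[f].append(base_auc - float(np.mean(perm_aucs)))
    rows = [
        {
            "feature": f,
            "mean_delta_auc": float(np.mean(d)),
            "per_model_delta": list(map(float, d)),
        }
        for f, d in deltas.items()
    ]
    out = pd.DataFrame(rows).sort_values(
        "mean_delta_auc", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)
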