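"""Feature selection cascade: split/balance -> Boruta + LASSO -> clustering -> VIF.

The gated feature table is split into training (67%) and testing (33%)
cohorts with per-class undersampling to equal class counts.  Two selectors
run independently on the training cohort: Boruta (all-relevant shadow
feature search with a random forest) and L1-penalized logistic regression
with five-fold cross-validation.  Their union is decorrelated by
average-linkage hierarchical clustering on 1 - |Spearman rho| with one
medoid representative per cluster, and the survivors' variance inflation
factors are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import binomtest, spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold


@dataclass
class BorutaResult:
    confirmed: list[str]
    tentative: list[str]
    rejected: list[str]
    n_iterations: int


@dataclass
class SelectionResult:
    split_seed: int
    train_ids: list[str]
    test_ids: list[str]
    boruta_selected: list[str] = field(default_factory=list)
    lasso_selected: list[str] = field(default_factory=list)
    lasso_lambda: float = np.nan
    union: list[str] = field(default_factory=list)
    clusters: dict[str, int] = field(default_factory=dict)
    independent: list[str] = field(default_factory=list)
    vif: dict[str, float] = field(default_factory=dict)


def split_and_balance(
    labels: pd.Series, train_frac: float = 0.67, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified split then per-split random undersampling to equal classes.

    Per class, ``floor(train_frac * n_class)`` cases go to training; within
    each split the majority class is undersampled to the minority count
    (e.g. 23+/19- -> train 15+/12- -> 24 balanced; test 8+/7- -> 14).
    """
    rng = np.random.default_rng(seed)
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    train: dict[object, list] = {}
    test: dict[object, list] = {}
    for cls in sorted(classes, key=str):
        ids = labels.index[labels == cls].to_numpy()
        ids = rng.permutation(ids)
        n_train = int(np.floor(train_frac * len(ids)))
        train[cls], test[cls] = list(ids[:n_train]), list(ids[n_train:])
    for part in (train, test):
        if any(len(v) == 0 for v in part.values()):
            raise ValueError("a class is absent from one split")
        n_min = min(len(v) for v in part.values())
        for cls in part:
            if len(part[cls]) > n_min:
                part[cls] = list(rng.permutation(part[cls])[:n_min])
    train_ids = sorted(sum(train.values(), []))
    test_ids = sorted(sum(test.values(), []))
    return train_ids, test_ids


def _scale(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=0).replace(0.0, 1.0)
    return (X - X.mean()) / sd


def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    max_iter: int = 100,
    n_estimators: int = 500,
    alpha: float = 0.01,
) -> BorutaResult:
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends a column-permuted shadow copy of every feature,
    fits a random forest, and scores a "hit" for features whose impurity
    importance beats the best shadow.  Two-sided Bonferroni-corrected
    binomial tests against p=0.5 confirm (greater) or reject (less)
    features; undecided features stay tentative.
    """
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite values in X")
    rng = np.random.default_rng(seed)
    Xs = _scale(X)
    names = list(Xs.columns)
    active = list(names)
    hits = dict.fromkeys(names, 0)
    trials = dict.fromkeys(names, 0)
    confirmed: list[str] = []
    rejected: list[str] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if not active:
            break
        # confirmed features stay in the forest (and contribute shadows) so
        # the max-shadow bar reflects the full model; only undecided features
        # accumulate hits
        kept = active + confirmed
        Xa = Xs[kept].to_numpy()
        shadows = np.column_stack([rng.permutation(col) for col in Xa.T])
        design = np.hstack([Xa, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(design, y)
        imp = forest.feature_importances_
        best_shadow = imp[len(kept):].max()
        for i, name in enumerate(active):
            trials[name] += 1
            if imp[i] > best_shadow:
                hits[name] += 1
        bonf = alpha / len(names)
        still = []
        for name in active:
            p_hi = binomtest(hits[name], trials[name], 0.5, alternative="greater").pvalue
            p_lo = binomtest(hits[name], trials[name], 0.5, alternative="less").pvalue
            if p_hi < bonf:
                confirmed.append(name)
            elif p_lo < bonf:
                rejected.append(name)
            else:
                still.append(name)
        active = still
    return BorutaResult(
        confirmed=sorted(confirmed),
        tentative=sorted(active),
        rejected=sorted(rejected),
        n_iterations=n_iter,
    )


def lasso_select(
    X: pd.DataFrame, y: np.ndarray, folds: int = 5, seed: int = 0
) -> tuple[list[str], float]:
    """L1-logistic selection; lambda = CV-deviance minimizer over a path."""
    Xs = _scale(X)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=np.logspace(-3, 3, 60),
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # sklearn 1.8+ renames penalty= to l1_ratios=; stay on the stable API
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(Xs.to_numpy(), y)
    lam = 1.0 / float(model.C_[0])
    coefs = model.coef_.ravel()
    selected = sorted(Xs.columns[np.abs(coefs) > 1e-10])
    return selected, lam


def hierarchical_decorrelate(
    X: pd.DataFrame,
    candidates: list[str],
    corr_threshold: float = 0.75,
) -> tuple[dict[str, int], list[str]]:
    """Cluster candidates on 1 - |Spearman rho| (average linkage) and keep one
    medoid per cluster (max mean |rho| to cluster members, ties alphabetical)."""
    candidates = sorted(candidates)
    if len(candidates) < 2:
        return {c: 1 for c in candidates}, list(candidates)
    sub = X[candidates].to_numpy()
    rho = spearmanr(sub).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    link = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(link, t=1.0 - corr_threshold, criterion="distance")
    clusters = {c: int(l) for c, l in zip(candidates, labels)}
    representatives = []
    for lab in sorted(set(labels)):
        members = [c for c in candidates if clusters[c] == lab]
        if len(members) == 1:
            representatives.append(members[0])
            continue
        idx = [candidates.index(m) for m in members]
        mean_abs = np.abs(rho[np.ix_(idx, idx)]).mean(axis=1)
        best = members[int(np.argmax(mean_abs))]  # argmax ties -> first = alphabetical
        representatives.append(best)
    return clusters, sorted(representatives)


def vif_check(X: pd.DataFrame, features: list[str]) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2) of feature j regressed on the other features."""
    features = list(features)
    if len(features) < 2:
        return {f: 1.0 for f in features}
    if X.shape[0] <= len(features):
        raise ValueError("need more observations than features for VIF")
    Z = _scale(X[features]).to_numpy()
    out: dict[str, float] = {}
    for j, name in enumerate(features):
        yj = Z[:, j]
        others = np.delete(Z, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        sst = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 1.0
        out[name] = float(np.inf) if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def select_features(
    X: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    train_frac: float = 0.67,
    corr_threshold: float = 0.75,
    vif_threshold: float = 5.0,
    boruta_kwargs: dict | None = None,
) -> SelectionResult:
    """Run the full cascade and record per-stage survivors."""
    train_ids, test_ids = split_and_balance(labels, train_frac, seed)
    Xtr = X.loc[train_ids]
    ytr = labels.loc[train_ids].to_numpy().astype(int)
    res = SelectionResult(split_seed=seed, train_ids=train_ids, test_ids=test_ids)
    boruta = boruta_select(Xtr, ytr, seed=seed, **(boruta_kwargs or {}))
    res.boruta_selected = boruta.confirmed
    res.lasso_selected, res.lasso_lambda = lasso_select(Xtr, ytr, seed=seed)
    res.union = sorted(set(res.boruta_selected) | set(res.lasso_selected))
    res.clusters, res.independent = hierarchical_decorrelate(
        Xtr, res.union, corr_threshold
    )
    # pairwise-|rho| clustering cannot rule out multi-feature collinearity;
    # prune the worst VIF until the independent set honours VIF < 5
    while len(res.independent) >= 2:
        res.vif = vif_check(Xtr, res.independent)
        worst = max(res.independent, key=lambda f: (res.vif[f], f))
        if res.vif[worst] < vif_threshold:
            break
        res.independent = [f for f in res.independent if f != worst]
    if len(res.independent) < 2:
        res.vif = {f: 1.0 for f in res.independent}
    return res
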