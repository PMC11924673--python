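"""Per-feature logistic classification, metric panel, and decision stump.

Each independent feature gets a univariate logistic model (z-scored on the
training cohort, scaler reused on the test cohort), assessed with seeded
stratified 10-fold cross-validation and ranked by AIC; held-out evaluation
reports accuracy with an exact Clopper-Pearson interval, balanced accuracy,
Cohen's kappa, F1, and rank-based AUC with a DeLong interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    aic: float
    loglik: float
    separation_fallback: bool = False
    x_mean: float = 0.0  # training-scaler parameters
    x_sd: float = 1.0

    def predict_proba(self, x_raw: np.ndarray) -> np.ndarray:
        z = (np.asarray(x_raw, dtype=float) - self.x_mean) / self.x_sd
        eta = self.intercept + self.slope * z
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ModelMetrics:
    accuracy: float
    accuracy_ci: tuple[float, float]
    balanced_accuracy: float
    kappa: float
    f1: float
    auc: float
    auc_ci: tuple[float, float]
    tp: int
    fp: int
    fn: int
    tn: int
    aic: float = np.nan
    threshold: float = np.nan

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "accuracy_ci_low": self.accuracy_ci[0],
            "accuracy_ci_high": self.accuracy_ci[1],
            "balanced_accuracy": self.balanced_accuracy,
            "kappa": self.kappa,
            "f1": self.f1,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "aic": self.aic,
        }
        if np.isfinite(self.threshold):
            d["threshold"] = self.threshold
        return d


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Bias-reduced (Firth) logistic fit; finite under complete separation."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        W = np.diag(w)
        info = X.T @ W @ X
        try:
            inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", X @ inv, np.eye(X.shape[1]), X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        step = inv @ score
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    return beta


def fit_logistic_univariate(x: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Univariate MLE logistic fit on z-scored x; Firth fallback on separation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    mu, sd = float(x.mean()), float(x.std())
    sd = sd if sd > 0 else 1.0
    z = (x - mu) / sd
    X = sm.add_constant(z)
    fallback = False
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter(
                "error", sm.tools.sm_exceptions.PerfectSeparationWarning
            )
            fit = sm.Logit(y, X).fit(disp=0, warn_convergence=False)
        params = np.asarray(fit.params)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            raise sm.tools.sm_exceptions.PerfectSeparationError
        loglik = float(fit.llf)
    except Exception:
        fallback = True
        params = _firth_logistic(X, y)
        eta = X @ params
        loglik = float((y * eta - np.log1p(np.exp(eta))).sum())
    aic = 2 * 2 - 2 * loglik
    return LogisticFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        aic=float(aic),
        loglik=loglik,
        separation_fallback=fallback,
        x_mean=mu,
        x_sd=sd,
    )


def cross_validate(
    x: np.ndarray, y: np.ndarray, folds: int = 10, seed: int = 0
) -> dict[str, float | np.ndarray]:
    """Seeded stratified k-fold CV of the univariate logistic model."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError("stratified folds infeasible: a class has too few cases")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x.reshape(-1, 1), y):
        fit = fit_logistic_univariate(x[tr], y[tr])
        pred = (fit.predict_proba(x[te]) >= 0.5).astype(int)
        accs.append(float((pred == y[te]).mean()))
    accs = np.asarray(accs)
    return {"fold_accuracy": accs, "mean": float(accs.mean()), "sd": float(accs.std(ddof=1))}


def clopper_pearson(successes: int, total: int, alpha: float = 0.05) -> tuple[float, float]:
    ci = stats.binomtest(successes, total).proportion_ci(
        confidence_level=1 - alpha, method="exact"
    )
    return (float(ci.low), float(ci.high))


def _delong_auc_ci(
    scores: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """AUC by the Mann-Whitney statistic with DeLong variance."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    zc = stats.norm.ppf(1 - alpha / 2)
    lo, hi = max(0.0, auc - zc * se), min(1.0, auc + zc * se)
    return auc, (lo, hi)


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """The Table-style panel from raw confusion counts."""
    total = tp + fp + fn + tn
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    bal = (sens + spec) / 2
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    p_yes = ((tp + fp) / total) * ((tp + fn) / total)
    p_no = ((tn + fn) / total) * ((tn + fp) / total)
    pe = p_yes + p_no
    kappa = (acc - pe) / (1 - pe) if pe < 1 else 1.0
    ci = clopper_pearson(tp + tn, total)
    return {
        "accuracy": acc,
        "accuracy_ci": ci,
        "balanced_accuracy": bal,
        "kappa": kappa,
        "f1": f1,
    }


def evaluate(
    fit: LogisticFit, x_test: np.ndarray, y_test: np.ndarray
) -> ModelMetrics:
    """Held-out metric panel; classification at probability 0.5."""
    y_test = np.asarray(y_test, dtype=int)
    if len(np.unique(y_test)) < 2:
        raise ValueError("single-class test set: AUC undefined")
    scores = fit.predict_proba(x_test)
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    panel = confusion_metrics(tp, fp, fn, tn)
    auc, auc_ci = _delong_auc_ci(scores, y_test)
    return ModelMetrics(
        accuracy=panel["accuracy"],
        accuracy_ci=panel["accuracy_ci"],
        balanced_accuracy=panel["balanced_accuracy"],
        kappa=panel["kappa"],
        f1=panel["f1"],
        auc=auc,
        auc_ci=auc_ci,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        aic=fit.aic,
    )


def rank_models(models: dict[str, LogisticFit]) -> list[str]:
    """Feature names by ascending AIC, ties broken alphabetically."""
    if not models:
        raise ValueError("no models to rank")
    return sorted(models, key=lambda name: (models[name].aic, name))


def stump_threshold(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Best single split by Gini impurity over midpoints of sorted unique x.

    Returns (threshold, direction) with direction +1 if the high side
    predicts class 1, -1 otherwise.  Ties in impurity prefer the
    maximal-margin (largest gap) midpoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    ux = np.unique(x)
    if len(ux) < 2:
        raise ValueError("constant x: no split exists")
    mids = (ux[:-1] + ux[1:]) / 2
    gaps = ux[1:] - ux[:-1]
    n = len(y)
    best = None
    for t, gap in zip(mids, gaps):
        hi = x > t
        n_hi = int(hi.sum())
        n_lo = n - n_hi
        p_hi = y[hi].mean() if n_hi else 0.0
        p_lo = y[~hi].mean() if n_lo else 0.0
        gini = (n_hi / n) * 2 * p_hi * (1 - p_hi) + (n_lo / n) * 2 * p_lo * (1 - p_lo)
        key = (gini, -gap)
        if best is None or key < best[0]:
            direction = 1 if p_hi >= p_lo else -1
            best = (key, float(t), direction)
    return best[1], best[2]


def evaluate_stump(
    threshold: float, direction: int, x: np.ndarray, y: np.ndarray
) -> ModelMetrics:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    pred = ((x > threshold).astype(int) if direction > 0 else (x <= threshold).astype(int))
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    panel = confusion_metrics(tp, fp, fn, tn)
    scores = x * direction
    auc, auc_ci = _delong_auc_ci(scores, y)
    return ModelMetrics(
        accuracy=panel["accuracy"],
        accuracy_ci=panel["accuracy_ci"],
        balanced_accuracy=panel["balanced_accuracy"],
        kappa=panel["kappa"],
        f1=panel["f1"],
        auc=auc,
        auc_ci=auc_ci,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        threshold=threshold,
    )
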