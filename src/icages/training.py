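"""Model fitting and evaluation for the variant-level ensemble and the
gene-level logistic model.

The ensemble is fit with libsvm (via scikit-learn) and then frozen into the
package's own dual-form container so that scoring runs through the explicit
radial-kernel path. The logistic model is fit directly by Newton iteration
on the mean cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import CollinearityError, ConfigurationError, ConvergenceError, TrainingError
from .variant_layer import (
    FEATURE_ORDER,
    UNIT_SCALE_FEATURES,
    EnsembleSvmModel,
    SvmHyperparams,
)

#: Default hyperparameter grid searched by train_ensemble.
DEFAULT_GRID = tuple(
    SvmHyperparams(c=c, gamma=g)
    for c in (0.1, 1.0, 10.0, 100.0)
    for g in (1e-4, 1e-3, 1e-2, 1e-1)
)

#: AUC difference below which two grid points count as tied.
AUC_TIE_TOL = 0.001


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    folds: int = 0
    replicates: int = 0

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC {self.auc} outside [0,1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must bracket the AUC")


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires both classes present")


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware pairwise concordance probability (rank form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise TrainingError("AUC undefined for single-class labels")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(
    scores,
    labels,
    replicates: int = 2000,
    seed: int = 0,
    folds: int = 0,
) -> RocResult:
    """AUC with a stratified bootstrap percentile 95% CI.

    Positives and negatives are resampled separately in each replicate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = _auc(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    stats = np.empty(replicates)
    for r in range(replicates):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([bp, bn])
        stats[r] = _auc(scores[idx], labels[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return RocResult(auc=point, ci_low=float(lo), ci_high=float(hi),
                     folds=folds, replicates=replicates)


# ---------------------------------------------------------------------------
# ensemble (variant layer) training


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_unit = len(UNIT_SCALE_FEATURES)
    wide = X[:, n_unit:]
    return np.nanmin(wide, axis=0), np.nanmax(wide, axis=0)


def _prepare(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Median-impute and scale a raw training matrix.

    Returns (X_scaled, medians, wide_min, wide_max).
    """
    X = np.asarray(X, dtype=float)
    medians = np.nanmedian(X, axis=0)
    Xi = np.where(np.isnan(X), medians, X)
    wmin, wmax = _fit_scaler(Xi)
    model = EnsembleSvmModel(wide_min=wmin, wide_max=wmax)
    return model.scale(Xi), medians, wmin, wmax


def _cv_auc(
    Xs: np.ndarray, y: np.ndarray, hp: SvmHyperparams, folds: int, seed: int
) -> tuple[float, np.ndarray]:
    """Mean out-of-fold AUC for one grid point; also returns pooled
    out-of-fold decision values."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    oof = np.empty(len(y))
    for tr, te in skf.split(Xs, y):
        clf = SVC(C=hp.c, gamma=hp.gamma, kernel="rbf")
        clf.fit(Xs[tr], y[tr])
        d = clf.decision_function(Xs[te])
        oof[te] = d
        aucs.append(_auc(d, y[te]))
    return float(np.mean(aucs)), oof


def fit_platt(decisions: np.ndarray, y: np.ndarray,
              max_iter: int = 100, tol: float = 1e-10) -> tuple[float, float]:
    """Platt scaling: fit (A, B) so that P(y=1|d) = 1/(1+exp(A d + B)).

    Newton iteration on the cross-entropy against Platt's smoothed targets.
    """
    d = np.asarray(decisions, dtype=float)
    y = np.asarray(y).astype(int)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A, B = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    for _ in range(max_iter):
        z = A * d + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        g = np.array([np.sum((t - p) * d), np.sum(t - p)])
        if np.max(np.abs(g)) < tol * len(d):
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        H = np.array([[np.sum(w * d * d), np.sum(w * d)],
                      [np.sum(w * d), np.sum(w)]])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        A -= step[0]
        B -= step[1]
    return float(A), float(B)


def _freeze(clf: SVC, oof_decisions: np.ndarray, y: np.ndarray,
            hp: SvmHyperparams, medians, wmin, wmax) -> EnsembleSvmModel:
    """Package a fitted sklearn SVC as the explicit dual-form container,
    calibrated on out-of-fold decision values."""
    prob_a, prob_b = fit_platt(oof_decisions, y)
    return EnsembleSvmModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        hyperparams=hp,
        prob_a=prob_a,
        prob_b=prob_b,
        training_medians=np.asarray(medians, dtype=float),
        wide_min=np.asarray(wmin, dtype=float),
        wide_max=np.asarray(wmax, dtype=float),
    )


def train_ensemble(
    X,
    y,
    grid: tuple[SvmHyperparams, ...] = DEFAULT_GRID,
    folds: int = 5,
    seed: int = 0,
    replicates: int = 2000,
) -> tuple[EnsembleSvmModel, RocResult]:
    """Grid-tune (c, gamma) by stratified CV AUC, refit on all data, freeze.

    Ties within AUC_TIE_TOL resolve to the smallest c, then smallest gamma
    (least overfitting potential). The returned RocResult is computed on
    pooled out-of-fold decision values at the selected grid point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    counts = np.bincount(y)
    if folds > counts[counts > 0].min():
        raise ConfigurationError(
            f"folds ({folds}) exceeds the smaller class size ({counts[counts > 0].min()})"
        )
    Xs, medians, wmin, wmax = _prepare(X)

    results = []
    for hp in grid:
        mean_auc, oof = _cv_auc(Xs, y, hp, folds, seed)
        results.append((mean_auc, hp, oof))
    best_auc = max(r[0] for r in results)
    tied = [r for r in results if best_auc - r[0] <= AUC_TIE_TOL]
    tied.sort(key=lambda r: (r[1].c, r[1].gamma))
    _, best_hp, best_oof = tied[0]

    clf = SVC(C=best_hp.c, gamma=best_hp.gamma, kernel="rbf")
    clf.fit(Xs, y)
    model = _freeze(clf, best_oof, y, best_hp, medians, wmin, wmax)
    roc = roc_auc(best_oof, y, replicates=replicates, seed=seed, folds=folds)
    return model, roc


def backward_select(
    X,
    y,
    feature_names: tuple[str, ...] = FEATURE_ORDER,
    hyperparams: SvmHyperparams = SvmHyperparams(),
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[tuple[list[str], float]]]:
    """Greedy backward feature elimination on CV AUC.

    At each step the feature whose removal most improves the mean CV AUC is
    dropped; elimination stops when no removal improves it. Returns the
    retained feature names and the (feature set, AUC) trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    _check_two_classes(y)
    if X.shape[1] < 2:
        raise ConfigurationError("backward selection needs >= 2 features")
    names = list(feature_names[: X.shape[1]])
    # scale the full matrix once; column subsets index into it
    Xs, *_ = _prepare(X)

    def cv(cols: list[int]) -> float:
        return _cv_auc(Xs[:, cols], y, hyperparams, folds, seed)[0]

    cols = list(range(X.shape[1]))
    current = cv(cols)
    trace = [([names[i] for i in cols], current)]
    while len(cols) > 1:
        candidates = []
        for j in cols:
            reduced = [c for c in cols if c != j]
            candidates.append((cv(reduced), j, reduced))
        best = max(candidates, key=lambda t: t[0])
        if best[0] <= current:
            break
        current, _, cols = best[0], best[1], best[2]
        trace.append(([names[i] for i in cols], current))
    return [names[i] for i in cols], trace


# ---------------------------------------------------------------------------
# logistic (gene layer) training


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def logistic_loss(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy of the sigmoid model (the training objective)."""
    z = X @ w + b
    # log(1+e^-|z|) form avoids overflow
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def check_collinearity(X: np.ndarray, r2_threshold: float = 0.90) -> None:
    """Reject feature pairs whose squared Pearson correlation reaches the
    threshold."""
    X = np.asarray(X, dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    p = X.shape[1]
    for i in range(p):
        for j in range(i + 1, p):
            if np.isfinite(corr[i, j]) and corr[i, j] ** 2 >= r2_threshold:
                raise CollinearityError(
                    f"features {i} and {j} are collinear (R^2="
                    f"{corr[i, j] ** 2:.3f} >= {r2_threshold})"
                )


def train_logistic(
    X,
    y,
    tol: float = 1e-8,
    max_iter: int = 200,
    r2_threshold: float = 0.90,
) -> tuple[np.ndarray, float]:
    """Fit the non-regularized logistic model by Newton iteration.

    Minimizes the mean cross-entropy of h(x) = 1/(1+e^-(w.x+b)) to a
    gradient-norm tolerance of 1e-8. Perfectly separable data makes the
    unregularized weights diverge; this is reported as a ConvergenceError
    carrying the diverging direction. Returns (w, b).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_two_classes(y.astype(int))
    check_collinearity(X, r2_threshold)
    n, p = X.shape
    Xb = np.hstack([X, np.ones((n, 1))])
    theta = np.zeros(p + 1)
    for _ in range(max_iter):
        z = Xb @ theta
        mu = _sigmoid(z)
        grad = Xb.T @ (mu - y) / n
        if np.linalg.norm(grad) <= tol:
            # a vanishing loss means the unregularized optimum does not
            # exist (weights diverge along a separating direction)
            if logistic_loss(theta[:p], float(theta[p]), X, y) < 1e-6:
                break
            return theta[:p].copy(), float(theta[p])
        wdiag = mu * (1.0 - mu)
        H = (Xb * wdiag[:, None]).T @ Xb / n
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p + 1), grad)
        except np.linalg.LinAlgError:
            break
        theta -= step
        if np.linalg.norm(theta) > 1e6:
            break
    direction = theta[:p] / max(np.linalg.norm(theta[:p]), 1e-300)
    raise ConvergenceError(
        "logistic fit did not reach gradient tolerance "
        "(data may be perfectly separable)",
        direction=direction,
    )
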