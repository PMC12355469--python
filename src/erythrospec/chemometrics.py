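"""Supervised and unsupervised chemometrics for single-cell spectra.

The discriminant workhorse is OPLS-DA: partial least squares with the
class-orthogonal X-variation split off into separate components, so that a
single predictive latent variable carries all class-correlated variation
(with ``n_orthogonal = 0`` the model is exactly a one-component PLS1).
VIP scores flag the wavenumbers that drive the separation (VIP > 1 by the
usual convention; mean squared VIP is identically 1).

Model assessment follows standard chemometric practice: group-stratified
cross-validation with all centering/scaling re-estimated inside each
training fold, pooled confusion counts summarised as sensitivity,
specificity and the Matthews correlation coefficient, a group-level label
permutation test of the cross-validated MCC, and ROC analysis with
Youden-J threshold selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold

from .core import SpectralAxis

__all__ = [
    "SpectraMatrix",
    "DiscriminantModel",
    "CVResult",
    "ROCResult",
    "pca",
    "opls_fit",
    "opls_predict",
    "vip",
    "metrics_from_confusion",
    "cross_validate",
    "permutation_test",
    "roc",
    "mann_whitney",
]


@dataclass
class SpectraMatrix:
    """Samples-by-channels spectra with class labels and grouping ids.

    ``y`` uses the +1 / -1 coding (+1 = precursor, -1 = erythrocyte-like).
    ``group_ids`` identify the cell each spectrum came from, so that
    grouped cross-validation never splits a cell across folds.
    """

    X: np.ndarray
    axis: SpectralAxis
    y: np.ndarray
    sample_ids: list[str]
    group_ids: list[str]
    class_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x channels)")
        if self.X.shape[1] != len(self.axis):
            raise ValueError("X channel count does not match axis")
        if self.X.shape[0] != self.y.size:
            raise ValueError("y length does not match X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing/non-finite values")
        if len(self.sample_ids) != self.X.shape[0] \
                or len(self.group_ids) != self.X.shape[0]:
            raise ValueError("id lists must match the number of samples")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(X: np.ndarray, n_components: int | None = None, center: bool = True,
        scale: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal component analysis by SVD.

    Returns ``(scores, loadings, explained_percent)`` with orthonormal
    loadings (channels x k), non-increasing explained-variance percentages
    of the total variance, and scores = (processed X) @ loadings.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components is None:
        n_components = min(n - 1, p)
    if n_components > min(n - 1 if center else n, p):
        raise ValueError("n_components too large for the data")
    Xw = X - X.mean(axis=0) if center else X.copy()
    if scale:
        sd = Xw.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xw = Xw / sd
    if np.allclose(Xw, 0):
        raise ValueError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(Xw, full_matrices=False)
    var = s**2
    explained = 100.0 * var / var.sum()
    loadings = Vt[:n_components].T
    # sign convention: largest-magnitude loading positive
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                             np.arange(n_components)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = Xw @ loadings
    return scores, loadings, explained[:n_components]


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """Fitted OPLS-DA model: one predictive + ``n_orthogonal`` orthogonal
    latent variables, centering/scaling vectors, and VIP scores."""

    w_pred: np.ndarray           # (channels,) predictive weight, unit norm
    p_pred: np.ndarray           # (channels,) predictive loading
    q_pred: float                # y-loading of the predictive score
    t_pred: np.ndarray           # (n,) predictive scores on training data
    W_ortho: np.ndarray          # (n_orthogonal, channels) unit weights
    P_ortho: np.ndarray          # (n_orthogonal, channels) loadings
    T_ortho: np.ndarray          # (n_orthogonal, n) training scores
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2x_total: float             # fraction of X variance captured by LVs
    n_orthogonal: int = 0
    vip_: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.w_pred.size


def opls_fit(X: np.ndarray, y: np.ndarray, n_orthogonal: int = 3,
             scale: bool = False) -> DiscriminantModel:
    """Fit OPLS-DA with a binary response.

    The orthogonal filter follows the standard O-PLS recipe: for each
    orthogonal component the X-loading of the current predictive score is
    stripped of its projection on the predictive weight, giving a weight
    direction that captures structured X-variation uncorrelated with y;
    that component is removed from X before the final one-component PLS
    fit.  Orthogonal scores are y-uncorrelated by construction (asserted
    to 1e-8 after every fit).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")

    x_mean = X.mean(axis=0)
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(X.shape[1])
    y_mean = float(y.mean())
    Xc = (X - x_mean) / x_scale
    yc = y - y_mean
    ss_x_total = float(np.sum(Xc**2))

    w = Xc.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("y carries no signal in X")
    w = w / nw

    E = Xc.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orthogonal):
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10 * max(1.0, np.linalg.norm(p)):
            # The predictive loading carries no orthogonal direction; this
            # happens when the confounding variation is *exactly*
            # y-orthogonal.  Fall back to the dominant principal direction
            # of the y-filtered residual (projected off w), the usual
            # residual-PCA variant of the orthogonal filter.
            resid = E - np.outer(t, p)
            if np.linalg.norm(resid) < 1e-12 * max(1.0, np.linalg.norm(E)):
                break                   # nothing orthogonal left to remove
            _, sv, Vt = np.linalg.svd(resid, full_matrices=False)
            w_o = Vt[0] - (w @ Vt[0]) * w
            n_o = np.linalg.norm(w_o)
            if sv[0] < 1e-12 or n_o < 1e-10:
                break
        w_o = w_o / n_o
        t_o = E @ w_o
        if t_o @ t_o < 1e-24:
            break
        # keep only genuinely y-uncorrelated components
        if t_o.std() > 0 and yc.std() > 0 \
                and abs(np.corrcoef(t_o, yc)[0, 1]) > 1e-8:
            break
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    t = E @ w
    p = E.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))

    k_o = len(W_o)
    ss_pred = float(t @ t) * float(p @ p)
    ss_ortho = sum(float(ti @ ti) * float(pi @ pi)
                   for ti, pi in zip(T_o, P_o))
    r2x = (ss_pred + ss_ortho) / ss_x_total if ss_x_total else 0.0

    model = DiscriminantModel(
        w_pred=w, p_pred=p, q_pred=q, t_pred=t,
        W_ortho=np.array(W_o).reshape(k_o, X.shape[1]),
        P_ortho=np.array(P_o).reshape(k_o, X.shape[1]),
        T_ortho=np.array(T_o).reshape(k_o, X.shape[0]),
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        r2x_total=r2x, n_orthogonal=k_o,
    )
    for t_o in model.T_ortho:
        if t_o.std() > 0 and yc.std() > 0:
            r = abs(np.corrcoef(t_o, yc)[0, 1])
            if r > 1e-8:
                raise AssertionError(
                    f"orthogonal score correlates with y (|r|={r:.2e})")
    model.vip_ = vip(model)
    return model


def opls_predict(model: DiscriminantModel, X_new: np.ndarray,
                 threshold: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Continuous predicted y and hard class calls (+1 / -1 around the
    threshold; ties go to +1)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_channels:
        raise ValueError("channel grid does not match the trained model")
    E = (X_new - model.x_mean) / model.x_scale
    for w_o, p_o in zip(model.W_ortho, model.P_ortho):
        t_o = E @ w_o
        E = E - np.outer(t_o, p_o)
    t = E @ model.w_pred
    y_hat = t * model.q_pred + model.y_mean
    calls = np.where(y_hat >= threshold, 1, -1)
    return y_hat, calls


def vip(model: DiscriminantModel) -> np.ndarray:
    """Variable importance in projection for the predictive component.

    With one predictive LV of unit weight ``w`` this reduces to
    ``VIP_j = sqrt(p) * |w_j|``, so mean(VIP^2) = 1 identically and
    channels with VIP > 1 are more important than average.
    """
    w = model.w_pred
    p = w.size
    return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

def metrics_from_confusion(TP: int, FP: int, TN: int, FN: int
                           ) -> tuple[float, float, float]:
    """Sensitivity, specificity and MCC from confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); when any
    marginal is zero the coefficient is 0 by convention.
    """
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    if TP + FN == 0 or TN + FP == 0:
        raise ValueError("sensitivity/specificity need both classes present")
    sens = TP / (TP + FN)
    spec = TN / (TN + FP)
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = 0.0 if denom == 0 else (TP * TN - FP * FN) / np.sqrt(denom)
    return float(sens), float(spec), float(mcc)


@dataclass
class CVResult:
    fold_predictions: list[np.ndarray]
    fold_indices: list[np.ndarray]
    y_true: np.ndarray
    y_score: np.ndarray              # pooled continuous predictions
    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float
    specificity: float
    mcc: float
    threshold: float


def _grouped_folds(y: np.ndarray, groups: Sequence[str], k_folds: int,
                   seed: int, max_retries: int = 20):
    """Group-stratified folds whose training parts keep both classes."""
    groups = np.asarray(groups)
    for attempt in range(max_retries):
        cv = StratifiedGroupKFold(n_splits=k_folds, shuffle=True,
                                  random_state=seed + attempt)
        plan = list(cv.split(np.zeros_like(y), (y > 0).astype(int), groups))
        if all(np.unique(y[tr]).size == 2 for tr, _ in plan):
            return plan
    raise ValueError("could not build folds with both classes in every "
                     f"training set after {max_retries} redraws")


def cross_validate(X: np.ndarray, y: np.ndarray, groups: Sequence[str],
                   n_orthogonal: int = 3, k_folds: int = 7,
                   threshold: float = 0.0, seed: int = 0,
                   scale: bool = False) -> CVResult:
    """Group-stratified k-fold cross-validation of OPLS-DA.

    Centering/scaling and the orthogonal filter are re-estimated inside
    each training fold (no leakage); per-fold test predictions are pooled
    into one confusion table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    plan = _grouped_folds(y, groups, k_folds, seed)
    y_score = np.empty(y.size)
    fold_preds, fold_idx = [], []
    for train, test in plan:
        model = opls_fit(X[train], y[train], n_orthogonal, scale)
        scores, _ = opls_predict(model, X[test], threshold)
        y_score[test] = scores
        fold_preds.append(scores)
        fold_idx.append(test)
    calls = np.where(y_score >= threshold, 1, -1)
    TP = int(np.sum((calls == 1) & (y == 1)))
    FN = int(np.sum((calls == -1) & (y == 1)))
    TN = int(np.sum((calls == -1) & (y == -1)))
    FP = int(np.sum((calls == 1) & (y == -1)))
    sens, spec, mcc = metrics_from_confusion(TP, FP, TN, FN)
    return CVResult(fold_preds, fold_idx, y, y_score, TP, FP, TN, FN,
                    sens, spec, mcc, threshold)


def permutation_test(X: np.ndarray, y: np.ndarray, groups: Sequence[str],
                     n_perm: int = 999,
                     statistic: Callable[..., float] | None = None,
                     seed: int = 0, n_orthogonal: int = 3,
                     k_folds: int = 7) -> tuple[float, np.ndarray, float]:
    """Group-level label permutation test of a CV statistic (default: the
    cross-validated MCC).

    Labels are permuted across groups (every spectrum of a cell keeps its
    cell-mates' label), the statistic is recomputed under each permutation,
    and the p-value uses add-one smoothing:
    p = (1 + #{null >= observed}) / (n_perm + 1).

    Returns ``(p_value, null_distribution, observed)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)

    def default_stat(Xs, ys, gs, sd):
        return cross_validate(Xs, ys, gs, n_orthogonal=n_orthogonal,
                              k_folds=k_folds, seed=sd).mcc

    stat = statistic or default_stat
    observed = stat(X, y, groups, seed)

    uniq, inverse = np.unique(groups, return_inverse=True)
    group_y = np.array([y[inverse == i][0] for i in range(uniq.size)])
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm_y = group_y[rng.permutation(uniq.size)][inverse]
        null[b] = stat(X, perm_y, groups, seed + b + 1)
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return float(p), null, float(observed)


# ---------------------------------------------------------------------------
# ROC and rank tests
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def roc(values: np.ndarray, labels: np.ndarray,
        direction: str = "greater") -> ROCResult:
    """ROC analysis over the sweep of unique values.

    ``direction='greater'`` means the positive class tends to larger
    values.  AUC is the trapezoid integral of TPR over FPR; the reported
    threshold maximises Youden's J = TPR - FPR, with ties broken toward
    higher specificity (lower FPR).  Constant values are degenerate:
    AUC = 0.5, threshold undefined and flagged.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("roc needs exactly two classes")
    pos = labels == classes[-1]          # larger / later label is positive
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    v = values if direction == "greater" else -values
    if np.ptp(v) == 0:
        return ROCResult(np.array([np.nan]), np.array([0.0, 1.0]),
                         np.array([0.0, 1.0]), 0.5, np.nan, np.nan, np.nan,
                         degenerate=True)
    fpr, tpr, thr = roc_curve(pos.astype(int), v)
    auc = float(np.trapezoid(tpr, fpr))
    J = tpr - fpr
    best = np.flatnonzero(J == J.max())
    best = best[np.argmin(fpr[best])]    # tie -> higher specificity
    # roc_curve's cuts mean "positive if v >= thr"; report a cut *between*
    # the adjacent unique values so a strict > comparison reproduces the
    # same confusion table and the threshold separates the classes.
    if not np.isfinite(thr[best]):       # the predict-none end of the sweep
        chosen = float(v.max())
    elif best + 1 < thr.size:
        chosen = float((thr[best] + thr[best + 1]) / 2.0)
    else:
        chosen = float(thr[best]) - max(1e-12, 1e-9 * abs(float(thr[best])))
    if direction == "less":
        chosen = -chosen
    return ROCResult(thr, tpr, fpr, auc, chosen,
                     float(tpr[best]), float(1.0 - fpr[best]))


def mann_whitney(sample_a: np.ndarray, sample_b: np.ndarray
                 ) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact by full enumeration of rank assignments when n1*n2 <= 400
    (handles ties), normal approximation with tie correction otherwise.
    Returns ``(U_a, p_value)`` where ``U_a`` counts pairs won by sample a.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if a.size * b.size <= 400:
        method = stats.PermutationMethod(n_resamples=np.inf,
                                         random_state=0)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
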