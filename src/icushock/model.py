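"""Seven-day mortality model: elastic net, CV with the 1-SE rule, VIF
pruning, and cross-validated AUC evaluation.

The outcome is modelled with penalized *linear* regression on the 0/1
label.  The elastic-net path minimizes

    (1/2n) * ||y - b0 - X beta||^2
        + lambda * (alpha_mix * ||beta||_1 + (1 - alpha_mix)/2 * ||beta||_2^2)

by cyclic coordinate descent with soft-thresholding on internally
standardized features, warm-started along a decreasing lambda grid.
Classification uses a 0.5 threshold on the linear prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .features import CohortMatrix

DEFAULT_ALPHA_MIX = 0.5
DEFAULT_N_LAMBDAS = 100
DEFAULT_LAMBDA_RATIO = 1e-4
CD_TOL = 1e-7
CD_MAX_SWEEPS = 100_000
VIF_THRESHOLD = 5.0


def _as_xy(matrix) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(matrix, CohortMatrix):
        return matrix.X, matrix.y
    X, y = matrix
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale to mean 0, unit (population) variance.

    Constant columns are mapped to all-zero columns so the penalty can
    never select them.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / safe
    Xs[:, sd == 0] = 0.0
    return Xs, mu, sd


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def _cd_path_kernel(G, c, diag, lambdas, alpha_mix, tol, max_sweeps):
    """Cyclic coordinate descent over the whole lambda grid (warm starts)."""
    p = len(c)
    n_lam = len(lambdas)
    coefs = np.zeros((n_lam, p))
    beta = np.zeros(p)
    for li in range(n_lam):
        lam = lambdas[li]
        gamma = lam * alpha_mix
        l2 = lam * (1.0 - alpha_mix)
        for _sweep in range(max_sweeps):
            max_delta = 0.0
            for j in range(p):
                if diag[j] == 0.0:
                    continue
                rho = c[j] - np.dot(G[j], beta) + diag[j] * beta[j]
                if rho > gamma:
                    new = (rho - gamma) / (diag[j] + l2)
                elif rho < -gamma:
                    new = (rho + gamma) / (diag[j] + l2)
                else:
                    new = 0.0
                delta = abs(new - beta[j])
                if delta > max_delta:
                    max_delta = delta
                beta[j] = new
            if max_delta < tol:
                break
        coefs[li] = beta
    return coefs


try:  # JIT when available; the pure-Python path is identical but slower
    from numba import njit

    _cd_path_kernel = njit(cache=True)(_cd_path_kernel)
except ImportError:  # pragma: no cover
    pass


@dataclass(frozen=True)
class ElasticNetPath:
    """Coefficient path over a decreasing lambda grid."""

    alpha_mix: float
    lambdas: np.ndarray
    coefficients: np.ndarray        # (n_lambda, p), standardized scale
    intercepts: np.ndarray          # (n_lambda,), standardized scale
    feature_mean: np.ndarray
    feature_std: np.ndarray

    def coef_at(self, lam: float) -> np.ndarray:
        """Standardized coefficients at the grid lambda closest to ``lam``."""
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefficients[i]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Linear predictions for all grid lambdas, shape (n, n_lambda)."""
        safe = np.where(self.feature_std > 0, self.feature_std, 1.0)
        Xs = (np.asarray(X, dtype=float) - self.feature_mean) / safe
        Xs[:, self.feature_std == 0] = 0.0
        return Xs @ self.coefficients.T + self.intercepts


def lambda_max(X: np.ndarray, y: np.ndarray, alpha_mix: float) -> float:
    """Smallest lambda at which every coefficient is zero."""
    if not 0 < alpha_mix <= 1:
        raise ValueError("alpha_mix must be in (0, 1]")
    Xs, _, _ = _standardize(X)
    yc = y - y.mean()
    n = len(y)
    return float(np.max(np.abs(Xs.T @ yc)) / (n * alpha_mix))


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, alpha_mix: float,
    n_lambdas: int = DEFAULT_N_LAMBDAS,
    ratio: float | None = None,
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to ratio*lambda_max.

    When ``ratio`` is None it defaults to 1e-2 for n < p (where the
    unpenalized end of the path is ill-posed) and 1e-4 otherwise.
    """
    if ratio is None:
        ratio = 1e-2 if X.shape[0] < X.shape[1] else DEFAULT_LAMBDA_RATIO
    lmax = lambda_max(X, y, alpha_mix)
    if lmax == 0:  # response orthogonal to every feature
        lmax = 1.0
    return np.logspace(np.log10(lmax), np.log10(lmax * ratio), n_lambdas)


def fit_elastic_net_path(
    matrix, alpha_mix: float, lambdas: np.ndarray | None = None,
    tol: float = CD_TOL,
) -> ElasticNetPath:
    """Fit the elastic-net coefficient path by cyclic coordinate descent.

    Features are standardized internally; the grid head is lambda_max, at
    which all coefficients are exactly zero.  Convergence is declared when
    the largest coefficient update in a full sweep falls below ``tol``.
    """
    X, y = _as_xy(matrix)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in the design or response")
    if not 0 < alpha_mix <= 1:
        raise ValueError("alpha_mix must be in (0, 1]")
    if lambdas is None:
        lambdas = default_lambda_grid(X, y, alpha_mix)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be decreasing")

    n, p = X.shape
    Xs, mu, sd = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    G = Xs.T @ Xs / n                  # Gram matrix, p x p
    c = Xs.T @ yc / n
    diag = np.diag(G).copy()

    coefs = _cd_path_kernel(G, c, diag, lambdas, float(alpha_mix),
                            float(tol), CD_MAX_SWEEPS)
    intercepts = np.full(len(lambdas), ybar)
    return ElasticNetPath(alpha_mix, lambdas, coefs, intercepts, mu, sd)


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (test-index arrays)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls} has {len(idx)} members, fewer than "
                f"{n_folds} folds"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return [np.flatnonzero(assignment == k) for k in range(n_folds)]


@dataclass(frozen=True)
class CvCurve:
    """Cross-validated misclassification error along the lambda grid."""

    n_folds: int
    lambdas: np.ndarray
    cv_error: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float

    @property
    def error_at_1se(self) -> float:
        i = int(np.argmin(np.abs(self.lambdas - self.lambda_1se)))
        return float(self.cv_error[i])


def cross_validate(
    matrix, alpha_mix: float, folds: int, seed: int,
    lambdas: np.ndarray | None = None,
) -> CvCurve:
    """Stratified k-fold CV of the path; threshold 0.5 on predictions.

    lambda_min minimizes the mean misclassification error (largest lambda
    on ties); lambda_1se is the largest lambda whose error is within one
    standard error of the minimum.
    """
    X, y = _as_xy(matrix)
    if lambdas is None:
        lambdas = default_lambda_grid(X, y, alpha_mix)
    fold_idx = stratified_folds(y, folds, seed)
    errors = np.empty((folds, len(lambdas)))
    for k, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(len(y)), test)
        path = fit_elastic_net_path((X[train], y[train]), alpha_mix, lambdas)
        pred = path.predict(X[test]) >= 0.5
        errors[k] = (pred != (y[test][:, None] == 1.0)).mean(axis=0)
    cv_error = errors.mean(axis=0)
    cv_se = errors.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(cv_error))           # first index = largest lambda
    threshold = cv_error[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_error <= threshold)[0])
    return CvCurve(folds, np.asarray(lambdas, dtype=float), cv_error, cv_se,
                   float(lambdas[i_min]), float(lambdas[i_1se]))


def compute_vifs(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column of ``X``.

    VIF_j = 1/(1 - R^2_j) with feature j regressed (with intercept) on the
    remaining features; exact collinearity yields +inf.
    """
    n, p = X.shape
    if p == 1:
        return np.ones(1)
    vifs = np.empty(p)
    for j in range(p):
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ coef
        ss_tot = np.sum((target - target.mean()) ** 2)
        if ss_tot == 0:
            vifs[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(
    matrix, features: list[str],
    threshold: float = VIF_THRESHOLD,
) -> tuple[list[str], list[str], dict[str, float]]:
    """Iteratively drop the feature with the largest VIF above ``threshold``.

    Ties are broken by removing the later feature in canonical order.
    While n <= p every feature is exactly collinear with the rest, so all
    VIFs are +inf and the tie-break rule prunes from the tail until VIF
    becomes defined.  Returns (kept features, removal order, final VIF per
    kept feature).
    """
    if isinstance(matrix, CohortMatrix):
        name_to_col = {f: i for i, f in enumerate(matrix.feature_names)}
        X_full = matrix.X
    else:
        X_full = np.asarray(matrix, dtype=float)
        name_to_col = {f: i for i, f in enumerate(features)}
    if not features:
        raise ValueError("need at least one feature")
    kept = list(features)
    removed: list[str] = []
    while True:
        X = X_full[:, [name_to_col[f] for f in kept]]
        if X.shape[0] <= X.shape[1]:
            vifs = np.full(X.shape[1], np.inf)
        else:
            vifs = compute_vifs(X)
        vmax = np.max(vifs)
        if vmax <= threshold:
            return kept, removed, {f: float(v) for f, v in zip(kept, vifs)}
        worst = int(np.flatnonzero(vifs == vmax)[-1])  # later on ties
        removed.append(kept.pop(worst))


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (trapezoidal) area under the ROC curve."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class ModelReport:
    """Selected features, coefficients, VIFs and evaluation summary."""

    alpha_mix: float
    chosen_folds: int
    lambda_1se: float
    selected_features: list[str]
    coefficients: dict[str, float]              # original scale, + intercept
    standardized_coefficients: dict[str, float]
    vif: dict[str, float]
    removed_by_vif: list[str]
    mse: float | None
    auc_mean: float | None
    auc_sd: float | None
    cv_curves: dict[int, CvCurve] = field(default_factory=dict)


def finalize_model(
    matrix, kept_features: list[str], seed: int, eval_folds: int = 5,
) -> tuple[dict[str, float], float, float, float]:
    """Unpenalized least-squares refit and stratified CV AUC.

    Returns (coefficients incl. intercept, in-sample MSE, AUC mean, AUC sd)
    with per-fold out-of-fold AUCs summarized as mean +/- sd.
    """
    if not kept_features:
        raise ValueError("kept_features must be non-empty")
    if isinstance(matrix, CohortMatrix):
        name_to_col = {f: i for i, f in enumerate(matrix.feature_names)}
        X = matrix.X[:, [name_to_col[f] for f in kept_features]]
        y = matrix.y
    else:
        X, y = _as_xy(matrix)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"cannot refit: n={n} <= p={p}")

    design = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    mse = float(np.mean((y - design @ coef) ** 2))
    coefficients = {"intercept": float(coef[0])}
    coefficients.update(
        {f: float(b) for f, b in zip(kept_features, coef[1:])})

    aucs = []
    for test in stratified_folds(y, eval_folds, seed):
        train = np.setdiff1d(np.arange(n), test)
        d_train = np.column_stack([np.ones(len(train)), X[train]])
        b, *_ = np.linalg.lstsq(d_train, y[train], rcond=None)
        scores = np.column_stack([np.ones(len(test)), X[test]]) @ b
        aucs.append(auc_score(y[test], scores))
    aucs = np.asarray(aucs)
    return coefficients, mse, float(aucs.mean()), float(aucs.std(ddof=1))


def fit_mortality_model(
    matrix: CohortMatrix,
    alpha_mix: float = DEFAULT_ALPHA_MIX,
    fold_counts: tuple[int, ...] = (3, 4, 5),
    seed: int = 0,
    eval_folds: int = 5,
    vif_threshold: float = VIF_THRESHOLD,
) -> ModelReport:
    """The full modelling pipeline on an imputed cohort matrix.

    Runs CV at each fold count, keeps the fold count whose 1-SE model has
    the lowest CV error (ties to more folds), selects the features active
    at that lambda, prunes by VIF, refits by least squares and evaluates
    by stratified CV AUC.
    """
    X, y = matrix.X, matrix.y
    lambdas = default_lambda_grid(X, y, alpha_mix)
    curves = {k: cross_validate(matrix, alpha_mix, k, seed, lambdas)
              for k in fold_counts}
    chosen = min(fold_counts,
                 key=lambda k: (curves[k].error_at_1se, -k))
    lam = curves[chosen].lambda_1se
    path = fit_elastic_net_path(matrix, alpha_mix, lambdas)
    beta = path.coef_at(lam)
    selected = [matrix.feature_names[j] for j in np.flatnonzero(beta)]

    report = ModelReport(
        alpha_mix=alpha_mix, chosen_folds=chosen, lambda_1se=float(lam),
        selected_features=selected, coefficients={},
        standardized_coefficients={}, vif={}, removed_by_vif=[],
        mse=None, auc_mean=None, auc_sd=None, cv_curves=curves,
    )
    if not selected:
        return report

    kept, removed, vifs = vif_prune(matrix, selected,
                                    threshold=vif_threshold)
    report.selected_features = kept
    report.removed_by_vif = removed
    report.vif = vifs
    coefficients, mse, auc_mean, auc_sd = finalize_model(
        matrix, kept, seed=seed, eval_folds=eval_folds)
    report.coefficients = coefficients
    report.mse = mse
    report.auc_mean = auc_mean
    report.auc_sd = auc_sd
    # standardized coefficients of the same refit, for reporting
    name_to_col = {f: i for i, f in enumerate(matrix.feature_names)}
    cols = [name_to_col[f] for f in kept]
    sd = matrix.X[:, cols].std(axis=0)
    report.standardized_coefficients = {
        f: float(coefficients[f] * s) for f, s in zip(kept, sd)}
    return report
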