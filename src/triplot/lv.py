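"""First layer: latent-variable modeling (PCA, NIPALS-PLS) and diagnostics.

Any external scores/loadings pair is equally accepted by
:func:`triplot.core.make_tpo`; the fitters here are conveniences with a
reproducible sign convention (the loading of largest absolute value in
each component is made positive, so plot orientation is deterministic).
Default preprocessing for both fitters is column centering and
unit-variance scaling, the common convention for metabolomics features
measured on heterogeneous scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .core import LVModel

__all__ = ["FeatureTable", "preprocess", "pca_fit", "pls_fit", "scree",
           "pls_cv"]

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


@dataclass
class FeatureTable:
    """Observations x variables numeric table with preprocessing flags."""

    values: pd.DataFrame
    centered: bool = False
    scaled: bool = False

    def __post_init__(self):
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 observations")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 variables")

    @property
    def var_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def obs_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]


def _to_table(x) -> FeatureTable:
    return x if isinstance(x, FeatureTable) else FeatureTable(pd.DataFrame(x))


def preprocess(x, center: bool = True, scale: bool = True) -> FeatureTable:
    """Center and/or unit-variance scale columns (sd with n-1 denominator).

    Missing or non-finite values are rejected — imputation is a separate
    concern and is not performed here.
    """
    x = _to_table(x)
    df = x.values.astype(float)
    if not np.all(np.isfinite(df.to_numpy())):
        bad = df.columns[~np.isfinite(df.to_numpy()).all(axis=0)]
        raise ValueError(
            f"non-finite values in columns: {list(map(str, bad[:5]))}")
    if scale:
        sd = df.std(ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(f"zero variance: {zero.index[0]}")
    if center:
        df = df - df.mean()
    if scale:
        df = df / df.std(ddof=1)
    return FeatureTable(df, centered=center or x.centered,
                        scaled=scale or x.scaled)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray, *extra):
    """Flip each component so its largest-|loading| entry is positive."""
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
            for arr in extra:
                arr[:, k] *= -1
    return scores, loadings


def pca_fit(x, n_comp: int) -> LVModel:
    """Principal component analysis on a preprocessed feature table.

    Loadings columns are orthonormal, scores = x . loadings, and
    ``explained_variance[k]`` is var(score_k) as a fraction of the total
    variance of x.  Components come ordered by decreasing explained
    variance with the deterministic sign convention applied.
    """
    x = _to_table(x)
    xv = x.values.to_numpy(dtype=float)
    n_obs, n_var = xv.shape
    if not (1 <= n_comp <= min(n_obs - 1, n_var)):
        raise ValueError(
            f"n_comp={n_comp} outside [1, {min(n_obs - 1, n_var)}]")
    xc = xv - xv.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if n_comp > rank:
        raise ValueError(f"n_comp={n_comp} exceeds matrix rank {rank}")
    pca = _SkPCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(xc)
    loadings = pca.components_.T.copy()
    scores, loadings = _fix_signs(scores, loadings)
    total_var = xc.var(axis=0, ddof=1).sum()
    ev = scores.var(axis=0, ddof=1) / total_var
    return LVModel(scores=scores, loadings=loadings, explained_variance=ev,
                   comp_names=[f"PC{k + 1}" for k in range(n_comp)],
                   var_names=x.var_names, obs_ids=x.obs_ids,
                   method_tag="pca")


def _nipals_component(X, Y, tol=NIPALS_TOL, max_iter=NIPALS_MAX_ITER):
    """One NIPALS PLS component; returns (w, t, p, c) or raises."""
    u = Y[:, 0].copy()
    if np.allclose(u, 0):
        u = Y[:, np.argmax(np.abs(Y).sum(axis=0))].copy()
    t_old = None
    for _ in range(max_iter):
        w = X.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ArithmeticError("zero weight vector (X deflated to zero)")
        w /= nw
        t = X @ w
        c = Y.T @ t / (t @ t)
        if Y.shape[1] == 1:
            # univariate y: the loop is exact after one pass
            p = X.T @ t / (t @ t)
            return w, t, p, c
        u = Y @ c / (c @ c)
        if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
            p = X.T @ t / (t @ t)
            return w, t, p, c
        t_old = t
    raise ArithmeticError("NIPALS inner loop did not converge")


def pls_fit(x, y, n_comp: int) -> LVModel:
    """Partial least squares by NIPALS with deflation.

    Returns x-scores, x-loadings and the per-component explained
    variance *of x*; the weight matrix ``W`` and y-loadings ``C`` (plus
    the y-variance fractions) are kept in ``meta`` for prediction.
    """
    x = _to_table(x)
    X = x.values.to_numpy(dtype=float).copy()
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"y rows ({Y.shape[0]}) do not match x rows ({X.shape[0]})")
    Y = Y - Y.mean(axis=0)
    if Y.shape[1] > 1:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = Y / sd
    n_obs, n_var = X.shape
    if not (1 <= n_comp <= min(n_obs - 1, n_var)):
        raise ValueError(
            f"n_comp={n_comp} outside [1, {min(n_obs - 1, n_var)}]")
    ss_x = (X ** 2).sum()
    ss_y = (Y ** 2).sum()
    W = np.zeros((n_var, n_comp))
    P = np.zeros((n_var, n_comp))
    C = np.zeros((Y.shape[1], n_comp))
    T = np.zeros((n_obs, n_comp))
    ev_x = np.zeros(n_comp)
    ev_y = np.zeros(n_comp)
    for k in range(n_comp):
        try:
            w, t, p, c = _nipals_component(X, Y)
        except ArithmeticError as err:
            raise ArithmeticError(f"component {k + 1}: {err}") from None
        W[:, k], T[:, k], P[:, k], C[:, k] = w, t, p, c
        ev_x[k] = (t @ t) * (p @ p) / ss_x if ss_x > 0 else 0.0
        ev_y[k] = (t @ t) * (c @ c) / ss_y if ss_y > 0 else 0.0
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, c)
    T, P = _fix_signs(T, P, W, C)
    return LVModel(scores=T, loadings=P, explained_variance=ev_x,
                   comp_names=[f"Comp{k + 1}" for k in range(n_comp)],
                   var_names=x.var_names, obs_ids=x.obs_ids,
                   method_tag="pls",
                   meta={"weights": W, "y_loadings": C,
                         "explained_variance_y": ev_y})


def pls_predict(model: LVModel, x_new) -> np.ndarray:
    """Predict centered y from a NIPALS PLS model (B = W (PᵀW)⁻¹ Cᵀ)."""
    W = model.meta["weights"]
    P = model.loadings
    C = model.meta["y_loadings"]
    B = W @ np.linalg.solve(P.T @ W, C.T)
    Xn = np.asarray(x_new, dtype=float)
    return Xn @ B


def scree(model: LVModel) -> pd.DataFrame:
    """Table of per-component and cumulative explained variance."""
    ev = model.explained_variance
    return pd.DataFrame({
        "component": model.comp_names,
        "explained_variance": ev,
        "cumulative": np.cumsum(ev),
    })


def pls_cv(x, y, max_comp: int, k_folds: int = 5, repeats: int = 1,
           seed: int = 0) -> pd.DataFrame:
    """Repeated k-fold cross-validation of the PLS component count.

    Returns a table (n_comp, mean CV RMSE, sd) with the attribute
    ``recommended`` set to the smallest component count whose mean error
    is within one sd of the global minimum (one-SE rule).  Folds are
    stratified on y when y is binary.  Deterministic given ``seed``.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    x = _to_table(x)
    X = x.values.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    min_fold = len(yv) - int(np.ceil(len(yv) / k_folds))
    if max_comp > min(min_fold - 1, X.shape[1]):
        raise ValueError(
            f"max_comp={max_comp} too large for fold size {min_fold}")
    binary = set(np.unique(yv)) <= {0.0, 1.0}
    rng = np.random.default_rng(seed)
    errors = {k: [] for k in range(1, max_comp + 1)}
    for _ in range(repeats):
        fold_seed = int(rng.integers(2 ** 31 - 1))
        if binary:
            splitter = StratifiedKFold(n_splits=k_folds, shuffle=True,
                                       random_state=fold_seed)
            splits = splitter.split(X, yv)
        else:
            splitter = KFold(n_splits=k_folds, shuffle=True,
                             random_state=fold_seed)
            splits = splitter.split(X)
        for train, test in splits:
            mu, sdv = X[train].mean(axis=0), X[train].std(axis=0, ddof=1)
            sdv[sdv == 0] = 1.0
            Xtr = (X[train] - mu) / sdv
            Xte = (X[test] - mu) / sdv
            ym = yv[train].mean()
            for k in range(1, max_comp + 1):
                model = pls_fit(FeatureTable(pd.DataFrame(Xtr)),
                                yv[train] - ym, k)
                pred = pls_predict(model, Xte) + ym
                rmse = float(np.sqrt(np.mean((yv[test] - pred.ravel()) ** 2)))
                errors[k].append(rmse)
    table = pd.DataFrame({
        "n_comp": list(errors),
        "mean_cv_error": [float(np.mean(v)) for v in errors.values()],
        "sd_cv_error": [float(np.std(v, ddof=1)) for v in errors.values()],
    })
    i_min = int(table["mean_cv_error"].idxmin())
    threshold = table.loc[i_min, "mean_cv_error"] + table.loc[i_min, "sd_cv_error"]
    rec = int(table.loc[table["mean_cv_error"] <= threshold, "n_comp"].min())
    table.attrs["recommended"] = rec
    return table
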