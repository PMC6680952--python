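"""Second layer: correlations between LV scores and exposures.

Plain Pearson/Spearman/Kendall correlations via :func:`make_corr`, and
covariate-adjusted partial correlations via :func:`partial_corr`.
Missing data are handled by pairwise-complete deletion per cell, with
the per-cell sample size recorded in ``n_used``.

Partial Spearman is defined as rank-then-residualize: both the score
and the exposure are rank-transformed (average ranks for ties) before
residualizing on the covariates and correlating the residuals.  This is
one of several definitions in the literature; it is recorded in the
block metadata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import CorrBlock

__all__ = ["make_corr", "partial_corr", "significance_mask",
           "MATCHED_CORR_ADJUSTMENT", "MATCHED_RISK_ADJUSTMENT",
           "CROSS_SECTIONAL_ADJUSTMENT"]

# Named adjustment-set presets for the two worked examples: the matched
# T2D case-control analysis adjusts correlations for case status and
# matching/lifestyle variables (energy intake enters only the risk-model
# adjustment), while the cross-sectional BMI analysis adjusts for age
# and gender only.
MATCHED_CORR_ADJUSTMENT = ["outcome", "gender", "age", "bmi", "smoking",
                           "education", "physical_activity"]
MATCHED_RISK_ADJUSTMENT = ["bmi", "smoking", "education",
                           "physical_activity", "energy_intake"]
CROSS_SECTIONAL_ADJUSTMENT = ["age", "gender"]


def _as_frame(x, prefix: str) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x.astype(float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return pd.DataFrame(x, columns=[f"{prefix}{i+1}" for i in range(x.shape[1])])


def _corr_cell(s: np.ndarray, e: np.ndarray, method: str):
    """Correlation and p-value for one complete-case pair of vectors."""
    if np.std(s) == 0 or np.std(e) == 0:
        warnings.warn("constant column on complete cases; r undefined",
                      RuntimeWarning, stacklevel=3)
        return np.nan, np.nan
    if method == "pearson":
        res = stats.pearsonr(s, e)
        return float(res.statistic), float(res.pvalue)
    if method == "spearman":
        rho, p = stats.spearmanr(s, e)
        return float(rho), float(p)
    if method == "kendall":
        res = stats.kendalltau(s, e, method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown correlation method {method!r}")


def make_corr(scores, exposures, method: str = "pearson") -> CorrBlock:
    """Correlate each LV score with each exposure column.

    Parameters
    ----------
    scores : (n_obs, n_comp) matrix or DataFrame of LV observation scores.
    exposures : (n_obs, n_exposure) table; row-aligned with ``scores``.
    method : ``"pearson"`` (linear), ``"spearman"`` (rank) or
        ``"kendall"``.

    Notes
    -----
    p-values use each method's standard test (Pearson/Spearman: t
    approximation with ``n_used - 2`` df; Kendall: normal
    approximation).  A constant exposure on the complete cases yields a
    NaN cell plus a warning, not a hard error.
    """
    S = _as_frame(scores, "LV")
    E = _as_frame(exposures, "E")
    if len(S) != len(E):
        raise ValueError(f"row mismatch: scores {len(S)} vs exposures {len(E)}")
    n_comp, n_exp = S.shape[1], E.shape[1]
    r = np.full((n_comp, n_exp), np.nan)
    p = np.full((n_comp, n_exp), np.nan)
    n = np.zeros((n_comp, n_exp), dtype=int)
    Sv, Ev = S.to_numpy(), E.to_numpy()
    for i in range(n_comp):
        for j in range(n_exp):
            mask = np.isfinite(Sv[:, i]) & np.isfinite(Ev[:, j])
            n[i, j] = int(mask.sum())
            if n[i, j] < 3:
                warnings.warn(
                    f"fewer than 3 complete cases for cell ({i},{j})",
                    RuntimeWarning, stacklevel=2)
                continue
            r[i, j], p[i, j] = _corr_cell(Sv[mask, i], Ev[mask, j], method)
    return CorrBlock(r=r, p=p, n_used=n, method=method,
                     exposure_names=[str(c) for c in E.columns])


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_corr(scores, exposures, covariates, method: str = "pearson"
                 ) -> CorrBlock:
    """Covariate-adjusted correlation of LV scores with exposures.

    Pearson: residualize both the score and the exposure on the
    covariates (plus intercept) by least squares and correlate the
    residuals.  Spearman: rank-transform the score and the exposure
    first, then residualize and correlate.  p-values use a t
    approximation with ``n_used - 2 - n_covariates`` df.

    An empty covariate table reduces exactly to :func:`make_corr`.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("partial correlation supports pearson and spearman")
    C = _as_frame(covariates, "C") if covariates is not None else pd.DataFrame()
    if C.shape[1] == 0:
        return make_corr(scores, exposures, method)
    S = _as_frame(scores, "LV")
    E = _as_frame(exposures, "E")
    if not (len(S) == len(E) == len(C)):
        raise ValueError("scores, exposures and covariates must be row-aligned")
    n_cov = C.shape[1]
    Cv = C.to_numpy()
    # full-rank check on the complete-case design (covariates + intercept)
    cc = np.isfinite(Cv).all(axis=1)
    Z_full = np.column_stack([np.ones(cc.sum()), Cv[cc]])
    if np.linalg.matrix_rank(Z_full) < Z_full.shape[1]:
        # identify collinear columns by incremental rank
        bad = []
        cols = [np.ones(cc.sum())]
        for name, col in zip(C.columns, Cv[cc].T):
            trial = np.column_stack(cols + [col])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                bad.append(str(name))
            else:
                cols.append(col)
        raise ValueError(f"rank-deficient covariate matrix; collinear "
                         f"columns: {bad}")
    n_comp, n_exp = S.shape[1], E.shape[1]
    r = np.full((n_comp, n_exp), np.nan)
    p = np.full((n_comp, n_exp), np.nan)
    n = np.zeros((n_comp, n_exp), dtype=int)
    Sv, Ev = S.to_numpy(), E.to_numpy()
    for i in range(n_comp):
        for j in range(n_exp):
            mask = (np.isfinite(Sv[:, i]) & np.isfinite(Ev[:, j])
                    & np.isfinite(Cv).all(axis=1))
            m = int(mask.sum())
            n[i, j] = m
            df = m - 2 - n_cov
            if df <= 0:
                raise ValueError(
                    f"non-positive degrees of freedom ({df}) in cell ({i},{j})")
            s, e = Sv[mask, i], Ev[mask, j]
            if method == "spearman":
                s = stats.rankdata(s)  # average ranks for ties
                e = stats.rankdata(e)
            Z = np.column_stack([np.ones(m), Cv[mask]])
            rs = _residualize(s, Z)
            re = _residualize(e, Z)
            if np.std(rs) < 1e-12 * max(1.0, np.std(s)) or \
               np.std(re) < 1e-12 * max(1.0, np.std(e)):
                warnings.warn(
                    f"zero-variance residual in cell ({i},{j}); partial r "
                    "undefined", RuntimeWarning, stacklevel=2)
                continue
            rij = float(np.corrcoef(rs, re)[0, 1])
            rij = max(-1.0, min(1.0, rij))
            t = rij * np.sqrt(df / max(1e-300, 1 - rij ** 2))
            p[i, j] = float(2 * stats.t.sf(abs(t), df))
            r[i, j] = rij
    return CorrBlock(r=r, p=p, n_used=n, method=method,
                     exposure_names=[str(c) for c in E.columns],
                     partial=True,
                     adjustment_vars=[str(c) for c in C.columns])


def significance_mask(block: CorrBlock, alpha: float = 0.05,
                      adjust: str = "none") -> np.ndarray:
    """Boolean matrix: True where p (optionally BH-adjusted) < alpha.

    ``adjust="benjamini_hochberg"`` applies the step-up FDR correction
    across every finite cell of the whole block.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    p = block.p
    if adjust == "none":
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(p), p < alpha, False)
    if adjust == "benjamini_hochberg":
        from statsmodels.stats.multitest import multipletests
        mask = np.zeros(p.shape, dtype=bool)
        finite = np.isfinite(p)
        if finite.any():
            rej, *_ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
            mask[finite] = rej
        return mask
    raise ValueError(f"unknown adjustment {adjust!r}")
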