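"""Third layer: associations between LV scores and outcomes.

Three regression families are provided, each crude or
covariate-adjusted:

- unconditional logistic regression (odds ratios) for unmatched binary
  outcomes (:func:`crude_lr`);
- conditional logistic regression (odds ratios) for matched
  case-control sets (:func:`crude_clr`), where the matching variables
  are absorbed by conditioning;
- ordinary least squares (betas) for continuous intermediate risk
  markers (:func:`linear_beta`).

By default the score predictor is standardized, so estimates read as
the odds ratio (or beta) per 1-SD increase in the LV score — the usual
epidemiological convention for unitless component scores.  Confidence
intervals are Wald intervals with z = 1.96 (configurable).

Externally fitted models (e.g. Cox hazard ratios from a survival
package) are ingested as plain (estimate, CI, p) rows via
:func:`risk_block_from_fits` with ``scale="ratio"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import RiskBlock

__all__ = ["OutcomeSpec", "FitRow", "crude_lr", "crude_clr", "adjusted_fit",
           "linear_beta", "risk_block_from_fits"]

MAX_SET_SIZE = 10
SEPARATION_BETA = 15.0


@dataclass
class OutcomeSpec:
    """Outcome description: binary, matched binary, or continuous.

    ``scaling="per_sd"`` divides the score by its sample SD before
    fitting; ``"raw"`` uses it as-is.
    """

    kind: str  # binary | matched_binary | continuous
    y: np.ndarray
    set_id: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    scaling: str = "per_sd"

    def __post_init__(self):
        if self.kind not in ("binary", "matched_binary", "continuous"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        self.y = np.asarray(self.y, dtype=float)
        if self.kind in ("binary", "matched_binary"):
            if not set(np.unique(self.y)) <= {0.0, 1.0}:
                raise ValueError("binary outcome must be coded 0/1")
        if self.kind == "matched_binary":
            if self.set_id is None:
                raise ValueError("matched_binary requires set_id")
            self.set_id = np.asarray(self.set_id)
            sids, counts = np.unique(self.set_id, return_counts=True)
            if counts.max() > MAX_SET_SIZE:
                sid = sids[int(np.argmax(counts))]
                raise ValueError(
                    f"matched set {sid!r} has {counts.max()} members; "
                    f"sets larger than {MAX_SET_SIZE} are not supported")
        if self.scaling not in ("per_sd", "raw"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass(frozen=True)
class FitRow:
    """One fitted risk association for a single LV component."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    scale: str  # ratio | linear
    model_tag: str = ""
    n_used: int = 0
    beta: float = float("nan")  # coefficient on the model's linear scale
    se: float = float("nan")
    extra: dict = field(default_factory=dict)


def _prep_score(score, scaling: str) -> tuple[np.ndarray, float]:
    s = np.asarray(score, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite values in score")
    sd = float(np.std(s, ddof=1))
    if scaling == "per_sd":
        if sd == 0:
            raise ValueError("score has zero variance; cannot scale per SD")
        return s / sd, sd
    return s, sd


def _cov_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    C = covariates if isinstance(covariates, pd.DataFrame) \
        else pd.DataFrame(np.asarray(covariates, dtype=float))
    if len(C) != n:
        raise ValueError(f"covariate rows ({len(C)}) do not match n ({n})")
    return C.to_numpy(dtype=float), [str(c) for c in C.columns]


def _check_rank(X: np.ndarray, names: list[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = []
        keep = [X[:, 0]]
        for j in range(1, X.shape[1]):
            trial = np.column_stack(keep + [X[:, j]])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                bad.append(names[j] if j < len(names) else f"col{j}")
            else:
                keep.append(X[:, j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _wald(beta: float, se: float, scale: str, z: float = 1.96):
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    lo, hi = beta - z * se, beta + z * se
    if scale == "ratio":
        return float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)), p
    return float(beta), float(lo), float(hi), p


def crude_lr(score, spec: OutcomeSpec, covariates=None, *, z: float = 1.96,
             model_tag: str | None = None) -> FitRow:
    """Odds ratio for an LV score from unconditional logistic regression.

    Maximum-likelihood fit (IRLS); OR = exp(beta) with a Wald CI.
    """
    if spec.kind not in ("binary", "matched_binary"):
        raise ValueError("crude_lr requires a binary outcome")
    y = spec.y
    if len(np.unique(y)) < 2:
        raise ValueError("single outcome class")
    s, sd = _prep_score(score, spec.scaling)
    if len(s) != len(y):
        raise ValueError("score and outcome lengths differ")
    C, cov_names = _cov_matrix(covariates, len(y))
    X = np.column_stack([np.ones(len(y)), s, C])
    _check_rank(X, ["const", "score"] + cov_names)
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
    except Exception as err:  # PerfectSeparationError and kin
        raise ValueError(
            "complete separation detected; consider a penalized fit "
            "(not implemented)") from err
    beta, se = float(res.params[1]), float(res.bse[1])
    if abs(beta) > SEPARATION_BETA:
        raise ValueError(
            "complete separation detected (|beta| > 15); consider a "
            "penalized fit (not implemented)")
    est, lo, hi, p = _wald(beta, se, "ratio", z)
    tag = model_tag if model_tag is not None else \
        ("LR adjusted" if cov_names else "LR crude")
    return FitRow(est, lo, hi, p, "ratio", tag, len(y), beta, se,
                  {"score_sd": sd, "scaling": spec.scaling})


def _informative_sets(y, set_id, s, C):
    """Keep outcome-discordant sets; return filtered arrays + drop count."""
    _, inv, counts = np.unique(set_id, return_inverse=True,
                               return_counts=True)
    n_cases = np.bincount(inv, weights=y)
    informative = (n_cases > 0) & (n_cases < counts)
    keep = informative[inv]
    dropped = int((~informative).sum())
    return y[keep], set_id[keep], s[keep], C[keep], dropped


def crude_clr(score, spec: OutcomeSpec, covariates=None, *, z: float = 1.96,
              model_tag: str | None = None) -> FitRow:
    """Odds ratio from conditional logistic regression for matched sets.

    Maximizes the conditional likelihood of the observed case pattern
    within each matched set; sets with no outcome variation drop out
    (their count is reported in ``extra["n_sets_dropped"]``).
    """
    if spec.kind != "matched_binary":
        raise ValueError("crude_clr requires a matched binary outcome")
    y = spec.y
    s, sd = _prep_score(score, spec.scaling)
    if len(s) != len(y):
        raise ValueError("score and outcome lengths differ")
    C, cov_names = _cov_matrix(covariates, len(y))
    y2, g2, s2, C2, dropped = _informative_sets(y, spec.set_id, s, C)
    if len(y2) == 0:
        raise ValueError("no informative (outcome-discordant) matched sets")
    # identifiability: the score must vary within at least one
    # informative set, and covariates must not be constant within every set
    _, inv2 = np.unique(g2, return_inverse=True)

    def _within_set_range(v):
        hi = np.full(inv2.max() + 1, -np.inf)
        lo = np.full(inv2.max() + 1, np.inf)
        np.maximum.at(hi, inv2, v)
        np.minimum.at(lo, inv2, v)
        return hi - lo

    if not np.any(_within_set_range(s2) > 0):
        raise ValueError("score constant within matched sets")
    for j, name in enumerate(cov_names):
        if not np.any(_within_set_range(C2[:, j]) > 0):
            raise ValueError(
                f"covariate {name!r} constant within all sets "
                "(absorbed by matching)")
    X = np.column_stack([s2, C2])
    if X.shape[1] > 1:
        _check_rank(X, ["score"] + cov_names)
    model = sm.ConditionalLogit(y2, X, groups=g2)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-12)
    beta, se = float(res.params[0]), float(res.bse[0])
    if abs(beta) > SEPARATION_BETA:
        raise ValueError(
            "complete separation detected (|beta| > 15) in the conditional "
            "likelihood")
    est, lo, hi, p = _wald(beta, se, "ratio", z)
    tag = model_tag if model_tag is not None else \
        ("CLR adjusted" if cov_names else "CLR crude")
    return FitRow(est, lo, hi, p, "ratio", tag, len(y2), beta, se,
                  {"score_sd": sd, "scaling": spec.scaling,
                   "n_sets_dropped": dropped})


def adjusted_fit(score, spec: OutcomeSpec, covariates) -> FitRow:
    """Covariate-adjusted association; dispatches on the outcome kind.

    With zero covariates this is bit-identical to the crude fit.  The
    reported estimate/CI/p always refer to the score coefficient only.
    """
    if covariates is not None and not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float))
    if covariates is not None and covariates.shape[1] == 0:
        covariates = None
    if spec.kind == "binary":
        return crude_lr(score, spec, covariates)
    if spec.kind == "matched_binary":
        return crude_clr(score, spec, covariates)
    if spec.kind == "continuous":
        return linear_beta(score, spec.y, covariates, scaling=spec.scaling)
    raise ValueError(f"unknown outcome kind {spec.kind!r}")


def linear_beta(score, marker, covariates=None, *, scaling: str = "per_sd",
                model_tag: str | None = None) -> FitRow:
    """Beta of a continuous risk marker on an LV score (OLS, t-based CI)."""
    m = np.asarray(marker, dtype=float).ravel()
    s, sd = _prep_score(score, scaling)
    if len(s) != len(m):
        raise ValueError("score and marker lengths differ")
    C, cov_names = _cov_matrix(covariates, len(m))
    X = np.column_stack([np.ones(len(m)), s, C])
    _check_rank(X, ["const", "score"] + cov_names)
    res = sm.OLS(m, X).fit()
    beta, se = float(res.params[1]), float(res.bse[1])
    ci = res.conf_int(alpha=0.05)
    lo, hi = float(ci[1][0]), float(ci[1][1])
    p = float(res.pvalues[1])
    tag = model_tag if model_tag is not None else \
        ("LM adjusted" if cov_names else "LM crude")
    return FitRow(beta, lo, hi, p, "linear", tag, len(m), beta, se,
                  {"score_sd": sd, "scaling": scaling})


def risk_block_from_fits(fits, scale: str | None = None,
                         model_tag: str | None = None,
                         adjustment_vars=None) -> RiskBlock:
    """Assemble component-aligned :class:`RiskBlock` from per-LV fits.

    ``fits`` is a sequence of :class:`FitRow` (or (estimate, ci_low,
    ci_high, p) tuples for externally computed models, e.g. Cox hazard
    ratios), one per LV component, all on the same scale.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    rows = []
    scales = set()
    for f in fits:
        if isinstance(f, FitRow):
            rows.append((f.estimate, f.ci_low, f.ci_high, f.p))
            scales.add(f.scale)
            if model_tag is None:
                model_tag = f.model_tag
        else:
            est, lo, hi, p = f
            rows.append((float(est), float(lo), float(hi), float(p)))
    if len(scales) > 1:
        raise ValueError(f"mixed scales in fits: {sorted(scales)}")
    if scale is None:
        if not scales:
            raise ValueError("scale must be given for plain tuples")
        scale = scales.pop()
    elif scales and scale not in scales:
        raise ValueError(f"mixed scales: declared {scale!r}, fits "
                         f"{sorted(scales)}")
    arr = np.array(rows, dtype=float)
    return RiskBlock(estimate=arr[:, 0], ci_low=arr[:, 1], ci_high=arr[:, 2],
                     p=arr[:, 3], scale=scale, model_tag=model_tag or "",
                     adjustment_vars=list(adjustment_vars or []))
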