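"""Core data model: the triplot object (TPO) and its building blocks.

A TPO binds one latent-variable (LV) model to any number of named
correlation blocks (LV scores vs. exposures) and risk blocks (per-LV
risk estimates).  It is the unit passed through the modular workflow:

    make_tpo -> add_corr* -> add_risk* -> check_tpo / triplot

``add_corr`` and ``add_risk`` return a new TPO; the input TPO is never
mutated.  Insertion order of blocks is preserved and drives plot
stacking order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LVModel",
    "CorrBlock",
    "RiskBlock",
    "TriplotObject",
    "make_tpo",
    "add_corr",
    "add_risk",
    "save_tpo",
    "load_tpo",
]

CORR_METHODS = ("pearson", "spearman", "kendall")
RISK_SCALES = ("ratio", "linear")


def _as_labels(names, n: int, prefix: str) -> list[str]:
    if names is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    names = [str(x) for x in names]
    if len(names) != n:
        raise ValueError(
            f"expected {n} labels for prefix {prefix!r}, got {len(names)}"
        )
    if len(set(names)) != len(names):
        raise ValueError(f"labels are not unique: {prefix}")
    return names


@dataclass(frozen=True)
class LVModel:
    """Scores/loadings pair from any latent-variable model.

    Attributes
    ----------
    scores : (n_obs, n_comp) array — observation scores.
    loadings : (n_var, n_comp) array — variable loadings.
    explained_variance : (n_comp,) array of fractions in [0, 1].
    method_tag : free text, e.g. ``"pca"``, ``"pls"`` or ``"external"``.
    meta : extra model metadata (e.g. PLS weight vectors).
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    comp_names: list[str]
    var_names: list[str]
    obs_ids: list[str]
    method_tag: str = "external"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        loadings = np.asarray(self.loadings, dtype=float)
        ev = np.asarray(self.explained_variance, dtype=float)
        if scores.ndim != 2 or loadings.ndim != 2:
            raise ValueError("scores and loadings must be 2-D matrices")
        if scores.shape[1] != loadings.shape[1]:
            raise ValueError(
                "component count mismatch "
                f"({scores.shape[1]} vs {loadings.shape[1]})"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite values in scores")
        if not np.all(np.isfinite(loadings)):
            raise ValueError("non-finite values in loadings")
        if ev.shape != (scores.shape[1],):
            raise ValueError(
                f"explained_variance length {ev.shape} does not match "
                f"{scores.shape[1]} components"
            )
        if np.any(ev < -1e-12):
            raise ValueError("explained_variance entries must be >= 0")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "loadings", loadings)
        object.__setattr__(self, "explained_variance", ev)
        object.__setattr__(
            self, "comp_names",
            _as_labels(self.comp_names, scores.shape[1], "LV"))
        object.__setattr__(
            self, "var_names",
            _as_labels(self.var_names, loadings.shape[0], "V"))
        object.__setattr__(
            self, "obs_ids",
            _as_labels(self.obs_ids, scores.shape[0], "obs"))

    @property
    def n_comp(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.obs_ids,
                            columns=self.comp_names)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.var_names,
                            columns=self.comp_names)


@dataclass(frozen=True)
class CorrBlock:
    """LV x exposure correlation coefficients with matched p-values.

    ``r``, ``p`` and ``n_used`` share shape (n_comp, n_exposure);
    ``n_used`` holds the per-cell pairwise-complete sample size.
    """

    r: np.ndarray
    p: np.ndarray
    n_used: np.ndarray
    method: str
    exposure_names: list[str]
    partial: bool = False
    adjustment_vars: list[str] = field(default_factory=list)

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        n = np.asarray(self.n_used)
        if self.method not in CORR_METHODS:
            raise ValueError(f"unknown correlation method {self.method!r}")
        if not (r.shape == p.shape == n.shape) or r.ndim != 2:
            raise ValueError(
                f"r/p/n_used shapes differ: {r.shape} {p.shape} {n.shape}")
        finite = np.isfinite(r)
        if np.any(np.abs(r[finite]) > 1 + 1e-12):
            raise ValueError("|r| > 1 encountered")
        pf = p[np.isfinite(p)]
        if np.any((pf < -1e-12) | (pf > 1 + 1e-12)):
            raise ValueError("p-values outside [0, 1]")
        if np.any(n[finite] < 3):
            raise ValueError("n_used < 3 where r is finite")
        if not self.partial and self.adjustment_vars:
            raise ValueError("adjustment_vars given but partial is False")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "n_used", np.asarray(n, dtype=int))
        object.__setattr__(
            self, "exposure_names",
            _as_labels(self.exposure_names, r.shape[1], "E"))
        object.__setattr__(self, "adjustment_vars",
                           [str(v) for v in self.adjustment_vars])

    @property
    def n_comp(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class RiskBlock:
    """Per-LV risk estimates (point, CI, p) on a ratio or linear scale.

    ``scale="ratio"`` means an odds or hazard ratio (log axis, null at 1);
    ``scale="linear"`` a regression beta (null at 0).
    """

    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    scale: str
    model_tag: str = ""
    adjustment_vars: list[str] = field(default_factory=list)

    def __post_init__(self):
        est = np.asarray(self.estimate, dtype=float)
        lo = np.asarray(self.ci_low, dtype=float)
        hi = np.asarray(self.ci_high, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if self.scale not in RISK_SCALES:
            raise ValueError(f"unknown risk scale {self.scale!r}")
        if not (est.shape == lo.shape == hi.shape == p.shape) or est.ndim != 1:
            raise ValueError("estimate/ci_low/ci_high/p must share 1-D shape")
        fin = np.isfinite(est) & np.isfinite(lo) & np.isfinite(hi)
        if np.any(lo[fin] > est[fin]) or np.any(est[fin] > hi[fin]):
            raise ValueError("CI must satisfy ci_low <= estimate <= ci_high")
        if self.scale == "ratio":
            if np.any(est[np.isfinite(est)] <= 0):
                raise ValueError("ratio-scale estimates must be positive")
            if np.any(lo[np.isfinite(lo)] <= 0) or np.any(hi[np.isfinite(hi)] <= 0):
                raise ValueError("ratio-scale CI bounds must be positive")
        object.__setattr__(self, "estimate", est)
        object.__setattr__(self, "ci_low", lo)
        object.__setattr__(self, "ci_high", hi)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "adjustment_vars",
                           [str(v) for v in self.adjustment_vars])

    @property
    def n_comp(self) -> int:
        return self.estimate.shape[0]


@dataclass(frozen=True)
class TriplotObject:
    """Container binding one LV model with named correlation/risk blocks."""

    lv: LVModel
    corr_blocks: dict[str, CorrBlock] = field(default_factory=dict)
    risk_blocks: dict[str, RiskBlock] = field(default_factory=dict)

    @property
    def n_comp(self) -> int:
        return self.lv.n_comp


def make_tpo(scores, loadings=None, explained_variance=None, *,
             comp_names=None, var_names=None, obs_ids=None,
             method_tag: str = "external", meta: dict | None = None
             ) -> TriplotObject:
    """Initiate a triplot object from any scores/loadings pair.

    Accepts raw matrices, pandas DataFrames (labels taken from the
    index/columns unless overridden) or an :class:`LVModel`.  Matrices
    are copied: mutating caller data does not alter the TPO.
    """
    if isinstance(scores, LVModel):
        return TriplotObject(lv=scores)
    if loadings is None:
        raise TypeError("loadings are required unless an LVModel is given")
    if isinstance(scores, pd.DataFrame):
        obs_ids = obs_ids if obs_ids is not None else list(scores.index)
        comp_names = comp_names if comp_names is not None else list(scores.columns)
        scores = scores.to_numpy()
    if isinstance(loadings, pd.DataFrame):
        var_names = var_names if var_names is not None else list(loadings.index)
        loadings = loadings.to_numpy()
    scores = np.array(scores, dtype=float)       # copy
    loadings = np.array(loadings, dtype=float)   # copy
    if explained_variance is None:
        # unknown for externally supplied models; axes then omit the %
        explained_variance = np.zeros(scores.shape[1])
    lv = LVModel(scores=scores, loadings=loadings,
                 explained_variance=np.array(explained_variance, dtype=float),
                 comp_names=comp_names, var_names=var_names, obs_ids=obs_ids,
                 method_tag=method_tag, meta=dict(meta or {}))
    return TriplotObject(lv=lv)


def add_corr(tpo: TriplotObject, block: CorrBlock, name: str) -> TriplotObject:
    """Return a new TPO with ``block`` appended under ``name``."""
    if name in tpo.corr_blocks:
        raise ValueError(f"block name exists: {name!r}")
    if block.n_comp != tpo.n_comp:
        raise ValueError(
            f"component count mismatch: block has {block.n_comp} rows, "
            f"TPO has {tpo.n_comp} components")
    blocks = dict(tpo.corr_blocks)
    blocks[name] = block
    return replace(tpo, corr_blocks=blocks)


def add_risk(tpo: TriplotObject, block: RiskBlock, name: str) -> TriplotObject:
    """Return a new TPO with the risk ``block`` appended under ``name``."""
    if name in tpo.risk_blocks:
        raise ValueError(f"block name exists: {name!r}")
    if block.n_comp != tpo.n_comp:
        raise ValueError(
            f"component count mismatch: block has {block.n_comp} entries, "
            f"TPO has {tpo.n_comp} components")
    blocks = dict(tpo.risk_blocks)
    blocks[name] = block
    return replace(tpo, risk_blocks=blocks)


# ---------------------------------------------------------------------------
# On-disk format: a directory of tab-delimited tables + a JSON manifest.
# Inspectable, diff-able and language-neutral.

def _write_tsv(path: Path, arr: np.ndarray, index, columns):
    pd.DataFrame(arr, index=index, columns=columns).to_csv(path, sep="\t")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def save_tpo(tpo: TriplotObject, path) -> Path:
    """Write a TPO to ``path`` (a directory; created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lv = tpo.lv
    _write_tsv(path / "scores.tsv", lv.scores, lv.obs_ids, lv.comp_names)
    _write_tsv(path / "loadings.tsv", lv.loadings, lv.var_names, lv.comp_names)
    _write_tsv(path / "explained_variance.tsv",
               lv.explained_variance[:, None], lv.comp_names, ["explained_variance"])
    for name, cb in tpo.corr_blocks.items():
        for part, arr in (("r", cb.r), ("p", cb.p), ("n", cb.n_used)):
            _write_tsv(path / f"corr_{name}_{part}.tsv", arr,
                       lv.comp_names, cb.exposure_names)
    for name, rb in tpo.risk_blocks.items():
        df = pd.DataFrame(
            {"estimate": rb.estimate, "ci_low": rb.ci_low,
             "ci_high": rb.ci_high, "p": rb.p},
            index=lv.comp_names)
        df.to_csv(path / f"risk_{name}.tsv", sep="\t")
    manifest = {
        "comp_names": lv.comp_names,
        "var_names": lv.var_names,
        "obs_ids": lv.obs_ids,
        "method_tag": lv.method_tag,
        "corr_blocks": [
            {"name": n, "method": b.method, "partial": b.partial,
             "adjustment_vars": b.adjustment_vars}
            for n, b in tpo.corr_blocks.items()],
        "risk_blocks": [
            {"name": n, "scale": b.scale, "model_tag": b.model_tag,
             "adjustment_vars": b.adjustment_vars}
            for n, b in tpo.risk_blocks.items()],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def load_tpo(path) -> TriplotObject:
    """Read a TPO previously written by :func:`save_tpo`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    scores = _read_tsv(path / "scores.tsv")
    loadings = _read_tsv(path / "loadings.tsv")
    ev = _read_tsv(path / "explained_variance.tsv")["explained_variance"]
    lv = LVModel(scores=scores.to_numpy(), loadings=loadings.to_numpy(),
                 explained_variance=ev.to_numpy(),
                 comp_names=manifest["comp_names"],
                 var_names=manifest["var_names"],
                 obs_ids=manifest["obs_ids"],
                 method_tag=manifest["method_tag"])
    tpo = TriplotObject(lv=lv)
    for entry in manifest["corr_blocks"]:
        name = entry["name"]
        r = _read_tsv(path / f"corr_{name}_r.tsv")
        p = _read_tsv(path / f"corr_{name}_p.tsv")
        n = _read_tsv(path / f"corr_{name}_n.tsv")
        block = CorrBlock(r=r.to_numpy(), p=p.to_numpy(),
                          n_used=n.to_numpy(), method=entry["method"],
                          exposure_names=list(r.columns),
                          partial=entry["partial"],
                          adjustment_vars=entry["adjustment_vars"])
        tpo = add_corr(tpo, block, name)
    for entry in manifest["risk_blocks"]:
        name = entry["name"]
        df = _read_tsv(path / f"risk_{name}.tsv")
        block = RiskBlock(estimate=df["estimate"].to_numpy(),
                          ci_low=df["ci_low"].to_numpy(),
                          ci_high=df["ci_high"].to_numpy(),
                          p=df["p"].to_numpy(), scale=entry["scale"],
                          model_tag=entry["model_tag"],
                          adjustment_vars=entry["adjustment_vars"])
        tpo = add_risk(tpo, block, name)
    return tpo
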