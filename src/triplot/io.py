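"""Table I/O and the end-to-end pipeline driver.

``read_study`` loads the three row-matched delimited tables (features,
exposures, outcome/covariates) and realigns them on their row labels;
``run_pipeline`` executes the full workflow described by a single YAML
config (sections: data, lv, corr, risk, viz, seed) and writes every
artifact — the TPO directory, the overview heatmap, the triplot and its
layout report, and a run log — to an output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation as corr_mod
from . import risk as risk_mod
from .core import make_tpo, add_corr, add_risk, save_tpo
from .lv import FeatureTable, preprocess, pca_fit, pls_fit, scree
from .viz import TriplotSpec, check_tpo, triplot

log = logging.getLogger("triplot")

__all__ = ["read_table", "read_study", "run_pipeline"]


def read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited table with a header row and row-label column.

    Delimiter auto-detection is limited to tab and comma; anything else
    must be declared explicitly.
    """
    path = Path(path)
    if delimiter is None:
        first = path.open().readline()
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_study(feature_path, exposure_path, outcome_path,
               delimiter: str | None = None):
    """Load and row-align the three study tables.

    Rows may arrive in different orders; they are realigned on the row
    labels.  A label present in one table but not another is an error
    (the first few mismatches are listed).
    """
    features = read_table(feature_path, delimiter)
    exposures = read_table(exposure_path, delimiter)
    outcome = read_table(outcome_path, delimiter)
    ref = list(features.index)
    for name, df in (("exposures", exposures), ("outcome", outcome)):
        missing = [str(i) for i in features.index.difference(df.index)]
        extra = [str(i) for i in df.index.difference(features.index)]
        if missing or extra:
            raise ValueError(
                f"row-label mismatch in {name} table; "
                f"missing={missing[:5]} extra={extra[:5]}")
    exposures = exposures.loc[ref]
    outcome = outcome.loc[ref]
    for name, df in (("features", features), ("exposures", exposures),
                     ("outcome", outcome)):
        miss = df.isna().sum()
        log.info("loaded %s: %d rows x %d cols, %d missing cells",
                 name, df.shape[0], df.shape[1], int(miss.sum()))
    return features, exposures, outcome


def _fit_lv(features: pd.DataFrame, outcome: pd.DataFrame, lv_cfg: dict):
    x = preprocess(FeatureTable(features),
                   center=lv_cfg.get("center", True),
                   scale=lv_cfg.get("scale", True))
    method = lv_cfg.get("method", "pca")
    n_comp = int(lv_cfg.get("n_comp", 2))
    if method == "pca":
        return pca_fit(x, n_comp)
    if method == "pls":
        ycol = lv_cfg["y"]
        return pls_fit(x, outcome[ycol].to_numpy(dtype=float), n_comp)
    raise ValueError(f"unknown lv method {method!r}")


def _corr_stage(tpo, scores, exposures, outcome, corr_cfgs):
    for cfg in corr_cfgs:
        name = cfg.get("name", cfg.get("method", "corr"))
        method = cfg.get("method", "pearson")
        adj = cfg.get("adjustment_vars", [])
        exp_table = exposures
        if cfg.get("exposure_vars"):
            exp_table = exposures[cfg["exposure_vars"]]
        if adj:
            cov = outcome[adj].astype(float)
            block = corr_mod.partial_corr(scores, exp_table, cov, method)
        else:
            block = corr_mod.make_corr(scores, exp_table, method)
        tpo = add_corr(tpo, block, name)
        log.info("corr block %r: method=%s partial=%s shape=%s",
                 name, method, bool(adj), block.r.shape)
    return tpo


def _risk_stage(tpo, lvmodel, outcome, risk_cfgs):
    for cfg in risk_cfgs:
        name = cfg["name"]
        model = cfg.get("model", "lr")
        adj = cfg.get("adjustment_vars", [])
        cov = outcome[adj].astype(float) if adj else None
        fits = []
        for k in range(lvmodel.n_comp):
            s = lvmodel.scores[:, k]
            if model == "clr":
                spec = risk_mod.OutcomeSpec(
                    kind="matched_binary",
                    y=outcome[cfg.get("outcome", "outcome")].to_numpy(),
                    set_id=outcome[cfg.get("set_id", "set_id")].to_numpy())
                fits.append(risk_mod.crude_clr(s, spec, cov))
            elif model == "lr":
                spec = risk_mod.OutcomeSpec(
                    kind="binary",
                    y=outcome[cfg.get("outcome", "outcome")].to_numpy())
                fits.append(risk_mod.crude_lr(s, spec, cov))
            elif model == "linear":
                marker = outcome[cfg["marker"]].to_numpy(dtype=float)
                fits.append(risk_mod.linear_beta(s, marker, cov))
            else:
                raise ValueError(f"unknown risk model {model!r}")
        block = risk_mod.risk_block_from_fits(fits,
                                              adjustment_vars=adj)
        tpo = add_risk(tpo, block, name)
        log.info("risk block %r: model=%s adjusted=%s", name, model,
                 bool(adj))
    return tpo


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute preprocess → LV fit → TPO → correlations → risks → figures.

    Returns the artifact directory.  Any stage failure aborts with the
    stage name in the raised message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stage = "data"
    try:
        data_cfg = config["data"]
        if "preset" in data_cfg:
            from . import synthetic
            preset = data_cfg["preset"]
            if preset == "healthy_nordic":
                study = synthetic.generate_healthy_nordic(seed)
            elif preset == "camp":
                study = synthetic.generate_camp(seed)
            else:
                raise ValueError(f"unknown preset {preset!r}")
            features, exposures, outcome = (study.metabolites, study.foods,
                                            study.baseline)
        else:
            features, exposures, outcome = read_study(
                data_cfg["features"], data_cfg["exposures"],
                data_cfg["outcome"], data_cfg.get("delimiter"))

        stage = "lv"
        lvmodel = _fit_lv(features, outcome, config.get("lv", {}))
        tpo = make_tpo(lvmodel)
        scree(lvmodel).to_csv(out / "scree.tsv", sep="\t", index=False)

        stage = "correlation"
        tpo = _corr_stage(tpo, lvmodel.scores_frame(), exposures, outcome,
                          config.get("corr", []))

        stage = "risk"
        tpo = _risk_stage(tpo, lvmodel, outcome, config.get("risk", []))

        stage = "output"
        save_tpo(tpo, out / "tpo")
        fig, table = check_tpo(tpo)
        fig.savefig(out / "check_tpo.svg")
        table.to_csv(out / "check_tpo.tsv", sep="\t")

        stage = "triplot"
        viz_cfg = dict(config.get("viz", {}))
        spec = TriplotSpec(**viz_cfg)
        fig, report = triplot(
            tpo, spec, out / f"triplot.{spec.output_format}")
        (out / "triplot_layout.json").write_text(json.dumps(report, indent=2))

        import matplotlib.pyplot as plt
        plt.close("all")
        (out / "run_log.json").write_text(json.dumps({
            "seed": seed,
            "n_obs": int(features.shape[0]),
            "n_features": int(features.shape[1]),
            "lv_method": lvmodel.method_tag,
            "n_comp": lvmodel.n_comp,
            "corr_blocks": list(tpo.corr_blocks),
            "risk_blocks": list(tpo.risk_blocks),
        }, indent=2))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return out
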