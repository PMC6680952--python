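"""Visualizations: the overview heatmap (check_tpo) and the triplot.

The triplot superimposes three layers on one figure:

1. variable loadings on two chosen LV components (center panel, axes
   scaled to the largest absolute loading, labels carry the explained
   variance of each component);
2. exposure arrows from the origin to the exposure's correlation with
   the two components, inside a unit correlation circle drawn on its
   own fixed [-1, 1] scale;
3. per-component risk estimates with confidence intervals on margin
   strips parallel to each axis (log scale with null line at 1 for
   ratio estimates, linear with null at 0 for betas).

Loadings and correlation arrows share the center panel but use
separate scales (both printed); risk markers sit on margin strips
because they are per-component scalars, not 2-D points.

Every rendering also returns a machine-readable *layout report* — a
list of drawn glyphs with kind, label and data coordinates — so the
plotted content can be asserted exactly without image comparison.
Rendering is deterministic: identical TPO + spec give an identical
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import TriplotObject
from .correlation import significance_mask

__all__ = ["TriplotSpec", "check_tpo", "filter_loadings", "triplot"]


@dataclass
class TriplotSpec:
    """Display options for :func:`triplot`.

    ``loading_threshold`` (default 0.25) hides variables whose absolute
    loading on both displayed components is at or below the threshold;
    ``corr_alpha`` (default 0.05) keeps only exposures significantly
    correlated with at least one displayed component.
    """

    comp_x: str | None = None
    comp_y: str | None = None
    loading_threshold: float = 0.25
    corr_alpha: float = 0.05
    show_all_exposures: bool = False
    always_show: list[str] = field(default_factory=list)
    corr_adjust: str = "none"
    output_format: str = "svg"
    width: float = 9.0
    height: float = 9.0

    def __post_init__(self):
        if self.loading_threshold < 0:
            raise ValueError("loading_threshold must be >= 0")
        if self.output_format not in ("svg", "png"):
            raise ValueError("output format must be svg or png")


def check_tpo(tpo: TriplotObject, corr_alpha: float = 0.05):
    """Overview heatmap of every correlation and risk block.

    Rows are LV components; columns are every exposure of every
    correlation block (cell = r) followed by one column per risk block
    (cell = signed standardized effect: log(estimate) for ratio scale,
    raw beta for linear, rescaled to the block's max |value|).  Returns
    ``(figure, table)`` where ``table`` is the underlying numeric
    DataFrame; significant correlation cells are marked on the figure.
    """
    if not tpo.corr_blocks and not tpo.risk_blocks:
        raise ValueError("nothing to display")
    comp_names = tpo.lv.comp_names
    cols, data, sig = [], [], []
    for name, cb in tpo.corr_blocks.items():
        for j, exp in enumerate(cb.exposure_names):
            cols.append(f"{name}:{exp}" if len(tpo.corr_blocks) > 1 else exp)
            data.append(cb.r[:, j])
            with np.errstate(invalid="ignore"):
                sig.append(np.where(np.isfinite(cb.p[:, j]),
                                    cb.p[:, j] < corr_alpha, False))
    for name, rb in tpo.risk_blocks.items():
        vals = np.log(rb.estimate) if rb.scale == "ratio" else rb.estimate
        vmax = np.nanmax(np.abs(vals))
        cols.append(name)
        data.append(vals / vmax if vmax > 0 else vals)
        sig.append(np.zeros(len(vals), dtype=bool))
    table = pd.DataFrame(np.column_stack(data), index=comp_names,
                         columns=cols)
    sig = np.column_stack(sig)

    fig, ax = plt.subplots(
        figsize=(max(6, 0.4 * len(cols)), max(2.5, 0.5 * len(comp_names))))
    im = ax.imshow(table.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=7)
    ax.set_yticks(range(len(comp_names)), comp_names)
    for (i, j) in zip(*np.where(sig)):
        ax.text(j, i, "*", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="r / scaled effect")
    fig.tight_layout()
    return fig, table


def filter_loadings(loadings, comp_x: int, comp_y: int,
                    threshold: float = 0.25) -> np.ndarray:
    """Indices of variables with |loading| > threshold on either component."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    L = np.asarray(loadings, dtype=float)
    keep = np.maximum(np.abs(L[:, comp_x]), np.abs(L[:, comp_y])) > threshold
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn("no variables pass the loading threshold",
                      RuntimeWarning, stacklevel=2)
    return idx


def _comp_index(tpo: TriplotObject, label: str | None, default: int) -> int:
    if label is None:
        return default
    try:
        return tpo.lv.comp_names.index(label)
    except ValueError:
        raise ValueError(
            f"component {label!r} not in {tpo.lv.comp_names}") from None


def _nudge_labels(glyphs: list[dict], min_sep: float = 0.04) -> None:
    """Deterministic greedy label displacement, ordered by magnitude."""
    order = sorted(range(len(glyphs)),
                   key=lambda i: (-abs(glyphs[i]["x"]) - abs(glyphs[i]["y"]),
                                  glyphs[i]["label"]))
    placed: list[tuple[float, float]] = []
    for i in order:
        g = glyphs[i]
        lx, ly = g["x"], g["y"]
        step = 0
        while any(abs(lx - px) < min_sep and abs(ly - py) < min_sep
                  for px, py in placed):
            step += 1
            ly += min_sep * (1 if step % 2 else -1) * ((step + 1) // 2)
        g["label_x"], g["label_y"] = lx, ly
        placed.append((lx, ly))


def triplot(tpo: TriplotObject, spec: TriplotSpec | None = None,
            path=None):
    """Render the composite triplot; returns ``(figure, layout_report)``.

    The layout report is a JSON-serializable dict listing every drawn
    glyph (kind, label, data coordinates) plus the active filters.  If
    ``path`` is given the figure is also written there in the spec's
    output format.
    """
    spec = spec or TriplotSpec()
    if not tpo.corr_blocks and not tpo.risk_blocks:
        raise ValueError("at least one correlation or risk block is required")
    ix = _comp_index(tpo, spec.comp_x, 0)
    iy = _comp_index(tpo, spec.comp_y, 1)
    if ix == iy:
        raise ValueError("comp_x and comp_y must differ")
    lv = tpo.lv
    cx, cy = lv.comp_names[ix], lv.comp_names[iy]

    glyphs: list[dict] = []
    kept = filter_loadings(lv.loadings, ix, iy, spec.loading_threshold)
    for v in kept:
        glyphs.append({"kind": "loading", "label": lv.var_names[v],
                       "x": float(lv.loadings[v, ix]),
                       "y": float(lv.loadings[v, iy])})

    n_loading = len(glyphs)
    for name, cb in tpo.corr_blocks.items():
        mask = significance_mask(cb, spec.corr_alpha, spec.corr_adjust)
        for j, exp in enumerate(cb.exposure_names):
            show = (spec.show_all_exposures or exp in spec.always_show
                    or mask[ix, j] or mask[iy, j])
            if not show or not (np.isfinite(cb.r[ix, j])
                                and np.isfinite(cb.r[iy, j])):
                continue
            glyphs.append({"kind": "exposure", "label": exp, "block": name,
                           "x": float(cb.r[ix, j]), "y": float(cb.r[iy, j])})

    risk_glyphs: list[dict] = []
    for name, rb in tpo.risk_blocks.items():
        for axis, ci in (("x", ix), ("y", iy)):
            risk_glyphs.append({
                "kind": "risk", "label": name, "component": lv.comp_names[ci],
                "axis": axis, "scale": rb.scale,
                "estimate": float(rb.estimate[ci]),
                "ci_low": float(rb.ci_low[ci]),
                "ci_high": float(rb.ci_high[ci]),
                "p": float(rb.p[ci])})

    if not glyphs and not risk_glyphs:
        raise ValueError(
            "nothing to draw after filtering; relax loading_threshold or "
            "corr_alpha")
    _nudge_labels(glyphs)

    load_scale = max((abs(g["x"]) for g in glyphs if g["kind"] == "loading"),
                     default=0.0)
    load_scale = max(load_scale,
                     *(abs(g["y"]) for g in glyphs
                       if g["kind"] == "loading"), 0.0) or 1.0

    # figure: center panel + one margin strip per displayed component
    fig = plt.figure(figsize=(spec.width, spec.height))
    gs = fig.add_gridspec(2, 2, width_ratios=[5, 1], height_ratios=[5, 1],
                          hspace=0.3, wspace=0.3)
    ax = fig.add_subplot(gs[0, 0])
    ax_rx = fig.add_subplot(gs[1, 0])   # strip parallel to the x component
    ax_ry = fig.add_subplot(gs[0, 1])   # strip parallel to the y component

    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="0.8", lw=0.8)
    ax.axhline(0, color="0.85", lw=0.6)
    ax.axvline(0, color="0.85", lw=0.6)
    for g in glyphs:
        if g["kind"] == "loading":
            x, y = g["x"] / load_scale, g["y"] / load_scale
            ax.scatter([x], [y], s=12, color="tab:gray", zorder=3)
            ax.annotate(g["label"],
                        (g["label_x"] / load_scale, g["label_y"] / load_scale),
                        fontsize=6, color="0.35")
        else:
            ax.annotate("", xy=(g["x"], g["y"]), xytext=(0, 0),
                        arrowprops=dict(arrowstyle="->", color="tab:blue",
                                        lw=1.0))
            ax.annotate(g["label"], (g["label_x"], g["label_y"]),
                        fontsize=7, color="tab:blue")
    ev = lv.explained_variance
    ax.set_xlabel(f"{cx} ({100 * ev[ix]:.1f}% of variance); "
                  f"loadings scaled by {load_scale:.2f}")
    ax.set_ylabel(f"{cy} ({100 * ev[iy]:.1f}% of variance)")
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")

    for strip, axis, horizontal in ((ax_rx, "x", True), (ax_ry, "y", False)):
        items = [g for g in risk_glyphs if g["axis"] == axis]
        if not items:
            strip.axis("off")
            continue
        ratio = items[0]["scale"] == "ratio"
        null = 1.0 if ratio else 0.0
        for k, g in enumerate(items):
            pos = k + 1
            if horizontal:
                strip.plot([g["ci_low"], g["ci_high"]], [pos, pos],
                           color="tab:red", lw=1.2)
                strip.plot([g["estimate"]], [pos], "o", color="tab:red",
                           ms=4)
                strip.text(g["ci_high"], pos, f' {g["label"]}', fontsize=6,
                           va="center")
            else:
                strip.plot([pos, pos], [g["ci_low"], g["ci_high"]],
                           color="tab:red", lw=1.2)
                strip.plot([pos], [g["estimate"]], "o", color="tab:red",
                           ms=4)
                strip.text(pos, g["ci_high"], g["label"], fontsize=6,
                           ha="center", va="bottom")
        if horizontal:
            strip.axvline(null, color="0.6", lw=0.8, ls="--")
            if ratio:
                strip.set_xscale("log")
            strip.set_yticks([])
            strip.set_xlabel(f"risk per SD of {cx}"
                             + (" (OR)" if ratio else " (beta)"))
        else:
            strip.axhline(null, color="0.6", lw=0.8, ls="--")
            if ratio:
                strip.set_yscale("log")
            strip.set_xticks([])
            strip.set_ylabel(f"risk per SD of {cy}"
                             + (" (OR)" if ratio else " (beta)"))

    report = {
        "comp_x": cx, "comp_y": cy,
        "loading_threshold": spec.loading_threshold,
        "corr_alpha": spec.corr_alpha,
        "loading_scale": load_scale,
        "glyphs": glyphs + risk_glyphs,
        "n_loading_glyphs": n_loading,
        "n_exposure_glyphs": len(glyphs) - n_loading,
        "n_risk_glyphs": len(risk_glyphs),
    }
    if path is not None:
        fig.savefig(path, format=spec.output_format)
    return fig, report
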