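"""Figure rendering: exposure maps, fitted curves, risk maps, sensitivity densities.

Four figure types mirror the analysis stages: ``exposure`` (per-chemical
choropleths of external concentration means), ``hill`` (fitted curves over
the concentration-response points), ``response`` (choropleth of the
region summary, or an assay-quantile × total-quantile panel grid for
multi-assay results), and ``sensitivity`` (kernel densities of the metric
by varied component). Continuous color scales throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PatchCollection
from matplotlib.patches import Polygon as MplPolygon
from scipy import stats

from .dose_response import _hill
from .summarize import region_summary, summarize_multi_assay

FIGURE_TYPES = ("exposure", "hill", "response", "sensitivity")

__all__ = ["FigureSpec", "render_figure", "FIGURE_TYPES"]


@dataclass
class FigureSpec:
    type: str
    path: str | Path
    metric: str = "GCA_Eff"
    assay_quantiles: tuple[float, ...] | None = None
    summary_quantiles: tuple[float, ...] | None = None
    image_format: str = "png"

    def __post_init__(self):
        if self.type not in FIGURE_TYPES:
            raise ValueError(f"figure type must be one of {FIGURE_TYPES}")
        if self.image_format not in ("png", "svg"):
            raise ValueError("image format must be png or svg")


def _choropleth(ax, regions, values: dict[str, float], title: str):
    if regions.kind == "point":
        xs, ys, cs = [], [], []
        for rid, geom in zip(regions.frame["region_id"], regions.frame["geometry"]):
            xs.append(geom.x)
            ys.append(geom.y)
            cs.append(values.get(str(rid), np.nan))
        sc = ax.scatter(xs, ys, c=cs, cmap="viridis", s=40)
        mappable = sc
    else:
        patches, cs = [], []
        for rid, geom in zip(regions.frame["region_id"], regions.frame["geometry"]):
            polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
            for poly in polys:
                patches.append(MplPolygon(np.asarray(poly.exterior.coords)))
                cs.append(values.get(str(rid), np.nan))
        coll = PatchCollection(patches, cmap="viridis", edgecolor="white",
                               linewidth=0.3)
        coll.set_array(np.asarray(cs, dtype=float))
        ax.add_collection(coll)
        ax.autoscale_view()
        mappable = coll
    ax.set_title(title, fontsize=8)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    return mappable


def _save(fig, spec: FigureSpec):
    path = Path(spec.path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format=spec.image_format, dpi=100,
                metadata={"Software": "mixrisk"} if spec.image_format == "png"
                else {"Date": None})
    plt.close(fig)
    return path


def render_figure(model, spec: FigureSpec) -> Path:
    """Render one figure of the model state; returns the written path."""
    if spec.type == "exposure":
        chems = sorted(model.exposure["chemical_id"].unique())
        ncol = min(3, len(chems))
        nrow = int(np.ceil(len(chems) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow),
                                 squeeze=False)
        for ax in axes.ravel():
            ax.set_axis_off()
        for ax, chem in zip(axes.ravel(), chems):
            ax.set_axis_on()
            sub = model.exposure[model.exposure["chemical_id"] == chem]
            vals = dict(zip(sub["region_id"].astype(str), sub["mean"]))
            m = _choropleth(ax, model.regions, vals, f"{chem} (µg/m³)")
            fig.colorbar(m, ax=ax, shrink=0.8)
        return _save(fig, spec)

    if spec.type == "hill":
        params = [p for p in model.hill_params if p.converged]
        if not params:
            raise ValueError("no converged hill fits to plot")
        chems = sorted({p.chemical_id for p in params})
        fig, ax = plt.subplots(figsize=(5, 4))
        grid = np.logspace(-3, 3, 200)
        for p in params:
            ax.plot(grid, _hill(grid, p.tp, p.log10_ac50, p.slope),
                    label=f"{p.chemical_id}/{p.assay_id}", lw=1)
        if model.concresp is not None:
            ax.plot(model.concresp["conc_um"], model.concresp["response"], ".",
                    ms=2, color="gray", alpha=0.5)
        ax.set_xscale("log")
        ax.set_xlabel("concentration (µM)")
        ax.set_ylabel("response (% activity)")
        if len(params) <= 12:
            ax.legend(fontsize=5)
        return _save(fig, spec)

    if spec.type == "response":
        if model.results is None:
            raise ValueError("results not computed; run calc_response first")
        aq = spec.assay_quantiles or tuple(model.config.assay_quantiles)
        sq = spec.summary_quantiles or tuple(model.config.summary_quantiles)
        n_assays = model.results["assay_id"].nunique()
        if n_assays == 1:
            med = region_summary(model.results, spec.metric, (50.0,))
            vals = dict(zip(med["region_id"].astype(str), med["value"]))
            fig, ax = plt.subplots(figsize=(5, 4))
            m = _choropleth(ax, model.regions, vals, f"median {spec.metric}")
            fig.colorbar(m, ax=ax, shrink=0.8)
            return _save(fig, spec)
        grid = summarize_multi_assay(model.results, spec.metric, aq, sq)
        fig, axes = plt.subplots(len(aq), len(sq),
                                 figsize=(3 * len(sq), 2.5 * len(aq)),
                                 squeeze=False)
        for i, q in enumerate(aq):
            for j, p in enumerate(sq):
                cell = grid[(grid["assay_quantile"] == q)
                            & (grid["summary_quantile"] == p)]
                vals = dict(zip(cell["region_id"].astype(str), cell["value"]))
                m = _choropleth(axes[i][j], model.regions, vals,
                                f"A-{q:g} / total p{p:g}")
                fig.colorbar(m, ax=axes[i][j], shrink=0.8)
        fig.suptitle(spec.metric, fontsize=10)
        return _save(fig, spec)

    # sensitivity: kernel densities per varied component
    sens = getattr(model, "sensitivity", None)
    if not sens:
        raise ValueError("no sensitivity results on model; run compute_sensitivity")
    fig, ax = plt.subplots(figsize=(5, 4))
    for comp in sorted(sens):
        vals = sens[comp].values["value"].to_numpy(dtype=float)
        if np.std(vals) > 0:
            kde = stats.gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 200)
            ax.plot(grid, kde(grid), label=comp)
        else:  # degenerate spread: draw a spike instead of a density
            ax.axvline(float(vals[0]) if vals.size else 0.0, ls="--", label=comp)
    ax.set_xlabel(spec.metric)
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    return _save(fig, spec)
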