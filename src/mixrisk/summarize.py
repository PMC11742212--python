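"""Spatial summarization of mixture results for risk mapping.

Single-assay maps use per-region percentiles of a metric over simulated
individuals. Multi-assay risk is the nested "p total quantile of the q
assay-level quantiles": per region, take the q-th percentile of the metric
over individuals within each assay, then the p-th percentile of those
assay-level values across assays. Percentiles are empirical with linear
interpolation between order statistics throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["region_summary", "summarize_multi_assay", "summarize_model"]


def _check(results: pd.DataFrame, metric: str):
    if results is None or len(results) == 0:
        raise ValueError("empty results table")
    if metric not in results.columns:
        raise ValueError(f"unknown metric {metric!r}; have {list(results.columns)}")


def region_summary(results: pd.DataFrame, metric: str,
                   quantiles=(50.0,)) -> pd.DataFrame:
    """Per-region percentiles of ``metric`` over individuals (all assays pooled).

    Returns long format: region_id, quantile, metric, value.
    """
    _check(results, metric)
    rows = []
    for region_id, grp in results.groupby("region_id", sort=True):
        vals = grp[metric].to_numpy(dtype=float)
        for q in quantiles:
            rows.append((region_id, float(q), metric, float(np.percentile(vals, q))))
    return pd.DataFrame(rows, columns=["region_id", "quantile", "metric", "value"])


def summarize_multi_assay(results: pd.DataFrame, metric: str,
                          assay_quantiles=(10.0, 50.0, 90.0),
                          summary_quantiles=(5.0, 10.0)) -> pd.DataFrame:
    """Nested assay-level / total quantile grid per region.

    Returns long format: region_id, assay_quantile, summary_quantile,
    metric, value — one row per (region, q, p) cell of the map grid.
    """
    _check(results, metric)
    rows = []
    for region_id, grp in results.groupby("region_id", sort=True):
        per_assay = grp.groupby("assay_id", sort=True)[metric]
        for q in assay_quantiles:
            assay_level = per_assay.apply(
                lambda v: np.percentile(v.to_numpy(dtype=float), q)
            ).to_numpy(dtype=float)
            for p in summary_quantiles:
                rows.append(
                    (region_id, float(q), float(p), metric,
                     float(np.percentile(assay_level, p)))
                )
    return pd.DataFrame(
        rows,
        columns=["region_id", "assay_quantile", "summary_quantile", "metric", "value"],
    )


def summarize_model(model, metric: str = "GCA_Eff") -> pd.DataFrame:
    """Summary grid from the model's results and configured quantile lists."""
    if model.results is None:
        raise ValueError("no results on model; run calc_response first")
    grid = summarize_multi_assay(
        model.results, metric,
        model.config.assay_quantiles, model.config.summary_quantiles,
    )
    model.summary = grid
    return grid
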