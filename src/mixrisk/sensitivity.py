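"""One-at-a-time Monte Carlo sensitivity analysis.

One pipeline component at a time is allowed to vary from its sampling
distribution while every other component is pinned to a central value:

==============  =============================================================
component       central value when pinned
==============  =============================================================
age             the region's exact median age (bracket-uniform distribution)
obesity         weight class "Normal" for every individual
C_ext           the exposure mean per (region, chemical)
css_params      the stratum-median Css
fit_params      the maximum-likelihood hill estimates
==============  =============================================================

When ``fit_params`` varies, hill parameters are drawn per replicate from
independent normals centred on the MLE with the fitted standard errors,
truncated to valid ranges (tp > 0, slope within the fitting box).
Inhalation rate is deterministic given age (the bracket mean), so its
variability enters only through the age component. Each component draws
from its dedicated RNG substream, so varying one never perturbs another's
draws; pinning every component reproduces the zero-variance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calculate import calc_response
from .dose_response import HillParams
from .model import RiskModel
from .population import (
    PopulationSample,
    age_group_label,
    simulate_age,
    simulate_css,
    simulate_exposure,
    simulate_obesity,
)
from .rng import substream

COMPONENTS = ("age", "obesity", "css_params", "fit_params", "C_ext")

__all__ = ["COMPONENTS", "SensitivityResult", "compute_sensitivity"]


@dataclass
class SensitivityResult:
    """Replicate metric values with one free component, plus the baseline."""

    component: str  # "baseline" for the all-pinned run
    metric: str
    values: pd.DataFrame  # region_id, assay_id, individual, value
    baseline: pd.DataFrame  # region_id, assay_id, value (constant per cell)


def _bracket_mean_ir(ages: np.ndarray, ir_table: pd.DataFrame) -> np.ndarray:
    lows = ir_table["age_low"].to_numpy(dtype=float)
    highs = ir_table["age_high"].to_numpy(dtype=float)
    means = ir_table["ir_mean"].to_numpy(dtype=float)
    hit = (ages[:, None] >= lows[None, :]) & (ages[:, None] <= highs[None, :])
    if not hit.any(axis=1).all():
        raise ValueError("age not covered by inhalation-rate table")
    return means[hit.argmax(axis=1)]


def _pinned_population(model: RiskModel, region_id: str, n: int,
                       vary: str | None) -> PopulationSample:
    inputs = model.population_inputs
    seed = model.config.seed
    chems = sorted(
        model.exposure.loc[
            (model.exposure["region_id"] == region_id)
            & model.exposure["chemical_id"].isin(model.chemical_roster),
            "chemical_id",
        ].astype(str)
    )
    exp_region = (
        model.exposure[model.exposure["region_id"] == region_id]
        .set_index("chemical_id").loc[chems].reset_index()
    )

    if vary == "age":
        ages = simulate_age(inputs.region_age_dist(region_id), n,
                            substream(seed, region_id, "age"))
    else:
        ages = np.full(n, inputs.median_age(region_id), dtype=int)

    if vary == "obesity":
        pm, ps = inputs.region_obesity(region_id)
        wclass = simulate_obesity(pm, ps, n, substream(seed, region_id, "obesity"))
    else:
        wclass = np.full(n, "Normal")

    ir = _bracket_mean_ir(ages.astype(float), inputs.ir_table)

    if vary == "C_ext":
        exposure = simulate_exposure(
            exp_region.rename(columns={"mean": "mean", "sd": "sd"}), n,
            substream(seed, region_id, "exposure"),
        )
    else:
        exposure = np.tile(exp_region["mean"].to_numpy(dtype=float), (n, 1))

    if vary == "css_params":
        css_draws, _ = simulate_css(model.css, ages, wclass, chems,
                                    substream(seed, region_id, "css"))
    else:
        groups = [age_group_label(int(a), model.css.age_groups) for a in ages]
        medians: dict[tuple[str, str, str], float] = {}
        css_draws = np.empty((n, len(chems)))
        for j, chem in enumerate(chems):
            for i in range(n):
                key = (chem, groups[i], str(wclass[i]))
                if key not in medians:
                    medians[key] = model.css.stratum_median(*key)
                css_draws[i, j] = medians[key]
    return PopulationSample(
        region_id=region_id, chemicals=chems, ages=ages, weight_class=wclass,
        ir=ir, exposure_draws=exposure, css_draws=css_draws,
        css_central=css_draws.copy(), seed_used=int(seed),
    )


def _perturbed_hill_params(model: RiskModel, region_id: str, n: int
                           ) -> list[list[HillParams]]:
    """Per-replicate hill parameter draws: Normal(MLE, se), truncated valid."""
    rng = substream(model.config.seed, region_id, "fit_params")
    reps: list[list[HillParams]] = [[] for _ in range(n)]
    for p in sorted(model.hill_params, key=lambda q: (q.chemical_id, q.assay_id)):
        if not p.converged:
            continue
        se_tp = p.se_tp if np.isfinite(p.se_tp) else 0.0
        se_a = p.se_log10_ac50 if np.isfinite(p.se_log10_ac50) else 0.0
        se_s = p.se_slope if np.isfinite(p.se_slope) else 0.0
        tp = np.clip(rng.normal(p.tp, se_tp, size=n), 1e-6, None)
        a = rng.normal(p.log10_ac50, se_a, size=n)
        s = np.clip(rng.normal(p.slope, se_s, size=n), 0.3, 8.0)
        for i in range(n):
            reps[i].append(
                HillParams(
                    chemical_id=p.chemical_id, assay_id=p.assay_id,
                    tp=float(tp[i]), log10_ac50=float(a[i]), slope=float(s[i]),
                    converged=True,
                )
            )
    return reps


def _run_metric(model: RiskModel, populations: dict[str, PopulationSample],
                metric: str,
                hill_reps: dict[str, list[list[HillParams]]] | None = None
                ) -> pd.DataFrame:
    shadow = RiskModel(
        regions=model.regions, exposure=model.exposure, concresp=model.concresp,
        css=model.css, population_inputs=model.population_inputs,
        config=model.config, hill_params=model.hill_params,
        chemical_roster=model.chemical_roster,
    )
    if hill_reps is None:
        shadow.population = populations
        res = calc_response(shadow)
        if metric not in res.columns:
            raise ValueError(f"metric {metric!r} not produced by configured methods")
        return res[["region_id", "assay_id", "individual", metric]].rename(
            columns={metric: "value"}
        )
    # fit_params varies: evaluate each replicate under its own parameter draw
    frames = []
    for region_id, pop in sorted(populations.items()):
        reps = hill_reps[region_id]
        for i in range(pop.n):
            one = PopulationSample(
                region_id=region_id, chemicals=pop.chemicals,
                ages=pop.ages[i:i + 1], weight_class=pop.weight_class[i:i + 1],
                ir=pop.ir[i:i + 1], exposure_draws=pop.exposure_draws[i:i + 1],
                css_draws=pop.css_draws[i:i + 1],
                css_central=pop.css_central[i:i + 1], seed_used=pop.seed_used,
            )
            shadow.population = {region_id: one}
            shadow.hill_params = reps[i]
            res = calc_response(shadow)
            res["individual"] = i
            frames.append(
                res[["region_id", "assay_id", "individual", metric]].rename(
                    columns={metric: "value"}
                )
            )
    return pd.concat(frames, ignore_index=True)


def compute_sensitivity(model: RiskModel, component: str, n: int | None = None,
                        metric: str = "GCA_Eff") -> SensitivityResult:
    """Vary one component freely, pin the rest, and re-run the pipeline.

    ``component`` is one of :data:`COMPONENTS` or "baseline" (everything
    pinned). Returns replicate values per region × assay × individual and
    the constant baseline per region × assay.
    """
    if component not in COMPONENTS and component != "baseline":
        raise ValueError(f"unknown component {component!r}; expected {COMPONENTS}")
    if n is None:
        n = model.config.effective_n(model.regions.kind)

    region_ids = [
        r for r in model.regions.region_ids
        if not model.exposure[
            (model.exposure["region_id"] == r)
            & model.exposure["chemical_id"].isin(model.chemical_roster)
        ].empty
    ]

    base_pops = {r: _pinned_population(model, r, 1, None) for r in region_ids}
    baseline = (
        _run_metric(model, base_pops, metric)
        .drop(columns="individual")
    )

    vary = None if component == "baseline" else component
    pops = {r: _pinned_population(model, r, n, vary) for r in region_ids}
    if component == "fit_params":
        hill_reps = {r: _perturbed_hill_params(model, r, n) for r in region_ids}
        values = _run_metric(model, pops, metric, hill_reps)
    else:
        values = _run_metric(model, pops, metric)
    return SensitivityResult(
        component=component, metric=metric, values=values, baseline=baseline
    )
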