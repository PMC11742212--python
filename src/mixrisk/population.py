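"""Monte Carlo simulation of region-specific populations.

For every region the pipeline draws, per simulated individual: an age
(multinomial over census-style age brackets, uniform within the bracket),
a weight class (one obesity-prevalence draw per region, then Bernoulli per
individual), an inhalation rate (truncated normal by age bracket,
m³/kg/day), external air-concentration draws per chemical (truncated
normal, µg/m³), and a steady-state plasma concentration Css per chemical
(bootstrap resample from a pre-simulated toxicokinetic sample table,
stratified by age group × weight class, µM per mg/kg/day).

All sampling goes through per-(region, component) substreams
(:mod:`mixrisk.rng`), so results are independent of region order and a
single component can be re-drawn in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rng import substream

__all__ = [
    "PopulationInputs",
    "CssTable",
    "PopulationSample",
    "simulate_age",
    "simulate_obesity",
    "simulate_inhalation_rate",
    "simulate_exposure",
    "simulate_css",
    "simulate_population",
]

#: default age-group labels used to stratify the Css table
DEFAULT_AGE_GROUPS: tuple[tuple[int, int, str], ...] = (
    (0, 17, "0-17"),
    (18, 44, "18-44"),
    (45, 64, "45-64"),
    (65, 150, "65+"),
)

#: open-ended top age brackets ("85+") are sampled uniformly on [85, 99]
MAX_AGE = 99

WEIGHT_CLASSES = ("Normal", "Obese")


def age_group_label(age: int, groups=DEFAULT_AGE_GROUPS) -> str:
    for lo, hi, label in groups:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} not covered by age-group definition")


def _truncated_normal(mean, sd, lower, upper, size, rng: np.random.Generator):
    """Inverse-CDF truncated-normal draws (exact, reproducible, sd=0 safe)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    sd = np.broadcast_to(np.asarray(sd, dtype=float), size).copy()
    u = rng.random(size)
    out = mean.copy()
    var = sd > 0
    if np.any(var):
        a = (lower - mean[var]) / sd[var]
        b = (upper - mean[var]) / sd[var] if np.isfinite(upper) else np.full(var.sum(), np.inf)
        out[var] = stats.truncnorm.ppf(u[var], a, b, loc=mean[var], scale=sd[var])
    else:
        np.clip(out, lower, None if np.isinf(upper) else upper, out=out)
    return out


@dataclass(frozen=True)
class PopulationInputs:
    """Demographic inputs: age brackets, obesity prevalence, inhalation rates.

    ``age_dist``: region_id, age_low, age_high, proportion (sums to 1 per
    region); ``obesity``: region_id, prev_mean, prev_sd; ``ir_table``:
    age_low, age_high, ir_mean (m³/kg/day), ir_sd.
    """

    age_dist: pd.DataFrame
    obesity: pd.DataFrame
    ir_table: pd.DataFrame

    def __post_init__(self):
        sums = self.age_dist.groupby("region_id")["proportion"].sum()
        bad = sums[np.abs(sums - 1.0) > 1e-9]
        if len(bad):
            raise ValueError(
                f"age-bracket proportions must sum to 1 per region; bad: {list(bad.index)}"
            )
        for rid, grp in self.age_dist.groupby("region_id"):
            g = grp.sort_values("age_low")
            if np.any(g["age_high"].to_numpy() < g["age_low"].to_numpy()):
                raise ValueError(f"region {rid}: age_high < age_low")
            if np.any(g["age_low"].to_numpy()[1:] <= g["age_high"].to_numpy()[:-1]):
                raise ValueError(f"region {rid}: overlapping age brackets")
        if np.any(self.ir_table["ir_mean"].to_numpy(dtype=float) <= 0):
            raise ValueError("ir_mean must be > 0")
        # every emittable age must have an inhalation-rate bracket
        for age in range(0, MAX_AGE + 1):
            emittable = np.any(
                (self.age_dist["age_low"] <= age)
                & (np.minimum(self.age_dist["age_high"], MAX_AGE) >= age)
            )
            if emittable and not np.any(
                (self.ir_table["age_low"] <= age) & (self.ir_table["age_high"] >= age)
            ):
                raise ValueError(f"inhalation-rate table does not cover age {age}")

    def region_age_dist(self, region_id: str) -> pd.DataFrame:
        sub = self.age_dist[self.age_dist["region_id"] == region_id]
        if sub.empty:
            raise ValueError(f"no age distribution for region {region_id!r}")
        return sub

    def region_obesity(self, region_id: str) -> tuple[float, float]:
        sub = self.obesity[self.obesity["region_id"] == region_id]
        if sub.empty:
            raise ValueError(f"no obesity prevalence for region {region_id!r}")
        return float(sub["prev_mean"].iloc[0]), float(sub["prev_sd"].iloc[0])

    def median_age(self, region_id: str) -> int:
        """Exact median of the discrete age distribution (bracket-uniform)."""
        sub = self.region_age_dist(region_id).sort_values("age_low")
        ages, probs = [], []
        for row in sub.itertuples(index=False):
            hi = int(min(row.age_high, MAX_AGE))
            span = np.arange(int(row.age_low), hi + 1)
            ages.append(span)
            probs.append(np.full(span.size, row.proportion / span.size))
        ages = np.concatenate(ages)
        probs = np.concatenate(probs)
        cum = np.cumsum(probs)
        return int(ages[np.searchsorted(cum, 0.5)])


@dataclass(frozen=True)
class CssTable:
    """Pre-simulated steady-state plasma concentration samples.

    Long format: chemical_id, age_group, weight_class, sample_value
    (µM per mg/kg/day, > 0). Strata are (chemical × age group × weight
    class); draws are bootstrap resamples within a stratum.
    """

    data: pd.DataFrame
    age_groups: tuple[tuple[int, int, str], ...] = DEFAULT_AGE_GROUPS

    def __post_init__(self):
        required = {"chemical_id", "age_group", "weight_class", "sample_value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Css table missing columns {sorted(missing)}")
        vals = self.data["sample_value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("Css samples must be finite and > 0")
        bad = set(self.data["weight_class"]) - set(WEIGHT_CLASSES)
        if bad:
            raise ValueError(f"unknown weight classes {sorted(bad)}")

    @property
    def chemicals(self) -> list[str]:
        return sorted(self.data["chemical_id"].astype(str).unique())

    def stratum(self, chemical: str, age_group: str, weight_class: str) -> np.ndarray:
        sub = self.data[
            (self.data["chemical_id"] == chemical)
            & (self.data["age_group"] == age_group)
            & (self.data["weight_class"] == weight_class)
        ]
        if sub.empty:
            raise ValueError(
                f"no Css stratum for (chemical={chemical!r}, "
                f"age_group={age_group!r}, weight_class={weight_class!r})"
            )
        return sub["sample_value"].to_numpy(dtype=float)

    def stratum_median(self, chemical: str, age_group: str, weight_class: str) -> float:
        return float(np.median(self.stratum(chemical, age_group, weight_class)))


@dataclass
class PopulationSample:
    """Simulated individuals of one region; matrices are n × |chemicals|."""

    region_id: str
    chemicals: list[str]
    ages: np.ndarray
    weight_class: np.ndarray
    ir: np.ndarray
    exposure_draws: np.ndarray
    css_draws: np.ndarray
    css_central: np.ndarray
    seed_used: int

    @property
    def n(self) -> int:
        return int(self.ages.size)


# ---------------------------------------------------------------------------
# component simulators


def simulate_age(age_dist: pd.DataFrame, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw integer ages: bracket multinomially, then uniform within bracket."""
    props = age_dist["proportion"].to_numpy(dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("age-bracket proportions must sum to 1")
    if n == 0:
        return np.empty(0, dtype=int)
    lows = age_dist["age_low"].to_numpy(dtype=int)
    highs = np.minimum(age_dist["age_high"].to_numpy(dtype=float), MAX_AGE).astype(int)
    idx = rng.choice(len(props), size=n, p=props)
    return rng.integers(lows[idx], highs[idx] + 1)


def simulate_obesity(prev_mean: float, prev_sd: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Weight-class labels: one truncated-normal prevalence draw, then Bernoulli."""
    if not 0.0 <= prev_mean <= 1.0:
        raise ValueError("prev_mean must lie in [0, 1]")
    p_star = float(_truncated_normal(prev_mean, prev_sd, 0.0, 1.0, (1,), rng)[0])
    obese = rng.random(n) < p_star
    return np.where(obese, "Obese", "Normal")


def simulate_inhalation_rate(ages: np.ndarray, ir_table: pd.DataFrame,
                             rng: np.random.Generator) -> np.ndarray:
    """Per-individual inhalation rate (m³/kg/day), truncated normal at 0."""
    lows = ir_table["age_low"].to_numpy(dtype=float)
    highs = ir_table["age_high"].to_numpy(dtype=float)
    means = ir_table["ir_mean"].to_numpy(dtype=float)
    sds = ir_table["ir_sd"].to_numpy(dtype=float)
    ages = np.asarray(ages)
    hit = (ages[:, None] >= lows[None, :]) & (ages[:, None] <= highs[None, :])
    uncovered = ~hit.any(axis=1)
    if np.any(uncovered):
        raise ValueError(
            f"age {int(ages[uncovered][0])} not covered by inhalation-rate table"
        )
    bracket = hit.argmax(axis=1)
    return _truncated_normal(means[bracket], sds[bracket], 0.0, np.inf, ages.shape, rng)


def simulate_exposure(exposure: pd.DataFrame, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """External-concentration draws (µg/m³), n × chemicals, truncated at 0.

    ``exposure`` holds one row per chemical of this region with columns
    ``chemical_id``, ``mean``, ``sd``; columns of the output follow the
    row order of ``exposure``.
    """
    means = exposure["mean"].to_numpy(dtype=float)
    sds = exposure["sd"].to_numpy(dtype=float)
    if np.any(means < 0) or np.any(sds < 0):
        raise ValueError("exposure mean and sd must be >= 0")
    out = np.empty((n, len(means)))
    for j in range(len(means)):  # one column at a time: stable draw order
        out[:, j] = _truncated_normal(means[j], sds[j], 0.0, np.inf, (n,), rng)
    return out


def simulate_css(css_table: CssTable, ages: np.ndarray, weight_class: np.ndarray,
                 chemicals: list[str], rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap Css draws and stratum medians, both n × |chemicals|."""
    n = len(ages)
    groups = np.array([age_group_label(int(a), css_table.age_groups) for a in ages]) \
        if n else np.empty(0, dtype=str)
    draws = np.empty((n, len(chemicals)))
    central = np.empty((n, len(chemicals)))
    for j, chem in enumerate(chemicals):
        strata = sorted(set(zip(groups.tolist(), np.asarray(weight_class).tolist())))
        for grp, wc in strata:
            mask = (groups == grp) & (np.asarray(weight_class) == wc)
            samples = css_table.stratum(chem, grp, wc)
            idx = rng.integers(0, samples.size, size=int(mask.sum()))
            draws[mask, j] = samples[idx]
            central[mask, j] = np.median(samples)
    return draws, central


# ---------------------------------------------------------------------------
# orchestration


def simulate_population(region_id: str, chemicals: list[str],
                        exposure_region: pd.DataFrame, inputs: PopulationInputs,
                        css_table: CssTable, n: int, seed: int) -> PopulationSample:
    """Simulate all components of one region from its dedicated substreams."""
    ages = simulate_age(inputs.region_age_dist(region_id), n,
                        substream(seed, region_id, "age"))
    prev_mean, prev_sd = inputs.region_obesity(region_id)
    wclass = simulate_obesity(prev_mean, prev_sd, n,
                              substream(seed, region_id, "obesity"))
    ir = simulate_inhalation_rate(ages, inputs.ir_table,
                                  substream(seed, region_id, "inhalation"))
    exp_sorted = (
        exposure_region.set_index("chemical_id").loc[chemicals].reset_index()
        .rename(columns={"index": "chemical_id"})
    )
    exposure = simulate_exposure(exp_sorted, n, substream(seed, region_id, "exposure"))
    css_draws, css_central = simulate_css(
        css_table, ages, wclass, chemicals, substream(seed, region_id, "css")
    )
    return PopulationSample(
        region_id=region_id, chemicals=list(chemicals), ages=ages,
        weight_class=wclass, ir=ir, exposure_draws=exposure,
        css_draws=css_draws, css_central=css_central, seed_used=int(seed),
    )
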