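"""The risk-model assemblage linking every pipeline stage.

A :class:`RiskModel` carries the region geometries, the exposure table,
the concentration-response data and fitted hill curves, the simulated
populations, and the computed mixture results, together with the run
configuration and provenance. Assembly enforces the chemical-intersection
rule: only chemicals present in the exposure table AND with a converged
hill fit AND with toxicokinetic (Css) samples enter the roster; everything
downstream references roster chemicals only. Dropped chemicals are logged
and retained in provenance, never silently discarded.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .dose_response import HillParams, fit_hill
from .population import CssTable, PopulationInputs, PopulationSample, simulate_population

logger = logging.getLogger("mixrisk")

__all__ = ["RegionSet", "RunConfig", "RiskModel", "assemble_model", "model_summary"]


@dataclass(frozen=True)
class RegionSet:
    """Georeferenced analysis units: polygons (areas) or points (individuals).

    Coordinates are WGS84 lon/lat; inputs in other CRSs are reprojected at
    load time. ``kind`` is uniform across features: "area" for
    (multi)polygons, "point" for point locations such as residential
    addresses.
    """

    frame: pd.DataFrame  # columns: region_id, geometry (shapely)
    kind: str

    def __post_init__(self):
        ids = self.frame["region_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate region_id {dup!r} in boundaries")
        if (ids.str.strip() == "").any():
            raise ValueError("empty region_id in boundaries")
        if self.kind not in ("area", "point"):
            raise ValueError(f"kind must be 'area' or 'point', got {self.kind!r}")
        for geom in self.frame["geometry"]:
            if not isinstance(geom, BaseGeometry) or geom.is_empty or not geom.is_valid:
                raise ValueError("invalid or empty geometry in boundaries")
            is_point = geom.geom_type == "Point"
            if is_point != (self.kind == "point"):
                raise ValueError("geometry type does not match RegionSet kind")

    @property
    def region_ids(self) -> list[str]:
        return sorted(self.frame["region_id"].astype(str))

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_features(cls, features: list[tuple[str, BaseGeometry]]) -> "RegionSet":
        frame = pd.DataFrame(features, columns=["region_id", "geometry"])
        kind = "point" if frame["geometry"].iloc[0].geom_type == "Point" else "area"
        return cls(frame=frame, kind=kind)

    @classmethod
    def from_geojson_dict(cls, obj: dict) -> "RegionSet":
        feats = []
        for f in obj.get("features", []):
            props = f.get("properties") or {}
            if "region_id" not in props:
                raise ValueError("GeoJSON feature missing 'region_id' property")
            feats.append((str(props["region_id"]), shapely_shape(f["geometry"])))
        if not feats:
            raise ValueError("GeoJSON contains no features")
        return cls.from_features(feats)

    def to_geojson_dict(self) -> dict:
        from shapely.geometry import mapping

        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"region_id": str(rid)},
                    "geometry": mapping(geom),
                }
                for rid, geom in sorted(
                    zip(self.frame["region_id"], self.frame["geometry"]),
                    key=lambda t: str(t[0]),
                )
            ],
        }


@dataclass(frozen=True)
class RunConfig:
    """Tunable run parameters; defaults follow the pipeline's conventions.

    ``time_days`` defaults to 1 (the steady-state plasma assumption is
    reached within a day); ``dose_scaling`` 1e-3 converts µg to mg;
    ``hq_percent`` sets the hazard-quotient reference response as a
    percent of the assay's maximal response.
    """

    seed: int = 0
    #: None = automatic (100 for area regions, 1 for point locations)
    n_per_region: int | None = None
    time_days: float = 1.0
    dose_scaling: float = 1e-3
    hq_percent: float = 10.0
    mixture_methods: tuple[str, ...] = ("GCA", "IA")
    assay_quantiles: tuple[float, ...] = (10.0, 50.0, 90.0)
    summary_quantiles: tuple[float, ...] = (5.0, 10.0)
    fixed_slope: bool = True

    def __post_init__(self):
        if self.n_per_region is not None and self.n_per_region < 1:
            raise ValueError("n_per_region must be >= 1")
        if not 0.0 < self.hq_percent < 100.0:
            raise ValueError("hq_percent must lie in (0, 100)")
        for q in tuple(self.assay_quantiles) + tuple(self.summary_quantiles):
            if not 0.0 <= q <= 100.0:
                raise ValueError(f"percentile {q} outside [0, 100]")
        unknown = set(self.mixture_methods) - {"GCA", "IA"}
        if unknown:
            raise ValueError(f"unknown mixture methods {sorted(unknown)}")
        if not self.mixture_methods:
            raise ValueError("at least one mixture method required")

    def effective_n(self, kind: str) -> int:
        if self.n_per_region is not None:
            return int(self.n_per_region)
        return 1 if kind == "point" else 100

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_per_region": None if self.n_per_region is None else int(self.n_per_region),
            "time_days": float(self.time_days),
            "dose_scaling": float(self.dose_scaling),
            "hq_percent": float(self.hq_percent),
            "mixture_methods": list(self.mixture_methods),
            "assay_quantiles": [float(q) for q in self.assay_quantiles],
            "summary_quantiles": [float(q) for q in self.summary_quantiles],
            "fixed_slope": bool(self.fixed_slope),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("mixture_methods", "assay_quantiles", "summary_quantiles"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)


@dataclass
class RiskModel:
    """Assembled state of one analysis: inputs, fits, simulations, results."""

    regions: RegionSet
    exposure: pd.DataFrame
    concresp: pd.DataFrame | None
    css: CssTable
    population_inputs: PopulationInputs
    config: RunConfig
    hill_params: list[HillParams] = field(default_factory=list)
    chemical_roster: list[str] = field(default_factory=list)
    population: dict[str, PopulationSample] = field(default_factory=dict)
    results: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def simulate(self) -> "RiskModel":
        """Simulate every region's population from per-region substreams."""
        for region_id in self.regions.region_ids:
            sub = self.exposure[self.exposure["region_id"] == region_id]
            sub = sub[sub["chemical_id"].isin(self.chemical_roster)]
            if sub.empty:
                continue
            n = self.config.effective_n(self.regions.kind)
            self.population[region_id] = simulate_population(
                region_id, sorted(sub["chemical_id"].astype(str)), sub,
                self.population_inputs, self.css, n, self.config.seed,
            )
        self.provenance["n_simulated"] = {
            r: p.n for r, p in sorted(self.population.items())
        }
        return self


def _roster(exposure_chems: set[str], fit_chems: set[str], css_chems: set[str]
            ) -> tuple[list[str], list[tuple[str, str]]]:
    roster = sorted(exposure_chems & fit_chems & css_chems)
    dropped = []
    for chem in sorted(exposure_chems | fit_chems | css_chems):
        if chem in roster:
            continue
        reasons = []
        if chem not in exposure_chems:
            reasons.append("no exposure data")
        if chem not in fit_chems:
            reasons.append("no converged dose-response fit")
        if chem not in css_chems:
            reasons.append("no toxicokinetic (Css) samples")
        dropped.append((chem, "; ".join(reasons)))
    return roster, dropped


def assemble_model(regions: RegionSet, exposure: pd.DataFrame,
                   concresp: pd.DataFrame | None, css: CssTable,
                   population_inputs: PopulationInputs, config: RunConfig,
                   hill_params: list[HillParams] | None = None) -> RiskModel:
    """Assemble the model and compute the chemical roster.

    The roster is the three-way intersection of chemicals with exposure
    data, converged hill fits (fitted here from ``concresp`` unless
    pre-fitted ``hill_params`` are supplied), and Css samples. Chemicals
    failing any leg are dropped with a logged reason and recorded in
    provenance.
    """
    required = {"region_id", "chemical_id", "mean", "sd"}
    missing = required - set(exposure.columns)
    if missing:
        raise ValueError(f"exposure table missing columns {sorted(missing)}")
    exposure = exposure.copy()
    exposure["chemical_id"] = exposure["chemical_id"].astype(str).str.strip()
    exposure["region_id"] = exposure["region_id"].astype(str)
    dup = exposure.duplicated(subset=["region_id", "chemical_id"])
    if dup.any():
        row = exposure[dup].iloc[0]
        raise ValueError(
            f"duplicate exposure row for (region {row['region_id']!r}, "
            f"chemical {row['chemical_id']!r})"
        )
    known = set(regions.region_ids)
    stray = sorted(set(exposure["region_id"]) - known)
    if stray:
        raise ValueError(f"exposure region id {stray[0]!r} absent from boundaries")

    if hill_params is None:
        if concresp is None:
            raise ValueError("either concresp data or pre-fitted hill_params required")
        hill_params = fit_hill(concresp, fixed_slope=config.fixed_slope)

    exposure_chems = set(exposure["chemical_id"])
    fit_chems = {p.chemical_id for p in hill_params if p.converged}
    css_chems = set(css.chemicals)
    roster, dropped = _roster(exposure_chems, fit_chems, css_chems)
    if not roster:
        raise ValueError("no analyzable chemicals: empty roster intersection")
    for chem, reason in dropped:
        logger.warning("chemical %s dropped from roster: %s", chem, reason)

    provenance = {
        "seed": int(config.seed),
        "assembled_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "n_regions": len(regions),
        "n_roster_chemicals": len(roster),
        "dropped_chemicals": [
            {"chemical_id": c, "reason": r} for c, r in dropped
        ],
    }
    return RiskModel(
        regions=regions, exposure=exposure, concresp=concresp, css=css,
        population_inputs=population_inputs, config=config,
        hill_params=hill_params, chemical_roster=roster, provenance=provenance,
    )


def _dims(obj) -> str:
    if obj is None:
        return "empty"
    if isinstance(obj, pd.DataFrame):
        return f"{obj.shape[0]} x {obj.shape[1]}"
    if isinstance(obj, (list, tuple, dict)):
        return str(len(obj)) if len(obj) else "empty"
    return "1"


def model_summary(model: RiskModel) -> str:
    """Stable multi-line console summary of the model state."""
    lines = [
        "RiskModel",
        f"  regions: {len(model.regions)} ({model.regions.kind})",
        f"  simulated individuals per region: {model.config.effective_n(model.regions.kind)}",
        f"  chemical roster: {len(model.chemical_roster)} chemicals",
        "  fields:",
    ]
    fields = [
        ("exposure", model.exposure, "DataFrame"),
        ("concresp", model.concresp, "DataFrame"),
        ("hill_params", model.hill_params, "list[HillParams]"),
        ("css", model.css.data, "CssTable"),
        ("population", model.population, "dict[region_id, PopulationSample]"),
        ("results", model.results, "DataFrame"),
        ("summary", model.summary, "DataFrame"),
    ]
    for name, obj, cls in fields:
        lines.append(f"    {name:<12} {cls:<34} {_dims(obj)}")
    return "\n".join(lines)
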