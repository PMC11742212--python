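"""Readers and writers for boundaries, input tables, and result artifacts.

Boundaries are GeoJSON FeatureCollections whose features carry a
``region_id`` property; geometries are normalized to WGS84 lon/lat at
load (a ``crs`` member naming EPSG:3857 triggers the inverse Web Mercator
transform). Tables are UTF-8 comma-separated CSV with a header row.

Outputs are deterministic: tables are written with sorted keys and fixed
column order, manifests carry no timestamps, so a rerun at the same seed
produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.ops import transform as shapely_transform

from .dose_response import hill_params_frame, hill_params_from_frame
from .model import RegionSet, RiskModel, RunConfig
from .population import CssTable, PopulationInputs, PopulationSample

logger = logging.getLogger("mixrisk")

__all__ = [
    "load_boundaries",
    "load_inputs",
    "write_results",
    "save_model",
    "load_model",
]

_EARTH_RADIUS = 6378137.0  # WGS84 semi-major axis, metres


def _web_mercator_to_wgs84(x, y):
    """Inverse spherical (Web) Mercator: EPSG:3857 metres -> lon/lat degrees."""
    lon = np.degrees(np.asarray(x, dtype=float) / _EARTH_RADIUS)
    lat = np.degrees(
        2.0 * np.arctan(np.exp(np.asarray(y, dtype=float) / _EARTH_RADIUS))
        - math.pi / 2.0
    )
    return lon, lat


def _geojson_crs_code(obj: dict) -> str | None:
    crs = obj.get("crs")
    if not crs:
        return None
    name = str(crs.get("properties", {}).get("name", ""))
    for tok in (":", "::"):
        if tok in name:
            code = name.rsplit(tok, 1)[-1]
            if code.isdigit():
                return code
    return None


def load_boundaries(path: str | os.PathLike) -> RegionSet:
    """Read a GeoJSON FeatureCollection into a WGS84 :class:`RegionSet`."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    regions = RegionSet.from_geojson_dict(obj)
    code = _geojson_crs_code(obj)
    if code == "3857":
        frame = regions.frame.copy()
        frame["geometry"] = frame["geometry"].map(
            lambda g: shapely_transform(_web_mercator_to_wgs84, g)
        )
        regions = RegionSet(frame=frame, kind=regions.kind)
    elif code not in (None, "4326"):
        raise ValueError(f"unsupported boundary CRS EPSG:{code}")
    logger.info("loaded %d regions (%s) from %s", len(regions), regions.kind, path)
    return regions


def _read_csv(path: str | os.PathLike, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    logger.info("loaded %d rows from %s", len(df), path)
    return df


def load_exposure(path) -> pd.DataFrame:
    return _read_csv(path, {"region_id", "chemical_id", "mean", "sd"}).astype(
        {"region_id": str, "chemical_id": str}
    )


def load_concresp(path) -> pd.DataFrame:
    return _read_csv(path, {"chemical_id", "assay_id", "conc_um", "response"}).astype(
        {"chemical_id": str, "assay_id": str}
    )


def load_css(path) -> CssTable:
    df = _read_csv(path, {"chemical_id", "age_group", "weight_class", "sample_value"})
    return CssTable(df.astype({"chemical_id": str, "age_group": str, "weight_class": str}))


def load_population_inputs(age_dist_path, obesity_path, ir_table_path) -> PopulationInputs:
    return PopulationInputs(
        age_dist=_read_csv(
            age_dist_path, {"region_id", "age_low", "age_high", "proportion"}
        ).astype({"region_id": str}),
        obesity=_read_csv(
            obesity_path, {"region_id", "prev_mean", "prev_sd"}
        ).astype({"region_id": str}),
        ir_table=_read_csv(ir_table_path, {"age_low", "age_high", "ir_mean", "ir_sd"}),
    )


def load_inputs(paths: dict) -> tuple[RegionSet, pd.DataFrame, pd.DataFrame, CssTable, PopulationInputs]:
    """Load every pipeline input from a path mapping.

    ``paths`` keys: boundaries, exposure, concresp, css, age_dist, obesity,
    ir_table.
    """
    required = {"boundaries", "exposure", "concresp", "css", "age_dist",
                "obesity", "ir_table"}
    missing = required - set(paths)
    if missing:
        raise ValueError(f"missing input path(s): {sorted(missing)}")
    return (
        load_boundaries(paths["boundaries"]),
        load_exposure(paths["exposure"]),
        load_concresp(paths["concresp"]),
        load_css(paths["css"]),
        load_population_inputs(paths["age_dist"], paths["obesity"], paths["ir_table"]),
    )


# ---------------------------------------------------------------------------
# writing


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, lineterminator="\n")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _population_frame(pop: PopulationSample) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "individual": np.arange(pop.n),
            "age": pop.ages,
            "weight_class": pop.weight_class,
            "ir": pop.ir,
        }
    )
    for j, chem in enumerate(pop.chemicals):
        frame[f"exposure_{chem}"] = pop.exposure_draws[:, j]
        frame[f"css_{chem}"] = pop.css_draws[:, j]
        frame[f"css_central_{chem}"] = pop.css_central[:, j]
    return frame


def write_results(model: RiskModel, out_dir: str | os.PathLike) -> dict:
    """Write the model's tables to ``out_dir``; return the manifest.

    The file set is deterministic (sorted keys, fixed column order, no
    timestamps): writing the same model twice yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, int] = {}

    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(model.config.to_dict(), fh, sort_keys=True)
    files["config.yaml"] = 1

    with open(out / "boundaries.geojson", "w", encoding="utf-8") as fh:
        json.dump(model.regions.to_geojson_dict(), fh, sort_keys=True)
    files["boundaries.geojson"] = len(model.regions)

    exposure = model.exposure.sort_values(["region_id", "chemical_id"]).reset_index(drop=True)
    _write_csv(exposure, out / "exposure.csv")
    files["exposure.csv"] = len(exposure)

    if model.hill_params:
        hp = hill_params_frame(model.hill_params).sort_values(
            ["chemical_id", "assay_id"]
        ).reset_index(drop=True)
        _write_csv(hp, out / "hill_params.csv")
        files["hill_params.csv"] = len(hp)

    roster = pd.DataFrame({"chemical_id": sorted(model.chemical_roster)})
    _write_csv(roster, out / "roster.csv")
    files["roster.csv"] = len(roster)

    dropped = pd.DataFrame(
        model.provenance.get("dropped_chemicals", []),
        columns=["chemical_id", "reason"],
    )
    _write_csv(dropped, out / "dropped_chemicals.csv")
    files["dropped_chemicals.csv"] = len(dropped)

    for region_id in sorted(model.population):
        name = f"population_{region_id}.csv"
        frame = _population_frame(model.population[region_id])
        _write_csv(frame, out / name)
        files[name] = len(frame)

    if model.results is not None:
        res = model.results.sort_values(
            ["region_id", "assay_id", "individual"]
        ).reset_index(drop=True)
        _write_csv(res, out / "results.csv")
        files["results.csv"] = len(res)

    if model.summary is not None:
        _write_csv(model.summary, out / "summary.csv")
        files["summary.csv"] = len(model.summary)

    manifest = {
        "config_sha256": _config_hash(model.config),
        "files": {k: files[k] for k in sorted(files)},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# model directory round trip (lets CLI subcommands compose)


def save_model(model: RiskModel, out_dir: str | os.PathLike) -> dict:
    """Serialize the full model state to a directory (superset of write_results)."""
    out = Path(out_dir)
    manifest = write_results(model, out)
    if model.concresp is not None:
        _write_csv(
            model.concresp.sort_values(
                ["chemical_id", "assay_id", "conc_um"]
            ).reset_index(drop=True),
            out / "concresp.csv",
        )
    _write_csv(
        model.css.data.sort_values(
            ["chemical_id", "age_group", "weight_class"]
        ).reset_index(drop=True),
        out / "css.csv",
    )
    pi = model.population_inputs
    _write_csv(pi.age_dist.sort_values(["region_id", "age_low"]).reset_index(drop=True),
               out / "age_dist.csv")
    _write_csv(pi.obesity.sort_values("region_id").reset_index(drop=True),
               out / "obesity.csv")
    _write_csv(pi.ir_table.sort_values("age_low").reset_index(drop=True),
               out / "ir_table.csv")
    return manifest


def load_model(model_dir: str | os.PathLike) -> RiskModel:
    """Reconstruct a model from a :func:`save_model` directory."""
    d = Path(model_dir)
    with open(d / "config.yaml", encoding="utf-8") as fh:
        config = RunConfig.from_dict(yaml.safe_load(fh))
    regions = load_boundaries(d / "boundaries.geojson")
    exposure = load_exposure(d / "exposure.csv")
    concresp = load_concresp(d / "concresp.csv") if (d / "concresp.csv").exists() else None
    css = load_css(d / "css.csv")
    inputs = load_population_inputs(d / "age_dist.csv", d / "obesity.csv",
                                    d / "ir_table.csv")
    hill_params = []
    if (d / "hill_params.csv").exists():
        hill_params = hill_params_from_frame(pd.read_csv(d / "hill_params.csv"))
    roster = pd.read_csv(d / "roster.csv")["chemical_id"].astype(str).tolist() \
        if (d / "roster.csv").exists() else []

    model = RiskModel(
        regions=regions, exposure=exposure, concresp=concresp, css=css,
        population_inputs=inputs, config=config, hill_params=hill_params,
        chemical_roster=roster,
    )
    for f in sorted(d.glob("population_*.csv")):
        region_id = f.stem[len("population_"):]
        frame = pd.read_csv(f)
        chems = sorted(
            c[len("exposure_"):] for c in frame.columns if c.startswith("exposure_")
        )
        model.population[region_id] = PopulationSample(
            region_id=region_id, chemicals=chems,
            ages=frame["age"].to_numpy(dtype=int),
            weight_class=frame["weight_class"].to_numpy(dtype=str),
            ir=frame["ir"].to_numpy(dtype=float),
            exposure_draws=frame[[f"exposure_{c}" for c in chems]].to_numpy(dtype=float),
            css_draws=frame[[f"css_{c}" for c in chems]].to_numpy(dtype=float),
            css_central=frame[[f"css_central_{c}" for c in chems]].to_numpy(dtype=float),
            seed_used=config.seed,
        )
    if (d / "results.csv").exists():
        model.results = pd.read_csv(d / "results.csv").astype(
            {"region_id": str, "assay_id": str}
        )
    if (d / "summary.csv").exists():
        model.summary = pd.read_csv(d / "summary.csv").astype({"region_id": str})
    return model
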