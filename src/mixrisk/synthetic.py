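"""Synthetic study generator with known ground truth.

Emulates the shape of the real inputs — census-tract style air
concentrations, demographic tables, screening concentration-response
curves, and pre-simulated toxicokinetic (Css) samples — at arbitrary
scale, so the whole pipeline runs and can be validated without any
download. Truth (hill parameters, exposure means) is retained so recovery
can be scored exactly.

What it deliberately does NOT emulate: spatial autocorrelation of real
exposure surfaces, real assay curve shapes beyond the hill family, and
demographic covariance structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from .dose_response import _hill
from .model import RegionSet
from .population import DEFAULT_AGE_GROUPS, CssTable, PopulationInputs

__all__ = ["SyntheticStudy", "gen_synthetic_study", "write_study"]

#: inhalation-rate brackets (m³/kg/day), monotone decreasing with age as in
#: exposure-factor reference tables (children breathe more per kg)
_IR_BRACKETS = (
    (0, 4, 0.60, 0.08),
    (5, 11, 0.42, 0.06),
    (12, 17, 0.33, 0.05),
    (18, 44, 0.25, 0.04),
    (45, 64, 0.22, 0.03),
    (65, 99, 0.20, 0.03),
)

_AGE_BRACKETS = ((0, 4), (5, 11), (12, 17), (18, 44), (45, 64), (65, 84), (85, 99))

#: Obese-stratum Css multiplier: an arbitrary, documented effect size that
#: makes weight-class contrasts visible in grouped densities; not a
#: physiological claim.
OBESE_CSS_FACTOR = 1.2

_CSS_SAMPLES_PER_STRATUM = 50


@dataclass
class SyntheticStudy:
    """Complete input bundle plus the generating truth."""

    regions: RegionSet
    exposure: pd.DataFrame
    concresp: pd.DataFrame
    css: CssTable
    population_inputs: PopulationInputs
    truth: pd.DataFrame  # chemical_id, assay_id, tp, log10_ac50, slope
    seed: int


def _region_ids(n: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n)]


def gen_synthetic_study(n_regions: int = 5, n_chems: int = 4, n_assays: int = 2,
                        n_conc: int = 10, noise_sd: float = 5.0, seed: int = 0,
                        unit_slope: bool = True) -> SyntheticStudy:
    """Generate a deterministic synthetic study.

    Exposure means are log-normal with sd fixed at 30 % of the mean; true
    hill tops lie in [50, 120] % activity, log10 AC50 in [−1, 1] (µM),
    slope 1 (or sampled in [0.8, 3] when ``unit_slope=False``); responses
    carry additive Normal(0, noise_sd) noise at ``n_conc`` log-spaced
    concentrations × 3 replicates. When the study has ≥ 2 assays and ≥ 2
    chemicals, the last assay omits the last chemical so partial assay
    coverage is always exercised.
    """
    if min(n_regions, n_chems, n_assays, n_conc) < 1:
        raise ValueError("all counts must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    region_ids = _region_ids(n_regions)
    ncol = int(np.ceil(np.sqrt(n_regions)))
    feats = []
    for i, rid in enumerate(region_ids):
        r, c = divmod(i, ncol)
        # unit-degree grid cells near (-80, 35): plausible mid-latitude extent
        feats.append((rid, box(-80.0 + c, 35.0 - r - 1.0, -79.0 + c, 35.0 - r)))
    regions = RegionSet.from_features(feats)

    chems = [f"{100 + i}-{10 + i}-{i % 10}" for i in range(n_chems)]  # CASRN-like
    assays = [f"ASSAY_{chr(65 + i)}" for i in range(n_assays)]

    exp_rows = []
    for rid in region_ids:
        means = rng.lognormal(mean=np.log(2.0), sigma=0.6, size=n_chems)
        for chem, m in zip(chems, means):
            exp_rows.append((rid, chem, float(m), float(0.3 * m)))
    exposure = pd.DataFrame(exp_rows, columns=["region_id", "chemical_id", "mean", "sd"])

    # truth + concentration-response data
    truth_rows, cr_rows = [], []
    concs = np.logspace(-2, 2, n_conc)
    for assay in assays:
        covered = chems[:-1] if (assay == assays[-1] and n_assays >= 2 and n_chems >= 2) \
            else chems
        for chem in covered:
            tp = float(rng.uniform(50.0, 120.0))
            a = float(rng.uniform(-1.0, 1.0))
            s = 1.0 if unit_slope else float(rng.uniform(0.8, 3.0))
            truth_rows.append((chem, assay, tp, a, s))
            clean = _hill(np.repeat(concs, 3), tp, a, s)
            noisy = clean + rng.normal(0.0, noise_sd, size=clean.size)
            for c, y in zip(np.repeat(concs, 3), noisy):
                cr_rows.append((chem, assay, float(c), float(y)))
    truth = pd.DataFrame(
        truth_rows, columns=["chemical_id", "assay_id", "tp", "log10_ac50", "slope"]
    )
    concresp = pd.DataFrame(
        cr_rows, columns=["chemical_id", "assay_id", "conc_um", "response"]
    )

    css_rows = []
    for chem in chems:
        gm = float(rng.uniform(1.0, 10.0))
        for _, _, label in DEFAULT_AGE_GROUPS:
            base = rng.lognormal(mean=np.log(gm), sigma=0.3,
                                 size=_CSS_SAMPLES_PER_STRATUM)
            for wc, factor in (("Normal", 1.0), ("Obese", OBESE_CSS_FACTOR)):
                for v in base * factor:
                    css_rows.append((chem, label, wc, float(v)))
    css = CssTable(pd.DataFrame(
        css_rows, columns=["chemical_id", "age_group", "weight_class", "sample_value"]
    ))

    age_rows = []
    base_props = np.array([0.06, 0.09, 0.08, 0.36, 0.25, 0.13, 0.03])
    for rid in region_ids:
        props = rng.dirichlet(base_props * 200.0)
        for (lo, hi), p in zip(_AGE_BRACKETS, props):
            age_rows.append((rid, lo, hi, float(p)))
    age_dist = pd.DataFrame(
        age_rows, columns=["region_id", "age_low", "age_high", "proportion"]
    )
    obesity = pd.DataFrame(
        {
            "region_id": region_ids,
            "prev_mean": rng.uniform(0.25, 0.40, size=n_regions),
            "prev_sd": np.full(n_regions, 0.03),
        }
    )
    ir_table = pd.DataFrame(
        _IR_BRACKETS, columns=["age_low", "age_high", "ir_mean", "ir_sd"]
    )
    inputs = PopulationInputs(age_dist=age_dist, obesity=obesity, ir_table=ir_table)

    return SyntheticStudy(
        regions=regions, exposure=exposure, concresp=concresp, css=css,
        population_inputs=inputs, truth=truth, seed=int(seed),
    )


def write_study(study: SyntheticStudy, out_dir, n_per_region: int = 100,
                seed: int | None = None) -> Path:
    """Write the study's input files plus a runnable pipeline config.

    Returns the path of the written ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import json

    with open(out / "boundaries.geojson", "w", encoding="utf-8") as fh:
        json.dump(study.regions.to_geojson_dict(), fh, sort_keys=True)
    study.exposure.to_csv(out / "exposure.csv", index=False, lineterminator="\n")
    study.concresp.to_csv(out / "concresp.csv", index=False, lineterminator="\n")
    study.css.data.to_csv(out / "css.csv", index=False, lineterminator="\n")
    pi = study.population_inputs
    pi.age_dist.to_csv(out / "age_dist.csv", index=False, lineterminator="\n")
    pi.obesity.to_csv(out / "obesity.csv", index=False, lineterminator="\n")
    pi.ir_table.to_csv(out / "ir_table.csv", index=False, lineterminator="\n")
    study.truth.to_csv(out / "truth.csv", index=False, lineterminator="\n")

    config = {
        "inputs": {
            "boundaries": "boundaries.geojson",
            "exposure": "exposure.csv",
            "concresp": "concresp.csv",
            "css": "css.csv",
            "age_dist": "age_dist.csv",
            "obesity": "obesity.csv",
            "ir_table": "ir_table.csv",
        },
        "output_dir": "output",
        "seed": int(study.seed if seed is None else seed),
        "n_per_region": int(n_per_region),
    }
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return cfg_path
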