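"""Deterministic calculators: dose conversion, IVIVE, and mixture response.

The chain per individual is

    external air concentration (µg/m³)
      → internal dose rate D = C_ext · IR · time · scaling   (mg/kg/day)
      → in-vitro-equivalent concentration C = D · Css        (µM)
      → mixture response metrics over the assay's chemicals.

Mixture models
--------------
Generalized concentration addition (GCA) finds the effect E solving
``Σᵢ Cᵢ / fᵢ⁻¹(E) = 1`` with fᵢ the chemical's hill curve. With all
slopes equal to 1 this has the closed form

    E = Σ(Cᵢ·tpᵢ/AC50ᵢ) / (1 + Σ(Cᵢ/AC50ᵢ)),

which correctly handles partial agonists (tpᵢ below the mixture effect
pull it down). For general slopes the root is found numerically on
E ∈ (0, min tpᵢ).

Independent action (IA) multiplies survival fractions normalized to a
reference maximum e_ref = maxᵢ tpᵢ:

    E = e_ref · (1 − Πᵢ (1 − fᵢ(Cᵢ)/e_ref)).

The hazard quotient (HQ) scales the whole mixture at fixed ratio until the
chosen model reaches the reference response (hq_percent % of e_ref):
``HQ = 1/s*`` with ``response(s*·C) = (hq_percent/100)·e_ref``. HQ > 1
means the mixture already exceeds the reference level. The classical
hazard-index convention ``Σ Cᵢ/ECpᵢ`` is available as an option.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .dose_response import HillParams, _hill, hill_inverse

__all__ = [
    "calc_internal_dose",
    "calc_invitro_concentration",
    "response_gca",
    "response_ia",
    "calc_hq",
    "calc_response",
]

_LOG10_S_RANGE = (-12.0, 12.0)


def calc_internal_dose(c_ext, ir, time_days: float = 1.0,
                       dose_scaling: float = 1e-3):
    """Internal dose rate (mg/kg/day) from inhaled air concentration.

    ``D = c_ext · ir · time_days · dose_scaling``; the inhalation rate is
    carried per kg body weight (m³/kg/day), so body weight needs no
    explicit division, and the default scaling 1e-3 converts µg to mg.
    """
    c_ext = np.asarray(c_ext, dtype=float)
    ir = np.asarray(ir, dtype=float)
    if np.any(c_ext < 0) or np.any(ir < 0) or time_days < 0 or dose_scaling < 0:
        raise ValueError("all inputs to calc_internal_dose must be >= 0")
    out = c_ext * ir * time_days * dose_scaling
    return float(out) if out.ndim == 0 else out


def calc_invitro_concentration(d_int, css):
    """In-vitro-equivalent concentration (µM): elementwise D · Css."""
    d_int = np.asarray(d_int, dtype=float)
    css = np.asarray(css, dtype=float)
    if d_int.shape != css.shape:
        raise ValueError(f"shape mismatch: dose {d_int.shape} vs Css {css.shape}")
    if np.any(d_int < 0) or np.any(css < 0):
        raise ValueError("dose and Css must be >= 0")
    out = d_int * css
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# mixture models


def _params_arrays(params: list[HillParams]):
    tp = np.array([p.tp for p in params])
    ac50 = np.array([p.ac50 for p in params])
    slope = np.array([p.slope for p in params])
    if not all(p.converged for p in params):
        raise ValueError("all hill fits must be converged")
    return tp, ac50, slope


def _gca_closed_form(concs, tp, ac50):
    """Slope-1 closed form, vectorized over rows of ``concs``.

    Elementwise multiply + reduce (not BLAS matmul) so identical rows give
    bitwise-identical effects — required for exact zero-variance baselines.
    """
    num = np.sum(concs * (tp / ac50), axis=1)
    den = 1.0 + np.sum(concs * (1.0 / ac50), axis=1)
    return num / den


def _gca_root(concs, tp, ac50, slope):
    """GCA effect by monotone root finding on Σ Cᵢ/fᵢ⁻¹(E) = 1.

    For slope-1 chemicals the generalized inverse ``AC50·E/(tp−E)`` extends
    algebraically past the top (negative branch), which is what lets GCA
    handle partial agonists: the admissible interval is (0, max tp). A
    chemical with non-unit slope has no real inverse above its own top, so
    such mixtures are restricted to E below the smallest non-unit-slope top.
    """
    active = concs > 0
    if not np.any(active):
        return 0.0
    c, t, a, s = concs[active], tp[active], ac50[active], slope[active]
    unit = np.isclose(s, 1.0)
    e_hi = float(np.min(t[~unit])) if np.any(~unit) else float(np.max(t))

    def g(e):
        inv = np.empty_like(t)
        inv[unit] = a[unit] * e / (t[unit] - e)  # extended inverse, sign-carrying
        if np.any(~unit):
            inv[~unit] = a[~unit] * (e / (t[~unit] - e)) ** (1.0 / s[~unit])
        return float(np.sum(c / inv)) - 1.0

    hi = e_hi * (1.0 - 1e-12)
    lo = e_hi * 1e-300
    if g(hi) > 0.0:
        warnings.warn(
            "GCA has no root in the admissible effect interval; "
            "returning the interval bound",
            RuntimeWarning, stacklevel=3,
        )
        return hi
    return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-15, maxiter=200))


def response_gca(concs, params: list[HillParams]) -> float:
    """GCA mixture effect (% activity) of one concentration vector (µM)."""
    concs = np.asarray(concs, dtype=float)
    if np.any(concs < 0):
        raise ValueError("concentrations must be >= 0")
    tp, ac50, slope = _params_arrays(params)
    if concs.shape != tp.shape:
        raise ValueError("one concentration per chemical required")
    if not np.any(concs > 0):
        return 0.0
    if np.allclose(slope, 1.0):
        return float(_gca_closed_form(concs[None, :], tp, ac50)[0])
    return _gca_root(concs, tp, ac50, slope)


def response_ia(concs, params: list[HillParams], e_ref: float | None = None) -> float:
    """IA mixture effect (% activity); e_ref defaults to maxᵢ tpᵢ."""
    concs = np.asarray(concs, dtype=float)
    if np.any(concs < 0):
        raise ValueError("concentrations must be >= 0")
    tp, ac50, slope = _params_arrays(params)
    if e_ref is None:
        e_ref = float(np.max(tp))
    if e_ref <= 0:
        raise ValueError("e_ref must be > 0")
    effects = np.array(
        [_hill(np.array(c), t, np.log10(a), s)
         for c, t, a, s in zip(concs, tp, ac50, slope)]
    ).ravel()
    return float(e_ref * (1.0 - np.prod(1.0 - effects / e_ref)))


def calc_hq(concs, params: list[HillParams], hq_percent: float = 10.0,
            method: str = "GCA", e_ref: float | None = None,
            convention: str = "fixed_ratio") -> float:
    """Hazard quotient of a mixture at the hq_percent reference response.

    ``fixed_ratio`` (default): find s* with response(s*·C) equal to
    (hq_percent/100)·e_ref by monotone bracketing on log10 s ∈ [−12, 12];
    HQ = 1/s*. If the model's asymptote never reaches the reference, the
    target is unreachable and HQ = 0 is returned with a warning.
    ``hazard_index``: classical Σᵢ Cᵢ/ECpᵢ with ECpᵢ the chemical's own
    concentration at hq_percent % of its top.
    """
    if not 0.0 < hq_percent < 100.0:
        raise ValueError("hq_percent must lie in (0, 100)")
    concs = np.asarray(concs, dtype=float)
    if np.any(concs < 0):
        raise ValueError("concentrations must be >= 0")
    tp, ac50, slope = _params_arrays(params)
    if not np.any(concs > 0):
        return 0.0

    if convention == "hazard_index":
        active = concs > 0
        ecp = np.array(
            [hill_inverse(hq_percent / 100.0 * p.tp, p) for p in params]
        )
        return float(np.sum(concs[active] / ecp[active]))
    if convention != "fixed_ratio":
        raise ValueError(f"unknown HQ convention {convention!r}")

    if e_ref is None:
        e_ref = float(np.max(tp))
    target = hq_percent / 100.0 * e_ref

    if method == "GCA" and np.allclose(slope, 1.0):
        # closed form: E(s·C) = sA/(1+sB) = target ⇒ s* = T/(A − T·B)
        a = float(concs @ (tp / ac50))
        b = float(concs @ (1.0 / ac50))
        if a / b <= target:
            warnings.warn("HQ target unreachable; returning 0", RuntimeWarning,
                          stacklevel=2)
            return 0.0
        s_star = target / (a - target * b)
        return 1.0 / s_star

    if method == "GCA":
        resp = lambda s: response_gca(s * concs, params)
    elif method == "IA":
        resp = lambda s: response_ia(s * concs, params, e_ref=e_ref)
    else:
        raise ValueError(f"unknown mixture method {method!r}")

    lo, hi = _LOG10_S_RANGE
    f = lambda ls: resp(10.0 ** ls) - target
    if f(hi) < 0.0:
        warnings.warn("HQ target unreachable; returning 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    if f(lo) > 0.0:
        warnings.warn("HQ exceeds the bracketing range; returning the bound",
                      RuntimeWarning, stacklevel=2)
        return 10.0 ** (-lo)
    ls_star = optimize.brentq(f, lo, hi, xtol=1e-10, maxiter=200)
    return 10.0 ** (-ls_star)


# ---------------------------------------------------------------------------
# model-level driver


def calc_response(model) -> pd.DataFrame:
    """Compute mixture metrics for every region × assay × individual.

    Requires a simulated population and converged hill fits on the model;
    each assay is evaluated over its covered subset of the chemical roster.
    Returns the long results table (also attached to ``model.results``)
    with one metric column per requested method
    (GCA → GCA_Eff, GCA_HQ; IA → IA_Eff, IA_HQ).
    """
    if not model.population:
        raise ValueError("population not simulated; run simulate first")
    if not model.hill_params:
        raise ValueError("no fitted hill parameters on the model")
    cfg = model.config
    methods = list(cfg.mixture_methods)
    by_assay: dict[str, dict[str, HillParams]] = {}
    for p in model.hill_params:
        if p.converged and p.chemical_id in model.chemical_roster:
            by_assay.setdefault(p.assay_id, {})[p.chemical_id] = p

    frames = []
    for region_id in sorted(model.population):
        pop = model.population[region_id]
        chem_index = {c: j for j, c in enumerate(pop.chemicals)}
        dose = calc_internal_dose(
            pop.exposure_draws, pop.ir[:, None], cfg.time_days, cfg.dose_scaling
        )
        conc_all = calc_invitro_concentration(dose, pop.css_draws)
        for assay_id in sorted(by_assay):
            cover = sorted(set(by_assay[assay_id]) & set(pop.chemicals))
            if not cover:
                continue
            params = [by_assay[assay_id][c] for c in cover]
            cols = [chem_index[c] for c in cover]
            concs = conc_all[:, cols]
            tp = np.array([p.tp for p in params])
            ac50 = np.array([p.ac50 for p in params])
            slope = np.array([p.slope for p in params])
            e_ref = float(np.max(tp))
            rec: dict[str, np.ndarray] = {}
            if "GCA" in methods:
                if np.allclose(slope, 1.0):
                    rec["GCA_Eff"] = _gca_closed_form(concs, tp, ac50)
                else:
                    rec["GCA_Eff"] = np.array(
                        [response_gca(row, params) for row in concs]
                    )
                rec["GCA_HQ"] = np.array(
                    [calc_hq(row, params, cfg.hq_percent, "GCA", e_ref)
                     if row.any() else 0.0 for row in concs]
                )
            if "IA" in methods:
                rec["IA_Eff"] = np.array(
                    [response_ia(row, params, e_ref) for row in concs]
                )
                rec["IA_HQ"] = np.array(
                    [calc_hq(row, params, cfg.hq_percent, "IA", e_ref)
                     if row.any() else 0.0 for row in concs]
                )
            frame = pd.DataFrame(rec)
            frame.insert(0, "individual", np.arange(pop.n))
            frame.insert(0, "assay_id", assay_id)
            frame.insert(0, "region_id", region_id)
            frames.append(frame)
    if not frames:
        raise ValueError("no assay covers any roster chemical")
    results = pd.concat(frames, ignore_index=True)
    model.results = results
    return results
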