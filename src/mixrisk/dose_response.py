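"""Hill concentration-response model: evaluation, inversion, and MLE fitting.

The response of a single chemical in a single assay is modelled with the
log-logistic (hill) curve used throughout high-throughput screening:

    f(c) = tp / (1 + 10^((log10_AC50 - log10 c) * slope))

with ``tp`` the maximal response (top, % activity), ``AC50`` the
concentration at half-maximal response (µM) and ``slope`` the hill
coefficient.  The 2-parameter variant fixes ``slope = 1`` — the form under
which generalized concentration addition has a closed-form mixture solution.

Fitting is maximum likelihood under independent Gaussian residuals with a
free residual scale (``log_sigma``), giving 3 or 4 free parameters per
curve.  Standard errors come from the inverse observed information at the
optimum; curves whose optimizer fails, whose gradient does not vanish,
whose information matrix is not positive definite, or whose solution sits
on a box bound are flagged ``converged=False`` and are excluded from the
chemical roster downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

LN10 = math.log(10.0)

__all__ = ["HillParams", "hill_response", "hill_inverse", "fit_hill", "hill_params_frame"]


@dataclass(frozen=True)
class HillParams:
    """Fitted hill curve for one chemical × assay pair."""

    chemical_id: str
    assay_id: str
    tp: float
    log10_ac50: float
    slope: float = 1.0
    log_sigma: float = float("nan")
    se_tp: float = float("nan")
    se_log10_ac50: float = float("nan")
    se_slope: float = float("nan")
    converged: bool = True
    loglik: float = float("nan")
    aic: float = float("nan")

    @property
    def ac50(self) -> float:
        return 10.0 ** self.log10_ac50


def _hill(conc, tp, log10_ac50, slope):
    """Vectorized hill response; conc = 0 maps to 0 (limit value)."""
    conc = np.asarray(conc, dtype=float)
    out = np.zeros_like(conc)
    pos = conc > 0
    with np.errstate(over="ignore"):
        out[pos] = tp / (1.0 + 10.0 ** ((log10_ac50 - np.log10(conc[pos])) * slope))
    return out


def hill_response(conc, params: HillParams):
    """Evaluate the fitted curve at concentration(s) ``conc`` (µM, > 0)."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentration must be > 0")
    res = _hill(conc, params.tp, params.log10_ac50, params.slope)
    return float(res) if res.ndim == 0 else res


def hill_inverse(effect, params: HillParams):
    """Concentration (µM) producing ``effect`` (% activity) on the fitted curve.

    Inverse of :func:`hill_response`: ``AC50 * (E / (tp - E))**(1/slope)``,
    defined on the open interval (0, tp).
    """
    effect = np.asarray(effect, dtype=float)
    if np.any(effect <= 0) or np.any(effect >= params.tp):
        raise ValueError(f"effect must lie strictly inside (0, {params.tp})")
    conc = params.ac50 * (effect / (params.tp - effect)) ** (1.0 / params.slope)
    return float(conc) if conc.ndim == 0 else conc


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _nll_grad(theta, x, y, fixed_slope):
    """Negative log-likelihood and its analytic gradient.

    theta = (tp, log10_ac50[, slope], log_sigma); x = log10 concentration.
    """
    if fixed_slope:
        tp, a, ls = theta
        s = 1.0
    else:
        tp, a, s, ls = theta
    n = x.size
    with np.errstate(over="ignore"):
        u = 10.0 ** ((a - x) * s)
    denom = 1.0 + u
    f = tp / denom
    r = y - f
    sigma2 = math.exp(2.0 * ls)
    ssr = float(r @ r)
    nll = 0.5 * n * math.log(2.0 * math.pi) + n * ls + ssr / (2.0 * sigma2)

    # df/dθ for each observation
    d_tp = 1.0 / denom
    core = tp * u / denom**2
    d_a = -core * LN10 * s
    common = -(r / sigma2)
    g_tp = float(common @ d_tp)
    g_a = float(common @ d_a)
    g_ls = n - ssr / sigma2
    if fixed_slope:
        grad = np.array([g_tp, g_a, g_ls])
    else:
        d_s = -core * LN10 * (a - x)
        g_s = float(common @ d_s)
        grad = np.array([g_tp, g_a, g_s, g_ls])
    return nll, grad


def _numeric_hessian(theta, x, y, fixed_slope, rel_step=1e-5):
    """Central finite differences of the analytic gradient."""
    k = theta.size
    hess = np.empty((k, k))
    for j in range(k):
        h = rel_step * max(1.0, abs(theta[j]))
        tp_ = theta.copy()
        tp_[j] += h
        _, gp = _nll_grad(tp_, x, y, fixed_slope)
        tm_ = theta.copy()
        tm_[j] -= h
        _, gm = _nll_grad(tm_, x, y, fixed_slope)
        hess[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (hess + hess.T)


def _fit_one(chem: str, assay: str, x: np.ndarray, y: np.ndarray,
             fixed_slope: bool) -> HillParams:
    n_conc = np.unique(x).size
    if n_conc < 5:
        raise ValueError(
            f"curve ({chem}, {assay}): needs >= 5 distinct concentrations, got {n_conc}"
        )
    degenerate = HillParams(
        chemical_id=chem, assay_id=assay, tp=float("nan"),
        log10_ac50=float("nan"), slope=1.0 if fixed_slope else float("nan"),
        converged=False,
    )
    resp_max = float(np.max(y))
    if np.ptp(y) == 0.0 or resp_max <= 0.0:
        # flat or non-positive response: no admissible top, flag instead of raise
        return degenerate

    tp_hi = 1.5 * resp_max
    sd0 = float(np.std(y))
    theta0 = [resp_max, float(np.median(x)), math.log(sd0) if sd0 > 0 else 0.0]
    bounds = [(1e-8, tp_hi), (x.min() - 3.0, x.max() + 3.0), (-12.0, 12.0)]
    if not fixed_slope:
        theta0.insert(2, 1.0)
        bounds.insert(2, (0.3, 8.0))
    theta0 = np.asarray(theta0, dtype=float)

    res = optimize.minimize(
        _nll_grad, theta0, args=(x, y, fixed_slope), jac=True,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    theta = res.x
    nll, grad = _nll_grad(theta, x, y, fixed_slope)
    # Newton polish: L-BFGS-B stops at its own tolerance; a few damped Newton
    # steps drive the gradient to the convergence threshold when the optimum
    # is interior and the information matrix is well conditioned
    for _ in range(20):
        if np.linalg.norm(grad) < 1e-8:
            break
        hess = _numeric_hessian(theta, x, y, fixed_slope)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        cand = theta - step
        if not all(lo < t < hi for t, (lo, hi) in zip(cand, bounds)):
            break
        cand_nll, cand_grad = _nll_grad(cand, x, y, fixed_slope)
        if not np.isfinite(cand_nll) or np.linalg.norm(cand_grad) >= np.linalg.norm(grad):
            break
        theta, nll, grad = cand, cand_nll, cand_grad
    loglik = -nll
    k = theta.size
    aic = 2.0 * k - 2.0 * loglik

    # convergence: vanishing gradient, PD information, interior solution
    on_bound = any(
        abs(t - lo) < 1e-9 or abs(t - hi) < 1e-9 for t, (lo, hi) in zip(theta, bounds)
    )
    grad_ok = float(np.linalg.norm(grad)) < 1e-6
    hess = _numeric_hessian(theta, x, y, fixed_slope)
    try:
        cov = np.linalg.inv(hess)
        pd_ok = bool(np.all(np.linalg.eigvalsh(hess) > 0)) and bool(
            np.all(np.diag(cov) > 0)
        )
    except np.linalg.LinAlgError:
        cov, pd_ok = None, False
    converged = bool(res.success) and grad_ok and pd_ok and not on_bound

    ses = np.sqrt(np.diag(cov)) if cov is not None and pd_ok else np.full(k, np.nan)
    if fixed_slope:
        tp, a, ls = theta
        slope, se_slope = 1.0, 0.0
        se_tp, se_a = ses[0], ses[1]
    else:
        tp, a, slope, ls = theta
        se_tp, se_a, se_slope = ses[0], ses[1], ses[2]
    return HillParams(
        chemical_id=chem, assay_id=assay, tp=float(tp), log10_ac50=float(a),
        slope=float(slope), log_sigma=float(ls), se_tp=float(se_tp),
        se_log10_ac50=float(se_a), se_slope=float(se_slope),
        converged=converged, loglik=float(loglik), aic=float(aic),
    )


def fit_hill(data: pd.DataFrame, fixed_slope: bool = True) -> list[HillParams]:
    """Fit one hill curve per (chemical_id, assay_id) group by MLE.

    Parameters
    ----------
    data
        Concentration-response table with columns ``chemical_id``,
        ``assay_id``, ``conc_um`` (linear µM, > 0) and ``response``
        (% activity; may be negative noise).
    fixed_slope
        Fit the 2-parameter variant (slope fixed at 1) when True, the
        3-parameter variant otherwise.

    Returns
    -------
    list of :class:`HillParams`, sorted by (chemical_id, assay_id).
    """
    required = {"chemical_id", "assay_id", "conc_um", "response"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"concentration-response table missing columns {sorted(missing)}")
    if np.any(data["conc_um"].to_numpy(dtype=float) <= 0):
        raise ValueError("conc_um must be strictly positive")
    vals = data[["conc_um", "response"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite concentration or response values")

    out: list[HillParams] = []
    for (chem, assay), grp in sorted(
        data.groupby(["chemical_id", "assay_id"], sort=True), key=lambda kv: kv[0]
    ):
        x = np.log10(grp["conc_um"].to_numpy(dtype=float))
        y = grp["response"].to_numpy(dtype=float)
        out.append(_fit_one(str(chem), str(assay), x, y, fixed_slope))
    return out


def hill_params_frame(params: list[HillParams]) -> pd.DataFrame:
    """Tabular view of fitted curves, one row per chemical × assay."""
    return pd.DataFrame([vars(p) for p in params])


def hill_params_from_frame(frame: pd.DataFrame) -> list[HillParams]:
    cols = [f.name for f in HillParams.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    out = []
    for row in frame[cols].itertuples(index=False):
        d = dict(zip(cols, row))
        d["converged"] = bool(d["converged"])
        d["chemical_id"] = str(d["chemical_id"])
        d["assay_id"] = str(d["assay_id"])
        out.append(HillParams(**d))
    return out
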