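"""Curve fitting for the analysis chain.

Covers Hill and biphasic-Hill dose-response fits (weighted nonlinear least
squares with log-parameterized midpoints and a fixed multi-start grid),
linear i-V conductance regression, the double-Hill fit of normalized mean
open time versus electrochemical driving force, and the flipped/scaled
overlay of that curve onto mean closed times.

Nonlinear fits are performed on linear concentration with midpoints
parameterized on the log scale (positivity) and, for the biphasic model,
the inhibition midpoint constrained above the activation midpoint by an
ordered parameterization.  Multi-start seeds span the data's x-range with
Hill slopes {1, 2, 4}; the lowest-RSS solution wins, ties broken by the
smaller slope.  Non-convergence is reported in the result, not raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares

from . import idealize as _idealize
from .gating import (
    BiphasicHillParams,
    FeedthroughMotParams,
    HillParams,
    biphasic_po,
    hill_po,
    mot_edf_model,
)

__all__ = [
    "FitResult",
    "fit_hill",
    "fit_biphasic_hill",
    "fit_linear_iv",
    "fit_mot_edf",
    "mct_overlay",
    "dose_response_pipeline",
]


@dataclass
class FitResult:
    """Parameter estimates with standard errors and fit diagnostics."""

    params: dict
    se: dict
    rss: float
    converged: bool
    n_points: int
    message: str = ""
    warnings: list = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def _as_xy(points, y_err=None):
    """Accept (x, y[, y_err]) arrays or a DataFrame with x/y[/y_err]."""
    if isinstance(points, pd.DataFrame):
        x = points["x"].to_numpy(dtype=float)
        y = points["y"].to_numpy(dtype=float)
        if y_err is None and "y_err" in points:
            y_err = points["y_err"].to_numpy(dtype=float)
    else:
        x, y = points
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if y_err is not None:
        y_err = np.asarray(y_err, dtype=float)
        if np.any(~np.isfinite(y_err)) or np.any(y_err <= 0):
            y_err = None
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    return x, y, y_err


def _solve(residual, starts, bounds):
    best = None
    for theta0 in starts:
        try:
            sol = least_squares(
                residual, theta0, bounds=bounds, method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(2 * sol.cost)
        key = (round(rss, 14), sol.x[-1])  # tie-break: smaller last slope
        if best is None or key < best[0]:
            best = (key, sol)
    return best[1] if best is not None else None


def _cov_se(sol, n: int, p: int, transform=None):
    """SE of (possibly transformed) parameters from the Jacobian."""
    rss = float(2 * sol.cost)
    dof = max(n - p, 1)
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = np.linalg.inv(JTJ) * (rss / dof)
        se_raw = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_raw = np.full(p, np.nan)
    if transform is not None:
        se_raw = transform(sol.x, se_raw)
    return se_raw, rss


def fit_hill(points, y_err=None) -> FitResult:
    """Fit ``y = pmax / (1 + (ec50/x)^h)`` by weighted least squares.

    Requires >= 4 points spanning at least one decade of positive x.
    Weights are ``1/y_err**2`` when errors are provided.  Returns a
    ``FitResult`` with params pmax, ec50, h; flat data yields a
    non-converged result rather than an exception.
    """
    x, y, y_err = _as_xy(points, y_err)
    pos = x > 0
    if len(x) < 4:
        raise ValueError("need >= 4 points for a Hill fit")
    if pos.sum() < 2 or x[pos].max() / x[pos].min() < 10:
        raise ValueError("x must span at least one decade")
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return FitResult(
            params={"pmax": float(np.mean(y)), "ec50": math.nan, "h": math.nan},
            se={}, rss=float(((y - y.mean()) ** 2).sum()),
            converged=False, n_points=len(x),
            message="flat response: ec50 unidentifiable",
        )
    w = 1.0 / y_err if y_err is not None else np.ones_like(y)

    def residual(theta):
        pmax, lec50, h = theta
        return w * (hill_po(x, HillParams(pmax, math.exp(lec50), h)) - y)

    lo, hi = math.log(x[pos].min()), math.log(x[pos].max())
    pmax0 = max(float(y.max()), 1e-9)
    starts = [
        (pmax0, l, h0)
        for l in np.linspace(lo, hi, 5)
        for h0 in (1.0, 2.0, 4.0)
    ]
    bounds = ([1e-12, lo - 7.0, 0.2], [np.inf, hi + 7.0, 20.0])
    sol = _solve(residual, starts, bounds)
    if sol is None:
        return FitResult({}, {}, math.nan, False, len(x), "no start converged")

    def transform(theta, se_raw):
        # d(ec50)/d(ln ec50) = ec50
        return np.array([se_raw[0], se_raw[1] * math.exp(theta[1]), se_raw[2]])

    se_vals, rss = _cov_se(sol, len(x), 3, transform)
    pmax, lec50, h = sol.x
    warnings_list = []
    if lec50 <= bounds[0][1] + 1e-6 or lec50 >= bounds[1][1] - 1e-6:
        warnings_list.append("ec50 at parameter bound: unidentifiable")
    return FitResult(
        params={"pmax": float(pmax), "ec50": float(math.exp(lec50)), "h": float(h)},
        se={"pmax": se_vals[0], "ec50": se_vals[1], "h": se_vals[2]},
        rss=rss, converged=sol.success and not warnings_list,
        n_points=len(x), warnings=warnings_list,
    )


def fit_biphasic_hill(points, y_err=None) -> FitResult:
    """Fit the bell-shaped product of activation and inhibition Hill terms.

    Requires >= 6 points.  ``ic50_inh > ec50_act`` is enforced through the
    ordered parameterization ``ln ic50 = ln ec50 + exp(g)``.  Monotone
    (non-descending) data leave the inhibition limb unidentifiable, which
    is flagged in ``warnings``.
    """
    x, y, y_err = _as_xy(points, y_err)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if y_err is not None:
        y_err = y_err[order]
    if len(x) < 6:
        raise ValueError("need >= 6 points for a biphasic Hill fit")
    pos = x > 0
    if pos.sum() < 4:
        raise ValueError("need >= 4 positive x values")
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return FitResult(
            params={}, se={}, rss=float(((y - y.mean()) ** 2).sum()),
            converged=False, n_points=len(x), message="flat response",
        )
    w = 1.0 / y_err if y_err is not None else np.ones_like(y)

    def unpack(theta):
        pmax, la, ha, g, hi_ = theta
        a = math.exp(la)
        i = math.exp(la + math.exp(g))
        return BiphasicHillParams(pmax, a, ha, i, hi_)

    def residual(theta):
        return w * (biphasic_po(x, unpack(theta)) - y)

    lo, hi = math.log(x[pos].min()), math.log(x[pos].max())
    # peak value of act*inh is < 1, so seed pmax above max(y)
    pmax0 = max(2.0 * float(y.max()), 1e-9)
    gap0 = math.log(math.log(10.0))  # one decade between midpoints
    starts = [
        (pmax0, l, ha0, g0, hi0)
        for l in np.linspace(lo, 0.5 * (lo + hi), 3)
        for ha0, hi0 in ((1.0, 1.0), (2.0, 2.0), (4.0, 4.0))
        for g0 in (gap0 - 0.7, gap0, gap0 + 0.7)
    ]
    bounds = (
        [1e-12, lo - 7.0, 0.2, -6.0, 0.2],
        [np.inf, hi + 7.0, 20.0, 4.0, 20.0],
    )
    sol = _solve(residual, starts, bounds)
    if sol is None:
        return FitResult({}, {}, math.nan, False, len(x), "no start converged")
    p = unpack(sol.x)

    def transform(theta, se_raw):
        pmax, la, ha, g, hi_ = theta
        ec50 = math.exp(la)
        ic50 = math.exp(la + math.exp(g))
        # delta method for ic50 from (la, g); ignore covariance term
        d_ic50 = math.hypot(ic50 * se_raw[1], ic50 * math.exp(g) * se_raw[3])
        return np.array([se_raw[0], ec50 * se_raw[1], se_raw[2], d_ic50, se_raw[4]])

    se_vals, rss = _cov_se(sol, len(x), 5, transform)
    warnings_list = []
    if p.ic50_inh > 10.0 * x[pos].max():
        warnings_list.append("ic50_inh beyond data range: unidentifiable")
    # monotone data: no descending limb sampled
    peak_idx = int(np.argmax(y))
    if peak_idx >= len(y) - 1:
        warnings_list.append("no descending limb: ic50_inh unidentifiable")
    return FitResult(
        params={
            "pmax": p.pmax, "ec50_act": p.ec50_act, "h_act": p.h_act,
            "ic50_inh": p.ic50_inh, "h_inh": p.h_inh,
        },
        se={
            "pmax": se_vals[0], "ec50_act": se_vals[1], "h_act": se_vals[2],
            "ic50_inh": se_vals[3], "h_inh": se_vals[4],
        },
        rss=rss, converged=sol.success and not warnings_list,
        n_points=len(x), warnings=warnings_list,
    )


def fit_linear_iv(points) -> FitResult:
    """Ordinary least-squares line through (voltage mV, current pA) points.

    The slope in pA/mV equals the conductance in nS; it is reported in pS.
    """
    if isinstance(points, pd.DataFrame):
        v = points["x"].to_numpy(dtype=float)
        i = points["y"].to_numpy(dtype=float)
    else:
        v, i = (np.asarray(a, dtype=float) for a in points)
    if len(v) < 2 or len(np.unique(v)) < 2:
        raise ValueError("need >= 2 distinct voltages")
    res = sps.linregress(v, i)
    slope_ps = res.slope * 1000.0
    reversal = -res.intercept / res.slope if res.slope != 0 else math.nan
    pred = res.slope * v + res.intercept
    rss = float(((i - pred) ** 2).sum())
    return FitResult(
        params={"conductance_pS": float(slope_ps), "reversal_mV": float(reversal)},
        se={"conductance_pS": float(res.stderr * 1000.0) if res.stderr else math.nan},
        rss=rss, converged=True, n_points=len(v),
    )


def fit_mot_edf(points, y_err=None) -> FitResult:
    """Fit the double-Hill MOT-vs-EDF model with baseline fixed at 1.

    Only points with EDF > 0 enter the fit; fewer than 5 raises.  Bounded
    multi-start: midpoints in [10, 500] mV, exponents in [0.5, 20].  Data
    confined to the activation limb leave vi50 unidentifiable (flagged).
    """
    x, y, y_err = _as_xy(points, y_err)
    mask = x > 0
    x, y = x[mask], y[mask]
    if y_err is not None:
        y_err = y_err[mask]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if y_err is not None:
        y_err = y_err[order]
    if len(x) < 5:
        raise ValueError("need >= 5 points with EDF > 0")
    w = 1.0 / y_err if y_err is not None else np.ones_like(y)

    def unpack(theta):
        lr, lva, ha, lvi, hi_ = theta
        return FeedthroughMotParams(
            math.exp(lr), math.exp(lva), ha, math.exp(lvi), hi_
        )

    def residual(theta):
        return w * (mot_edf_model(x, unpack(theta)) - y)

    r0 = max(float(y.max()) - 1.0, 0.1)
    starts = [
        (math.log(r0), math.log(va), ha0, math.log(vi), hi0)
        for va in (80.0, 120.0, 160.0)
        for vi in (150.0, 220.0, 320.0)
        for ha0, hi0 in ((4.0, 2.0), (8.0, 4.0))
    ]
    bounds = (
        [math.log(1e-2), math.log(10.0), 0.5, math.log(10.0), 0.5],
        [math.log(1e2), math.log(500.0), 20.0, math.log(500.0), 20.0],
    )
    sol = _solve(residual, starts, bounds)
    if sol is None:
        return FitResult({}, {}, math.nan, False, len(x), "no start converged")
    p = unpack(sol.x)

    def transform(theta, se_raw):
        return np.array([
            p.range * se_raw[0], p.va50 * se_raw[1], se_raw[2],
            p.vi50 * se_raw[3], se_raw[4],
        ])

    se_vals, rss = _cov_se(sol, len(x), 5, transform)
    warnings_list = []
    peak_idx = int(np.argmax(y))
    if peak_idx >= len(y) - 1:
        warnings_list.append("no descending limb: vi50 unidentifiable")
    return FitResult(
        params={
            "range": p.range, "va50": p.va50, "ha": p.ha,
            "vi50": p.vi50, "hi": p.hi,
        },
        se={
            "range": se_vals[0], "va50": se_vals[1], "ha": se_vals[2],
            "vi50": se_vals[3], "hi": se_vals[4],
        },
        rss=rss, converged=sol.success and not warnings_list,
        n_points=len(x), warnings=warnings_list,
    )


def mct_overlay(mot_fit: FitResult, mct_points) -> dict:
    """Overlay the fitted MOT curve, flipped and scaled, onto MCT data.

    Fits ``MCT_pred(EDF) = a - b * MOT_model(EDF)`` over (a, b) with
    b >= 0 by linear least squares, and compares against a constant-only
    fit with an F-test.  Returns a, b, rss, rss_const, f_stat, p_value.
    """
    if not mot_fit.converged and not mot_fit.params:
        raise ValueError("MOT fit did not converge")
    x, y, _ = _as_xy(mct_points)
    p = FeedthroughMotParams(
        mot_fit.params["range"], mot_fit.params["va50"], mot_fit.params["ha"],
        mot_fit.params["vi50"], mot_fit.params["hi"],
    )
    m = np.asarray(mot_edf_model(x, p), dtype=float)
    A = np.column_stack([np.ones_like(m), -m])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    if b < 0:
        a, b = float(np.mean(y)), 0.0
    pred = a - b * m
    rss = float(((y - pred) ** 2).sum())
    rss_const = float(((y - y.mean()) ** 2).sum())
    n = len(y)
    if n > 2 and rss > 0:
        f_stat = (rss_const - rss) / (rss / (n - 2))
        p_value = float(sps.f.sf(f_stat, 1, n - 2))
    else:
        f_stat, p_value = math.inf, 0.0
    return {
        "a": a, "b": b, "rss": rss, "rss_const": rss_const,
        "f_stat": float(f_stat), "p_value": p_value, "n_points": n,
    }


def dose_response_pipeline(
    traces_by_condition: dict,
    unitary: float,
    baseline: float = 0.0,
    n_levels: int = 1,
    dead_time: float = _idealize.DEFAULT_DEAD_TIME,
    fit: Optional[str] = "hill",
    min_record_s: float = 0.0,
) -> tuple[pd.DataFrame, Optional[FitResult]]:
    """Idealize replicate traces per ligand condition, pool nPo, then fit.

    ``traces_by_condition`` maps ligand concentration (mol/L) to a sequence
    of current traces.  Each trace is idealized at the half-amplitude
    threshold, dead-time censored, and summarized as nPo; per-condition
    mean and SE form the dose-response table.  ``fit`` selects 'hill',
    'biphasic' or None (table only).  Zero-activity traces contribute
    zero-valued points and are retained.
    """
    if not traces_by_condition:
        raise ValueError("no conditions supplied")
    rows = []
    for conc in sorted(traces_by_condition):
        npos = []
        for trace in traces_by_condition[conc]:
            ideal = _idealize.idealize_trace(
                trace, unitary=unitary, baseline=baseline, n_levels=n_levels
            )
            ideal = _idealize.apply_dead_time(ideal, dead_time)
            st = _idealize.channel_stats(ideal, min_record_s=min_record_s)
            npos.append(st.npo)
        npos = np.asarray(npos)
        se = float(npos.std(ddof=1) / math.sqrt(len(npos))) if len(npos) > 1 else math.nan
        rows.append({"x": conc, "y": float(npos.mean()), "y_err": se, "n": len(npos)})
    table = pd.DataFrame(rows)
    if fit is None:
        return table, None
    min_pts = {"hill": 4, "biphasic": 6}[fit]
    if len(table) < min_pts:
        raise ValueError(
            f"{len(table)} condition(s) is too few for a {fit} fit "
            f"(need >= {min_pts}); call with fit=None for the table alone"
        )
    fitter = fit_hill if fit == "hill" else fit_biphasic_hill
    return table, fitter((table["x"].to_numpy(), table["y"].to_numpy()))
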