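"""Chromatographic peak integration.

Integrators operate on an EIC (or any rt/intensity trace) restricted to
a closed RT window:

``trapezoid``
    trapezoidal quadrature of the baseline-subtracted trace (clipped at
    zero).
``sgolay``
    trapezoid on a Savitzky-Golay smoothed trace; the reported rmse is
    the RMS difference between raw and smoothed points.
``emg``
    least-squares fit of an exponentially modified Gaussian
    h(t; H, mu, sigma, tau) with closed-form area H*sigma*sqrt(2*pi);
    H is the height of the tau -> 0 Gaussian limit.
``max``
    the maximum intensity in the window (reported as area).
``no_integration``
    a placeholder result with everything missing.

Table-level integration (:func:`integrate_table`) applies one method to
every row of a peak table — a table with columns id, mzmin, mzmax,
rtmin, rtmax and a peakmap reference — and writes method, area, rmse
and serialized model parameters back as columns.  The output is
bit-identical for any worker count.
"""

from __future__ import annotations

import json
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from scipy.special import erfc, erfcx

from . import table as tbl
from .peakmap import EIC, extract_eic

__all__ = [
    "IntegrationResult",
    "integrate_trapezoid",
    "integrate_sgolay",
    "fit_emg",
    "integrate_max",
    "emg_model",
    "emg_area",
    "integrate",
    "integrate_table",
    "reintegrate",
    "PEAK_TABLE_COLUMNS",
]

#: columns any integratable peak table must provide
PEAK_TABLE_COLUMNS = ("id", "mzmin", "mzmax", "rtmin", "rtmax", "peakmap")

METHODS = ("trapezoid", "sgolay", "emg", "max", "no_integration")


@dataclass(frozen=True)
class IntegrationResult:
    """Outcome of integrating one chromatographic peak."""

    method: str
    area: Optional[float]
    rmse: Optional[float] = None
    params: dict = field(default_factory=dict)
    baseline: float = 0.0
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.area is not None


def _window(rts, intensities, rtmin, rtmax):
    rts = np.asarray(rts, dtype=np.float64)
    intensities = np.asarray(intensities, dtype=np.float64)
    mask = (rts >= rtmin) & (rts <= rtmax)
    return rts[mask], intensities[mask]


def _trace(eic) -> tuple[np.ndarray, np.ndarray]:
    # accepts EIC, Chromatogram or a (rts, intensities) pair
    if hasattr(eic, "rts"):
        return eic.rts, eic.intensities
    rts, intensities = eic
    return np.asarray(rts, dtype=np.float64), np.asarray(intensities, dtype=np.float64)


def integrate_trapezoid(eic, rtmin=-np.inf, rtmax=np.inf, baseline: float = 0.0
                        ) -> IntegrationResult:
    """Trapezoidal area of (intensity - baseline) clipped at 0, in the window."""
    if rtmin > rtmax:
        raise ValueError("rtmin must be <= rtmax")
    rts, intensities = _trace(eic)
    rts, intensities = _window(rts, intensities, rtmin, rtmax)
    if len(rts) < 2:
        return IntegrationResult("trapezoid", 0.0, baseline=baseline,
                                 message="fewer than 2 points in window")
    y = np.clip(intensities - baseline, 0.0, None)
    area = float(np.trapezoid(y, rts))
    return IntegrationResult("trapezoid", area, baseline=baseline)


def integrate_sgolay(eic, rtmin=-np.inf, rtmax=np.inf, window_pts: int = 7,
                     poly_order: int = 3, baseline: float = 0.0) -> IntegrationResult:
    """Trapezoid on a Savitzky-Golay smoothed trace."""
    if window_pts % 2 == 0 or window_pts <= poly_order:
        raise ValueError("window_pts must be odd and > poly_order")
    rts, intensities = _trace(eic)
    rts, intensities = _window(rts, intensities, rtmin, rtmax)
    if len(rts) < 2:
        return IntegrationResult("sgolay", 0.0, baseline=baseline,
                                 message="fewer than 2 points in window")
    if len(rts) < window_pts:
        res = integrate_trapezoid((rts, intensities), baseline=baseline)
        return IntegrationResult("sgolay_fallback_trapezoid", res.area,
                                 baseline=baseline,
                                 message="too few points for the filter")
    smoothed = savgol_filter(intensities, window_pts, poly_order)
    rmse = float(np.sqrt(np.mean((intensities - smoothed) ** 2)))
    y = np.clip(smoothed - baseline, 0.0, None)
    area = float(np.trapezoid(y, rts))
    return IntegrationResult("sgolay", area, rmse, baseline=baseline,
                             params={"window_pts": window_pts, "poly_order": poly_order})


# -- exponentially modified Gaussian --------------------------------------

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


def emg_model(t, height, center, sigma, tau):
    """EMG evaluated stably for any sigma/tau ratio.

    Normalized so that for tau -> 0 the curve tends to a Gaussian of
    height ``height``; the area is height*sigma*sqrt(2*pi) exactly.
    """
    t = np.asarray(t, dtype=np.float64)
    z = (center + (sigma ** 2) / tau - t) / (_SQRT2 * sigma)
    # area-normalized EMG times the area; exp*erfc evaluated via erfcx
    # where the plain product would overflow (Kalambet-style switch)
    amp = height * sigma * _SQRT2PI / (2.0 * tau)
    arg = (center - t) / tau + (sigma ** 2) / (2.0 * tau ** 2)
    out = np.empty_like(t)
    small = z < 26.0
    with np.errstate(over="ignore", invalid="ignore"):
        if np.any(small):
            out[small] = amp * np.exp(arg[small]) * erfc(z[small])
        big = ~small
        if np.any(big):
            # exp(arg)*erfc(z) = erfcx(z)*exp(arg - z^2)
            out[big] = amp * erfcx(z[big]) * np.exp(arg[big] - z[big] ** 2)
    return np.nan_to_num(out, nan=0.0, posinf=0.0)


def emg_area(height, sigma):
    return height * sigma * _SQRT2PI


def fit_emg(eic, rtmin=-np.inf, rtmax=np.inf, baseline: float = 0.0,
            max_nfev: int = 2000) -> IntegrationResult:
    """Least-squares EMG fit; never raises on non-convergence.

    Deterministic initialization: center at the intensity maximum
    (earliest on ties), sigma from the half width at half maximum,
    tau = sigma, height = maximum intensity.
    """
    rts, intensities = _trace(eic)
    rts, intensities = _window(rts, intensities, rtmin, rtmax)
    if len(rts) < 5:
        return IntegrationResult("emg", None, baseline=baseline,
                                 message="fewer than 5 points in window")
    y = np.clip(intensities - baseline, 0.0, None)
    ymax = float(y.max())
    if ymax <= 0:
        return IntegrationResult("emg", None, baseline=baseline,
                                 message="no signal above baseline in window")
    imax = int(np.argmax(y))  # argmax returns the first (earliest RT) maximum
    mu0 = float(rts[imax])
    above = np.nonzero(y >= ymax / 2.0)[0]
    hwhm = max((rts[above[-1]] - rts[above[0]]) / 2.0, np.min(np.diff(rts)) / 2.0)
    sigma0 = float(hwhm / math.sqrt(2.0 * math.log(2.0)))
    x0 = np.array([ymax, mu0, sigma0, sigma0])

    def residuals(p):
        return emg_model(rts, *p) - y

    span = rts[-1] - rts[0]
    try:
        fit = least_squares(
            residuals, x0,
            bounds=([0.0, rts[0] - span, 1e-6, 1e-6],
                    [np.inf, rts[-1] + span, 10 * span + 1.0, 10 * span + 1.0]),
            max_nfev=max_nfev,
        )
    except Exception as exc:  # defensive: solver failures become failed fits
        return IntegrationResult("emg", None, baseline=baseline,
                                 message=f"fit failed: {exc}")
    if not fit.success:
        return IntegrationResult("emg", None, baseline=baseline,
                                 message=f"fit did not converge: {fit.message}")
    height, center, sigma, tau = (float(v) for v in fit.x)
    rmse = float(np.sqrt(np.mean(fit.fun ** 2)))
    return IntegrationResult(
        "emg", emg_area(height, sigma), rmse,
        params={"height": height, "center": center, "sigma": sigma, "tau": tau},
        baseline=baseline,
    )


def integrate_max(eic, rtmin=-np.inf, rtmax=np.inf, baseline: float = 0.0
                  ) -> IntegrationResult:
    """Maximum baseline-subtracted intensity in the window (as 'area')."""
    rts, intensities = _trace(eic)
    rts, intensities = _window(rts, intensities, rtmin, rtmax)
    if len(rts) == 0:
        return IntegrationResult("max", 0.0, baseline=baseline, message="empty window")
    return IntegrationResult(
        "max", float(np.clip(intensities - baseline, 0.0, None).max()),
        baseline=baseline,
    )


def integrate(eic, method: str = "trapezoid", rtmin=-np.inf, rtmax=np.inf,
              baseline: float = 0.0, **params) -> IntegrationResult:
    """Dispatch to one of the named integrators."""
    if method == "trapezoid":
        return integrate_trapezoid(eic, rtmin, rtmax, baseline)
    if method == "sgolay":
        return integrate_sgolay(eic, rtmin, rtmax, baseline=baseline, **params)
    if method == "emg":
        return fit_emg(eic, rtmin, rtmax, baseline, **params)
    if method == "max":
        return integrate_max(eic, rtmin, rtmax, baseline)
    if method == "no_integration":
        return IntegrationResult("no_integration", None)
    raise ValueError(f"unknown integration method {method!r} (choose from {METHODS})")


# -- table-level integration ----------------------------------------------

RESULT_COLUMNS = ("method", "area", "rmse", "model_params")


def _check_peak_table(pt: tbl.Table):
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in pt.col_names]
    if missing:
        raise tbl.SchemaError(f"peak table lacks required columns: {missing}")


def _integrate_payload(args):
    rts, intensities, rtmin, rtmax, method, baseline, params = args
    res = integrate((rts, intensities), method, rtmin, rtmax, baseline, **params)
    return (res.method, res.area, res.rmse, json.dumps(res.params, sort_keys=True))


def _result_rows(pt: tbl.Table, method: str, baseline: float, params: dict,
                 workers: int, ms_level: int):
    """One result tuple per row, in row order; parallelism-invariant."""
    payloads = []
    statuses = []  # None = integrate, str = flag message
    for row in pt:
        pm = row["peakmap"]
        if pm is None:
            payloads.append(None)
            statuses.append("unresolvable peakmap reference")
            continue
        eic = extract_eic(pm, row["mzmin"], row["mzmax"], row["rtmin"], row["rtmax"],
                          ms_level)
        payloads.append((eic.rts, eic.intensities, row["rtmin"], row["rtmax"],
                         method, baseline, params))
        statuses.append(None)
    todo = [p for p in payloads if p is not None]
    if workers > 1 and len(todo) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            done = list(pool.map(_integrate_payload, todo, chunksize=8))
    else:
        done = [_integrate_payload(p) for p in todo]
    results = []
    it = iter(done)
    for status in statuses:
        if status is None:
            results.append(next(it) + (None,))
        else:
            results.append(("no_integration", None, None, "{}", status))
    return results


def integrate_table(pt: tbl.Table, method: str = "trapezoid", baseline: float = 0.0,
                    params: dict | None = None, workers: int = 1,
                    ms_level: int = 1) -> tbl.Table:
    """Integrate every row of a peak table; adds method/area/rmse/model_params.

    Rows whose peakmap reference is missing are flagged (method
    ``no_integration``) and the rest proceed.  Output is identical for
    any ``workers`` value.
    """
    _check_peak_table(pt)
    if method not in METHODS:
        raise ValueError(f"unknown integration method {method!r}")
    results = _result_rows(pt, method, baseline, params or {}, workers, ms_level)
    base_cols = [c for c in pt.col_names if c not in RESULT_COLUMNS]
    out_names = base_cols + list(RESULT_COLUMNS)
    schema = pt.schema()
    out_types = [schema[c] for c in base_cols] + ["text", "real", "real", "text"]
    rows = []
    base_idx = [pt.col_names.index(c) for c in base_cols]
    for row, res in zip(pt.rows(), results):
        rows.append(tuple(row[i] for i in base_idx) + res[:4])
    return tbl.create_table(out_names, out_types, rows, meta=pt.meta)


def reintegrate(pt: tbl.Table, row_id, rtmin: float, rtmax: float,
                method: str = "trapezoid", baseline: float = 0.0,
                params: dict | None = None, ms_level: int = 1) -> tbl.Table:
    """Re-integrate a single row with a new RT window.

    Only that row's rtmin/rtmax and result columns change.
    """
    _check_peak_table(pt)
    ids = pt.col_values("id")
    if row_id not in ids:
        raise KeyError(f"no row with id {row_id!r}")
    i = ids.index(row_id)
    schema = pt.schema()
    has_results = all(c in pt.col_names for c in RESULT_COLUMNS)
    out_names = list(pt.col_names)
    out_types = [schema[c] for c in out_names]
    if not has_results:
        out_names += list(RESULT_COLUMNS)
        out_types += ["text", "real", "real", "text"]
    rows = []
    for k, row in enumerate(pt):
        if k == i:
            row = dict(row)
            row["rtmin"], row["rtmax"] = float(rtmin), float(rtmax)
            pm = row["peakmap"]
            if pm is None:
                res = ("no_integration", None, None, "{}")
            else:
                eic = extract_eic(pm, row["mzmin"], row["mzmax"], rtmin, rtmax, ms_level)
                r = integrate(eic, method, rtmin, rtmax, baseline, **(params or {}))
                res = (r.method, r.area, r.rmse, json.dumps(r.params, sort_keys=True))
            row["method"], row["area"], row["rmse"], row["model_params"] = res
        elif not has_results:
            row = dict(row)
            row["method"] = row["area"] = row["rmse"] = row["model_params"] = None
        rows.append(tuple(row.get(c) for c in out_names))
    return tbl.create_table(out_names, out_types, rows, meta=pt.meta)
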