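"""RT alignment, m/z recalibration and isotope/adduct grouping.

RT alignment maps observed retention times onto a reference time axis
through anchor pairs (well-identified compounds seen in both runs).
The fitted mapping is strictly monotone over the anchor span — enforced
by isotonic repair of the anchor targets — so applying it can never
reorder spectra; beyond the anchors it continues linearly.

Isotope grouping partitions a feature table into isotopologue envelopes
using the 13C-12C spacing of 1.0033548378 Da divided by charge; adduct
grouping then links envelopes that are consistent with one neutral mass
ionized under different adducts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import isotonic_regression

from . import table as tbl
from .chemistry import Adduct, default_adducts
from .peakmap import PeakMap, Spectrum

__all__ = [
    "ISOTOPE_SPACING",
    "RtAlignmentModel",
    "fit_rt_alignment",
    "apply_rt_alignment",
    "MzCalibration",
    "fit_mz_calibration",
    "group_isotopes",
    "group_adducts",
]

#: 13C - 12C mass difference in Da
ISOTOPE_SPACING = 1.0033548378

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# RT alignment

class RtAlignmentModel:
    """Monotone mapping rt -> rt' through anchor pairs.

    ``kind`` is 'piecewise_linear' (interpolates the anchors exactly) or
    'local_regression' (lowess-smoothed targets, then interpolation).
    Extrapolation beyond the anchors continues the boundary slope.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, kind: str):
        self.x = x
        self.y = y
        self.kind = kind

    def __call__(self, rt):
        scalar = np.isscalar(rt)
        rt = np.atleast_1d(np.asarray(rt, dtype=np.float64))
        out = np.interp(rt, self.x, self.y)
        # linear continuation outside the anchor span
        if len(self.x) >= 2:
            s0 = (self.y[1] - self.y[0]) / (self.x[1] - self.x[0])
            s1 = (self.y[-1] - self.y[-2]) / (self.x[-1] - self.x[-2])
            left = rt < self.x[0]
            right = rt > self.x[-1]
            out[left] = self.y[0] + s0 * (rt[left] - self.x[0])
            out[right] = self.y[-1] + s1 * (rt[right] - self.x[-1])
        return float(out[0]) if scalar else out

    def inverse(self) -> "RtAlignmentModel":
        """Inverse mapping (piecewise-linear models are invertible)."""
        return RtAlignmentModel(self.y.copy(), self.x.copy(), self.kind)

    @property
    def anchors(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def _strictly_increasing(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Minimal epsilon repair so y is strictly increasing."""
    y = y.copy()
    span = max(y[-1] - y[0], x[-1] - x[0], 1.0)
    eps = 1e-9 * span
    for i in range(1, len(y)):
        if y[i] <= y[i - 1]:
            y[i] = y[i - 1] + eps
    return y


def fit_rt_alignment(anchors, kind: str = "piecewise_linear",
                     lowess_frac: float = 0.5) -> RtAlignmentModel:
    """Fit a monotone RT mapping from (rt_observed, rt_reference) anchors.

    Non-monotone anchor targets are repaired by isotonic regression
    (with a warning) rather than rejected: alignment must never reorder
    spectra.
    """
    anchors = np.asarray(anchors, dtype=np.float64)
    if anchors.ndim != 2 or anchors.shape[1] != 2 or anchors.shape[0] < 2:
        raise ValueError("need >= 2 anchor pairs of (rt_observed, rt_reference)")
    order = np.argsort(anchors[:, 0], kind="stable")
    x = anchors[order, 0]
    y = anchors[order, 1]
    if np.any(np.diff(x) <= 0):
        raise ValueError("observed anchor rts must be strictly increasing")
    if kind == "piecewise_linear":
        fitted = y
    elif kind == "local_regression":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fitted = lowess(y, x, frac=lowess_frac, return_sorted=False)
    else:
        raise ValueError("kind must be 'piecewise_linear' or 'local_regression'")
    if np.any(np.diff(fitted) <= 0):
        if np.any(np.diff(fitted) < 0):
            logger.warning("anchor targets not monotone; applying isotonic repair")
            fitted = isotonic_regression(fitted).x
        fitted = _strictly_increasing(np.asarray(fitted, dtype=np.float64), x)
    return RtAlignmentModel(x, np.asarray(fitted, dtype=np.float64), kind)


def apply_rt_alignment(target, model: RtAlignmentModel):
    """Map all RT fields of a PeakMap or a table through the model.

    For tables, any of the columns rt, rtmin, rtmax, rt_expected and
    apex_rt that exist are mapped.  Ordering invariants are preserved
    because the model is strictly monotone.
    """
    if isinstance(target, PeakMap):
        spectra = tuple(
            Spectrum(model(s.rt), s.mzs, s.intensities, s.ms_level, s.polarity,
                     s.precursors)
            for s in target.spectra
        )
        chroms = tuple(
            type(c)(c.kind, model(c.rts), c.intensities, c.precursor_mz, c.product_mz)
            for c in target.chromatograms
        )
        return PeakMap(spectra, chroms, dict(target.metadata))
    if isinstance(target, tbl.Table):
        rt_cols = [c for c in ("rt", "rtmin", "rtmax", "rt_expected", "apex_rt")
                   if c in target.col_names]
        rows = []
        for row in target:
            row = dict(row)
            for c in rt_cols:
                if row[c] is not None:
                    row[c] = float(model(row[c]))
            rows.append(tuple(row[c] for c in target.col_names))
        return tbl.create_table(target.col_names, target.col_types, rows,
                                col_formats=target.col_formats, meta=target.meta)
    raise TypeError("target must be a PeakMap or a Table")


# --------------------------------------------------------------------------
# m/z calibration

@dataclass(frozen=True)
class MzCalibration:
    """Affine recalibration mz -> a*mz + b with an RMS residual summary."""

    a: float
    b: float
    rms_residual: float

    def __call__(self, mz):
        return self.a * np.asarray(mz, dtype=np.float64) + self.b


def fit_mz_calibration(pairs) -> MzCalibration:
    """Least-squares affine fit of (observed, reference) m/z pairs."""
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 (observed, reference) m/z pairs")
    obs, ref = pairs[:, 0], pairs[:, 1]
    a, b = np.polyfit(obs, ref, 1)
    if not 0.99 <= a <= 1.01:
        logger.warning("m/z calibration gain %.6f outside [0.99, 1.01]", a)
    corrected = a * obs + b
    rms = float(np.sqrt(np.mean((corrected - ref) ** 2)))
    return MzCalibration(float(a), float(b), rms)


# --------------------------------------------------------------------------
# isotope grouping

def group_isotopes(ft: tbl.Table, mz_tol: float, rt_tol: float,
                   max_charge: int = 2, max_isotopologues: int = 8) -> tbl.Table:
    """Partition a feature table (mz, rt, intensity) into isotope groups.

    Greedy by descending intensity (ties broken by ascending m/z): each
    unclaimed seed claims unclaimed peaks at mz_seed + k*spacing/z for
    k = 1..max_isotopologues and z = 1..max_charge within the
    tolerances, keeping the charge that explains the most members.
    Every peak ends up in exactly one group; adds columns group_id,
    charge, isotopologue.
    """
    for c in ("mz", "rt", "intensity"):
        if c not in ft.col_names:
            raise tbl.SchemaError(f"feature table lacks column {c!r}")
    rows = [dict(r) for r in ft]
    n = len(rows)
    order = sorted(range(n), key=lambda i: (-(rows[i]["intensity"] or 0.0),
                                            rows[i]["mz"]))
    claimed = [False] * n
    group_of = [None] * n
    charge_of = [None] * n
    iso_of = [None] * n
    # peaks sorted by mz for window lookups
    by_mz = sorted(range(n), key=lambda i: rows[i]["mz"])
    mz_sorted = np.array([rows[i]["mz"] for i in by_mz])

    def candidates(mz_target, rt_seed):
        lo = np.searchsorted(mz_sorted, mz_target - mz_tol, side="left")
        hi = np.searchsorted(mz_sorted, mz_target + mz_tol, side="right")
        found = []
        for p in range(lo, hi):
            i = by_mz[p]
            if not claimed[i] and abs(rows[i]["rt"] - rt_seed) <= rt_tol:
                found.append(i)
        # closest in m/z first, deterministic tie-break on index
        found.sort(key=lambda i: (abs(rows[i]["mz"] - mz_target), i))
        return found

    next_group = 0
    for seed in order:
        if claimed[seed]:
            continue
        claimed[seed] = True
        best_members: list[tuple[int, int]] = []  # (row index, isotopologue k)
        best_z = 1
        for z in range(1, max_charge + 1):
            members = []
            trial_claim = set()
            for k in range(1, max_isotopologues + 1):
                mz_target = rows[seed]["mz"] + k * ISOTOPE_SPACING / z
                cand = [i for i in candidates(mz_target, rows[seed]["rt"])
                        if i not in trial_claim]
                if not cand:
                    break
                members.append((cand[0], k))
                trial_claim.add(cand[0])
            if len(members) > len(best_members):
                best_members, best_z = members, z
        group_of[seed] = next_group
        charge_of[seed] = best_z if best_members else 1
        iso_of[seed] = 0
        for i, k in best_members:
            claimed[i] = True
            group_of[i] = next_group
            charge_of[i] = best_z
            iso_of[i] = k
        next_group += 1
    out_rows = []
    for i, row in enumerate(rows):
        out_rows.append(tuple(row[c] for c in ft.col_names)
                        + (group_of[i], charge_of[i], iso_of[i]))
    return tbl.create_table(
        ft.col_names + ["group_id", "charge", "isotopologue"],
        ft.col_types + ["integer", "integer", "integer"],
        out_rows, meta=ft.meta,
    )


def group_adducts(gt: tbl.Table, adducts: Optional[list[Adduct]] = None,
                  mz_tol: float = 0.003, rt_tol: float = 5.0) -> tbl.Table:
    """Link isotope groups consistent with one neutral mass under two adducts.

    For every pair of co-eluting groups, each adduct assignment implies
    a neutral mass M = (mz*|z| - delta)/multiplier from the group's
    monoisotopic member; if two assignments agree within ``mz_tol`` the
    groups share an ``adduct_group`` and get ``neutral_mass`` and
    ``adduct`` annotations.
    """
    if adducts is None:
        adducts = default_adducts()
    for c in ("mz", "rt", "group_id", "charge", "isotopologue"):
        if c not in gt.col_names:
            raise tbl.SchemaError(f"grouped table lacks column {c!r}")
    rows = [dict(r) for r in gt]
    monos = {}
    for row in rows:
        if row["isotopologue"] == 0:
            monos[row["group_id"]] = row
    gids = sorted(monos)
    parent = {g: g for g in gids}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    annotation: dict[int, tuple[str, float]] = {}
    for ai in range(len(gids)):
        for bi in range(ai + 1, len(gids)):
            ga, gb = gids[ai], gids[bi]
            ra, rb = monos[ga], monos[gb]
            if abs(ra["rt"] - rb["rt"]) > rt_tol:
                continue
            hit = None
            for ad_a in adducts:
                if abs(ad_a.charge) != ra["charge"]:
                    continue
                ma = (ra["mz"] * abs(ad_a.charge) - ad_a.mass_delta) / ad_a.multiplier
                if ma <= 0:
                    continue
                for ad_b in adducts:
                    if ad_b.name == ad_a.name or abs(ad_b.charge) != rb["charge"]:
                        continue
                    mb = (rb["mz"] * abs(ad_b.charge) - ad_b.mass_delta) / ad_b.multiplier
                    if mb > 0 and abs(ma - mb) <= mz_tol:
                        hit = (ad_a, ad_b, (ma + mb) / 2.0)
                        break
                if hit:
                    break
            if hit:
                union(ga, gb)
                ad_a, ad_b, mass = hit
                annotation.setdefault(ga, (ad_a.name, mass))
                annotation.setdefault(gb, (ad_b.name, mass))
    out_rows = []
    for row in rows:
        g = row["group_id"]
        ag = find(g) if g in parent else None
        name, mass = annotation.get(g, (None, None))
        out_rows.append(tuple(row[c] for c in gt.col_names) + (ag, name, mass))
    return tbl.create_table(
        gt.col_names + ["adduct_group", "adduct", "neutral_mass"],
        gt.col_types + ["integer", "text", "real"],
        out_rows, meta=gt.meta,
    )
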