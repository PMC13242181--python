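"""Targeted extraction with reference-based RT-shift correction.

Chromatographic retention times drift between samples.  When two
analytes are mass isomers (identical molecular formula, hence identical
m/z — e.g. leucine and isoleucine) they can only be told apart by RT,
so their integration windows cannot simply be widened to absorb the
drift: widened windows would overlap and merge the isomers.  Instead,
reliable reference compounds at other m/z are located in each sample,
the median deviation of their apexes from the expected RTs is taken as
that sample's global shift, and the isomers' integration windows are
translated by that estimate before integration.

The module builds peak tables from target lists, locates EIC apexes,
estimates per-sample shifts and runs the whole workflow over many
samples.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import table as tbl
from .chemistry import Adduct, MolecularFormula, adduct_mz, find_adduct, \
    monoisotopic_mass, parse_formula
from .integrate import integrate_table
from .mzml import read_mzml
from .peakmap import PeakMap, extract_eic

__all__ = [
    "Target",
    "RtShiftEstimate",
    "RtShiftError",
    "WorkflowConfig",
    "read_targets_csv",
    "build_peak_table",
    "locate_apex",
    "estimate_rt_shift",
    "apply_rt_shift",
    "run_targeted_workflow",
]

logger = logging.getLogger(__name__)


class RtShiftError(RuntimeError):
    """No reference compound could be located in a sample."""


@dataclass(frozen=True)
class Target:
    """One compound to extract: identity, expected RT and tolerances."""

    name: str
    formula: "MolecularFormula | str"
    adduct: "Adduct | str" = "[M+H]+"
    rt: float = 0.0               # expected RT, seconds
    rt_tol: float = 10.0          # half-width of the RT window, seconds
    mz_tol: float = 0.003         # Da, or ppm if mz_tol_unit == 'ppm'
    mz_tol_unit: str = "da"
    role: str = "analyte"         # 'analyte' or 'reference'

    def __post_init__(self):
        if self.rt_tol <= 0 or self.mz_tol <= 0:
            raise ValueError(f"target {self.name!r}: tolerances must be positive")
        if self.rt < 0:
            raise ValueError(f"target {self.name!r}: expected rt must be >= 0")
        if self.mz_tol_unit not in ("da", "ppm"):
            raise ValueError(f"target {self.name!r}: mz_tol unit must be 'da' or 'ppm'")
        if self.role not in ("analyte", "reference"):
            raise ValueError(f"target {self.name!r}: role must be 'analyte' or 'reference'")

    def theoretical_mz(self) -> float:
        try:
            adduct = self.adduct if isinstance(self.adduct, Adduct) else find_adduct(self.adduct)
            return adduct_mz(monoisotopic_mass(self.formula), adduct)
        except Exception as exc:
            raise type(exc)(f"target {self.name!r}: {exc}") from exc

    def mz_window(self) -> tuple[float, float]:
        mz = self.theoretical_mz()
        half = self.mz_tol * mz * 1e-6 if self.mz_tol_unit == "ppm" else self.mz_tol
        return mz - half, mz + half


def read_targets_csv(path, delimiter: str = ",") -> list[Target]:
    """Target list from delimited text.

    Header: ``name, formula, adduct, rt_sec, rt_tol_sec, mz_tol, role``
    where ``mz_tol`` carries a unit suffix, e.g. ``10ppm`` or ``0.003da``.
    """
    targets = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"name", "formula", "adduct", "rt_sec", "rt_tol_sec", "mz_tol", "role"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"target file must have columns {sorted(required)}")
        for row in reader:
            raw_tol = row["mz_tol"].strip().lower()
            if raw_tol.endswith("ppm"):
                tol, unit = float(raw_tol[:-3]), "ppm"
            elif raw_tol.endswith("da"):
                tol, unit = float(raw_tol[:-2]), "da"
            else:
                tol, unit = float(raw_tol), "da"
            targets.append(
                Target(
                    row["name"], row["formula"], row["adduct"],
                    float(row["rt_sec"]), float(row["rt_tol_sec"]),
                    tol, unit, row["role"],
                )
            )
    return targets


@dataclass(frozen=True)
class RtShiftEstimate:
    """Per-sample global RT shift from reference compounds."""

    sample_id: str
    shift: float                                 # seconds, signed
    deviations: tuple[tuple[str, float], ...]    # (reference name, apex - expected)
    n_used: int


@dataclass(frozen=True)
class WorkflowConfig:
    """Options for :func:`run_targeted_workflow`."""

    correct_rt_shift: bool = True
    shift_subset: Optional[tuple[str, ...]] = None  # None = shift all analytes
    method: str = "trapezoid"
    method_params: dict = field(default_factory=dict)
    baseline: float = 0.0
    workers: int = 1
    search_factor: float = 3.0     # widening of reference windows for apex search
    shift_summary: str = "median"  # 'median' or 'mean'


def build_peak_table(targets: Sequence[Target], pm: Optional[PeakMap] = None) -> tbl.Table:
    """One peak-table row per target, windows from formula/adduct/tolerances."""
    rows = []
    for i, t in enumerate(targets):
        mzmin, mzmax = t.mz_window()
        rows.append((
            i, t.name, t.role, t.theoretical_mz(), mzmin, mzmax,
            t.rt, max(t.rt - t.rt_tol, 0.0), t.rt + t.rt_tol, pm,
        ))
    return tbl.create_table(
        ["id", "name", "role", "mz", "mzmin", "mzmax", "rt_expected",
         "rtmin", "rtmax", "peakmap"],
        ["integer", "text", "text", "real", "real", "real", "real",
         "real", "real", "peakmap"],
        rows,
    )


def locate_apex(pm: PeakMap, target: Target, search_factor: float = 1.0,
                ms_level: int = 1):
    """RT and intensity of the EIC maximum in the (optionally widened) window.

    Returns ``None`` when the maximum is zero (peak absent).  Ties take
    the earliest RT.
    """
    mzmin, mzmax = target.mz_window()
    half = target.rt_tol * search_factor
    eic = extract_eic(pm, mzmin, mzmax, target.rt - half, target.rt + half, ms_level)
    if len(eic) == 0:
        return None
    imax = int(np.argmax(eic.intensities))  # argmax: first (earliest) maximum
    if eic.intensities[imax] <= 0:
        return None
    return float(eic.rts[imax]), float(eic.intensities[imax])


def estimate_rt_shift(pm: PeakMap, references: Sequence[Target],
                      search_factor: float = 3.0, summary: str = "median",
                      sample_id: str = "", ms_level: int = 1) -> RtShiftEstimate:
    """Global RT shift of one sample from its reference compounds.

    Each reference is searched in a window widened by ``search_factor``;
    the shift is the median (or mean) of apex-minus-expected deviations
    over the references that were found.
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    deviations = []
    for ref in references:
        if ref.role != "reference":
            continue
        located = locate_apex(pm, ref, search_factor, ms_level)
        if located is None:
            logger.warning("sample %s: reference %r not found", sample_id, ref.name)
            continue
        deviations.append((ref.name, located[0] - ref.rt))
    if not deviations:
        raise RtShiftError(
            f"sample {sample_id or '<unnamed>'}: no reference compound located"
        )
    values = [d for _, d in deviations]
    shift = float(np.median(values)) if summary == "median" else float(np.mean(values))
    return RtShiftEstimate(sample_id, shift, tuple(deviations), len(deviations))


def apply_rt_shift(pt: tbl.Table, shift: float,
                   names: Optional[Sequence[str]] = None) -> tbl.Table:
    """Translate rtmin/rtmax of the selected rows (by target name) by ``shift``.

    ``names=None`` shifts every row; all other columns are unchanged.
    """
    available = set(pt.col_values("name"))
    if names is not None:
        unknown = set(names) - available
        if unknown:
            raise KeyError(f"no peak-table rows named {sorted(unknown)}")
        selected = set(names)
    else:
        selected = available
    rows = []
    for row in pt:
        if row["name"] in selected:
            row = dict(row)
            row["rtmin"] = row["rtmin"] + shift
            row["rtmax"] = row["rtmax"] + shift
        rows.append(tuple(row[c] for c in pt.col_names))
    return tbl.create_table(pt.col_names, pt.col_types, rows,
                            col_formats=pt.col_formats, meta=pt.meta)


def _load_sample(sample) -> tuple[str, Optional[PeakMap], str]:
    """Accept a path, a PeakMap, or an (id, PeakMap) pair."""
    if isinstance(sample, PeakMap):
        return str(sample.metadata.get("run_id", "sample")), sample, ""
    if isinstance(sample, tuple) and len(sample) == 2:
        return str(sample[0]), sample[1], ""
    try:
        return str(sample), read_mzml(sample), ""
    except Exception as exc:
        return str(sample), None, f"load failed: {exc}"


def run_targeted_workflow(samples, targets: Sequence[Target],
                          config: WorkflowConfig = WorkflowConfig()) -> tbl.Table:
    """Extract and integrate every target in every sample.

    Returns a long-format table (sample x target) with the shift used,
    apex RT, area, rmse, method and a per-row flag.  Samples that fail
    shift estimation or loading are flagged and kept, not dropped.
    """
    if not samples:
        raise ValueError("at least one sample is required")
    references = [t for t in targets if t.role == "reference"]
    if config.correct_rt_shift and not references:
        raise ValueError("shift correction enabled but no reference targets given")

    out_rows = []
    for sample in samples:
        sample_id, pm, err = _load_sample(sample)
        if pm is None:
            logger.error("sample %s: %s", sample_id, err)
            for t in targets:
                out_rows.append((sample_id, t.name, t.role, t.theoretical_mz(),
                                 None, None, None, None, None, None, "load_failed"))
            continue
        shift = 0.0
        n_refs = 0
        flag = "ok"
        if config.correct_rt_shift:
            try:
                est = estimate_rt_shift(pm, references, config.search_factor,
                                        config.shift_summary, sample_id)
                shift, n_refs = est.shift, est.n_used
            except RtShiftError as exc:
                logger.warning("%s", exc)
                flag = "shift_failed"
                shift = 0.0
        pt = build_peak_table(targets, pm)
        if config.correct_rt_shift and flag == "ok":
            subset = list(config.shift_subset) if config.shift_subset is not None else None
            pt = apply_rt_shift(pt, shift, subset)
        it = integrate_table(pt, config.method, config.baseline,
                             config.method_params, config.workers)
        apexes = {}
        for t in targets:
            shifted = (config.shift_subset is None or t.name in config.shift_subset)
            offset = shift if (config.correct_rt_shift and flag == "ok" and shifted) else 0.0
            loc = locate_apex(pm, Target(t.name, t.formula, t.adduct, t.rt + offset,
                                         t.rt_tol, t.mz_tol, t.mz_tol_unit, t.role))
            apexes[t.name] = None if loc is None else loc[0]
        for row in it:
            out_rows.append((
                sample_id, row["name"], row["role"], row["mz"],
                shift if config.correct_rt_shift else None,
                n_refs if config.correct_rt_shift else None,
                apexes.get(row["name"]), row["area"], row["rmse"], row["method"],
                flag,
            ))
    return tbl.create_table(
        ["sample", "target", "role", "mz", "shift_used", "n_references",
         "apex_rt", "area", "rmse", "method", "flag"],
        ["text", "text", "text", "real", "real", "integer", "real", "real",
         "real", "text", "text"],
        out_rows,
    )
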