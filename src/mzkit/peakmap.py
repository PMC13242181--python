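"""PeakMap data model: centroided spectra and MRM chromatograms.

A :class:`PeakMap` is the full raw dataset of one LC-MS run — all
spectra and/or chromatograms with acquisition metadata.  Retention time
is in seconds everywhere.  m/z and RT windows are closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Precursor",
    "Spectrum",
    "Chromatogram",
    "PeakMap",
    "EIC",
    "extract_eic",
    "extract_mrm_trace",
    "bin2d",
    "AmbiguousTransitionError",
    "TransitionNotFoundError",
]


class TransitionNotFoundError(LookupError):
    pass


class AmbiguousTransitionError(LookupError):
    pass


@dataclass(frozen=True)
class Precursor:
    mz: float
    charge: Optional[int] = None
    isolation_window: Optional[float] = None  # +- m/z half width


def _as_f8(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D array")
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class Spectrum:
    """One centroided mass spectrum: parallel m/z (ascending) and intensity."""

    rt: float  # seconds
    mzs: np.ndarray
    intensities: np.ndarray
    ms_level: int = 1
    polarity: str = "?"  # '+', '-' or '?'
    precursors: tuple[Precursor, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mzs", _as_f8(self.mzs))
        object.__setattr__(self, "intensities", _as_f8(self.intensities))
        if len(self.mzs) != len(self.intensities):
            raise ValueError("mz and intensity arrays differ in length")
        if len(self.mzs) > 1 and not np.all(np.diff(self.mzs) > 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if self.ms_level < 1:
            raise ValueError("ms_level must be >= 1")
        if self.ms_level >= 2 and not self.precursors:
            raise ValueError("MSn spectrum (n >= 2) requires at least one precursor")
        if self.polarity not in ("+", "-", "?"):
            raise ValueError("polarity must be '+', '-' or '?'")

    def __len__(self) -> int:
        return len(self.mzs)

    @property
    def tic(self) -> float:
        return float(self.intensities.sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Spectrum)
            and self.rt == other.rt
            and self.ms_level == other.ms_level
            and self.polarity == other.polarity
            and self.precursors == other.precursors
            and np.array_equal(self.mzs, other.mzs)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class Chromatogram:
    """Intensity-vs-RT trace (SRM transition, EIC or TIC)."""

    kind: str  # 'SRM', 'EIC' or 'TIC'
    rts: np.ndarray
    intensities: np.ndarray
    precursor_mz: Optional[float] = None
    product_mz: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "rts", _as_f8(self.rts))
        object.__setattr__(self, "intensities", _as_f8(self.intensities))
        if self.kind not in ("SRM", "EIC", "TIC"):
            raise ValueError("kind must be 'SRM', 'EIC' or 'TIC'")
        if len(self.rts) != len(self.intensities):
            raise ValueError("rt and intensity arrays differ in length")
        if len(self.rts) > 1 and not np.all(np.diff(self.rts) > 0):
            raise ValueError("rt values must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if self.kind == "SRM" and (self.precursor_mz is None or self.product_mz is None):
            raise ValueError("SRM chromatogram requires precursor and product m/z")

    def __len__(self) -> int:
        return len(self.rts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Chromatogram)
            and self.kind == other.kind
            and self.precursor_mz == other.precursor_mz
            and self.product_mz == other.product_mz
            and np.array_equal(self.rts, other.rts)
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class PeakMap:
    """All spectra (sorted by RT) and chromatograms of one run."""

    spectra: tuple[Spectrum, ...] = ()
    chromatograms: tuple[Chromatogram, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        spectra = tuple(sorted(self.spectra, key=lambda s: s.rt))
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "chromatograms", tuple(self.chromatograms))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakMap)
            and self.spectra == other.spectra
            and self.chromatograms == other.chromatograms
        )

    def __len__(self) -> int:
        return len(self.spectra)

    def ms_levels(self) -> dict[int, int]:
        """Spectrum count per MS level."""
        counts: dict[int, int] = {}
        for s in self.spectra:
            counts[s.ms_level] = counts.get(s.ms_level, 0) + 1
        return counts

    def rt_range(self) -> tuple[float, float] | None:
        rts = [s.rt for s in self.spectra]
        for c in self.chromatograms:
            if len(c):
                rts.extend((float(c.rts[0]), float(c.rts[-1])))
        if not rts:
            return None
        return min(rts), max(rts)

    def mz_range(self) -> tuple[float, float] | None:
        lo, hi = np.inf, -np.inf
        for s in self.spectra:
            if len(s):
                lo = min(lo, float(s.mzs[0]))
                hi = max(hi, float(s.mzs[-1]))
        if lo > hi:
            return None
        return lo, hi


@dataclass(frozen=True)
class EIC:
    """Extracted ion chromatogram with its generating window.

    One point per source spectrum whose RT lies in the window; spectra
    with no peak inside the m/z window contribute an explicit zero.
    """

    rts: np.ndarray
    intensities: np.ndarray
    mzmin: float
    mzmax: float
    rtmin: float
    rtmax: float
    ms_level: int = 1

    def __post_init__(self):
        object.__setattr__(self, "rts", _as_f8(self.rts))
        object.__setattr__(self, "intensities", _as_f8(self.intensities))

    def __len__(self) -> int:
        return len(self.rts)

    def to_csv(self, path, delimiter: str = ",") -> None:
        with open(path, "w") as fh:
            fh.write(f"rt{delimiter}intensity\n")
            for rt, i in zip(self.rts, self.intensities):
                fh.write(f"{rt!r}{delimiter}{i!r}\n")


def extract_eic(pm: PeakMap, mzmin: float, mzmax: float,
                rtmin: float = -np.inf, rtmax: float = np.inf,
                ms_level: int = 1) -> EIC:
    """Sum intensities in the closed m/z window, per spectrum in the RT window."""
    if mzmin > mzmax:
        raise ValueError("mzmin must be <= mzmax")
    if rtmin > rtmax:
        raise ValueError("rtmin must be <= rtmax")
    rts, intensities = [], []
    for s in pm.spectra:
        if s.ms_level != ms_level or not (rtmin <= s.rt <= rtmax):
            continue
        lo = np.searchsorted(s.mzs, mzmin, side="left")
        hi = np.searchsorted(s.mzs, mzmax, side="right")
        rts.append(s.rt)
        intensities.append(float(s.intensities[lo:hi].sum()))
    return EIC(np.array(rts), np.array(intensities), mzmin, mzmax,
               float(rtmin), float(rtmax), ms_level)


def extract_mrm_trace(pm: PeakMap, precursor_mz: float, product_mz: float,
                      tol_mz: float = 0.1) -> Chromatogram:
    """The unique SRM chromatogram matching the transition within tol_mz."""
    matches = [
        c for c in pm.chromatograms
        if c.kind == "SRM"
        and abs(c.precursor_mz - precursor_mz) <= tol_mz
        and abs(c.product_mz - product_mz) <= tol_mz
    ]
    if not matches:
        raise TransitionNotFoundError(
            f"no SRM transition within {tol_mz} of {precursor_mz} -> {product_mz}"
        )
    if len(matches) > 1:
        cands = ", ".join(f"{c.precursor_mz}->{c.product_mz}" for c in matches)
        raise AmbiguousTransitionError(
            f"{len(matches)} SRM transitions match {precursor_mz} -> {product_mz} "
            f"within {tol_mz}: {cands}"
        )
    return matches[0]


def bin2d(pm: PeakMap, rt_edges, mz_edges, ms_level: int = 1) -> np.ndarray:
    """2D intensity histogram over half-open RT x m/z bins.

    ``matrix[i, j]`` sums peak intensities with rt in
    ``[rt_edges[i], rt_edges[i+1])`` and m/z in ``[mz_edges[j], mz_edges[j+1])``.
    This is the computation behind peakmap heatmap displays.
    """
    rt_edges = np.asarray(rt_edges, dtype=np.float64)
    mz_edges = np.asarray(mz_edges, dtype=np.float64)
    for edges in (rt_edges, mz_edges):
        if len(edges) < 2 or not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be ascending with >= 2 entries")
    out = np.zeros((len(rt_edges) - 1, len(mz_edges) - 1))
    for s in pm.spectra:
        if s.ms_level != ms_level:
            continue
        i = np.searchsorted(rt_edges, s.rt, side="right") - 1
        if i < 0 or i >= out.shape[0]:
            continue
        j = np.searchsorted(mz_edges, s.mzs, side="right") - 1
        ok = (j >= 0) & (j < out.shape[1])
        np.add.at(out[i], j[ok], s.intensities[ok])
    return out
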