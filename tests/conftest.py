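"""Shared fixtures: random peakmaps, random tables and demo-run helpers."""

from __future__ import annotations

import numpy as np
import pytest

import mzkit.table as tbl
from mzkit.peakmap import Chromatogram, PeakMap, Precursor, Spectrum


def make_random_peakmap(seed: int, n_spectra: int = 10, n_peaks: int = 25,
                        with_chromatograms: bool = True,
                        with_ms2: bool = True) -> PeakMap:
    rng = np.random.default_rng(seed)
    spectra = []
    rt = 0.0
    for i in range(n_spectra):
        rt += float(rng.uniform(0.5, 2.0))
        n = int(rng.integers(0, n_peaks + 1))
        mzs = np.sort(rng.uniform(80.0, 900.0, n))
        mzs = np.unique(mzs)
        intensities = rng.uniform(0.0, 1e6, len(mzs))
        if with_ms2 and i % 4 == 3:
            spectra.append(Spectrum(rt, mzs, intensities, 2, "-",
                                    (Precursor(float(rng.uniform(100, 800)),
                                               int(rng.integers(1, 4)), 0.5),)))
        else:
            spectra.append(Spectrum(rt, mzs, intensities, 1, "+"))
    chroms = []
    if with_chromatograms:
        for k in range(int(rng.integers(1, 4))):
            rts = np.cumsum(rng.uniform(0.2, 1.0, 30))
            chroms.append(Chromatogram("SRM", rts, rng.uniform(0, 1e5, 30),
                                       float(rng.uniform(100, 800)),
                                       float(rng.uniform(50, 500))))
    return PeakMap(tuple(spectra), tuple(chroms), {"run_id": f"random-{seed}"})


_CELL_MAKERS = {
    "integer": lambda rng: int(rng.integers(-50, 50)),
    "real": lambda rng: float(np.round(rng.normal(0, 10), 3)),
    "text": lambda rng: str(rng.choice(["aa", "bb", "cc", "dd", ""])),
    "boolean": lambda rng: bool(rng.integers(0, 2)),
}


def make_random_table(seed: int, n_rows: int = 30, missing_rate: float = 0.15,
                      col_types=("integer", "real", "text", "boolean")):
    rng = np.random.default_rng(seed)
    names = [f"c{i}" for i in range(len(col_types))]
    rows = []
    for _ in range(n_rows):
        row = []
        for t in col_types:
            if rng.random() < missing_rate:
                row.append(None)
            else:
                row.append(_CELL_MAKERS[t](rng))
        rows.append(tuple(row))
    return names, list(col_types), rows


@pytest.fixture
def random_peakmap():
    return make_random_peakmap(42)


@pytest.fixture
def small_table():
    return tbl.create_table(
        ["id", "mz", "name", "ok"],
        ["integer", "real", "text", "boolean"],
        [
            (1, 100.5, "a", True),
            (2, None, "b", False),
            (3, 300.25, None, None),
            (4, 100.5, "a", True),
        ],
    )
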