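"""Synthetic LC-MS and MRM runs with exact ground truth.

The generator emulates the situation a targeted metabolomics workflow
faces: a handful of compounds eluting as parametric Gaussian or EMG
peaks on a regular scan grid, optionally with a global retention-time
shift per run (systematic drift between samples), constant baseline and
additive/multiplicative intensity noise.  There is no chromatographic
physics: peak shapes are parametric, which is what makes the ground
truth exact.

Each compound is expanded into its isotopologues (via
:mod:`mzkit.chemistry`) at natural abundances; every isotopologue above
a relative-abundance cutoff becomes one m/z channel.  The ground-truth
table lists, per compound and isotopologue, the theoretical m/z, the
apex RT after the shift, and the closed-form trace area (compound area
times absolute isotopologue abundance).

Identical seed and parameters produce bit-identical runs; the noise
algorithm (numpy PCG64) and seed are recorded in the run metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import table as tbl
from .chemistry import adduct_mz, default_adducts, find_adduct, isotope_pattern, parse_formula
from .integrate import emg_model
from .peakmap import Chromatogram, PeakMap, Spectrum

__all__ = [
    "SimulatedCompound",
    "SimulatedRun",
    "MrmTransition",
    "simulate_run",
    "simulate_mrm_run",
    "load_run_config",
    "SimulationSpecError",
]


class SimulationSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SimulatedCompound:
    name: str
    formula: str
    rt: float                      # apex RT in seconds, before the global shift
    area: float = 1e5              # closed-form trace area of the whole compound
    adduct: str = "[M+H]+"
    shape: str = "gaussian"        # 'gaussian' or 'emg'
    sigma: float = 3.0             # seconds
    tau: float = 0.0               # EMG tailing, seconds (shape 'emg' only)


@dataclass(frozen=True)
class SimulatedRun:
    compounds: tuple[SimulatedCompound, ...] = ()
    scan_interval: float = 1.0     # seconds between MS1 scans
    rt_start: float = 0.0
    rt_end: float = 600.0
    rt_shift: float = 0.0          # global shift applied to every apex
    baseline: float = 0.0          # constant intensity added to each channel
    noise_sigma_add: float = 0.0   # additive Gaussian noise, intensity units
    noise_sigma_mult: float = 0.0  # multiplicative noise, fraction
    noise_mz_channels: int = 0     # extra channels carrying only baseline/noise
    min_rel_abundance: float = 1e-3
    seed: int = 0
    polarity: str = "+"

    def __post_init__(self):
        if self.scan_interval <= 0:
            raise SimulationSpecError("scan_interval must be positive")
        if self.rt_end < self.rt_start:
            raise SimulationSpecError("rt_end must be >= rt_start")
        object.__setattr__(self, "compounds", tuple(self.compounds))


@dataclass(frozen=True)
class MrmTransition:
    precursor_mz: float
    product_mz: float
    rt: float
    area: float = 1e5
    sigma: float = 3.0
    shape: str = "gaussian"
    tau: float = 0.0


def _shape_trace(t: np.ndarray, shape: str, area: float, mu: float,
                 sigma: float, tau: float) -> np.ndarray:
    height = area / (sigma * np.sqrt(2 * np.pi))
    if shape == "gaussian" or tau <= 0:
        return height * np.exp(-((t - mu) ** 2) / (2 * sigma ** 2))
    if shape == "emg":
        return emg_model(t, height, mu, sigma, tau)
    raise SimulationSpecError(f"unknown peak shape {shape!r}")


def _apex_rt(shape: str, mu: float, sigma: float, tau: float) -> float:
    if shape == "gaussian" or tau <= 0:
        return mu
    grid = np.arange(mu - 5 * sigma, mu + 5 * (sigma + tau), sigma / 200.0)
    vals = emg_model(grid, 1.0, mu, sigma, tau)
    return float(grid[int(np.argmax(vals))])


def _channels(run: SimulatedRun):
    """(mz, shape, area, mu, sigma, tau, name, isotopologue) per channel."""
    adducts = default_adducts()
    channels = []
    for c in run.compounds:
        adduct = find_adduct(c.adduct, adducts)
        f = parse_formula(c.formula) * adduct.multiplier
        pattern = isotope_pattern(f, min_abundance=1e-9)
        top = max(a for _, a in pattern.entries)
        mu = c.rt + run.rt_shift
        for k, (mass, ab) in enumerate(pattern.entries):
            if ab / top < run.min_rel_abundance:
                continue
            mz = (mass + adduct.mass_delta) / abs(adduct.charge)
            channels.append((mz, c.shape, c.area * ab, mu, c.sigma, c.tau, c.name, k))
    # ambiguous ground truth: identical m/z AND identical apex RT
    for i in range(len(channels)):
        for j in range(i + 1, len(channels)):
            if (abs(channels[i][0] - channels[j][0]) <= 1e-6
                    and abs(channels[i][3] - channels[j][3]) <= 1e-9):
                raise SimulationSpecError(
                    f"compounds {channels[i][6]!r} and {channels[j][6]!r} overlap at "
                    f"m/z {channels[i][0]:.6f} with identical apex RT"
                )
    return channels


def _noisy(values: np.ndarray, run: SimulatedRun, rng: np.random.Generator) -> np.ndarray:
    v = values + run.baseline
    if run.noise_sigma_mult > 0:
        v = v * (1.0 + rng.normal(0.0, run.noise_sigma_mult, size=v.shape))
    if run.noise_sigma_add > 0:
        v = v + rng.normal(0.0, run.noise_sigma_add, size=v.shape)
    return np.clip(v, 0.0, None)


def simulate_run(run: SimulatedRun) -> tuple[PeakMap, tbl.Table]:
    """Generate centroided MS1 spectra on the scan grid plus ground truth."""
    rng = np.random.default_rng(run.seed)
    channels = _channels(run)
    if run.noise_mz_channels:
        for i in range(run.noise_mz_channels):
            mz = float(rng.uniform(100.0, 900.0))
            channels.append((mz, "gaussian", 0.0, run.rt_start - 1.0, 1.0, 0.0,
                             f"_noise_{i}", -1))
    channels.sort(key=lambda ch: ch[0])
    scans = np.arange(run.rt_start, run.rt_end + run.scan_interval / 2.0,
                      run.scan_interval)
    mzs = np.array([ch[0] for ch in channels])
    # trace matrix: channels x scans
    traces = np.zeros((len(channels), len(scans)))
    for i, (mz, shape, area, mu, sigma, tau, _, k) in enumerate(channels):
        if area > 0:
            traces[i] = _shape_trace(scans, shape, area, mu, sigma, tau)
    spectra = []
    emit_floor = 1e-12
    for j, rt in enumerate(scans):
        col_v = _noisy(traces[:, j], run, rng)
        keep = (col_v > 0) & ((traces[:, j] > emit_floor) | (run.baseline > 0)
                              | (run.noise_sigma_add > 0))
        mz_keep = mzs[keep]
        int_keep = col_v[keep]
        # merge exact m/z collisions (mass isomers share a channel m/z)
        if len(mz_keep) > 1:
            uniq, inv = np.unique(mz_keep, return_inverse=True)
            summed = np.zeros(len(uniq))
            np.add.at(summed, inv, int_keep)
            mz_keep, int_keep = uniq, summed
        spectra.append(Spectrum(float(rt), mz_keep, int_keep, 1, run.polarity))
    metadata = {
        "run_id": "simulated",
        "instrument": "synthetic LC-MS generator",
        "noise_algorithm": "numpy-pcg64",
        "seed": run.seed,
    }
    pm = PeakMap(tuple(spectra), (), metadata)
    truth_rows = [
        (name, k, mz, _apex_rt(shape, mu, sigma, tau), area)
        for mz, shape, area, mu, sigma, tau, name, k in channels
        if k >= 0
    ]
    truth = tbl.create_table(
        ["name", "isotopologue", "mz", "rt_apex", "area"],
        ["text", "integer", "real", "real", "real"],
        truth_rows,
    )
    return pm, truth


def simulate_mrm_run(transitions, scan_interval: float = 1.0, rt_start: float = 0.0,
                     rt_end: float = 600.0, baseline: float = 0.0,
                     noise_sigma_add: float = 0.0, noise_sigma_mult: float = 0.0,
                     seed: int = 0) -> tuple[PeakMap, tbl.Table]:
    """Generate SRM chromatograms with known areas."""
    rng = np.random.default_rng(seed)
    seen = set()
    for tr in transitions:
        key = (round(tr.precursor_mz, 9), round(tr.product_mz, 9))
        if key in seen:
            raise SimulationSpecError(
                f"duplicate transition {tr.precursor_mz} -> {tr.product_mz}"
            )
        seen.add(key)
    scans = np.arange(rt_start, rt_end + scan_interval / 2.0, scan_interval)
    helper = SimulatedRun(baseline=baseline, noise_sigma_add=noise_sigma_add,
                          noise_sigma_mult=noise_sigma_mult, seed=seed)
    chroms = []
    truth_rows = []
    for tr in transitions:
        trace = _shape_trace(scans, tr.shape, tr.area, tr.rt, tr.sigma, tr.tau)
        trace = _noisy(trace, helper, rng)
        chroms.append(Chromatogram("SRM", scans, trace, tr.precursor_mz, tr.product_mz))
        truth_rows.append((tr.precursor_mz, tr.product_mz,
                           _apex_rt(tr.shape, tr.rt, tr.sigma, tr.tau), tr.area))
    metadata = {
        "run_id": "simulated-mrm",
        "instrument": "synthetic MRM generator",
        "noise_algorithm": "numpy-pcg64",
        "seed": seed,
    }
    pm = PeakMap((), tuple(chroms), metadata)
    truth = tbl.create_table(
        ["precursor_mz", "product_mz", "rt_apex", "area"],
        ["real", "real", "real", "real"],
        truth_rows,
    )
    return pm, truth


# --------------------------------------------------------------------------
# canonical amino-acid demo run
#
# Five well-separated reference amino acids plus the mass isomers leucine
# and isoleucine (identical formula C6H13NO2, hence identical m/z), which
# elute 18 s apart.  With 6 s integration half-windows and inter-sample RT
# shifts of up to +-10 s, widening the windows enough to absorb the drift
# (half-width >= 13 s) would make the two isomer windows overlap and merge
# the peaks -- the situation that requires reference-based shift correction.

#: (name, formula, apex RT in s, role)
AMINO_ACID_PANEL: tuple[tuple[str, str, float, str], ...] = (
    ("glycine", "C2H5NO2", 60.0, "reference"),
    ("alanine", "C3H7NO2", 120.0, "reference"),
    ("proline", "C5H9NO2", 240.0, "reference"),
    ("valine", "C5H11NO2", 180.0, "reference"),
    ("phenylalanine", "C9H11NO2", 420.0, "reference"),
    ("leucine", "C6H13NO2", 300.0, "analyte"),
    ("isoleucine", "C6H13NO2", 318.0, "analyte"),
)

#: chromatographic peak width of the demo run, seconds
AMINO_ACID_SIGMA = 1.5
#: compound area of every demo peak, intensity*seconds
AMINO_ACID_AREA = 1e5


def amino_acid_run(rt_shift: float = 0.0, seed: int = 0,
                   noise_sigma_add: float = 100.0) -> SimulatedRun:
    """The demo run: 1 s scans over 0-480 s, peak height ~2.6e4.

    The default additive noise of 100 counts gives an apex
    signal-to-noise ratio of roughly 250 — abundant, well-detected
    compounds, where integration error is dominated by quadrature
    rather than noise.  Pass a larger value to emulate weak signals.
    """
    compounds = tuple(
        SimulatedCompound(name, formula, rt=rt, area=AMINO_ACID_AREA,
                          sigma=AMINO_ACID_SIGMA)
        for name, formula, rt, _ in AMINO_ACID_PANEL
    )
    return SimulatedRun(compounds=compounds, scan_interval=1.0, rt_start=0.0,
                        rt_end=480.0, rt_shift=rt_shift,
                        noise_sigma_add=noise_sigma_add, seed=seed)


def amino_acid_targets(rt_tol: float = 6.0, mz_tol: float = 0.003):
    """Target list matching :func:`amino_acid_run` (6 s RT half-windows)."""
    from .targeted import Target

    return [
        Target(name, formula, rt=rt, rt_tol=rt_tol, mz_tol=mz_tol, role=role)
        for name, formula, rt, role in AMINO_ACID_PANEL
    ]


def load_run_config(path) -> SimulatedRun:
    """Read a run spec from a YAML/JSON key-value file.

    Top-level keys mirror :class:`SimulatedRun` fields; ``compounds`` is
    a list of mappings mirroring :class:`SimulatedCompound`.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SimulationSpecError("run config must be a mapping")

    def _coerce(mapping: dict, cls) -> dict:
        # YAML leaves "1.0e4" (unsigned exponent) as a string; coerce
        # numeric fields so configs stay forgiving
        out = {}
        for key, value in mapping.items():
            f = cls.__dataclass_fields__.get(key)
            if f is not None and f.type == "float" and isinstance(value, str):
                value = float(value)
            out[key] = value
        return out

    compounds = [SimulatedCompound(**_coerce(c, SimulatedCompound))
                 for c in raw.pop("compounds", [])]
    known = set(SimulatedRun.__dataclass_fields__) - {"compounds"}
    unknown = set(raw) - known
    if unknown:
        raise SimulationSpecError(f"unknown run config keys: {sorted(unknown)}")
    return SimulatedRun(compounds=tuple(compounds), **_coerce(raw, SimulatedRun))
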