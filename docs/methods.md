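# Methods

This note documents the models, numerical choices and limitations
behind mzkit, module by module.

## Chemistry

Molecular formulas are immutable atom multisets over a versioned,
embedded element table (IUPAC/NIST exact masses and natural abundances;
per-element abundances sum to 1 within 1e-6). The grammar accepts
element tokens with counts, parenthesized groups with multipliers and
bracketed fixed isotopes (`[13]C6`); charge notation is rejected so that
formula algebra stays closed under addition and integer multiplication —
charges belong to adducts.

*Monoisotopic mass* sums the most-abundant-isotope mass per atom (a
fixed isotope contributes its own mass). *Isotope patterns* are built by
convolving per-element multinomial distributions: the n-atom
distribution of one element is formed by n sequential convolutions with
the single-atom distribution, entries within 1e-9 Da are merged by
abundance-weighted mass, and entries below the `min_abundance` threshold
are pruned after each convolution step. Sequential (rather than
binary-exponentiation) convolution is used deliberately: because each
convolution partner sums to exactly 1, the pruned abundance accumulates
additively and the conservation bound sum ≥ 1 − pruned is exact and
checkable. Abundances are reported absolutely (sum ≤ 1);
max-normalization is a separate transform.

Adduct m/z is (multiplier · M + Δ) / |z| where Δ includes the gained or
lost electrons. The built-in library of ~20 common ESI adducts derives
every Δ from the element table rather than hard-coding constants, and
can be overridden from a delimited file.

## PeakMap and mzML

A PeakMap is the immutable full dataset of one run: centroided spectra
sorted by RT plus chromatograms (SRM/EIC/TIC). Conventions fixed here:
RT is in seconds everywhere; m/z and RT extraction windows are closed
intervals; spectra with no peak inside the m/z window contribute an
explicit zero EIC point, so the number of EIC points is determined by
the RT window alone. Profile-mode spectra are accepted with a warning
but not centroided.

mzML reading is a streaming parser over the mzML schema (stdlib
ElementTree iterparse, constant memory): it accepts 32- and 64-bit
arrays, zlib or uncompressed, and converts times declared in minutes to
seconds. Writing emits indexed mzML with zlib-compressed 64-bit arrays
for both spectrum and chromatogram lists, so write→read round-trips are
bit-identical; the files are also readable by Bioconductor's mzR, which
the test suite uses as an independent oracle. 2D binning for heatmaps
uses half-open bins on both axes so the matrix total equals the total
in-range intensity exactly.

## Table engine

Tables are typed, named-column relational containers backed by SQLite —
in memory by default, on a file (or an anonymous on-disk temporary) for
out-of-core work. All operations stream rows in fixed-size batches
through SQL, so peak memory is bounded independent of row count in both
modes, and every operation returns a new table, leaving inputs
untouched.

Missing values follow SQL three-valued logic: any operator applied to
missing yields missing (division by zero also yields missing), filters
keep only rows whose predicate is *true*, aggregates ignore missing,
`count` counts non-missing, and missing keys group together.
Deterministic ordering rules: filters and computed columns preserve row
order; joins order output by (left row, right row); grouping orders by
first appearance of the key; sorts are stable with the SQL convention
for missing (first ascending, last descending). Right-side join columns
colliding with left names get a configurable `__1` postfix. Expressions
are a closed operator set compiled to SQL; a row-wise `apply` escape
hatch exists for memory-mode tables only.

Persistence is a single SQLite file with a versioned JSON header, the
row data, and content-addressed blob tables for referenced peakmaps
(serialized as mzML) and nested tables — each referenced object is
stored once no matter how many rows share it, and sharing is
reconstructed on load. Floating-point aggregate values may differ from a
naive left-fold summation in the last ulp because SQLite ≥ 3.44 sums
with compensation; the differential tests therefore compare engine
modes bit-exactly but allow 1e-12 relative slack against the naive
oracle.

## Integration

Five integrators, each tagging its method id into the result for
provenance:

- **trapezoid** — quadrature of (intensity − baseline) clipped at 0.
  Fewer than two points in the window yields area 0.
- **sgolay** — trapezoid on a Savitzky-Golay smoothed trace
  (default window 7 points, order 3); rmse is the RMS raw-minus-smoothed
  difference. Too few points falls back to trapezoid with a flagged
  method id.
- **emg** — least-squares fit of the exponentially modified Gaussian
  h(t; H, μ, σ, τ), parameterized so that τ→0 tends to a Gaussian of
  height H and the area is H·σ·√(2π) in closed form. Evaluation switches
  to the scaled complementary error function (erfcx) where the plain
  exp·erfc product would overflow, so large σ/τ is stable.
  Initialization is deterministic: μ₀ at the intensity maximum (earliest
  RT on ties), σ₀ from the half width at half maximum, τ₀ = σ₀, H₀ = max.
  Non-convergence returns an explicit failed-fit result, never an
  exception.
- **max** and **no_integration** — peak height as a quantification
  proxy, and an explicit placeholder.

The baseline is a constant parameter (default 0); there is no automatic
baseline estimation. Table-level integration requires the peak-table
convention (id, mzmin, mzmax, rtmin, rtmax, peakmap reference), flags
rows with unresolvable peakmaps while the rest proceed, and computes
each row independently, so the output is bit-identical for any worker
count; parallelism uses a process pool over extracted traces.
Re-integration replaces one row's window and result columns and touches
nothing else.

## Targeted workflow

Targets carry a formula, adduct, expected RT, RT half-window and m/z
tolerance (Da, or ppm converted at the theoretical m/z). The per-sample
shift estimate is the median (configurable to mean) of apex-minus-expected
deviations over the reference compounds, searched in windows widened by
a factor of 3 (configurable); references that are not found are excluded
and a sample with no located reference is flagged, not dropped. A single
global shift per sample is used — not RT-dependent warping — matching
the failure mode being corrected: a small set of co-eluting isomer
windows translated by one estimate. Which targets get shifted is a
parameter (default: all).

## Alignment and grouping

RT alignment fits a monotone map through anchor pairs: piecewise-linear
interpolation that passes exactly through the anchors, or a
lowess-smoothed variant. Monotonicity is enforced by isotonic repair of
the anchor targets (plus a minimal-epsilon strictification) rather than
rejection, because applying an alignment must never reorder spectra;
outside the anchor span the boundary slope continues linearly.
Piecewise-linear models expose an exact inverse. m/z recalibration is an
affine least-squares fit with an RMS residual summary; gains outside
[0.99, 1.01] are warned about.

Isotope grouping partitions a feature table greedily: seeds in
descending intensity (ties by ascending m/z) claim unclaimed peaks at
mz + k·Δ/z (Δ = 1.0033548378 Da, the ¹³C−¹²C difference; k up to 8,
z up to `max_charge`) within the m/z and RT tolerances, keeping the
charge that explains the most members (lower z on ties). Greedy
intensity-descending seeding was chosen for determinism under row
permutation. Averagine-style spacing refinements are out of scope.
Adduct grouping links co-eluting groups whose monoisotopic m/z values
imply the same neutral mass under two different library adducts, via
union-find with deterministic pair order.

## Synthetic runs

The generator emulates what the targeted modules need from real data:
compounds as parametric Gaussian/EMG peaks on a regular scan grid,
expanded into isotopologue channels (natural abundances, relative
cutoff 0.1%), a per-run global RT shift, constant baseline and
additive/multiplicative Gaussian noise floored at zero (numpy PCG64;
algorithm and seed recorded in run metadata). Channels sharing an exact
m/z — mass isomers — are summed into one centroid per scan. Ground truth
lists each isotopologue's theoretical m/z, post-shift apex RT and
closed-form area (compound area × absolute abundance). Identical seeds
give bit-identical runs, and a spec with two channels at the same m/z
*and* the same apex RT is rejected as ambiguous.

What it does not model: chromatographic physics (no column model, no
RT-dependent warping), detector saturation, centroiding artifacts,
electronic spray ionization suppression, or correlated noise. Passing
tests therefore demonstrate the correctness of the algorithms under the
stated peak model, not robustness to every artifact of real
chromatography.

The canonical demo (`amino_acid_run`) fixes the study conditions used
throughout the tests and the acceptance script: five reference amino
acids at 60–420 s, leucine/isoleucine at 300/318 s (identical m/z
132.1019), peak σ = 1.5 s, area 10⁵ per compound, 1 s scans over
0–480 s, and additive noise of 100 counts (apex SNR ≈ 250; the
shift-recovery grid overrides this to 1300 counts, apex SNR ≈ 20). The
18 s isomer separation with 6 s integration half-windows means drifts of
up to ±10 s cannot be absorbed by window widening — half-widths ≥ 13 s
would make the isomer windows overlap — while a 9 s drift against
uncorrected windows loses ≈ 95% of both isomer areas. Noise at the zero
floor biases trapezoid areas upward by ≈ 0.4·σ_noise·W per window, which
at the default noise level stays ≈ 0.3% of the true area — small against
the workflow's 2% recovery budget, and the reason the demo models
abundant rather than trace-level compounds.

## Problem sizes

Tests and the acceptance script run entirely on generated data: runs of
~500 scans with ≤ 40 m/z channels, tables of ≤ 100 rows for differential
checks (500 randomized sequences), 100 persistence round-trips, 20 mzML
round-trips, and a 21-point shift grid with several seeds per point.
These sizes keep the whole suite in the tens of seconds while every
check remains statistically meaningful; all generators scale up by
parameter if heavier validation is wanted.
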