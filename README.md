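# mzkit

Scriptable building blocks for targeted and untargeted LC-MS/MS data
analysis in Python: peakmaps (centroided MS<sup>n</sup> spectra and MRM
chromatograms) with mzML I/O, a typed relational **Table** engine over
SQLite with optional out-of-core storage, molecular-formula chemistry
with isotope-pattern generation, extracted-ion-chromatogram (EIC)
integration, retention-time and m/z alignment, isotope/adduct grouping,
and a synthetic-run generator with exact ground truth.

The package is aimed at analytical labs and core facilities that need
*programmable* peak-list processing — workflows that go beyond what
fixed-pipeline GUI tools offer — while staying close to the raw data.

## The problem the workflow modules solve

Retention times drift between LC-MS samples. For most compounds the fix
is trivial: widen the RT integration windows. It fails when two analytes
are **mass isomers** — same molecular formula, hence exactly the same
m/z — such as leucine and isoleucine (both C₆H₁₃NO₂, monoisotopic mass
131.094629 Da). They are distinguishable only chromatographically, so
windows wide enough to absorb the drift would overlap and merge the two
peaks.

`mzkit.targeted` implements the reference-based correction: locate
well-separated *reference* compounds (other amino acids, at distinct
m/z) in each sample, take the **median deviation of their EIC apexes
from the expected RTs** as that sample's global shift Δ̂, translate the
isomers' integration windows by Δ̂, then integrate:

&nbsp;&nbsp;&nbsp;&nbsp;Δ̂ = median<sub>r ∈ references</sub> ( rt<sub>apex</sub>(r) − rt<sub>expected</sub>(r) )

Peak areas come from trapezoidal quadrature of the EIC, a
Savitzky-Golay-smoothed variant, or a least-squares fit of the
exponentially modified Gaussian (EMG) peak model
h(t; H, μ, σ, τ) with closed-form area H·σ·√(2π).

## Worked example

Three simulated samples with known RT shifts {0, +4, +9} s, seven amino
acid targets (five references plus the Leu/Ile isomer pair at identical
m/z 132.1019, eluting 18 s apart, integrated with 6 s half-windows):

```python
from mzkit.simulate import amino_acid_run, amino_acid_targets, simulate_run
from mzkit.targeted import WorkflowConfig, run_targeted_workflow

samples = [(f"sample{i}", simulate_run(amino_acid_run(rt_shift=shift, seed=i))[0])
           for i, shift in enumerate([0.0, 4.0, 9.0])]
result = run_targeted_workflow(samples, amino_acid_targets(), WorkflowConfig())

for row in result:
    if row["target"] in ("leucine", "isoleucine"):
        print(f"{row['sample']}  {row['target']:<11} shift={row['shift_used']:+.1f}s  "
              f"apex={row['apex_rt']:.0f}s  area={row['area']:.0f}")
```

Output:

```
sample0  leucine     shift=+0.0s  apex=300s  area=93205
sample0  isoleucine  shift=+0.0s  apex=318s  area=93527
sample1  leucine     shift=+4.0s  apex=304s  area=92890
sample1  isoleucine  shift=+4.0s  apex=322s  area=93675
sample2  leucine     shift=+9.0s  apex=309s  area=93751
sample2  isoleucine  shift=+9.0s  apex=327s  area=93820
```

Every sample's shift is estimated exactly from the references, and all
areas agree with the generator's ground truth (the monoisotopic
isotopologue carries 92 816 of each compound's 10⁵ total area; the
integrals land within ~1%). With `WorkflowConfig(correct_rt_shift=False)`
the +9 s sample recovers only ~5% of the Leu/Ile areas — the stale
windows miss the peaks.

Tables are relational and SQLite-backed (in memory by default, on disk
for large peak lists):

```python
from mzkit import col, create_table
from mzkit.table import group_aggregate, set_storage_mode

t = set_storage_mode(result, "disk")                    # out-of-core copy
good = t.filter((col("flag") == "ok") & (col("area") > 1e4))
means = group_aggregate(good, ["target"], [("area", "mean"), ("area", "count")])
```

## Command line

```bash
mzkit simulate run.yaml --out-mzml run.mzML --out-truth truth.csv
mzkit info run.mzML
mzkit extract run.mzML --mz-min 132.0989 --mz-max 132.1049 -o eic.csv
mzkit integrate --targets targets.csv --sample s1.mzML --sample s2.mzML \
      --out-csv result.csv --out-table result.table
```

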