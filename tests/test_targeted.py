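"""Targeted workflow: peak tables, apex location, RT-shift correction."""

import numpy as np
import pytest

import mzkit.table as T
from mzkit.peakmap import PeakMap, Spectrum
from mzkit.simulate import amino_acid_run, amino_acid_targets, simulate_run
from mzkit.targeted import (
    RtShiftError,
    Target,
    WorkflowConfig,
    apply_rt_shift,
    build_peak_table,
    estimate_rt_shift,
    locate_apex,
    read_targets_csv,
    run_targeted_workflow,
)


class TestTarget:
    def test_ppm_versus_da_tolerance(self):
        t_ppm = Target("leu", "C6H13NO2", rt=300, mz_tol=10, mz_tol_unit="ppm")
        lo, hi = t_ppm.mz_window()
        assert (hi - lo) / 2 == pytest.approx(132.10191 * 10e-6, abs=1e-6)
        assert (hi - lo) / 2 == pytest.approx(0.00132, abs=1e-5)

    def test_invalid_tolerances_rejected(self):
        with pytest.raises(ValueError):
            Target("x", "H2O", rt_tol=0.0)
        with pytest.raises(ValueError):
            Target("x", "H2O", mz_tol=-1.0)

    def test_formula_error_names_target(self):
        bad = Target("mystery", "Xx2", rt=10)
        with pytest.raises(Exception, match="mystery"):
            bad.theoretical_mz()

    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "targets.csv"
        p.write_text(
            "name,formula,adduct,rt_sec,rt_tol_sec,mz_tol,role\n"
            "leucine,C6H13NO2,[M+H]+,300,6,0.003da,analyte\n"
            "glycine,C2H5NO2,[M+H]+,60,6,10ppm,reference\n"
        )
        targets = read_targets_csv(p)
        assert targets[0].mz_tol_unit == "da" and targets[1].mz_tol_unit == "ppm"
        assert targets[1].role == "reference"


class TestBuildPeakTable:
    def test_mass_isomers_share_mz_but_not_rt(self):
        # leucine/isoleucine have identical formulas, so their m/z windows
        # coincide and only the RT windows can separate them
        targets = [Target("leu", "C6H13NO2", rt=300, rt_tol=6),
                   Target("ile", "C6H13NO2", rt=318, rt_tol=6)]
        pt = build_peak_table(targets)
        leu, ile = pt[0], pt[1]
        assert leu["mzmin"] == ile["mzmin"] and leu["mzmax"] == ile["mzmax"]
        assert leu["rtmax"] < ile["rtmin"]

    def test_zero_targets(self):
        assert len(build_peak_table([])) == 0

    def test_satisfies_peak_table_convention(self):
        pt = build_peak_table(amino_acid_targets())
        for c in ("id", "mzmin", "mzmax", "rtmin", "rtmax", "peakmap"):
            assert c in pt.col_names
        ids = pt.col_values("id")
        assert len(set(ids)) == len(ids)
        for row in pt:
            assert row["mzmin"] <= row["mzmax"] and row["rtmin"] <= row["rtmax"]


class TestLocateApex:
    def test_single_gaussian_apex(self):
        pm, _ = simulate_run(amino_acid_run(seed=3))
        t = Target("leucine", "C6H13NO2", rt=300, rt_tol=6)
        rt, intensity = locate_apex(pm, t)
        assert abs(rt - 300.0) <= 1.0  # within one scan interval
        assert intensity > 0

    def test_empty_window_is_not_found(self):
        pm = PeakMap((Spectrum(1.0, np.array([500.0]), np.array([10.0])),))
        t = Target("leucine", "C6H13NO2", rt=300, rt_tol=6)
        assert locate_apex(pm, t) is None

    def test_tie_takes_earliest_rt(self):
        mz = Target("leucine", "C6H13NO2", rt=10, rt_tol=10).theoretical_mz()
        spectra = tuple(
            Spectrum(float(i), np.array([mz]), np.array([v]))
            for i, v in enumerate([1.0, 7.0, 7.0, 2.0])
        )
        rt, _ = locate_apex(PeakMap(spectra), Target("leucine", "C6H13NO2",
                                                     rt=10, rt_tol=10))
        assert rt == 1.0


class TestEstimateShift:
    def test_uniform_shift_recovered(self):
        pm, _ = simulate_run(amino_acid_run(rt_shift=5.0, seed=1))
        refs = [t for t in amino_acid_targets() if t.role == "reference"]
        est = estimate_rt_shift(pm, refs, sample_id="s")
        assert abs(est.shift - 5.0) <= 0.5
        assert est.n_used == 5

    def test_zero_shift(self):
        pm, _ = simulate_run(amino_acid_run(seed=2))
        refs = [t for t in amino_acid_targets() if t.role == "reference"]
        est = estimate_rt_shift(pm, refs)
        assert abs(est.shift) <= 0.5

    def test_median_robust_to_one_outlier(self):
        # four references drifted +5 s, one bogus +30 s: the median holds
        refs = [Target(f"r{i}", "C3H7NO2", rt=float(60 * (i + 1)), rt_tol=6,
                       role="reference") for i in range(5)]
        mz = refs[0].theoretical_mz()
        spectra = []
        for i, ref in enumerate(refs):
            shift = 30.0 if i == 4 else 5.0
            for dt in np.arange(-10, 10.5, 1.0):
                rt = ref.rt + shift + dt
                spectra.append(Spectrum(rt, np.array([mz]),
                                        np.array([np.exp(-dt ** 2 / 8) * 1e4])))
        est = estimate_rt_shift(PeakMap(tuple(spectra)), refs)
        assert est.shift == pytest.approx(5.0, abs=0.5)

    def test_no_references_found_raises(self):
        pm = PeakMap((Spectrum(1.0, np.array([500.0]), np.array([1.0])),))
        refs = [t for t in amino_acid_targets() if t.role == "reference"]
        with pytest.raises(RtShiftError, match="sampleX"):
            estimate_rt_shift(pm, refs, sample_id="sampleX")


class TestApplyShift:
    def _pt(self):
        return build_peak_table(amino_acid_targets())

    def test_zero_shift_is_identity(self):
        pt = self._pt()
        assert T.tables_equal(apply_rt_shift(pt, 0.0), pt)

    def test_shift_then_unshift_is_identity(self):
        pt = self._pt()
        back = apply_rt_shift(apply_rt_shift(pt, 5.0), -5.0)
        assert T.tables_equal(back, pt)

    def test_only_subset_rows_change(self):
        pt = self._pt()
        shifted = apply_rt_shift(pt, 9.0, ["leucine", "isoleucine"])
        for a, b in zip(pt, shifted):
            if a["name"] in ("leucine", "isoleucine"):
                assert b["rtmin"] == a["rtmin"] + 9.0
            else:
                assert b == a

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            apply_rt_shift(self._pt(), 1.0, ["nonexistent"])

    def test_translation_preserves_window_gaps(self):
        pt = self._pt()
        shifted = apply_rt_shift(pt, 9.0, ["leucine", "isoleucine"])
        rows = {r["name"]: r for r in shifted}
        assert rows["leucine"]["rtmax"] < rows["isoleucine"]["rtmin"]


class TestWorkflow:
    def test_three_samples_with_known_shifts(self):
        samples = [(f"s{i}", simulate_run(amino_acid_run(rt_shift=s, seed=10 + i))[0])
                   for i, s in enumerate((0.0, 4.0, 9.0))]
        truth = {r["name"]: r["area"] for r in
                 simulate_run(amino_acid_run())[1] if r["isotopologue"] == 0}
        res = run_targeted_workflow(samples, amino_acid_targets(), WorkflowConfig())
        assert len(res) == 3 * 7
        for row in res:
            assert row["flag"] == "ok"
            assert row["area"] == pytest.approx(truth[row["target"]], rel=0.02)

    def test_uncorrected_windows_miss_shifted_isomers(self):
        # the failure mode: a 9 s drift against 6 s half-windows loses the
        # leucine/isoleucine peaks almost entirely
        pm, truth = simulate_run(amino_acid_run(rt_shift=9.0, seed=33))
        truth_mono = {r["name"]: r["area"] for r in truth if r["isotopologue"] == 0}
        res = run_targeted_workflow(
            [("s", pm)], amino_acid_targets(),
            WorkflowConfig(correct_rt_shift=False),
        )
        for row in res:
            if row["target"] in ("leucine", "isoleucine"):
                assert row["area"] < 0.5 * truth_mono[row["target"]]

    def test_correction_restores_recovery(self):
        pm, truth = simulate_run(amino_acid_run(rt_shift=9.0, seed=33))
        truth_mono = {r["name"]: r["area"] for r in truth if r["isotopologue"] == 0}
        res = run_targeted_workflow([("s", pm)], amino_acid_targets(), WorkflowConfig())
        for row in res:
            if row["target"] in ("leucine", "isoleucine"):
                assert row["area"] >= 0.98 * truth_mono[row["target"]]

    def test_single_sample_no_references_correction_off(self):
        pm, _ = simulate_run(amino_acid_run(seed=4))
        res = run_targeted_workflow(
            [("s", pm)], [Target("leucine", "C6H13NO2", rt=300, rt_tol=6)],
            WorkflowConfig(correct_rt_shift=False),
        )
        assert len(res) == 1 and res[0]["flag"] == "ok"

    def test_correction_requires_references(self):
        pm, _ = simulate_run(amino_acid_run(seed=4))
        with pytest.raises(ValueError):
            run_targeted_workflow(
                [("s", pm)], [Target("leucine", "C6H13NO2", rt=300)],
                WorkflowConfig(correct_rt_shift=True),
            )

    def test_unreadable_sample_flagged_not_dropped(self, tmp_path):
        bad = tmp_path / "missing.mzML"
        pm, _ = simulate_run(amino_acid_run(seed=5))
        res = run_targeted_workflow([str(bad), ("ok", pm)], amino_acid_targets(),
                                    WorkflowConfig())
        flags = {r["sample"]: r["flag"] for r in res}
        assert flags[str(bad)] == "load_failed"
        assert flags["ok"] == "ok"

    def test_shift_failure_flagged(self):
        pm = PeakMap((Spectrum(1.0, np.array([500.0]), np.array([1.0])),))
        res = run_targeted_workflow([("empty", pm)], amino_acid_targets(),
                                    WorkflowConfig())
        assert all(r["flag"] == "shift_failed" for r in res)


class TestShiftGridProperty:
    def test_shift_recovery_across_grid(self):
        # simulated drifts on a 1 s grid at apex signal-to-noise ~20:
        # the estimate lands within half a scan interval almost always
        refs = [t for t in amino_acid_targets() if t.role == "reference"]
        hits = trials = 0
        for delta in range(-10, 11, 2):
            for seed in range(3):
                run = amino_acid_run(rt_shift=float(delta), seed=100 + seed,
                                     noise_sigma_add=1300.0)
                pm, _ = simulate_run(run)
                est = estimate_rt_shift(pm, refs)
                trials += 1
                if abs(est.shift - delta) <= run.scan_interval / 2:
                    hits += 1
        assert hits / trials >= 0.95

    def test_correction_never_hurts(self):
        # monotone benefit: corrected recovery >= uncorrected, per sample
        targets = amino_acid_targets()
        truth_mono = {r["name"]: r["area"] for r in
                      simulate_run(amino_acid_run())[1] if r["isotopologue"] == 0}
        for delta in (-9.0, -4.0, 0.0, 4.0, 9.0):
            pm, _ = simulate_run(amino_acid_run(rt_shift=delta, seed=int(50 + delta)))
            on = run_targeted_workflow([("s", pm)], targets, WorkflowConfig())
            off = run_targeted_workflow([("s", pm)], targets,
                                        WorkflowConfig(correct_rt_shift=False))
            for r_on, r_off in zip(on, off):
                if r_on["role"] != "analyte":
                    continue
                t = truth_mono[r_on["target"]]
                rec_on = min(r_on["area"] / t, 1.0)
                rec_off = min(r_off["area"] / t, 1.0)
                assert rec_on >= rec_off - 1e-6
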