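"""Generators: inversion identities, determinism, and designed effects."""

import numpy as np
import pandas as pd
import pytest

from npqkit.fluor_core import CF_IMAGER, compute_npq_curve
from npqkit.npq_adjust import WarmReference, npq_a_curve
from npqkit.quant_assays import CtRecord, relative_expression
from npqkit.synthetic import (
    AssayEffects,
    CellParams,
    ExperimentDesign,
    TraceGroundTruth,
    default_chilling_design,
    default_infiltration_design,
    simulate_assay_tables,
    simulate_plate_experiment,
    simulate_spectrum,
    simulate_trace,
)


class TestTraceGenerator:
    def test_noiseless_inversion_recovers_hyperbola(self):
        gt = TraceGroundTruth(q_s=0.0, amplitude=2.0, half_time=1.0, noise_cv=0.0)
        tr = simulate_trace(gt, CF_IMAGER, seed=0)
        curve = compute_npq_curve(tr)
        for p in curve.light_points():
            expected = 2.0 * p.time_min / (p.time_min + 1.0)
            assert p.npq == pytest.approx(expected, abs=1e-9)

    def test_noiseless_twin_reference_recovers_qs_exactly(self):
        gt = TraceGroundTruth(q_s=0.3, noise_cv=0.0)
        twin = TraceGroundTruth(q_s=0.0, noise_cv=0.0)
        tr = simulate_trace(gt, CF_IMAGER, seed=1)
        warm = simulate_trace(twin, CF_IMAGER, seed=2)
        ref = WarmReference(fvfm_warm=warm.dark.fvfm)
        assert npq_a_curve(tr, ref).npq_a_dark == pytest.approx(0.3, abs=1e-9)

    def test_same_seed_bitwise_identical(self):
        gt = TraceGroundTruth(q_s=0.2, noise_cv=0.02)
        a = simulate_trace(gt, CF_IMAGER, seed=42)
        b = simulate_trace(gt, CF_IMAGER, seed=42)
        assert a.dark == b.dark and a.flashes == b.flashes

    def test_dark_phase_relaxes_toward_sustained_level(self):
        gt = TraceGroundTruth(q_s=0.2, amplitude=2.0, half_time=1.0,
                              relaxation_fraction=0.9, noise_cv=0.0)
        curve = compute_npq_curve(simulate_trace(gt, CF_IMAGER, seed=0))
        dark = [p.npq for p in curve.points if p.phase == "dark"]
        assert all(b < a for a, b in zip(dark, dark[1:]))  # monotone decay

    def test_cold_fvfm_target_rescales_f_o(self):
        gt = TraceGroundTruth(q_s=0.3, noise_cv=0.0, cold_fvfm_target=0.6)
        tr = simulate_trace(gt, CF_IMAGER, seed=0)
        assert tr.dark.fvfm == pytest.approx(0.6, abs=1e-9)


class TestPlateExperiment:
    def test_ground_truth_table_matches_design(self):
        design = default_chilling_design(seed=11, replicates=3)
        traces, meta, gt = simulate_plate_experiment(design)
        assert len(traces) == len(design.cells) * 3
        assert set(gt.columns) >= {"disc_id", "q_s", "amplitude", "half_time"}
        cell = gt[(gt.accession == "MsaRB") & (gt.treatment == "chill")]
        assert (cell["q_s"] == 0.30).all()

    def test_same_seed_reproducible(self):
        d = default_chilling_design(seed=5, replicates=2)
        t1, _, g1 = simulate_plate_experiment(d)
        t2, _, g2 = simulate_plate_experiment(d)
        assert all(a.dark == b.dark and a.flashes == b.flashes
                   for a, b in zip(t1, t2))
        pd.testing.assert_frame_equal(g1, g2)

    def test_single_replicate_design_valid(self):
        design = ExperimentDesign(
            cells={("A", "warm"): CellParams(0.0, 2.0, 1.0)}, seed=1, replicates=1)
        traces, meta, gt = simulate_plate_experiment(design)
        assert len(traces) == 1 and len(gt) == 1

    def test_infiltration_design_encodes_retained_rates(self):
        d = default_infiltration_design(seed=0)
        base = d.cells[("MsaRB", "chill+water")]
        dtt = d.cells[("MsaRB", "chill+DTT")]
        assert dtt.induction_rate / base.induction_rate == pytest.approx(0.76)


class TestSpectrumGenerator:
    def test_deepoxidation_deepens_531_dip(self):
        s0 = simulate_spectrum(0.0, seed=3, noise_sd=0.0)
        s1 = simulate_spectrum(1.0, seed=3, noise_sd=0.0)
        wl = np.array([w for w, _ in s0])
        r0 = np.array([r for _, r in s0])
        r1 = np.array([r for _, r in s1])
        at = lambda nm: int(np.argmin(np.abs(wl - nm)))
        assert r1[at(531)] < r0[at(531)]
        assert r1[at(800)] == pytest.approx(r0[at(800)])  # NIR untouched

    def test_same_seed_reproducible(self):
        assert simulate_spectrum(0.5, seed=9) == simulate_spectrum(0.5, seed=9)

    def test_level_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_spectrum(1.5, seed=0)


class TestAssayGenerator:
    def test_zero_noise_recovers_designed_fold_change(self):
        eff = AssayEffects(noise_cv=0.0, ct_noise_sd=0.0)
        tables = simulate_assay_tables(seed=0, replicates=2, effects=eff)
        ct = tables["ct"]
        zep = ct[ct.target == "ZEP"]

        def rec(row):
            return CtRecord(row.sample_id, "ZEP", row.ct_target, row.ct_ref1,
                            row.ct_ref2)

        calib = rec(zep[(zep.accession == "MxgI") & (zep.treatment == "warm")].iloc[0])
        chill = rec(zep[(zep.accession == "MxgI") & (zep.treatment == "chill")].iloc[0])
        assert relative_expression(chill, calib) == pytest.approx(2.5, rel=1e-9)

    def test_zero_noise_zeaxanthin_ratio_exact(self):
        eff = AssayEffects(noise_cv=0.0, ct_noise_sd=0.0)
        pig = simulate_assay_tables(seed=0, replicates=2, effects=eff)["pigments"]
        chill = pig[pig.treatment == "chill"].groupby("accession")["zeaxanthin"].mean()
        assert chill["MsaRB"] / chill["MsiCR"] == pytest.approx(3.0, rel=1e-9)

    def test_calibration_points_are_exact_lines(self):
        cal = simulate_assay_tables(seed=1, replicates=2)["calibration"]
        zea = cal[cal.analyte == "zeaxanthin"]
        np.testing.assert_allclose(zea["response"], 1000.0 * zea["concentration"])

    def test_metabolite_table_roundtrips_amount(self):
        eff = AssayEffects(noise_cv=0.0, ct_noise_sd=0.0)
        met = simulate_assay_tables(seed=2, replicates=2, effects=eff)["metabolites"]
        row = met.iloc[0]
        conc = row.peak_area / 1000.0
        amount = conc * 0.05 / row.sample_weight_mg
        assert amount == pytest.approx(row.true_amount_per_mg, rel=1e-9)
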