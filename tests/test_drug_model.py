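import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from labpbpk.drug_model import (
    VSS_WINDOW_L_PER_KG,
    DrugParameters,
    allocate_clearance,
    calibrate_kp_scale,
    compute_partition_coefficients,
    load_labetalol,
    load_tissue_composition,
    vss_per_kg,
)
from labpbpk.physiology import build_reference_individual


class TestDrugParameters:
    def test_labetalol_inputs(self, drug):
        assert drug.molecular_weight == 328.412
        assert drug.pka == 9.38
        assert drug.logp == 2.79
        assert drug.fraction_unbound == 0.45
        assert drug.intestinal_permeability == pytest.approx(4.67e-5)
        assert drug.total_body_clearance == 15.0
        # optimizer metadata carried but unused by the engine
        assert drug.specific_organ_permeability == 0.1
        assert drug.specific_clearance == 6.0

    def test_fraction_unbound_bounds(self, drug):
        with pytest.raises(ValueError, match="fraction_unbound"):
            dataclasses.replace(drug, fraction_unbound=0.0)
        with pytest.raises(ValueError, match="fraction_unbound"):
            dataclasses.replace(drug, fraction_unbound=1.2)

    def test_mostly_ionised_base(self, drug):
        # pKa 9.38 at pH 7.4: ~1% neutral
        assert drug.neutral_fraction == pytest.approx(1 / (1 + 10 ** (9.38 - 7.4)))


class TestPartitionCoefficients:
    def test_identity_composition_gives_unit_kp(self, drug, reference_individual):
        table = load_tissue_composition()
        identity = pd.DataFrame(
            [table.loc["plasma"]] * len(table.index), index=table.index
        )
        part = compute_partition_coefficients(drug, reference_individual,
                                              composition=identity)
        for organ, kp in part.kp.items():
            assert kp == pytest.approx(1.0), organ

    def test_unknown_method_rejected(self, drug, reference_individual):
        with pytest.raises(ValueError, match="method"):
            compute_partition_coefficients(drug, reference_individual, method="rodgers")

    def test_calibrated_vss_in_literature_window(self, calibrated_partition):
        lo, hi = VSS_WINDOW_L_PER_KG
        assert lo <= calibrated_partition.vss_per_kg <= hi

    def test_kp_monotone_in_logp(self, drug, reference_individual):
        low = compute_partition_coefficients(
            dataclasses.replace(drug, logp=2.0), reference_individual
        )
        high = compute_partition_coefficients(
            dataclasses.replace(drug, logp=3.0), reference_individual
        )
        for organ in low.kp:
            assert high.kp[organ] >= low.kp[organ]

    @settings(max_examples=25, deadline=None)
    @given(
        logp_a=st.floats(min_value=-1.0, max_value=5.0),
        delta=st.floats(min_value=0.0, max_value=3.0),
    )
    def test_kp_monotone_property(self, logp_a, delta):
        drug = load_labetalol()
        individual = build_reference_individual(30, 70)
        low = compute_partition_coefficients(
            dataclasses.replace(drug, logp=logp_a), individual
        )
        high = compute_partition_coefficients(
            dataclasses.replace(drug, logp=logp_a + delta), individual
        )
        assert all(high.kp[o] >= low.kp[o] * (1 - 1e-12) for o in low.kp)


class TestCalibration:
    def test_hits_target(self, drug, reference_individual):
        raw = compute_partition_coefficients(drug, reference_individual)
        cal = calibrate_kp_scale(raw, reference_individual, 11.0)
        assert cal.vss_per_kg == pytest.approx(11.0, rel=1e-3)

    def test_matches_bisection_oracle(self, drug, reference_individual):
        raw = compute_partition_coefficients(drug, reference_individual)
        target = 11.0

        # independent route: bisection on the global scale factor
        def vss_at(scale):
            kp = {o: v * scale for o, v in raw.kp.items()}
            return vss_per_kg(kp, reference_individual)

        lo, hi = 1e-6, 1e3
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if vss_at(mid) < target:
                lo = mid
            else:
                hi = mid
        oracle_scale = 0.5 * (lo + hi)

        cal = calibrate_kp_scale(raw, reference_individual, target)
        assert cal.kp_scale == pytest.approx(oracle_scale, rel=1e-6)
        assert cal.vss_per_kg == pytest.approx(target, rel=1e-3)

    def test_identity_when_target_equals_current(self, drug, reference_individual):
        raw = compute_partition_coefficients(drug, reference_individual)
        cal = calibrate_kp_scale(raw, reference_individual, raw.vss_per_kg)
        assert cal.kp_scale == pytest.approx(raw.kp_scale, rel=1e-12)

    @pytest.mark.parametrize("target", [0.0, -1.0, 60.0])
    def test_invalid_targets(self, drug, reference_individual, target):
        raw = compute_partition_coefficients(drug, reference_individual)
        with pytest.raises(ValueError):
            calibrate_kp_scale(raw, reference_individual, target)


class TestClearanceAllocation:
    def test_total_clearance(self, clearance):
        # 15 mL/min/kg x 70 kg x 0.06 = 63 L/h
        assert clearance.total_plasma_clearance == pytest.approx(63.0, rel=1e-6)

    def test_renal_component(self, clearance):
        # 0.45 x 120 mL/min x 0.06 = 3.24 L/h
        assert clearance.renal_clearance == pytest.approx(3.24, rel=1e-6)

    def test_round_trip(self, clearance, reference_individual):
        hepatic = clearance.hepatic_plasma_clearance(
            reference_individual.hepatic_blood_flow
        )
        total = hepatic + clearance.renal_clearance
        assert total == pytest.approx(clearance.total_plasma_clearance, rel=1e-6)

    def test_zero_gfr_puts_everything_hepatic(self, drug):
        individual = build_reference_individual(30, 70, gfr=1e-12)
        model = allocate_clearance(drug, individual)
        assert model.renal_clearance == pytest.approx(0.0, abs=1e-10)
        hepatic = model.hepatic_plasma_clearance(individual.hepatic_blood_flow)
        assert hepatic == pytest.approx(63.0, rel=1e-6)

    def test_infeasible_total_names_flow_limit(self, drug):
        fast = dataclasses.replace(drug, total_body_clearance=75.0)
        individual = build_reference_individual(30, 70)
        with pytest.raises(ValueError, match="liver blood flow"):
            allocate_clearance(fast, individual)

    def test_requires_healthy_baseline(self, drug, reference_individual):
        diseased = dataclasses.replace(reference_individual, disease_label="CP-A")
        with pytest.raises(ValueError, match="healthy"):
            allocate_clearance(drug, diseased)

    @settings(max_examples=30, deadline=None)
    @given(
        fu=st.floats(min_value=0.1, max_value=1.0),
        gfr=st.floats(min_value=0.0, max_value=150.0),
        tbc=st.floats(min_value=2.0, max_value=18.0),
    )
    def test_well_stirred_bound_property(self, fu, gfr, tbc):
        drug = dataclasses.replace(
            load_labetalol(), fraction_unbound=fu, total_body_clearance=tbc
        )
        individual = build_reference_individual(30, 70, gfr=gfr)
        try:
            model = allocate_clearance(drug, individual)
        except ValueError:
            return  # infeasible splits are rejected, not silently clamped
        hepatic = model.hepatic_plasma_clearance(individual.hepatic_blood_flow)
        assert hepatic < individual.hepatic_blood_flow
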