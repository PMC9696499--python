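import dataclasses

import numpy as np
import pytest

from labpbpk.drug_model import ClearanceModel, PartitionSet
from labpbpk.nca import ConcentrationProfile, nca_summary
from labpbpk.pbpk_engine import (
    CompartmentSystem,
    DoseEvent,
    assemble_model,
    mass_balance,
    simulate,
)
from labpbpk.physiology import build_reference_individual

AUC_IV_ORACLE = 35.0 / 63.0 * 1000.0  # Dose/CL: 35 mg / 63 L/h in ng*h/mL


def unit_partition(individual):
    kp = {o: 1.0 for o in individual.organ_volumes
          if o not in ("arterial_blood", "venous_blood")}
    from labpbpk.drug_model import vss_per_kg

    return PartitionSet(kp=kp, kp_scale=1.0,
                        vss_per_kg=vss_per_kg(kp, individual))


def zero_clearance():
    return ClearanceModel(
        hepatic_intrinsic_clearance=0.0,
        renal_clearance=0.0,
        total_plasma_clearance=0.0,
        fraction_unbound=0.45,
    )


class TestDoseEvent:
    def test_zero_amount_rejected(self):
        with pytest.raises(ValueError, match="amount"):
            DoseEvent(route="oral", amount=0.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="infusion_duration"):
            DoseEvent(route="iv_infusion", amount=10, infusion_duration=-1.0)

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError, match="route"):
            DoseEvent(route="topical", amount=10)

    def test_mg_per_kg_resolution(self):
        dose = DoseEvent(route="oral", amount=0.5, amount_basis="mg_per_kg")
        assert dose.resolve_mg(80.0) == pytest.approx(40.0)

    def test_unresolved_iv_duration_fails_at_simulate(self, healthy_system):
        dose = DoseEvent(route="iv_infusion", amount=35.0)
        with pytest.raises(ValueError, match="unresolved"):
            simulate(healthy_system, dose, t_end=8.0)


class TestAssembly:
    def test_structural_counts(self, healthy_system):
        # stomach + 7 segments + unabsorbed sink = K + 2 lumen-chain states
        lumen_chain = set(healthy_system.lumen_labels) | {"unabsorbed"}
        assert len(lumen_chain) == healthy_system.n_segments + 2
        assert len(healthy_system.organ_labels) >= 12
        assert len(set(healthy_system.labels)) == len(healthy_system.labels)

    def test_halving_get_doubles_emptying_rate(
        self, reference_individual, drug, calibrated_partition, clearance
    ):
        fast = dataclasses.replace(reference_individual, gastric_emptying_time=7.5)
        slow_sys = assemble_model(reference_individual, drug, calibrated_partition, clearance)
        fast_sys = assemble_model(fast, drug, calibrated_partition, clearance)
        i = slow_sys.index["stomach"]
        assert fast_sys.matrix[i, i] == pytest.approx(2.0 * slow_sys.matrix[i, i])

    def test_missing_organ_named(self, reference_individual, drug,
                                 calibrated_partition, clearance):
        partition = dataclasses.replace(
            calibrated_partition,
            kp={o: v for o, v in calibrated_partition.kp.items() if o != "brain"},
        )
        with pytest.raises(ValueError, match="brain"):
            assemble_model(reference_individual, drug, partition, clearance)

    def test_equilibrium_with_unit_kp_and_no_clearance(self, reference_individual, drug):
        system = assemble_model(
            reference_individual, drug, unit_partition(reference_individual),
            zero_clearance(),
        )
        dose = DoseEvent(route="iv_infusion", amount=35.0, infusion_duration=0.1)
        result = simulate(system, dose, t_end=500.0, grid_dt=0.5)
        final = {label: values[-1] for label, values in result.amounts.items()}
        concentrations = [
            final[o] / reference_individual.organ_volumes[o]
            for o in reference_individual.organ_volumes
        ]
        assert np.allclose(concentrations, concentrations[0], rtol=1e-6)


class TestSimulation:
    def test_iv_auc_equals_dose_over_clearance(self, iv_profile_long):
        summary = nca_summary(iv_profile_long)
        assert summary.auc_0_inf == pytest.approx(AUC_IV_ORACLE, rel=0.005)

    def test_auc_independent_of_infusion_duration(self, healthy_system):
        aucs = []
        for duration in (0.1, 0.5):
            dose = DoseEvent(route="iv_infusion", amount=0.5,
                             amount_basis="mg_per_kg", infusion_duration=duration)
            result = simulate(healthy_system, dose, t_end=96.0)
            profile = ConcentrationProfile(result.time, result.plasma_concentration,
                                           dose, 70.0)
            aucs.append(nca_summary(profile).auc_0_inf)
        assert aucs[0] == pytest.approx(aucs[1], rel=0.005)
        assert aucs[0] == pytest.approx(AUC_IV_ORACLE, rel=0.005)

    def test_oral_conservation_and_incomplete_availability(self, oral_result):
        ledger = oral_result.mass_ledger
        total = (
            ledger["in_body"][-1]
            + ledger["eliminated_hepatic"][-1]
            + ledger["eliminated_renal"][-1]
            + ledger["unabsorbed"][-1]
        )
        assert total == pytest.approx(200.0, rel=1e-3)
        # fraction reaching systemic circulation is strictly < 1
        assert ledger["eliminated_hepatic"][-1] > 0
        assert ledger["unabsorbed"][-1] > 0

    def test_dose_proportionality(self, healthy_system):
        profiles = []
        for amount in (100.0, 200.0):
            result = simulate(healthy_system, DoseEvent(route="oral", amount=amount),
                              t_end=12.0)
            profiles.append(result.plasma_concentration)
        ratio = profiles[1][1:] / profiles[0][1:]
        assert np.allclose(ratio, 2.0, rtol=1e-3)
        assert np.trapezoid(profiles[1]) == pytest.approx(
            2.0 * np.trapezoid(profiles[0]), rel=1e-3
        )

    def test_oral_bioavailability_bracket(self, healthy_system, oral_dose, iv_dose):
        oral = simulate(healthy_system, oral_dose, t_end=240.0, grid_dt=0.1)
        iv = simulate(healthy_system, iv_dose, t_end=240.0, grid_dt=0.1)
        auc_oral = nca_summary(
            ConcentrationProfile(oral.time, oral.plasma_concentration, oral_dose, 70.0)
        ).auc_0_inf
        auc_iv = nca_summary(
            ConcentrationProfile(iv.time, iv.plasma_concentration, iv_dose, 70.0)
        ).auc_0_inf
        f = (auc_oral / 200.0) / (auc_iv / 35.0)
        assert 0.15 <= f <= 0.45
        assert f < 1.0

    def test_route_equivalence_limit(self, reference_individual, drug):
        """Instant complete absorption + no clearance converges to the IV bolus."""
        fast_gut = dataclasses.replace(
            reference_individual, gastric_emptying_time=0.01,
            small_intestine_transit_time=100.0,
        )
        instant_drug = dataclasses.replace(drug, intestinal_permeability=1.0)
        partition = unit_partition(reference_individual)
        oral_sys = assemble_model(fast_gut, instant_drug, partition, zero_clearance())
        iv_sys = assemble_model(reference_individual, drug, partition, zero_clearance())
        oral = simulate(oral_sys, DoseEvent(route="oral", amount=35.0), t_end=12.0)
        iv = simulate(
            iv_sys,
            DoseEvent(route="iv_infusion", amount=35.0, infusion_duration=0.001),
            t_end=12.0,
        )
        late = oral.time >= 2.0
        assert np.allclose(
            oral.plasma_concentration[late], iv.plasma_concentration[late], rtol=0.005
        )

    def test_expm_matches_lsoda(self, healthy_system, iv_dose, oral_dose):
        for dose in (iv_dose, oral_dose):
            exact = simulate(healthy_system, dose, t_end=8.0, solver="expm")
            ode = simulate(healthy_system, dose, t_end=8.0, solver="lsoda")
            scale = exact.plasma_concentration.max()
            assert np.allclose(
                exact.plasma_concentration, ode.plasma_concentration,
                rtol=1e-5, atol=1e-6 * scale,
            )

    @pytest.mark.parametrize("bad", [
        dict(t_end=-1.0),
        dict(t_end=8.0, rtol=-1e-8),
        dict(t_end=8.0, solver="euler"),
    ])
    def test_invalid_simulate_arguments(self, healthy_system, iv_dose, bad):
        with pytest.raises((ValueError,)):
            simulate(healthy_system, iv_dose, **bad)


class TestMassBalance:
    def test_iv_balance_tight(self, iv_result_long):
        assert mass_balance(iv_result_long)["max_relative_error"] <= 1e-3

    def test_oral_balance_tight(self, oral_result):
        assert mass_balance(oral_result)["max_relative_error"] <= 1e-3

    def test_no_clearance_means_no_elimination(self, reference_individual, drug,
                                               calibrated_partition):
        system = assemble_model(reference_individual, drug, calibrated_partition,
                                zero_clearance())
        result = simulate(
            system,
            DoseEvent(route="iv_infusion", amount=35.0, infusion_duration=0.5),
            t_end=24.0,
        )
        assert result.mass_ledger["eliminated_hepatic"][-1] == pytest.approx(0.0, abs=1e-9)
        assert result.mass_ledger["eliminated_renal"][-1] == pytest.approx(0.0, abs=1e-9)

    def test_zero_permeability_routes_dose_to_unabsorbed(
        self, reference_individual, drug, calibrated_partition, clearance
    ):
        sealed = dataclasses.replace(drug, intestinal_permeability=0.0)
        system = assemble_model(reference_individual, sealed, calibrated_partition,
                                clearance)
        result = simulate(system, DoseEvent(route="oral", amount=200.0), t_end=100.0,
                          grid_dt=0.5)
        assert result.mass_ledger["unabsorbed"][-1] == pytest.approx(200.0, rel=1e-3)
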