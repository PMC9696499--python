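import numpy as np
import pytest

from labpbpk.drug_model import (
    allocate_clearance,
    calibrate_kp_scale,
    compute_partition_coefficients,
    load_labetalol,
)
from labpbpk.nca import ConcentrationProfile
from labpbpk.pbpk_engine import DoseEvent, assemble_model, simulate
from labpbpk.physiology import build_reference_individual

REFERENCE_TOTAL_CL_L_H = 63.0  # 15 mL/min/kg x 70 kg


@pytest.fixture(scope="session")
def reference_individual():
    return build_reference_individual(30.0, 70.0, 170.0, "male")


@pytest.fixture(scope="session")
def drug():
    return load_labetalol()


@pytest.fixture(scope="session")
def calibrated_partition(drug, reference_individual):
    raw = compute_partition_coefficients(drug, reference_individual)
    return calibrate_kp_scale(raw, reference_individual, 11.0)


@pytest.fixture(scope="session")
def clearance(drug, reference_individual):
    return allocate_clearance(drug, reference_individual)


@pytest.fixture(scope="session")
def healthy_system(reference_individual, drug, calibrated_partition, clearance):
    return assemble_model(reference_individual, drug, calibrated_partition, clearance)


@pytest.fixture(scope="session")
def iv_dose():
    return DoseEvent(route="iv_infusion", amount=0.5, amount_basis="mg_per_kg",
                     infusion_duration=1.0)


@pytest.fixture(scope="session")
def oral_dose():
    return DoseEvent(route="oral", amount=200.0)


@pytest.fixture(scope="session")
def iv_result_long(healthy_system, iv_dose):
    """Dense IV simulation long enough for terminal-phase work (96 h)."""
    return simulate(healthy_system, iv_dose, t_end=96.0)


@pytest.fixture(scope="session")
def oral_result(healthy_system, oral_dose):
    return simulate(healthy_system, oral_dose, t_end=12.0)


@pytest.fixture(scope="session")
def iv_profile_long(iv_result_long, iv_dose):
    return ConcentrationProfile(
        time=iv_result_long.time,
        concentration=iv_result_long.plasma_concentration,
        dose=iv_dose,
        weight=70.0,
    )
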