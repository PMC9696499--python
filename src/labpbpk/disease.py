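"""Disease-population extrapolation: cirrhosis (CP-A/B/C) and CKD.

A :class:`DiseaseModifiers` record transforms a healthy baseline individual:
absolute fields (hematocrit, GFR, GI transit times) are replaced, factor
fields multiply (liver volume; the protein-binding factor multiplies the
*bound* fraction, so the effective unbound fraction becomes
``fu_disease = 1 - PBF x (1 - fu_healthy)``).  Hepatic intrinsic clearance
scales by its own factor and renal clearance is recomputed as
``fu_disease x GFR_disease``.

The severe-CKD record carries the printed physiological values (GET
24.375 min, SITT 2.94 h, hematocrit 0.398, protein-binding factor 0.843,
GFR 11).  The printed GFR unit (mL/min/kg) would exceed a healthy GFR and is
treated as a typographical artifact: the default reading is 11 mL/min
absolute, with the literal per-kg reading available via ``gfr_unit``.
Cirrhosis factor values are literature-informed defaults shipped as an
editable CSV table; every claim made against them is an ordering claim.
A documented reduction of non-renal (hepatic intrinsic) clearance in CKD is
included so the uraemic depression of metabolic clearance is represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

from .drug_model import ClearanceModel
from .physiology import HEALTHY_DEFAULTS, Individual

CP_CLASSES = ("CP-A", "CP-B", "CP-C")
CKD_SEVERITIES = ("moderate", "severe")

#: printed physiological values for severe kidney failure
SEVERE_CKD = {
    "gastric_emptying_time": 24.375,  # min
    "small_intestine_transit_time": 2.94,  # h
    "hematocrit": 0.398,
    "protein_binding_factor": 0.843,
    "gfr": 11.0,  # default reading: mL/min absolute
}

#: documented default reduction of non-renal intrinsic clearance in CKD
SEVERE_CKD_CLINT_FACTOR = 0.70


@dataclass(frozen=True)
class DiseaseModifiers:
    """Physiological modifier set for one disease label."""

    label: str
    liver_volume_factor: float = 1.0
    hematocrit: float | None = None  # absolute replacement
    protein_binding_factor: float = 1.0  # multiplies the bound fraction
    gfr: float | None = None  # absolute, unit per gfr_unit
    gfr_unit: str = "mL/min"  # "mL/min" | "mL/min/kg"
    gastric_emptying_time: float | None = None  # min, absolute
    small_intestine_transit_time: float | None = None  # h, absolute
    hepatic_intrinsic_clearance_factor: float = 1.0
    hepatic_flow_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("liver_volume_factor", "protein_binding_factor",
                     "hepatic_intrinsic_clearance_factor", "hepatic_flow_factor"):
            value = getattr(self, name)
            if not 0.0 < value <= 2.0:
                raise ValueError(f"{name} must be in (0, 2], got {value}")
        if self.hematocrit is not None and not 0.0 < self.hematocrit < 1.0:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        if self.gfr is not None and self.gfr < 0:
            raise ValueError(f"gfr must be >= 0, got {self.gfr}")
        if self.gfr_unit not in ("mL/min", "mL/min/kg"):
            raise ValueError(f"unknown gfr_unit {self.gfr_unit!r}")

    def resolved_gfr(self, weight: float) -> float | None:
        """GFR in mL/min for a subject of the given weight."""
        if self.gfr is None:
            return None
        if self.gfr_unit == "mL/min/kg":
            return self.gfr * weight
        return self.gfr


HEALTHY_MODIFIERS = DiseaseModifiers(label="healthy")


def load_cirrhosis_table() -> pd.DataFrame:
    """Default Child-Pugh modifier table shipped with the package."""
    with resources.files("labpbpk.data").joinpath("cirrhosis_modifiers.csv").open() as fh:
        return pd.read_csv(fh).set_index("label")


_SEVERITY_COLUMNS = ("liver_volume_factor", "gfr_ml_min", "hepatic_intrinsic_clearance_factor")


def cirrhosis_modifiers(cp_class: str, table: pd.DataFrame | None = None) -> DiseaseModifiers:
    """Modifier set for one Child-Pugh class.

    With a user-supplied table, non-monotone severity progressions are
    reported as a warning rather than an error.
    """
    if cp_class not in CP_CLASSES:
        raise ValueError(f"unknown Child-Pugh class {cp_class!r}; expected one of {CP_CLASSES}")
    if table is None:
        table = load_cirrhosis_table()
    else:
        present = [c for c in CP_CLASSES if c in table.index]
        for column in _SEVERITY_COLUMNS:
            if column not in table.columns:
                continue
            values = table.loc[present, column].to_numpy(dtype=float)
            if any(b > a for a, b in zip(values[:-1], values[1:])):
                warnings.warn(
                    f"cirrhosis table column {column!r} is not non-increasing "
                    "with severity", UserWarning,
                )
    if cp_class not in table.index:
        raise ValueError(f"cirrhosis table has no row for {cp_class!r}")
    row = table.loc[cp_class]
    return DiseaseModifiers(
        label=cp_class,
        liver_volume_factor=float(row["liver_volume_factor"]),
        hematocrit=float(row["hematocrit"]),
        protein_binding_factor=float(row["protein_binding_factor"]),
        gfr=float(row["gfr_ml_min"]),
        gfr_unit="mL/min",
        hepatic_intrinsic_clearance_factor=float(row["hepatic_intrinsic_clearance_factor"]),
        hepatic_flow_factor=float(row["hepatic_flow_factor"]),
    )


def renal_modifiers(
    severity: str,
    gfr_unit: str = "mL/min",
    moderate_rule: str = "midpoint",
) -> DiseaseModifiers:
    """Modifier set for moderate or severe chronic kidney disease.

    ``severe`` carries the printed values verbatim; ``moderate`` interpolates
    between the healthy baselines and the severe values (default: midpoint).
    """
    if severity not in CKD_SEVERITIES:
        raise ValueError(f"unknown CKD severity {severity!r}; expected one of {CKD_SEVERITIES}")
    if moderate_rule != "midpoint":
        raise ValueError(f"unknown moderate_rule {moderate_rule!r}")

    healthy_gfr = HEALTHY_DEFAULTS["gfr"]  # mL/min
    if severity == "severe":
        return DiseaseModifiers(
            label="CKD-severe",
            gastric_emptying_time=SEVERE_CKD["gastric_emptying_time"],
            small_intestine_transit_time=SEVERE_CKD["small_intestine_transit_time"],
            hematocrit=SEVERE_CKD["hematocrit"],
            protein_binding_factor=SEVERE_CKD["protein_binding_factor"],
            gfr=SEVERE_CKD["gfr"],
            gfr_unit=gfr_unit,
            hepatic_intrinsic_clearance_factor=SEVERE_CKD_CLINT_FACTOR,
        )

    def mid(a: float, b: float) -> float:
        return 0.5 * (a + b)

    # the healthy GFR baseline is always mL/min; under the per-kg reading the
    # severe value is converted at the 70 kg reference for interpolation
    severe_gfr_ml_min = SEVERE_CKD["gfr"] * (70.0 if gfr_unit == "mL/min/kg" else 1.0)
    return DiseaseModifiers(
        label="CKD-moderate",
        gastric_emptying_time=mid(HEALTHY_DEFAULTS["gastric_emptying_time"],
                                  SEVERE_CKD["gastric_emptying_time"]),
        small_intestine_transit_time=mid(HEALTHY_DEFAULTS["small_intestine_transit_time"],
                                         SEVERE_CKD["small_intestine_transit_time"]),
        hematocrit=mid(HEALTHY_DEFAULTS["hematocrit"], SEVERE_CKD["hematocrit"]),
        protein_binding_factor=mid(1.0, SEVERE_CKD["protein_binding_factor"]),
        gfr=mid(healthy_gfr, severe_gfr_ml_min),
        gfr_unit="mL/min",
        hepatic_intrinsic_clearance_factor=mid(1.0, SEVERE_CKD_CLINT_FACTOR),
    )


def apply_modifiers(
    individual: Individual,
    modifiers: DiseaseModifiers,
    clearance: ClearanceModel,
) -> tuple[Individual, ClearanceModel]:
    """Transform a healthy baseline into the diseased individual + clearance.

    Applying modifiers to an already-diseased individual raises: the factors
    are defined against the healthy baseline and are not idempotent.
    """
    if individual.disease_label != "healthy":
        raise ValueError(
            f"modifiers must be applied to a healthy baseline; individual is "
            f"{individual.disease_label!r}"
        )
    if modifiers.label == "healthy":
        return individual, clearance

    fu_healthy = clearance.fraction_unbound
    fu_disease = 1.0 - modifiers.protein_binding_factor * (1.0 - fu_healthy)
    if not 0.0 < fu_disease <= 1.0:
        raise ValueError(f"disease fraction unbound {fu_disease} outside (0, 1]")

    volumes = dict(individual.organ_volumes)
    volumes["liver"] = volumes["liver"] * modifiers.liver_volume_factor
    flows = dict(individual.organ_blood_flows)
    cardiac_output = individual.cardiac_output
    if modifiers.hepatic_flow_factor != 1.0:
        delta = flows["liver"] * (modifiers.hepatic_flow_factor - 1.0)
        flows["liver"] += delta
        cardiac_output += delta

    gfr = modifiers.resolved_gfr(individual.weight)
    diseased = replace(
        individual,
        hematocrit=individual.hematocrit if modifiers.hematocrit is None else modifiers.hematocrit,
        gfr=individual.gfr if gfr is None else gfr,
        protein_binding_scale=modifiers.protein_binding_factor,
        gastric_emptying_time=(individual.gastric_emptying_time
                               if modifiers.gastric_emptying_time is None
                               else modifiers.gastric_emptying_time),
        small_intestine_transit_time=(individual.small_intestine_transit_time
                                      if modifiers.small_intestine_transit_time is None
                                      else modifiers.small_intestine_transit_time),
        organ_volumes=volumes,
        organ_blood_flows=flows,
        cardiac_output=cardiac_output,
        disease_label=modifiers.label,
    )

    clint = (clearance.hepatic_intrinsic_clearance
             * modifiers.hepatic_intrinsic_clearance_factor)
    renal = fu_disease * diseased.gfr * 60.0 / 1000.0  # L/h
    q_h = diseased.hepatic_blood_flow
    fu_clint = fu_disease * clint
    hepatic = q_h * fu_clint / (q_h + fu_clint)
    diseased_clearance = ClearanceModel(
        hepatic_intrinsic_clearance=clint,
        renal_clearance=renal,
        total_plasma_clearance=hepatic + renal,
        fraction_unbound=fu_disease,
    )
    return diseased, diseased_clearance
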