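"""Drug parameters, tissue partition coefficients, and clearance allocation.

Partitioning uses a published tissue-composition scheme (Poulin & Theil-type
vegetable-oil surrogate: lipid and water fractions per tissue, shipped as
``data/tissue_composition.csv``), with ionisation of the single basic site at
plasma pH 7.4.  Because the absolute scale of composition-based Kp values is
method-dependent, a single global multiplicative factor (``kp_scale``) is
calibrated so the implied steady-state volume of distribution hits a target
inside the literature window for labetalol (9-15.7 L/kg).

Clearance is split mechanistically: renal clearance of unchanged drug is
filtration only (fu x GFR); the hepatic component is solved through the
well-stirred liver model so the implied total equals the input total body
clearance (mL/min/kg) at the healthy baseline.  Blood-to-plasma ratio is
taken as 1, so plasma and blood clearances coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .physiology import BLOOD_COMPARTMENTS, Individual

PLASMA_PH = 7.4

#: default calibration target for the steady-state volume of distribution
DEFAULT_VSS_TARGET_L_PER_KG = 11.0

#: literature window used to sanity-check the calibrated distribution volume
VSS_WINDOW_L_PER_KG = (9.0, 15.7)


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and disposition inputs for one compound."""

    name: str
    molecular_weight: float  # g/mol
    pka: float  # monoprotic base convention
    logp: float
    fraction_unbound: float  # fraction (0, 1]
    intestinal_permeability: float  # cm/min
    total_body_clearance: float  # mL/min/kg
    specific_organ_permeability: float = 0.0  # L/min; metadata only
    specific_clearance: float = 0.0  # L/h; metadata only

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_unbound <= 1.0:
            raise ValueError(
                f"fraction_unbound must be in (0, 1], got {self.fraction_unbound}"
            )
        for name in ("intestinal_permeability", "total_body_clearance",
                     "specific_organ_permeability", "specific_clearance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def neutral_fraction(self) -> float:
        """Fraction of neutral species at plasma pH (Henderson-Hasselbalch)."""
        return 1.0 / (1.0 + 10.0 ** (self.pka - PLASMA_PH))


def load_labetalol() -> DrugParameters:
    """Labetalol parameter set shipped with the package."""
    with resources.files("labpbpk.data").joinpath("labetalol.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return DrugParameters(
        name=raw["name"],
        molecular_weight=float(raw["molecular_weight"]),
        pka=float(raw["pka"]),
        logp=float(raw["logp"]),
        fraction_unbound=float(raw["fraction_unbound"]),
        intestinal_permeability=float(raw["intestinal_permeability"]),
        total_body_clearance=float(raw["total_body_clearance"]),
        specific_organ_permeability=float(raw["specific_organ_permeability"]),
        specific_clearance=float(raw["specific_clearance"]),
    )


def load_tissue_composition() -> pd.DataFrame:
    """Embedded tissue-composition fractions (plasma row included)."""
    with resources.files("labpbpk.data").joinpath("tissue_composition.csv").open() as fh:
        return pd.read_csv(fh).set_index("organ")


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:plasma partition coefficients plus the implied Vss."""

    kp: Mapping[str, float]  # organ -> dimensionless Kp
    kp_scale: float  # global calibration factor already folded into kp
    vss_per_kg: float  # L/kg implied by kp on the generating individual

    def __post_init__(self) -> None:
        for organ, value in self.kp.items():
            if value <= 0:
                raise ValueError(f"kp must be > 0: {organ}={value}")
        if self.vss_per_kg <= 0:
            raise ValueError(f"vss_per_kg must be > 0, got {self.vss_per_kg}")


@dataclass(frozen=True)
class ClearanceModel:
    """Hepatic intrinsic + renal clearance consistent with a total input."""

    hepatic_intrinsic_clearance: float  # L/h, unbound, well-stirred convention
    renal_clearance: float  # L/h, emergent plasma clearance
    total_plasma_clearance: float  # L/h at the generating individual
    fraction_unbound: float  # fu in effect (healthy = drug fu)

    def __post_init__(self) -> None:
        if self.hepatic_intrinsic_clearance < 0 or self.renal_clearance < 0:
            raise ValueError("clearance components must be >= 0")
        if not 0.0 < self.fraction_unbound <= 1.0:
            raise ValueError("fraction_unbound must be in (0, 1]")

    def hepatic_plasma_clearance(self, hepatic_blood_flow: float) -> float:
        """Well-stirred hepatic clearance for the given total liver inflow."""
        fu_clint = self.fraction_unbound * self.hepatic_intrinsic_clearance
        return hepatic_blood_flow * fu_clint / (hepatic_blood_flow + fu_clint)


def vss_per_kg(kp: Mapping[str, float], individual: Individual) -> float:
    """Plasma-referenced steady-state distribution volume per kg body weight."""
    tissue = sum(
        kp[o] * v
        for o, v in individual.organ_volumes.items()
        if o not in BLOOD_COMPARTMENTS
    )
    return (individual.plasma_volume + tissue) / individual.weight


def compute_partition_coefficients(
    drug: DrugParameters,
    individual: Individual,
    method: str = "standard",
    composition: pd.DataFrame | None = None,
) -> PartitionSet:
    """Compute one Kp per perfused organ from tissue composition.

    ``method`` currently admits only ``"standard"`` (the composition-based
    scheme described in the module docstring).  ``composition`` may replace
    the embedded table, e.g. for identity checks.
    """
    if method != "standard":
        raise ValueError(f"unknown partition method {method!r}")
    table = load_tissue_composition() if composition is None else composition
    if "plasma" not in table.index:
        raise ValueError("composition table must contain a 'plasma' row")

    d_eff = 10.0 ** drug.logp * drug.neutral_fraction

    def affinity(row: pd.Series) -> float:
        lipid = row["f_neutral_lipid"] + 0.3 * row["f_phospholipid"]
        aqueous = row["f_water"] + 0.7 * row["f_phospholipid"]
        return d_eff * lipid + aqueous

    plasma_affinity = affinity(table.loc["plasma"])
    kp = {}
    for organ in individual.organ_volumes:
        if organ in BLOOD_COMPARTMENTS:
            continue
        if organ not in table.index:
            raise ValueError(f"composition table missing organ {organ!r}")
        kp[organ] = float(affinity(table.loc[organ]) / plasma_affinity)

    return PartitionSet(kp=kp, kp_scale=1.0, vss_per_kg=vss_per_kg(kp, individual))


def calibrate_kp_scale(
    partition: PartitionSet,
    individual: Individual,
    target_vss_per_kg: float = DEFAULT_VSS_TARGET_L_PER_KG,
) -> PartitionSet:
    """Rescale all Kp by one global factor so Vss/kg hits the target.

    The dependence of Vss on the scale is linear, so the factor is solved in
    closed form; the result matches the target to machine precision.
    """
    if not 0.0 < target_vss_per_kg <= 50.0:
        raise ValueError(f"target_vss_per_kg must be in (0, 50], got {target_vss_per_kg}")
    tissue_sum = sum(
        partition.kp[o] * v
        for o, v in individual.organ_volumes.items()
        if o not in BLOOD_COMPARTMENTS
    )
    target_tissue = target_vss_per_kg * individual.weight - individual.plasma_volume
    if target_tissue <= 0:
        raise ValueError("target_vss_per_kg is below the plasma volume floor")
    factor = target_tissue / tissue_sum
    kp = {o: v * factor for o, v in partition.kp.items()}
    return PartitionSet(
        kp=kp,
        kp_scale=partition.kp_scale * factor,
        vss_per_kg=vss_per_kg(kp, individual),
    )


def allocate_clearance(drug: DrugParameters, individual: Individual) -> ClearanceModel:
    """Split total body clearance into renal (fu x GFR) and hepatic pathways.

    The hepatic intrinsic clearance is solved so that the well-stirred hepatic
    clearance plus the renal component reproduces
    ``total_body_clearance x weight`` exactly at this (healthy) individual.
    """
    if individual.disease_label != "healthy":
        raise ValueError("allocate_clearance expects a healthy-baseline individual")
    fu = drug.fraction_unbound
    total = drug.total_body_clearance * individual.weight * 60.0 / 1000.0  # L/h
    renal = fu * individual.gfr * 60.0 / 1000.0  # L/h
    if renal >= total:
        raise ValueError(
            f"renal clearance {renal:.3f} L/h meets or exceeds total {total:.3f} L/h"
        )
    hepatic = total - renal
    q_h = individual.hepatic_blood_flow
    if hepatic >= q_h:
        raise ValueError(
            f"required hepatic clearance {hepatic:.3f} L/h is not attainable: "
            f"well-stirred limit is the liver blood flow {q_h:.3f} L/h"
        )
    clint = hepatic * q_h / (fu * (q_h - hepatic))
    return ClearanceModel(
        hepatic_intrinsic_clearance=clint,
        renal_clearance=renal,
        total_plasma_clearance=total,
        fraction_unbound=fu,
    )
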