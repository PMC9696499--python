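"""Reference adult physiology and virtual-population sampling.

The anatomy is an embedded reference-adult table (ICRP-style organ volumes
and regional blood flows, normalised to a 70 kg adult, shipped as
``data/reference_physiology.csv``).  All organ volumes and flows scale
linearly with body weight relative to 70 kg.  The liver entry of
``organ_blood_flows`` is the *hepatic arterial* supply only; the portal
contribution arrives through the gut and is added by the engine, so the
non-lung flows sum exactly to cardiac output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REFERENCE_WEIGHT_KG = 70.0

#: organs whose entries must exist in every Individual
REQUIRED_ORGANS = (
    "arterial_blood",
    "venous_blood",
    "lung",
    "liver",
    "kidney",
    "gut",
    "muscle",
    "adipose",
    "skin",
    "brain",
    "heart",
    "bone",
    "rest",
)

BLOOD_COMPARTMENTS = ("arterial_blood", "venous_blood")

#: conventional healthy-adult baselines (documented config, not study data)
HEALTHY_DEFAULTS = {
    "hematocrit": 0.45,
    "gfr": 120.0,  # mL/min
    "protein_binding_scale": 1.0,
    "gastric_emptying_time": 15.0,  # min
    "small_intestine_transit_time": 3.3,  # h
}

#: fixed sex-specific heights used when a study reports none
DEFAULT_HEIGHT_CM = {"male": 176.0, "female": 163.0}

#: default body weight when a study reports "N/R"
DEFAULT_WEIGHT_KG = 70.0

AGE_BOUNDS = (18.0, 80.0)
WEIGHT_BOUNDS = (40.0, 150.0)

_FLOW_TOL = 1e-6


def load_reference_table() -> pd.DataFrame:
    """Return the embedded 70 kg reference physiology table."""
    with resources.files("labpbpk.data").joinpath("reference_physiology.csv").open() as fh:
        table = pd.read_csv(fh)
    return table.set_index("organ")


@dataclass(frozen=True)
class Individual:
    """One virtual subject's anatomy and physiology."""

    age: float  # years
    weight: float  # kg
    height: float  # cm
    sex: str  # "male" | "female"
    hematocrit: float  # fraction of blood volume
    gfr: float  # mL/min
    protein_binding_scale: float  # multiplier on the bound fraction; healthy = 1
    gastric_emptying_time: float  # min
    small_intestine_transit_time: float  # h
    organ_volumes: Mapping[str, float]  # organ -> L
    organ_blood_flows: Mapping[str, float]  # organ -> L/h (liver = hepatic artery)
    cardiac_output: float  # L/h
    disease_label: str = "healthy"

    def __post_init__(self) -> None:
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        if self.gfr < 0:
            raise ValueError(f"gfr must be >= 0, got {self.gfr}")
        for organ in REQUIRED_ORGANS:
            if organ not in self.organ_volumes:
                raise ValueError(f"organ_volumes missing required organ {organ!r}")
        for organ, vol in self.organ_volumes.items():
            if vol <= 0:
                raise ValueError(f"organ volume must be > 0: {organ}={vol}")
        for organ, flow in self.organ_blood_flows.items():
            if flow <= 0:
                raise ValueError(f"organ blood flow must be > 0: {organ}={flow}")
        non_lung = sum(q for o, q in self.organ_blood_flows.items() if o != "lung")
        if abs(non_lung - self.cardiac_output) > _FLOW_TOL * self.cardiac_output:
            raise ValueError(
                "non-lung organ blood flows must sum to cardiac output "
                f"({non_lung:.6f} != {self.cardiac_output:.6f})"
            )

    @property
    def plasma_volume(self) -> float:
        """Plasma volume (L) of the circulating blood pool."""
        blood = sum(self.organ_volumes[o] for o in BLOOD_COMPARTMENTS)
        return blood * (1.0 - self.hematocrit)

    @property
    def hepatic_blood_flow(self) -> float:
        """Total liver inflow (L/h): hepatic artery plus portal (gut) flow."""
        return self.organ_blood_flows["liver"] + self.organ_blood_flows["gut"]

    def total_organ_volume(self) -> float:
        return float(sum(self.organ_volumes.values()))


@dataclass(frozen=True)
class PopulationSpec:
    """Cohort descriptor: size, demographic ranges, and a sampling seed."""

    n: int
    age_range: tuple[float, float]
    weight_range: tuple[float, float] | None = None  # None = unreported -> 70 kg
    female_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        lo, hi = self.age_range
        if lo > hi:
            raise ValueError(f"age_range must be (min, max), got {self.age_range}")
        if self.weight_range is not None:
            wlo, whi = self.weight_range
            if wlo > whi:
                raise ValueError(f"weight_range must be (min, max), got {self.weight_range}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError(f"female_fraction must be in [0, 1], got {self.female_fraction}")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "age_range": list(self.age_range),
            "weight_range": None if self.weight_range is None else list(self.weight_range),
            "female_fraction": self.female_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PopulationSpec":
        weight = raw.get("weight_range")
        return cls(
            n=int(raw["n"]),
            age_range=tuple(raw["age_range"]),
            weight_range=None if weight in (None, "unreported") else tuple(weight),
            female_fraction=float(raw.get("female_fraction", 0.0)),
            seed=int(raw.get("seed", 0)),
        )


def build_reference_individual(
    age: float,
    weight: float,
    height: float | None = None,
    sex: str = "male",
    **overrides: float,
) -> Individual:
    """Build a complete healthy adult with organs scaled linearly to weight.

    Parameters outside ``age in [18, 80]`` or ``weight in [40, 150]`` raise a
    :class:`ValueError` naming the offending field.  ``overrides`` may replace
    any of the healthy-default physiological fields (hematocrit, gfr, ...).
    """
    if not AGE_BOUNDS[0] <= age <= AGE_BOUNDS[1]:
        raise ValueError(f"age must be in {AGE_BOUNDS}, got {age}")
    if not WEIGHT_BOUNDS[0] <= weight <= WEIGHT_BOUNDS[1]:
        raise ValueError(f"weight must be in {WEIGHT_BOUNDS}, got {weight}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if height is None:
        height = DEFAULT_HEIGHT_CM[sex]
    if height <= 0:
        raise ValueError(f"height must be > 0, got {height}")

    table = load_reference_table()
    scale = weight / REFERENCE_WEIGHT_KG
    volumes = {o: float(v) * scale for o, v in table["volume_l_per_70kg"].items()}
    flows = {
        o: float(q) * scale
        for o, q in table["flow_l_per_h_per_70kg"].items()
        if pd.notna(q)
    }
    cardiac_output = sum(flows.values())
    flows["lung"] = cardiac_output

    defaults = dict(HEALTHY_DEFAULTS)
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown physiology overrides: {sorted(unknown)}")
    defaults.update(overrides)

    return Individual(
        age=age,
        weight=weight,
        height=height,
        sex=sex,
        organ_volumes=volumes,
        organ_blood_flows=flows,
        cardiac_output=cardiac_output,
        **defaults,
    )


def sample_population(spec: PopulationSpec) -> list[Individual]:
    """Sample ``spec.n`` healthy individuals (uniform age/weight, Bernoulli sex).

    Sampling is driven entirely by ``spec.seed`` and is bitwise reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    individuals = []
    for _ in range(spec.n):
        age = float(rng.uniform(*spec.age_range))
        if spec.weight_range is None:
            weight = DEFAULT_WEIGHT_KG
        else:
            weight = float(rng.uniform(*spec.weight_range))
        sex = "female" if rng.random() < spec.female_fraction else "male"
        individuals.append(build_reference_individual(age, weight, sex=sex))
    return individuals
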