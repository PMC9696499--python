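"""Synthetic observed-data generation and the eight study fixtures.

The fixtures transcribe the source study designs (cohort sizes, doses,
demographics) and the observed/predicted PK-parameter tables shipped under
``data/``.  The noise model stands in for digitized clinical profiles:
sparse clinical-style sampling of a true simulated curve with multiplicative
log-normal residual error (mean 1, configurable CV), fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .nca import ConcentrationProfile, ObservedRecord, PKSummary, nca_summary, observed_table_reader
from .pbpk_engine import DoseEvent
from .physiology import PopulationSpec

DEFAULT_RESIDUAL_CV = 0.20


def default_sampling_times(t_end: float = 12.0) -> np.ndarray:
    """Sparse clinical-style schedule: 5/10/20/30/45/60/90 min, then hourly."""
    minutes = np.array([5, 10, 20, 30, 45, 60, 90]) / 60.0
    hourly = np.arange(2.0, t_end + 1e-9, 1.0)
    return np.concatenate([minutes, hourly])


@dataclass(frozen=True)
class StudyScenario:
    """One source-study row: population, route, dose, cohort, observed PK."""

    id: int
    population: str  # "healthy" | "CP-A" | "CKD-severe"
    route: str
    dose: DoseEvent
    cohort: PopulationSpec
    observed: tuple[ObservedRecord, ...]
    weight_reported: bool = True


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal residual error on a sampling schedule."""

    residual_cv: float = DEFAULT_RESIDUAL_CV
    sampling_times: np.ndarray = field(default_factory=default_sampling_times)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_cv < 1.0:
            raise ValueError(f"residual_cv must be in [0, 1), got {self.residual_cv}")
        times = np.asarray(self.sampling_times, dtype=float)
        object.__setattr__(self, "sampling_times", times)
        if np.any(np.diff(times) <= 0):
            raise ValueError("sampling_times must be strictly increasing")


def _observed_records() -> list[ObservedRecord]:
    with resources.files("labpbpk.data").joinpath("observed_pk.csv").open() as fh:
        return observed_table_reader(fh)


def study_fixtures(base_seed: int = 0) -> list[StudyScenario]:
    """The eight study scenarios, field-for-field from the shipped designs."""
    with resources.files("labpbpk.data").joinpath("study_designs.csv").open() as fh:
        designs = pd.read_csv(fh)
    observed = _observed_records()
    scenarios = []
    for _, row in designs.iterrows():
        study_id = int(row["study_id"])
        weight_reported = bool(row["weight_reported"])
        weight_range = (
            (float(row["weight_min_kg"]), float(row["weight_max_kg"]))
            if weight_reported
            else None
        )
        cohort = PopulationSpec(
            n=int(row["n_subjects"]),
            age_range=(float(row["age_min"]), float(row["age_max"])),
            weight_range=weight_range,
            female_fraction=float(row["n_female"]) / float(row["n_subjects"]),
            seed=base_seed + study_id,
        )
        dose = DoseEvent(
            route=str(row["route"]),
            amount=float(row["dose_amount"]),
            amount_basis=str(row["dose_basis"]),
        )
        scenarios.append(
            StudyScenario(
                id=study_id,
                population=str(row["population"]),
                route=str(row["route"]),
                dose=dose,
                cohort=cohort,
                observed=tuple(r for r in observed if r.study_id == study_id),
                weight_reported=weight_reported,
            )
        )
    return scenarios


def generate_observed(
    true_profile: ConcentrationProfile, noise: NoiseModel
) -> ConcentrationProfile:
    """Sample the true curve at the schedule and apply mean-1 log-normal error."""
    times = noise.sampling_times
    if times[0] < true_profile.time[0] or times[-1] > true_profile.time[-1]:
        raise ValueError("sampling times fall outside the true profile's span")
    truth = np.interp(times, true_profile.time, true_profile.concentration)
    if noise.residual_cv == 0.0:
        noisy = truth
    else:
        rng = np.random.default_rng(noise.seed)
        sigma = np.sqrt(np.log1p(noise.residual_cv**2))
        # mu = -sigma^2/2 makes the multiplicative error mean-one
        noisy = truth * rng.lognormal(-0.5 * sigma**2, sigma, size=times.size)
    return ConcentrationProfile(
        time=times,
        concentration=noisy,
        dose=true_profile.dose,
        weight=true_profile.weight,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Per-replicate NCA estimates against truth, with bias/RMSE summaries."""

    estimates: pd.DataFrame  # one row per replicate
    truth: dict
    bias: dict  # parameter -> mean relative bias
    rmse: dict  # parameter -> relative RMSE


def recovery_experiment(
    scenario: StudyScenario,
    noise: NoiseModel,
    replicates: int,
    t_end: float = 24.0,
    terminal_points: int = 3,
    options=None,
) -> RecoveryReport:
    """Simulate the scenario's true profile on the reference subject, then
    repeatedly regenerate noisy observations and summarise NCA recovery."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .pipeline import EngineOptions, build_subject_system, simulate_subject
    from .physiology import build_reference_individual

    options = options or EngineOptions()
    subject = build_reference_individual(30.0, 70.0)
    system = build_subject_system(subject, population_label=scenario.population,
                                  options=options)
    _, truth_profile = simulate_subject(system, scenario.dose, options, t_end=t_end)
    truth_summary = nca_summary(truth_profile, terminal_points=terminal_points)
    truth = {
        "cmax": truth_summary.cmax,
        "auc_0_t": truth_summary.auc_0_t,
        "auc_0_inf": truth_summary.auc_0_inf,
        "clearance": truth_summary.clearance,
    }

    rows = []
    times = noise.sampling_times[noise.sampling_times <= t_end + 1e-9]
    for rep in range(replicates):
        rep_noise = NoiseModel(
            residual_cv=noise.residual_cv,
            sampling_times=times,
            seed=noise.seed + rep,
        )
        observed = generate_observed(truth_profile, rep_noise)
        summary = nca_summary(observed, terminal_points=terminal_points)
        rows.append(
            {
                "replicate": rep,
                "cmax": summary.cmax,
                "auc_0_t": summary.auc_0_t,
                "auc_0_inf": summary.auc_0_inf,
                "clearance": summary.clearance,
            }
        )
    estimates = pd.DataFrame(rows)
    bias = {}
    rmse = {}
    for key, true_value in truth.items():
        rel = (estimates[key] - true_value) / true_value
        bias[key] = float(rel.mean())
        rmse[key] = float(np.sqrt((rel**2).mean()))
    return RecoveryReport(estimates=estimates, truth=truth, bias=bias, rmse=rmse)
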