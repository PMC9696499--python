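"""Non-compartmental analysis of concentration-time profiles.

Conventions: linear trapezoidal AUC0-t (lin-log available by flag), terminal
slope by unweighted log-linear regression on the last ``terminal_points``
positive concentrations (default 3, flagged when R^2 < 0.9),
``AUC0-inf = AUC0-t + C_last/lambda_z``, and clearance from dose and
AUC0-inf (reported as apparent CL/F for oral dosing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pbpk_engine import DoseEvent

DEFAULT_TERMINAL_POINTS = 3
R2_FLAG_THRESHOLD = 0.9


@dataclass(frozen=True)
class ConcentrationProfile:
    """A sampled plasma concentration-time course (ng/mL over h)."""

    time: np.ndarray  # h, strictly increasing
    concentration: np.ndarray  # ng/mL, >= 0
    dose: DoseEvent | None = None
    weight: float | None = None  # kg, needed to resolve mg/kg doses

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        conc = np.asarray(self.concentration, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "concentration", conc)
        if time.ndim != 1 or time.size < 3:
            raise ValueError("profile needs at least 3 time points")
        if conc.shape != time.shape:
            raise ValueError("time and concentration must have the same shape")
        if np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")

    def dose_mg(self) -> float | None:
        if self.dose is None:
            return None
        if self.dose.amount_basis == "mg_per_kg":
            if self.weight is None:
                raise ValueError("mg/kg dose requires a subject weight")
            return self.dose.amount * self.weight
        return self.dose.amount


@dataclass(frozen=True)
class PKSummary:
    """NCA outputs for one profile."""

    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_t: float  # ng*h/mL
    auc_0_inf: float  # ng*h/mL (nan when lambda_z undefined)
    lambda_z: float  # 1/h (nan when undefined)
    half_life: float  # h (nan when undefined)
    clearance: float  # L/h (nan without dose); CL/F for oral
    cl_is_apparent: bool = False
    lambda_z_r_squared: float = float("nan")
    lambda_z_flagged: bool = False


def auc_trapezoid(time: np.ndarray, conc: np.ndarray, method: str = "linear") -> float:
    """AUC by the trapezoidal rule; ``method`` is "linear" or "linlog".

    The lin-log rule uses the logarithmic trapezoid on strictly declining
    positive segments and the linear rule elsewhere.
    """
    if method == "linear":
        return float(np.trapezoid(conc, time))
    if method != "linlog":
        raise ValueError(f"unknown AUC method {method!r}")
    total = 0.0
    for i in range(len(time) - 1):
        dt = time[i + 1] - time[i]
        c0, c1 = conc[i], conc[i + 1]
        if c0 > c1 > 0:
            total += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            total += dt * (c0 + c1) / 2.0
    return float(total)


def terminal_slope(
    time: np.ndarray, conc: np.ndarray, n_points: int = DEFAULT_TERMINAL_POINTS
) -> tuple[float, float]:
    """(lambda_z, R^2) from log-linear regression on the last n positive points.

    Returns (nan, nan) when fewer than ``n_points`` positive concentrations
    exist or the fitted slope is non-negative.
    """
    positive = conc > 0
    if positive.sum() < n_points:
        return float("nan"), float("nan")
    t = time[positive][-n_points:]
    y = np.log(conc[positive][-n_points:])
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope >= 0:
        return float("nan"), r2
    return -float(slope), r2


def nca_summary(
    profile: ConcentrationProfile,
    terminal_points: int = DEFAULT_TERMINAL_POINTS,
    auc_method: str = "linear",
) -> PKSummary:
    """Full NCA for one profile."""
    time, conc = profile.time, profile.concentration
    i_max = int(np.argmax(conc))
    cmax = float(conc[i_max])
    tmax = float(time[i_max])
    auc_t = auc_trapezoid(time, conc, auc_method)

    lambda_z, r2 = terminal_slope(time, conc, terminal_points)
    flagged = (not math.isnan(r2)) and r2 < R2_FLAG_THRESHOLD
    if math.isnan(lambda_z):
        auc_inf = float("nan")
        half_life = float("nan")
    else:
        c_last = float(conc[conc > 0][-1])
        auc_inf = auc_t + c_last / lambda_z
        half_life = math.log(2.0) / lambda_z

    dose_mg = profile.dose_mg()
    if dose_mg is None or math.isnan(auc_inf) or auc_inf <= 0:
        clearance = float("nan")
    else:
        # dose [mg] / AUC [ng*h/mL] -> L/h needs the 1000x unit factor
        clearance = dose_mg / auc_inf * 1000.0
    apparent = profile.dose is not None and profile.dose.route == "oral"

    return PKSummary(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        lambda_z=lambda_z,
        half_life=half_life,
        clearance=clearance,
        cl_is_apparent=apparent,
        lambda_z_r_squared=r2,
        lambda_z_flagged=flagged,
    )


@dataclass(frozen=True)
class ObservedRecord:
    """One observed/predicted PK-parameter row from the transcription table."""

    study_id: int
    route: str
    population: str
    parameter: str  # "cmax" | "auc_0_t" | "cl"
    observed: float
    predicted: float
    ratio_printed: float
    unit: str  # stored verbatim; never silently rescaled


_VALID_PARAMETERS = ("cmax", "auc_0_t", "cl")


def observed_table_reader(path) -> list[ObservedRecord]:
    """Read an observed-PK CSV (study_id, route, population, parameter,
    observed, predicted, ratio_printed, unit) into typed records."""
    frame = pd.read_csv(path)
    if frame.empty:
        return []
    required = {"study_id", "route", "population", "parameter",
                "observed", "predicted", "ratio_printed", "unit"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"observed table missing columns: {sorted(missing)}")
    records = []
    for i, row in frame.iterrows():
        if row["parameter"] not in _VALID_PARAMETERS:
            raise ValueError(f"row {i}: unknown parameter {row['parameter']!r}")
        try:
            observed = float(row["observed"])
            predicted = float(row["predicted"])
            ratio = float(row["ratio_printed"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: non-numeric value ({exc})") from exc
        if observed <= 0 or predicted <= 0:
            raise ValueError(f"row {i}: observed/predicted must be positive")
        records.append(
            ObservedRecord(
                study_id=int(row["study_id"]),
                route=str(row["route"]),
                population=str(row["population"]),
                parameter=str(row["parameter"]),
                observed=observed,
                predicted=predicted,
                ratio_printed=ratio,
                unit=str(row["unit"]),
            )
        )
    return records
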