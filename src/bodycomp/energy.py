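"""Energy-balance coupling: one-dimensional weight-change dynamics.

With FFM written as a function phi of FM, the energy balance
``c_f dFM/dt + c_l dFFM/dt = I - E`` reduces by the chain rule to the
single ordinary differential equation

    dFM/dt = (I - E(FM, phi(FM))) / (c_f + c_l * phi'(FM)),

where I is energy intake (kcal/d), E the expenditure rate (kcal/d), and
c_l, c_f the energy conversion constants for one kg of FFM and FM.  No
numeric defaults are assumed for c_l and c_f; callers supply them, along
with a pluggable expenditure function.  Trajectories are integrated with
the classical fixed-step fourth-order Runge-Kutta scheme for exact
reproducibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ModelValidityError, ValidationError
from .models import SubjectCovariates
from .registry import get_coefficients
from .models import evaluate_polynomial, evaluate_polynomial_derivative
from .solver import solve_fm

#: FM bound (kg) beyond which integration is truncated with a warning.
FM_MAX_KG = 250.0

ExpenditureFunction = Callable[[float, float], float]
"""Callable mapping (fm_kg, ffm_kg) to expenditure in kcal/day."""


@dataclass(frozen=True)
class EnergyParams:
    """Energy conversion constants, kcal per kg of FFM (c_l) and FM (c_f)."""

    c_l: float
    c_f: float

    def __post_init__(self):
        if not (self.c_l > 0 and self.c_f > 0):
            raise ValidationError(
                f"c_l/c_f: must be > 0, got ({self.c_l}, {self.c_f})")
        if not self.c_f > self.c_l:
            raise ValidationError(
                f"c_f: fat must be more energy dense than lean tissue "
                f"(c_f={self.c_f} <= c_l={self.c_l})")


def linear_expenditure(k_kcal_d: float, gamma_ffm: float,
                       gamma_fm: float) -> ExpenditureFunction:
    """Reference linear expenditure ``E = K + g_ffm*FFM + g_fm*FM``.

    Shipped for testing and examples only; all constants are caller
    supplied (this package takes no position on expenditure modelling).
    """

    def expenditure(fm_kg: float, ffm_kg: float) -> float:
        return k_kcal_d + gamma_ffm * ffm_kg + gamma_fm * fm_kg

    return expenditure


def dfm_dt(fm_kg: float, cov: SubjectCovariates, intake_kcal_d: float,
           expenditure: ExpenditureFunction, params: EnergyParams,
           registry_variant: str | None = None, *,
           coefficients=None) -> float:
    """Right-hand side of the reduced energy-balance equation (kg/day).

    ``coefficients`` is an expert hook to evaluate against an explicit
    coefficient row instead of the registry.
    """
    coeffs = coefficients if coefficients is not None else \
        get_coefficients(cov.race, cov.sex, registry_variant)
    ffm = evaluate_polynomial(coeffs, fm_kg, cov.age_y, cov.height_cm)
    dphi = evaluate_polynomial_derivative(coeffs, fm_kg, cov.age_y,
                                          cov.height_cm)
    denom = params.c_f + params.c_l * dphi
    if denom <= 0:
        raise ModelValidityError(
            f"energy-balance reduction invalid: c_f + c_l*phi'(FM) = "
            f"{denom:.4g} <= 0 at FM = {fm_kg:.4g} kg")
    return (intake_kcal_d - expenditure(fm_kg, ffm)) / denom


@dataclass(frozen=True)
class Trajectory:
    """Sampled weight-change trajectory.

    The fat-free mass column is the model evaluation at the fat-mass
    column at every sample (the constraint defining the 1-D reduction), so
    ``total = fm + ffm`` holds exactly.
    """

    times_d: np.ndarray
    fm_kg: np.ndarray
    ffm_kg: np.ndarray
    intake_kcal_d: np.ndarray

    @property
    def total_kg(self) -> np.ndarray:
        return self.fm_kg + self.ffm_kg

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.times_d,
            "fm_kg": self.fm_kg,
            "ffm_kg": self.ffm_kg,
            "total_kg": self.total_kg,
            "intake_kcal_d": self.intake_kcal_d,
        })


def simulate_trajectory(initial_total_kg: float, cov: SubjectCovariates,
                        intake, expenditure: ExpenditureFunction,
                        params: EnergyParams, duration_d: float,
                        dt_d: float = 1.0,
                        registry_variant: str | None = None) -> Trajectory:
    """Integrate the reduced equation with classical fixed-step RK4.

    Parameters
    ----------
    intake : float or callable
        Constant intake in kcal/day, or a function of time (days).
    duration_d, dt_d : float
        Total duration and step, days; the number of steps is
        ``round(duration_d / dt_d)``.

    If FM leaves [0, 250] kg during integration the trajectory is
    truncated at the boundary-crossing step with a warning.
    """
    if not dt_d > 0:
        raise ValidationError(f"dt_d: must be > 0, got {dt_d}")
    if not duration_d > 0:
        raise ValidationError(f"duration_d: must be > 0, got {duration_d}")
    intake_fn = intake if callable(intake) else (lambda t, v=float(intake): v)
    coeffs = get_coefficients(cov.race, cov.sex, registry_variant)

    def phi(F):
        return evaluate_polynomial(coeffs, F, cov.age_y, cov.height_cm)

    def rhs(t, F):
        if not 0.0 <= F <= FM_MAX_KG:
            raise _Truncation
        dphi = evaluate_polynomial_derivative(coeffs, F, cov.age_y,
                                              cov.height_cm)
        denom = params.c_f + params.c_l * dphi
        if denom <= 0:
            raise ModelValidityError(
                f"c_f + c_l*phi'(FM) = {denom:.4g} <= 0 at FM = {F:.4g} kg")
        return (intake_fn(t) - expenditure(F, phi(F))) / denom

    n_steps = max(1, int(round(duration_d / dt_d)))
    fm0 = solve_fm(initial_total_kg, cov, registry_variant)
    times = [0.0]
    fms = [fm0]
    intakes = [float(intake_fn(0.0))]
    F = fm0
    for k in range(n_steps):
        t = k * dt_d
        try:
            k1 = rhs(t, F)
            k2 = rhs(t + dt_d / 2, F + dt_d / 2 * k1)
            k3 = rhs(t + dt_d / 2, F + dt_d / 2 * k2)
            k4 = rhs(t + dt_d, F + dt_d * k3)
            F_next = F + dt_d / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        except _Truncation:
            warnings.warn(
                f"fat mass left [0, {FM_MAX_KG}] kg at day {t:.3g}; "
                "trajectory truncated", RuntimeWarning, stacklevel=2)
            break
        if not 0.0 <= F_next <= FM_MAX_KG:
            warnings.warn(
                f"fat mass left [0, {FM_MAX_KG}] kg at day {t + dt_d:.3g}; "
                "trajectory truncated", RuntimeWarning, stacklevel=2)
            break
        F = F_next
        times.append(t + dt_d)
        fms.append(F)
        intakes.append(float(intake_fn(t + dt_d)))
    fm_arr = np.array(fms)
    return Trajectory(
        times_d=np.array(times),
        fm_kg=fm_arr,
        ffm_kg=np.array([phi(f) for f in fm_arr]),
        intake_kcal_d=np.array(intakes),
    )


class _Truncation(Exception):
    """Internal: an RK4 stage stepped outside the valid FM range."""
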