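"""Branched first-order parent-metabolite kinetics.

The model describes a parent compound S (e.g. pyrene, mg/L) degraded with
total first-order rate constant ``k_tot`` (1/d), a fraction ``f`` of the
degraded flux channelled into a tracked intermediate P (e.g. 2,2'-diphenic
acid) which itself decays with first-order rate constant ``k2``:

    dS/dt = -k_tot * S
    dP/dt = f * k_tot * S - k2 * P

The effective formation rate constant of the intermediate is
``k_a = f * k_tot``.  The closed-form solution of the P equation is the
classical Bateman daughter-product expression; the degenerate case
``k2 == k_tot`` uses its analytic limit.

All times are in days and all concentrations in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, ValidationError

__all__ = [
    "KineticParams",
    "StateTrajectory",
    "closed_form_solution",
    "solve_numeric",
    "parent_concentration",
    "intermediate_concentration",
    "half_life",
    "formation_rate_constant",
    "intermediate_peak",
]

#: Rate-difference threshold (1/d) below which the equal-rate limit formula is
#: used for the intermediate; below double-precision cancellation noise for
#: the exponent ranges encountered here.
DEGENERATE_RATE_EPS = 1e-8

#: Negative concentrations larger in magnitude than this are treated as bugs,
#: not float noise.
_NEGATIVE_NOISE_TOL = 1e-12


@dataclass(frozen=True)
class KineticParams:
    """Parameter vector of the branched first-order model.

    Parameters
    ----------
    k_tot : float
        Total parent degradation rate constant, 1/d.  Must be > 0.
    f : float
        Branching fraction of degraded parent converted to the intermediate,
        dimensionless in [0, 1].
    k2 : float
        Intermediate degradation rate constant, 1/d.  Must be >= 0.
    S0 : float
        Initial parent concentration, mg/L.  Must be >= 0.
    P0 : float, optional
        Initial intermediate concentration, mg/L (default 0; cultures start
        without intermediate).
    """

    k_tot: float
    f: float
    k2: float
    S0: float
    P0: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.k_tot, self.f, self.k2, self.S0, self.P0)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite kinetic parameter in {vals}")
        if self.k_tot <= 0:
            raise ValidationError(f"k_tot must be > 0, got {self.k_tot}")
        if not 0.0 <= self.f <= 1.0:
            raise ValidationError(f"branching fraction f must lie in [0, 1], got {self.f}")
        if self.k2 < 0:
            raise ValidationError(f"k2 must be >= 0, got {self.k2}")
        if self.S0 < 0 or self.P0 < 0:
            raise ValidationError(f"initial concentrations must be >= 0, got S0={self.S0}, P0={self.P0}")

    @property
    def k_a(self) -> float:
        """Effective intermediate formation rate constant, ``f * k_tot`` (1/d)."""
        return self.f * self.k_tot

    def as_dict(self) -> dict[str, float]:
        return {
            "k_tot": self.k_tot,
            "f": self.f,
            "k2": self.k2,
            "k_a": self.k_a,
            "S0": self.S0,
            "P0": self.P0,
        }


@dataclass(frozen=True)
class StateTrajectory:
    """Model trajectory: parent and intermediate concentration per time point."""

    times: np.ndarray
    S_values: np.ndarray
    P_values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        S = np.asarray(self.S_values, dtype=float)
        P = np.asarray(self.P_values, dtype=float)
        if times.ndim != 1 or S.shape != times.shape or P.shape != times.shape:
            raise ValidationError("times, S_values and P_values must be 1-D arrays of equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "S_values", _clip_float_noise(S))
        object.__setattr__(self, "P_values", _clip_float_noise(P))


def _clip_float_noise(values: np.ndarray) -> np.ndarray:
    """Zero out tiny negative float noise; reject genuinely negative values."""
    values = np.asarray(values, dtype=float)
    if np.any(values < -_NEGATIVE_NOISE_TOL):
        raise ValidationError(
            f"negative concentration {values.min():.3e} mg/L exceeds float-noise tolerance"
        )
    return np.where(values < 0, 0.0, values)


def _check_times(times) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if not np.all(np.isfinite(times)):
        raise ValidationError("times must be finite")
    if np.any(times < 0):
        raise ValidationError("times must be >= 0 days")
    return times


def parent_concentration(params: KineticParams, times) -> np.ndarray:
    """Closed-form parent concentration ``S(t) = S0 * exp(-k_tot t)``, mg/L."""
    t = _check_times(times)
    return params.S0 * np.exp(-params.k_tot * t)


def intermediate_concentration(params: KineticParams, times) -> np.ndarray:
    """Closed-form intermediate concentration P(t), mg/L (Bateman solution).

    For distinct rates::

        P(t) = P0 e^{-k2 t} + f k_tot S0 / (k2 - k_tot) * (e^{-k_tot t} - e^{-k2 t})

    and in the degenerate limit ``|k2 - k_tot| <= eps``::

        P(t) = P0 e^{-k_tot t} + f k_tot S0 * t * e^{-k_tot t}
    """
    t = _check_times(times)
    k_tot, k2 = params.k_tot, params.k2
    if abs(k2 - k_tot) <= DEGENERATE_RATE_EPS:
        return (params.P0 + params.f * k_tot * params.S0 * t) * np.exp(-k_tot * t)
    formation = params.f * k_tot * params.S0 / (k2 - k_tot)
    return params.P0 * np.exp(-k2 * t) + formation * (np.exp(-k_tot * t) - np.exp(-k2 * t))


def closed_form_solution(params: KineticParams, times) -> StateTrajectory:
    """Evaluate the closed-form model on a strictly increasing time grid.

    Parameters
    ----------
    params : KineticParams
        Validated model parameters.
    times : array-like
        Sample times in days, >= 0 and strictly increasing.

    Returns
    -------
    StateTrajectory
    """
    t = _check_times(times)
    return StateTrajectory(
        times=t,
        S_values=parent_concentration(params, t),
        P_values=intermediate_concentration(params, t),
    )


def solve_numeric(
    params: KineticParams,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> StateTrajectory:
    """Integrate the coupled ODEs with an adaptive Runge-Kutta scheme.

    Serves as the internal cross-check oracle for :func:`closed_form_solution`;
    both must agree to well below measurement precision.

    Raises
    ------
    IntegrationError
        If the solver does not complete; the message carries its diagnostics.
    """
    t = _check_times(times)

    def rhs(_t, y):
        s, p = y
        return [-params.k_tot * s, params.f * params.k_tot * s - params.k2 * p]

    t_end = float(t[-1]) if t.size else 0.0
    sol = solve_ivp(
        rhs,
        (0.0, max(t_end, 1e-12)),
        [params.S0, params.P0],
        t_eval=t,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    S, P = sol.y
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(P))):
        raise IntegrationError("ODE integration produced non-finite concentrations")
    return StateTrajectory(times=t, S_values=S, P_values=P)


def half_life(k: float) -> float:
    """First-order half-life ``ln(2)/k`` in days, for a rate constant in 1/d."""
    if not (math.isfinite(k) and k > 0):
        raise ValidationError(f"rate constant must be finite and > 0, got {k}")
    return math.log(2.0) / k


def formation_rate_constant(f: float, k_tot: float) -> float:
    """Effective intermediate formation rate constant ``k_a = f * k_tot`` (1/d)."""
    if not (math.isfinite(f) and 0.0 <= f <= 1.0):
        raise ValidationError(f"branching fraction f must lie in [0, 1], got {f}")
    if not (math.isfinite(k_tot) and k_tot > 0):
        raise ValidationError(f"k_tot must be > 0, got {k_tot}")
    return f * k_tot


def intermediate_peak(params: KineticParams) -> tuple[float, float]:
    """Time and height of the intermediate concentration maximum.

    With no initial intermediate the peak time is
    ``ln(k2 / k_tot) / (k2 - k_tot)`` (or ``1/k_tot`` when the rates
    coincide); it does not depend on ``f`` or ``S0``, which only scale the
    curve.

    Returns
    -------
    (peak_time, peak_conc) : tuple of float
        Days and mg/L.
    """
    if params.f <= 0:
        raise ValidationError("no intermediate formed: branching fraction f is 0")
    if params.S0 <= 0:
        raise ValidationError("no intermediate formed: S0 is 0")
    if params.P0 != 0:
        raise ValidationError("peak formula requires P0 = 0")
    if params.k2 <= 0:
        raise ValidationError("peak requires k2 > 0 (otherwise P is monotone)")
    k_tot, k2 = params.k_tot, params.k2
    if abs(k2 - k_tot) <= DEGENERATE_RATE_EPS:
        t_peak = 1.0 / k_tot
    else:
        t_peak = math.log(k2 / k_tot) / (k2 - k_tot)
    p_peak = float(intermediate_concentration(params, t_peak)[0])
    return t_peak, p_peak
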