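"""Burgers viscoelastic forward model.

The Burgers material is a Maxwell element (spring ``E1 = 1/J1`` in series
with dashpot ``eta0``) in series with a Kelvin–Voigt element (spring
``E2 = 1/J2`` in parallel with dashpot ``eta2 = tau/J2``).  Under a constant
stress applied at ``t = 0`` its creep compliance is

    J(t) = J1 + J2 * (1 - exp(-t / tau)) + t / eta0

with instantaneous compliance ``J1``, retarded compliance amplitude ``J2``,
retardation time ``tau`` and zero-shear viscosity ``eta0``.  The recoverable
part ``Je0 = J1 + J2`` is the steady-state compliance: the intercept of the
long-time flow asymptote ``Je0 + t/eta0``.

A viscoelastic solid (no steady flow) is represented exactly by
``eta0 = inf`` rather than by a large finite viscosity, so the complete
recovery limit holds to machine precision.

Displacement of a probe dragged through the material by a step-force
protocol follows from Boltzmann superposition: each force step of size
``+/-F0`` at time ``s`` contributes ``+/-(F0/C) * J(t - s)`` for ``t >= s``,
where ``C`` is the geometric drag coefficient (units of length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BurgersParams",
    "ForceProtocol",
    "ComplianceCurve",
    "creep_compliance",
    "steady_state_compliance",
    "displacement_response",
]


@dataclass(frozen=True)
class BurgersParams:
    """Four-parameter Burgers material state.

    Parameters
    ----------
    J1 : float
        Instantaneous elastic compliance, Pa^-1 (reciprocal of the Maxwell
        spring modulus).  Strictly positive.
    J2 : float
        Retarded compliance amplitude, Pa^-1 (reciprocal of the Kelvin-Voigt
        spring modulus).  Nonnegative.
    tau : float
        Retardation time, s (Kelvin-Voigt dashpot viscosity divided by its
        spring modulus).  Strictly positive.
    eta0 : float
        Zero-shear viscosity, Pa*s (Maxwell dashpot).  Strictly positive;
        ``math.inf`` denotes a viscoelastic solid (no steady flow).
    """

    J1: float
    J2: float
    tau: float
    eta0: float

    def __post_init__(self) -> None:
        if not (self.J1 > 0 and math.isfinite(self.J1)):
            raise ValueError(f"J1 must be finite and > 0, got {self.J1}")
        if not (self.J2 >= 0 and math.isfinite(self.J2)):
            raise ValueError(f"J2 must be finite and >= 0, got {self.J2}")
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise ValueError(f"tau must be finite and > 0, got {self.tau}")
        if not self.eta0 > 0:  # inf allowed
            raise ValueError(f"eta0 must be > 0 (inf allowed), got {self.eta0}")

    @property
    def Je0(self) -> float:
        """Steady-state (recoverable) compliance J1 + J2, Pa^-1."""
        return self.J1 + self.J2

    @property
    def is_solid(self) -> bool:
        """True for the viscoelastic-solid sentinel eta0 = inf."""
        return math.isinf(self.eta0)

    def moduli(self) -> dict:
        """Spring/dashpot view: E1 = 1/J1, E2 = 1/J2, eta2 = tau/J2, eta1 = eta0."""
        return {
            "E1_Pa": 1.0 / self.J1,
            "E2_Pa": (1.0 / self.J2) if self.J2 > 0 else math.inf,
            "eta2_Pa_s": self.tau / self.J2 if self.J2 > 0 else math.inf,
            "eta1_Pa_s": self.eta0,
        }

    def to_dict(self) -> dict:
        return {
            "J1": self.J1,
            "J2": self.J2,
            "tau": self.tau,
            "eta0": self.eta0 if math.isfinite(self.eta0) else "inf",
            "units": {"J1": "1/Pa", "J2": "1/Pa", "tau": "s", "eta0": "Pa*s"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BurgersParams":
        eta0 = d["eta0"]
        if isinstance(eta0, str):
            eta0 = math.inf
        return cls(J1=float(d["J1"]), J2=float(d["J2"]), tau=float(d["tau"]), eta0=float(eta0))


@dataclass(frozen=True)
class ForceProtocol:
    """Square-wave step-force protocol.

    Default values are the acquisition protocol used throughout: a step
    force held for 10 s, released for 20 s, repeated twice, sampled every
    500 ms.

    ``F0`` is in newtons.  ``current`` optionally records the coil current
    (A) the force was derived from.
    """

    F0: float
    t_on: float = 10.0
    t_off: float = 20.0
    n_cycles: int = 2
    dt: float = 0.5
    current: Optional[float] = None

    def __post_init__(self) -> None:
        if self.F0 < 0:
            raise ValueError("F0 must be >= 0")
        if self.t_on <= 0 or self.t_off < 0:
            raise ValueError("t_on must be > 0 and t_off >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not (0 < self.dt < self.t_on):
            raise ValueError("dt must satisfy 0 < dt < t_on")

    @property
    def period(self) -> float:
        return self.t_on + self.t_off

    @property
    def duration(self) -> float:
        return self.n_cycles * self.period

    def times(self) -> np.ndarray:
        """Sample grid [0, duration) at spacing dt."""
        n = int(round(self.duration / self.dt))
        return np.arange(n) * self.dt

    def on_mask(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: force on at sample time t.

        A sample belongs to the on phase iff ``t mod period < t_on``; the
        sample at the off switch itself is labelled off.
        """
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period)
        return (phase < self.t_on) & (t < self.duration)

    def force_series(self, t: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
        if t is None:
            t = self.times()
        return t, np.where(self.on_mask(t), self.F0, 0.0)


@dataclass(frozen=True)
class ComplianceCurve:
    """Sampled creep compliance J(t) with on/off phase annotation.

    ``t`` is in seconds relative to the first force onset, ``J`` in Pa^-1,
    and ``on`` is a boolean mask marking force-on samples.  ``F0`` (N)
    records the applied force the curve was measured at.
    """

    t: np.ndarray
    J: np.ndarray
    on: np.ndarray
    F0: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        J = np.asarray(self.J, dtype=float)
        on = np.asarray(self.on, dtype=bool)
        if not (t.shape == J.shape == on.shape):
            raise ValueError("t, J and on must have equal shapes")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(J)):
            raise ValueError("J must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "on", on)

    def __len__(self) -> int:
        return self.t.size


def creep_compliance(params: BurgersParams, t) -> np.ndarray:
    """Creep compliance J(t) = J1 + J2*(1 - exp(-t/tau)) + t/eta0.

    Parameters
    ----------
    params : BurgersParams
    t : array_like
        Time since force onset, s.  Must be >= 0.

    Returns
    -------
    ndarray (or scalar for scalar input) of compliance values, Pa^-1.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("creep compliance is defined for t >= 0 only")
    flow = np.zeros_like(t_arr) if params.is_solid else t_arr / params.eta0
    J = params.J1 + params.J2 * (-np.expm1(-t_arr / params.tau)) + flow
    return J if np.ndim(t) else float(J)


def steady_state_compliance(params: BurgersParams) -> float:
    """Steady-state compliance Je0 = J1 + J2, Pa^-1."""
    return params.Je0


def _step_response(params: BurgersParams, t: np.ndarray) -> np.ndarray:
    """J(t) extended with 0 for t < 0 (causal step response)."""
    out = np.zeros_like(t)
    pos = t >= 0
    if np.any(pos):
        out[pos] = creep_compliance(params, t[pos])
    return out


def displacement_response(
    params: BurgersParams,
    drag: float,
    protocol: ForceProtocol,
    t: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probe displacement under an on/off step-force protocol.

    Boltzmann superposition over the square wave: each cycle k contributes
    a positive force step at ``k*period`` and a negative step at
    ``k*period + t_on``, so

        x(t) = (F0/C) * sum_k [ J(t - k*P) - J(t - k*P - t_on) ]

    with terms zero before their step time.  After a single on phase of
    length t1 the recovery is ``(F0/C) * (J(t) - J(t - t1))``, which tends
    to the unrecoverable ``(F0/C) * t1/eta0`` (zero for a solid).

    Parameters
    ----------
    params : BurgersParams
    drag : float
        Geometric drag coefficient C, m.  Must be > 0.
    protocol : ForceProtocol
    t : ndarray, optional
        Sample times, s.  Defaults to ``protocol.times()``.

    Returns
    -------
    (t, x) : tuple of ndarray
        Sample times (s) and displacements (m).
    """
    if not drag > 0:
        raise ValueError("drag coefficient must be > 0")
    if t is None:
        t = protocol.times()
    t = np.asarray(t, dtype=float)
    if protocol.F0 == 0:
        return t, np.zeros_like(t)
    x = np.zeros_like(t)
    for k in range(protocol.n_cycles):
        s_on = k * protocol.period
        x += _step_response(params, t - s_on)
        x -= _step_response(params, t - s_on - protocol.t_on)
    x *= protocol.F0 / drag
    return t, x
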