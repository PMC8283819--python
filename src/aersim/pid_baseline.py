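"""Discrete PID comparator for the dissolved-oxygen loop.

The PID acts on the same normalized output range as the fuzzy controller
(u in [-1, 1], actuator-mapped to air flow), so the two are compared on
equal footing.  Default gains come from a step-response (FOPDT reaction
curve) characterization of the default plant with conservative IMC-style
detuning; they are deliberately modest — a single linear controller tuned
not to overshoot the nonlinear oxygen balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fuzzy_controller import ActuatorMap

__all__ = ["PIDGains", "PIDState", "pid_step", "PIDController"]


@dataclass(frozen=True)
class PIDGains:
    """Proportional / integral / derivative gains on the error in mg/L.

    ``kp`` is dimensionless (normalized u per mg/L), ``ki`` per hour,
    ``kd`` in hours; ``windup_limit`` clamps the integral term in output
    units.
    """

    kp: float = 0.35
    ki: float = 0.7
    kd: float = 0.01
    windup_limit: float = 1.0

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("gains must be nonnegative")
        if self.windup_limit <= 0:
            raise ValueError("windup_limit must be positive")


@dataclass
class PIDState:
    integral: float = 0.0
    prev_error: float | None = None


def pid_step(
    e: float, gains: PIDGains, state: PIDState, dt: float
) -> tuple[float, PIDState]:
    """One discrete PID update; returns (u, new state) with u in [-1, 1].

    The integral term is clamped at ±windup_limit; the derivative is zero on
    the first step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(e):
        raise ValueError("error must be finite")
    integral = state.integral + gains.ki * e * dt
    integral = float(np.clip(integral, -gains.windup_limit, gains.windup_limit))
    deriv = 0.0 if state.prev_error is None else (e - state.prev_error) / dt
    u = gains.kp * e + integral + gains.kd * deriv
    u = float(np.clip(u, -1.0, 1.0))
    return u, PIDState(integral=integral, prev_error=e)


@dataclass
class PIDController:
    """Closed-loop PID policy: ``controller(setpoint, measured_DO, t) -> airflow``."""

    gains: PIDGains = field(default_factory=PIDGains)
    actuator: ActuatorMap = field(
        default_factory=lambda: ActuatorMap(trim_gain=0.0)
    )
    dt: float = 0.02
    state: PIDState = field(default_factory=PIDState)

    @classmethod
    def default(cls, mu_max: float = 100.0, **kwargs) -> "PIDController":
        act = ActuatorMap(bias=mu_max / 2, mu_max=mu_max, trim_gain=0.0)
        return cls(actuator=act, **kwargs)

    def reset(self) -> None:
        self.state = PIDState()
        self.actuator.reset()

    def __call__(self, y_ref: float, y: float, t: float) -> float:
        u, self.state = pid_step(y_ref - y, self.gains, self.state, self.dt)
        return self.actuator(u, 0.0, self.dt)
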