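"""Three-state activated-sludge aeration-tank model.

The plant is a completely-mixed aeration tank described by dissolved oxygen
``O``, substrate (COD) ``S`` and biomass (MLVSS) ``X``, all in mg/L.  The
state equations combine a Lawrence--McCarty substrate/biomass balance with an
oxygen balance in which aeration enters through a transfer term and oxygen is
consumed by substrate oxidation and endogenous respiration::

    dO/dt = k_air * mu * (o_sat - O) - 0.57 * lam * (s_in - S) - 1.1 * k_resp * X
    dS/dt = lam * (s_in - S) - k_max * S * X / (k_s + S)
    dX/dt = eta * k_max * S * X / (k_s + S) - k_d * X

where ``mu`` is the air flow in m^3/h.  The oxygen-demand coefficients 0.57
(oxygen per unit substrate removed) and 1.1 (oxygen per unit endogenous decay)
are classical activated-sludge values.  All rates are harmonized to hours;
``k_max`` and ``k_d`` are conventionally quoted per day and converted on
construction via :meth:`ProcessParams.default`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ProcessState",
    "ProcessParams",
    "Trajectory",
    "SimulationDiverged",
    "derivatives",
    "simulate",
    "steady_state",
    "HOURS_PER_DAY",
]

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0

#: Oxygen consumed per unit of substrate COD removed (dimensionless).
O2_PER_SUBSTRATE = 0.57
#: Oxygen consumed per unit of biomass in endogenous respiration.
O2_PER_BIOMASS = 1.1

_DIVERGENCE_LIMIT = 1.0e6


class SimulationDiverged(RuntimeError):
    """Raised when any state magnitude exceeds 1e6 mg/L during integration."""


@dataclass(frozen=True)
class ProcessState:
    """Plant state at one time point (concentrations in mg/L, time in h)."""

    O: float
    S: float
    X: float
    t: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.O, self.S, self.X, self.t)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite state {vals!r}")
        if self.O < 0 or self.S < 0 or self.X < 0:
            raise ValueError(f"negative concentration in state {vals!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.O, self.S, self.X], dtype=float)


@dataclass(frozen=True)
class ProcessParams:
    """Kinetic and operational constants, harmonized to hours.

    Parameters
    ----------
    eta : float
        True yield coefficient of the sludge microorganisms (g biomass per
        g substrate), dimensionless, in (0, 1].
    k_resp : float
        Endogenous respiration rate constant, 1/h.
    k_max : float
        Maximum specific substrate utilization rate, 1/h.
    k_s : float
        Half-saturation (half-velocity) constant, mg/L.
    lam : float
        Reciprocal of the hydraulic fill time (dilution rate), 1/h.
    k_d : float
        Biomass decay constant, 1/h.
    s_in : float
        Influent substrate concentration, mg/L.
    o_sat : float
        Dissolved-oxygen saturation concentration, mg/L (9.08 at 20 C).
    k_air : float
        Oxygen-transfer gain per unit air flow, 1/(m^3) (so that
        ``k_air * airflow`` is a volumetric transfer coefficient in 1/h;
        tank-volume dependence is absorbed here).
    mu_max : float
        Maximum deliverable air flow, m^3/h.
    """

    eta: float
    k_resp: float
    k_max: float
    k_s: float
    lam: float
    k_d: float
    s_in: float
    o_sat: float
    k_air: float
    mu_max: float

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        for name in ("k_resp", "k_max", "k_s", "lam", "k_d", "o_sat", "k_air", "mu_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.s_in < 0:
            raise ValueError("s_in must be nonnegative")

    @classmethod
    def default(
        cls,
        *,
        eta: float = 0.6,
        k_max_per_day: float = 5.0,
        k_s: float = 60.0,
        k_d_per_day: float = 0.06,
        k_resp: float = 0.005,
        lam: float = 0.125,
        s_in: float = 400.0,
        o_sat: float = 9.08,
        mu_max: float = 100.0,
        k_air: float | None = None,
        design_airflow: float = 50.0,
        design_oxygen: float = 2.0,
    ) -> "ProcessParams":
        """Default parameter set from typical activated-sludge ranges.

        ``k_max`` and ``k_d`` are quoted per day and converted to 1/h.  When
        ``k_air`` is not given it is sized so that ``design_airflow`` m^3/h
        sustains ``design_oxygen`` mg/L DO at the biological steady state --
        i.e. the nominal operating point is an equilibrium of the loop.
        """
        k_max = k_max_per_day / HOURS_PER_DAY
        k_d = k_d_per_day / HOURS_PER_DAY
        if k_air is None:
            s_star = k_d * k_s / (eta * k_max - k_d)
            x_star = lam * (s_in - s_star) * (k_s + s_star) / (k_max * s_star)
            demand = O2_PER_SUBSTRATE * lam * (s_in - s_star) + O2_PER_BIOMASS * k_resp * x_star
            k_air = demand / (design_airflow * (o_sat - design_oxygen))
        return cls(
            eta=eta,
            k_resp=k_resp,
            k_max=k_max,
            k_s=k_s,
            lam=lam,
            k_d=k_d,
            s_in=s_in,
            o_sat=o_sat,
            k_air=k_air,
            mu_max=mu_max,
        )

    def substrate_steady_state(self) -> float:
        """Closed-form steady-state substrate K_d*K_s/(eta*K - K_d) (mg/L).

        Valid whenever a steady state with positive biomass exists, i.e.
        ``eta * k_max > k_d``.
        """
        denom = self.eta * self.k_max - self.k_d
        if denom <= 0:
            raise ValueError("no positive-biomass steady state: eta*k_max <= k_d")
        return self.k_d * self.k_s / denom


def derivatives(
    state: ProcessState, params: ProcessParams, airflow: float
) -> tuple[float, float, float]:
    """Right-hand side (dO/dt, dS/dt, dX/dt) in mg/L/h at a given air flow."""
    if not math.isfinite(airflow):
        raise ValueError("airflow must be finite")
    if airflow < 0 or airflow > params.mu_max:
        raise ValueError(f"airflow {airflow} outside [0, {params.mu_max}] m^3/h")
    return _rhs(state.as_array(), params, airflow)


def _rhs(y: np.ndarray, p: ProcessParams, airflow: float) -> tuple[float, float, float]:
    O, S, X = float(y[0]), float(y[1]), float(y[2])
    uptake = p.k_max * S * X / (p.k_s + S)
    dO = (
        p.k_air * airflow * (p.o_sat - O)
        - O2_PER_SUBSTRATE * p.lam * (p.s_in - S)
        - O2_PER_BIOMASS * p.k_resp * X
    )
    dS = p.lam * (p.s_in - S) - uptake
    dX = p.eta * uptake - p.k_d * X
    return dO, dS, dX


@dataclass
class Trajectory:
    """Equal-length simulated time series on a strictly increasing grid."""

    t: np.ndarray
    O: np.ndarray
    S: np.ndarray
    X: np.ndarray
    airflow: np.ndarray
    setpoint: np.ndarray
    clip_events: int = 0

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("O", "S", "X", "airflow", "setpoint"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory series lengths differ")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def final_state(self) -> ProcessState:
        return ProcessState(
            O=float(self.O[-1]), S=float(self.S[-1]), X=float(self.X[-1]), t=float(self.t[-1])
        )

    def to_frame(self):
        """Trajectory as a pandas DataFrame with the canonical CSV columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_h": self.t,
                "O_mgL": self.O,
                "S_mgL": self.S,
                "X_mgL": self.X,
                "airflow_m3h": self.airflow,
                "setpoint_mgL": self.setpoint,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


Controller = Callable[[float, float, float], float]
"""Control policy: (setpoint mg/L, measured DO mg/L, time h) -> airflow m^3/h."""


def simulate(
    initial: ProcessState,
    params: ProcessParams,
    controller: Controller,
    setpoint: float,
    horizon: float,
    dt: float = 0.01,
    disturbances: Sequence[tuple[float, str, float]] = (),
    control_interval: float = 0.02,
) -> Trajectory:
    """Integrate the closed loop with fixed-step RK4 and zero-order-hold control.

    The controller is sampled every ``control_interval`` hours and its output
    held between samples; out-of-range or non-finite commands are clipped to
    ``[0, mu_max]`` and logged.  ``disturbances`` are step changes
    ``(time_h, param_name, new_value)`` applied to the plant parameters.
    Negative state excursions (a numerical artifact of the stiff oxygen
    balance at low DO) are clipped to zero and counted in
    ``Trajectory.clip_events``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    if horizon and horizon < dt:
        raise ValueError("horizon must be at least dt")
    for dtime, name, _ in disturbances:
        if not 0 <= dtime <= horizon:
            raise ValueError(f"disturbance time {dtime} outside [0, {horizon}]")
        if not hasattr(params, name):
            raise ValueError(f"unknown plant parameter {name!r}")

    n_steps = int(math.ceil(horizon / dt)) if horizon > 0 else 0
    t = initial.t + np.arange(n_steps + 1) * dt
    y = np.empty((n_steps + 1, 3))
    y[0] = initial.as_array()
    airflow_series = np.empty(n_steps + 1)
    pending = sorted(disturbances, key=lambda d: d[0])
    clip_events = 0

    p = params
    airflow = _sample_controller(controller, setpoint, y[0][0], float(t[0]), p)
    airflow_series[0] = airflow
    next_sample = control_interval

    for i in range(n_steps):
        ti = float(t[i] - initial.t)
        while pending and pending[0][0] <= ti + 1e-12:
            _, name, value = pending.pop(0)
            p = replace(p, **{name: value})
        if ti + 1e-12 >= next_sample:
            airflow = _sample_controller(controller, setpoint, float(y[i][0]), float(t[i]), p)
            next_sample += control_interval

        y[i + 1] = _rk4_step(y[i], p, airflow, dt)
        neg = y[i + 1] < 0
        if neg.any():
            clip_events += int(neg.sum())
            logger.debug("clipped negative state at t=%.3f h: %s", t[i + 1], y[i + 1])
            y[i + 1][neg] = 0.0
        if np.any(np.abs(y[i + 1]) > _DIVERGENCE_LIMIT):
            raise SimulationDiverged(
                f"state magnitude exceeded {_DIVERGENCE_LIMIT:g} mg/L at t={t[i + 1]:.3f} h: "
                f"{y[i + 1]!r}"
            )
        airflow_series[i + 1] = airflow

    return Trajectory(
        t=t,
        O=y[:, 0].copy(),
        S=y[:, 1].copy(),
        X=y[:, 2].copy(),
        airflow=airflow_series,
        setpoint=np.full(n_steps + 1, setpoint, dtype=float),
        clip_events=clip_events,
    )


def _sample_controller(
    controller: Controller, setpoint: float, y_meas: float, t: float, params: ProcessParams
) -> float:
    cmd = controller(setpoint, y_meas, t)
    if not math.isfinite(cmd) or cmd < 0 or cmd > params.mu_max:
        clipped = float(np.clip(cmd if math.isfinite(cmd) else 0.0, 0.0, params.mu_max))
        logger.debug("controller command %r clipped to %.3f m^3/h at t=%.3f h", cmd, clipped, t)
        cmd = clipped
    return float(cmd)


def _rk4_step(y: np.ndarray, p: ProcessParams, airflow: float, dt: float) -> np.ndarray:
    k1 = np.asarray(_rhs(y, p, airflow))
    k2 = np.asarray(_rhs(y + 0.5 * dt * k1, p, airflow))
    k3 = np.asarray(_rhs(y + 0.5 * dt * k2, p, airflow))
    k4 = np.asarray(_rhs(y + dt * k3, p, airflow))
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of the steady-state search; ``state`` is None when no
    nonnegative root exists (e.g. zero airflow cannot sustain DO)."""

    state: ProcessState | None
    residual: float = math.inf

    @property
    def found(self) -> bool:
        return self.state is not None


def steady_state(
    params: ProcessParams, airflow: float, residual_tol: float = 1e-8
) -> SteadyStateResult:
    """Nonnegative root of the RHS at fixed airflow, found numerically.

    Uses the positive-biomass closed form as the starting guess and verifies
    the residual norm is below ``residual_tol`` mg/L/h.
    """
    if airflow < 0 or airflow > params.mu_max:
        raise ValueError(f"airflow {airflow} outside [0, {params.mu_max}]")

    if params.k_air * airflow < 1e-12:
        # O does not appear in the oxygen balance: a steady state exists only
        # if the oxygen sinks vanish, i.e. washout (X=0, S=s_in), where any O
        # is neutrally stable; report the O=0 member or no root at all
        washout = np.array([0.0, params.s_in, 0.0])
        resid = float(np.linalg.norm(_rhs(washout, params, airflow)))
        if resid < residual_tol:
            return SteadyStateResult(
                state=ProcessState(O=0.0, S=params.s_in, X=0.0), residual=resid
            )
        return SteadyStateResult(state=None)

    guesses: list[np.ndarray] = []
    try:
        s0 = params.substrate_steady_state()
        if s0 < params.s_in:
            x0 = params.lam * (params.s_in - s0) * (params.k_s + s0) / (params.k_max * s0)
            o0 = min(max(params.o_sat / 2, 0.1), params.o_sat)
            guesses.append(np.array([o0, s0, x0]))
    except ValueError:
        pass
    # washout branch (X = 0, S -> s_in)
    guesses.append(np.array([params.o_sat / 2, params.s_in, 0.0]))

    for guess in guesses:
        sol = optimize.root(lambda y: np.asarray(_rhs(y, params, airflow)), guess, method="hybr")
        y = sol.x
        resid = float(np.linalg.norm(_rhs(y, params, airflow)))
        if sol.success and resid < residual_tol and np.all(y >= -1e-9):
            y = np.clip(y, 0.0, None)
            return SteadyStateResult(
                state=ProcessState(O=float(y[0]), S=float(y[1]), X=float(y[2])),
                residual=resid,
            )
    return SteadyStateResult(state=None)
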