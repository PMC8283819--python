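"""Closed-loop step experiments and control-quality metrics.

The default scenario applies a 2.0 mg/L dissolved-oxygen setpoint step at
t=0 to a plant started at its biological steady state with low DO, adds an
influent-load disturbance (+25% influent COD) at half the horizon, and runs
both the quantized fuzzy controller and the PID baseline on identical plant,
horizon and disturbance schedule.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import config as cfgmod
from .process_model import SimulationDiverged, Trajectory, simulate

__all__ = [
    "StepMetrics",
    "ExperimentResult",
    "compute_metrics",
    "run_step_experiment",
    "compare_controllers",
]

UNSETTLED = math.inf


@dataclass(frozen=True)
class StepMetrics:
    """Summary of a setpoint step response.

    rise_time: 10% -> 90% of the step, h.  overshoot: peak beyond the
    setpoint as % of the step size.  settling_time: first time after which
    the output stays inside the +-band (fraction of step size) around the
    setpoint, h; infinity when the band is never held (``settled`` False).
    steady_state_error: mean absolute error over the final window, mg/L.
    iae: integral of absolute error, mg*h/L.
    """

    rise_time: float
    overshoot: float
    settling_time: float
    steady_state_error: float
    iae: float
    settled: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        if not self.settled:
            d["settling_time"] = "not settled"
        return d


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """Linearly interpolated first time y crosses level (nan if never)."""
    above = y >= level if rising else y <= level
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return math.nan
    i = idx[0]
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def compute_metrics(
    traj: Trajectory,
    setpoint: float,
    settling_band_frac: float = 0.02,
    steady_window_frac: float = 0.10,
) -> StepMetrics:
    """Step metrics for a trajectory spanning a setpoint step at t[0]."""
    t = traj.t - traj.t[0]
    y = traj.O
    err = np.abs(setpoint - y)
    iae = float(np.trapezoid(err, t))

    window = max(1, int(math.ceil(steady_window_frac * len(y))))
    sse = float(err[-window:].mean())

    y0 = float(y[0])
    step = setpoint - y0
    if step == 0:
        rise = 0.0
        overshoot = 0.0
    else:
        rising = step > 0
        lo = y0 + 0.1 * step
        hi = y0 + 0.9 * step
        t_lo = _first_crossing(t, y, lo, rising)
        t_hi = _first_crossing(t, y, hi, rising)
        rise = t_hi - t_lo if math.isfinite(t_hi) and math.isfinite(t_lo) else math.nan
        peak = float((y - setpoint).max() if rising else (setpoint - y).max())
        overshoot = max(0.0, 100.0 * peak / abs(step))

    band = settling_band_frac * (abs(step) if step != 0 else max(abs(setpoint), 1.0))
    outside = np.flatnonzero(err > band)
    if outside.size == 0:
        settling, settled = 0.0, True
    elif outside[-1] == len(y) - 1:
        settling, settled = UNSETTLED, False
    else:
        settling, settled = float(t[outside[-1] + 1]), True

    return StepMetrics(
        rise_time=rise,
        overshoot=overshoot,
        settling_time=settling,
        steady_state_error=sse,
        iae=iae,
        settled=settled,
    )


@dataclass
class ExperimentResult:
    traj_fuzzy: Trajectory | None
    traj_pid: Trajectory | None
    metrics_fuzzy: StepMetrics | None
    metrics_pid: StepMetrics | None
    report: dict


def _disturbance_schedule(cfg: dict, plant) -> list[tuple[float, str, float]]:
    d = cfg["scenario"].get("disturbance")
    if not d:
        return []
    param = d.get("param", "s_in")
    if "value" in d and d["value"] is not None:
        value = float(d["value"])
    else:
        value = float(getattr(plant, param)) * float(d.get("factor", 1.0))
    return [(float(d["time"]), param, value)]


def run_step_experiment(cfg: dict | None = None) -> ExperimentResult:
    """Run the fuzzy and PID loops on the identical scenario.

    A diverging simulation is reported for that controller without aborting
    the other.  The report carries scenario echoes, per-controller metrics
    and the head-to-head comparison.
    """
    cfg = cfgmod.merge_config(cfgmod.default_config(), cfg or {})
    plant = cfgmod.build_plant(cfg)
    initial = cfgmod.build_initial_state(cfg, plant)
    sc = cfg["scenario"]
    disturbances = _disturbance_schedule(cfg, plant)

    controllers = {
        "fuzzy": cfgmod.build_fuzzy_controller(cfg),
        "pid": cfgmod.build_pid_controller(cfg),
    }
    trajs: dict[str, Trajectory | None] = {}
    metrics: dict[str, StepMetrics | None] = {}
    errors: dict[str, str] = {}
    for name, ctrl in controllers.items():
        ctrl.reset()
        try:
            traj = simulate(
                initial,
                plant,
                ctrl,
                setpoint=sc["setpoint"],
                horizon=sc["horizon"],
                dt=sc["dt"],
                disturbances=disturbances,
                control_interval=sc["control_interval"],
            )
        except SimulationDiverged as exc:
            trajs[name], metrics[name] = None, None
            errors[name] = str(exc)
            continue
        trajs[name] = traj
        metrics[name] = compute_metrics(
            traj,
            sc["setpoint"],
            settling_band_frac=cfg["metrics"]["settling_band_frac"],
            steady_window_frac=cfg["metrics"]["steady_window_frac"],
        )

    report = {
        "scenario": {
            "setpoint_mgL": sc["setpoint"],
            "horizon_h": sc["horizon"],
            "dt_h": sc["dt"],
            "control_interval_h": sc["control_interval"],
            "disturbances": [
                {"time_h": t, "param": p, "value": v} for t, p, v in disturbances
            ],
        },
        "metrics": {
            name: (m.to_dict() if m is not None else {"error": errors.get(name)})
            for name, m in metrics.items()
        },
    }
    if metrics["fuzzy"] is not None and metrics["pid"] is not None:
        report["comparison"] = compare_controllers(metrics["fuzzy"], metrics["pid"])

    return ExperimentResult(
        traj_fuzzy=trajs["fuzzy"],
        traj_pid=trajs["pid"],
        metrics_fuzzy=metrics["fuzzy"],
        metrics_pid=metrics["pid"],
        report=report,
    )


def compare_controllers(metrics_fuzzy: StepMetrics, metrics_pid: StepMetrics) -> dict:
    """Tabulate fuzzy-minus-PID metric deltas on a shared scenario."""
    deltas = {}
    for name in ("rise_time", "overshoot", "settling_time", "steady_state_error", "iae"):
        a, b = getattr(metrics_fuzzy, name), getattr(metrics_pid, name)
        deltas[name] = a - b if math.isfinite(a) and math.isfinite(b) else math.nan
    one_sided = metrics_fuzzy.settled != metrics_pid.settled
    fuzzy_faster = (
        metrics_fuzzy.settled
        and (not metrics_pid.settled or metrics_fuzzy.settling_time < metrics_pid.settling_time)
    )
    return {
        "delta_fuzzy_minus_pid": deltas,
        "fuzzy_settles_faster": bool(fuzzy_faster),
        "one_sided": bool(one_sided),
    }


def write_outputs(result: ExperimentResult, outdir: str | Path) -> None:
    """Write traj_fuzzy.csv, traj_pid.csv and metrics.json into outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.traj_fuzzy is not None:
        result.traj_fuzzy.to_csv(outdir / "traj_fuzzy.csv")
    if result.traj_pid is not None:
        result.traj_pid.to_csv(outdir / "traj_pid.csv")
    with open(outdir / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(result.report, fh, indent=2)
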