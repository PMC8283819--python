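"""Plain-text (YAML) configuration for plant, controllers and scenarios.

A config is a nested dict with sections ``plant``, ``controller``, ``pid``,
``scenario`` and ``metrics``; any subset may be given and is deep-merged
over the defaults below.  Builders turn the merged dict into the concrete
objects of the other modules.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import fuzzy_controller as fc
from . import pid_baseline
from .process_model import ProcessParams, ProcessState, steady_state

__all__ = [
    "default_config",
    "load_config",
    "merge_config",
    "build_plant",
    "build_initial_state",
    "build_fuzzy_controller",
    "build_pid_controller",
]

_DEFAULTS: dict[str, Any] = {
    "plant": {
        "eta": 0.6,
        "k_max_per_day": 5.0,
        "k_s": 60.0,
        "k_d_per_day": 0.06,
        "k_resp": 0.005,
        "lam": 0.125,
        "s_in": 400.0,
        "o_sat": 9.08,
        "mu_max": 100.0,
        # oxygen-transfer gain; null -> sized so design_airflow holds
        # design_oxygen at the biological steady state
        "k_air": None,
        "design_airflow": 50.0,
        "design_oxygen": 2.0,
    },
    "controller": {
        "n": 6,
        "e_max": 2.0,
        "ec_max": 1.5,
        "u_max": 1.0,
        "kec_override": None,
        "rule_table": None,  # 7x7 matrix of term labels; null -> built-in PD table
        "bias": 50.0,
        "span": 20.0,
        "trim_gain": 20.0,
        "trim_limit": 50.0,
    },
    "pid": {
        "kp": 0.35,
        "ki": 0.7,
        "kd": 0.01,
        "windup_limit": 1.0,
    },
    "scenario": {
        "initial_O": 0.5,
        "initial_S": None,  # null -> biological steady state
        "initial_X": None,
        "setpoint": 2.0,
        "horizon": 24.0,
        "dt": 0.01,
        "control_interval": 0.02,
        "disturbance": {"time": 12.0, "param": "s_in", "factor": 1.25},
    },
    "metrics": {
        "settling_band_frac": 0.02,
        "steady_window_frac": 0.10,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def merge_config(base: Mapping, override: Mapping | None) -> dict:
    """Recursive dict merge; override values win, sections combine."""
    merged = copy.deepcopy(dict(base))
    for key, value in (override or {}).items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), Mapping):
            merged[key] = merge_config(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, user)
    return cfg


def build_plant(cfg: Mapping) -> ProcessParams:
    p = dict(cfg["plant"])
    return ProcessParams.default(
        eta=p["eta"],
        k_max_per_day=p["k_max_per_day"],
        k_s=p["k_s"],
        k_d_per_day=p["k_d_per_day"],
        k_resp=p["k_resp"],
        lam=p["lam"],
        s_in=p["s_in"],
        o_sat=p["o_sat"],
        mu_max=p["mu_max"],
        k_air=p.get("k_air"),
        design_airflow=p.get("design_airflow", 50.0),
        design_oxygen=p.get("design_oxygen", 2.0),
    )


def build_initial_state(cfg: Mapping, params: ProcessParams) -> ProcessState:
    """Initial state; S and X default to the biological steady state so the
    scenario isolates the DO step response."""
    sc = cfg["scenario"]
    s0, x0 = sc.get("initial_S"), sc.get("initial_X")
    if s0 is None or x0 is None:
        ss = steady_state(params, cfg["plant"].get("design_airflow", 50.0))
        if not ss.found:
            raise RuntimeError("no plant steady state to initialize from")
        s0 = ss.state.S if s0 is None else s0
        x0 = ss.state.X if x0 is None else x0
    return ProcessState(O=float(sc["initial_O"]), S=float(s0), X=float(x0))


def build_fuzzy_controller(cfg: Mapping) -> fc.FuzzyController:
    c = cfg["controller"]
    spec = fc.compute_quantization(
        n=c["n"],
        e_max=c["e_max"],
        ec_max=c["ec_max"],
        u_max=c["u_max"],
        kec_override=c.get("kec_override"),
    )
    if c.get("rule_table"):
        rulebase = fc.RuleBase.from_labels(c["rule_table"], n=c["n"])
    else:
        rulebase = fc.RuleBase(n=c["n"])
    actuator = fc.ActuatorMap(
        bias=c["bias"],
        span=c["span"],
        mu_max=cfg["plant"]["mu_max"],
        trim_gain=c["trim_gain"],
        trim_limit=c["trim_limit"],
    )
    return fc.FuzzyController(
        spec=spec,
        rulebase=rulebase,
        actuator=actuator,
        dt=cfg["scenario"]["control_interval"],
    )


def build_pid_controller(cfg: Mapping) -> pid_baseline.PIDController:
    p = cfg["pid"]
    gains = pid_baseline.PIDGains(
        kp=p["kp"], ki=p["ki"], kd=p["kd"], windup_limit=p["windup_limit"]
    )
    c = cfg["controller"]
    actuator = fc.ActuatorMap(
        bias=c["bias"], span=c["span"], mu_max=cfg["plant"]["mu_max"], trim_gain=0.0
    )
    return pid_baseline.PIDController(
        gains=gains, actuator=actuator, dt=cfg["scenario"]["control_interval"]
    )
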