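"""Quantized fuzzy dissolved-oxygen controller, with adaptive tuning.

The controller works on a discrete universe ``N = [-n, ..., n]``.  The
tracking error ``e = y_ref - y`` and its per-step change ``ec`` are mapped
onto ``N`` by the quantization factors

    K_e = n / e_max,   K_ec = n / ec_max,

rounded to the nearest integer (ties away from zero) and clipped.  Seven
triangular linguistic terms (NB, NM, NS, ZO, PS, PM, PB) partition the
universe; a 7x7 rule table maps (error term, error-change term) to an output
term.  Inference is Mamdani with product t-norm; defuzzification is the
centroid of output-term singletons scaled by ``K_u = u_max / n``, giving a
normalized command ``u`` in ``[-u_max, u_max]``.

With the default universes (n=6, e in [-2, +2] mg/L, ec in [-1.5, +1.5]
mg/L per control step, u in [-1, 1]) the factors are K_e = 3, K_ec = 4,
K_u = 1/6.  ``kec_override`` allows forcing K_ec = 3 where that legacy value
is wanted.

``u`` is turned into an air-flow command by :class:`ActuatorMap`, an affine
map around a bias flow.  Because integer quantization creates a deadband of
half a quantization level (1/(2 K_e) mg/L in error), the map optionally
carries a slow integral trim on the bias that removes the resulting
steady-state offset — the usual fuzzy-PD-plus-integral arrangement.

The "fuzzy neural network" adaptation layer is implemented as a seeded,
derivative-free coordinate refinement of the output-term centers against a
closed-loop tracking cost (:func:`tune_fnn`): reproducible and testable, and
documented as an interpretation of adaptive tuning rather than a particular
network architecture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TERMS",
    "QuantizationSpec",
    "RuleBase",
    "LoopSignals",
    "ActuatorMap",
    "FuzzyController",
    "compute_quantization",
    "quantize",
    "fuzzify",
    "infer",
    "defuzzify",
    "control_step",
    "tune_fnn",
]

logger = logging.getLogger(__name__)

#: Linguistic terms in universe order: negative big ... positive big.
TERMS = ("NB", "NM", "NS", "ZO", "PS", "PM", "PB")
_N_TERMS = len(TERMS)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (so 1.5 -> 2, -1.5 -> -2)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class QuantizationSpec:
    """Discretization of the controller's input/output universes.

    ``K_e`` and ``K_ec`` map physical error / error-change onto the integer
    universe [-n, n]; ``K_u`` scales the defuzzified centroid back to the
    normalized output range [-u_max, u_max].
    """

    n: int
    e_max: float
    ec_max: float
    u_max: float
    K_e: float
    K_ec: float
    K_u: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.n != int(self.n):
            raise ValueError("n must be an integer >= 1")
        for name in ("e_max", "ec_max", "u_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_quantization(
    n: int,
    e_max: float,
    ec_max: float,
    u_max: float,
    kec_override: float | None = None,
) -> QuantizationSpec:
    """Quantization factors K_e = n/e_max, K_ec = n/ec_max, K_u = u_max/n.

    ``kec_override`` replaces the computed K_ec (some published tunings quote
    a rounded-down value).
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be an integer >= 1")
    if e_max <= 0 or ec_max <= 0 or u_max <= 0:
        raise ValueError("universe half-widths must be positive")
    k_ec = n / ec_max if kec_override is None else float(kec_override)
    return QuantizationSpec(
        n=int(n),
        e_max=e_max,
        ec_max=ec_max,
        u_max=u_max,
        K_e=n / e_max,
        K_ec=k_ec,
        K_u=u_max / n,
    )


def quantize(value: float, factor: float, n: int) -> int:
    """Map a physical value onto the integer universe: round(value*factor),
    half away from zero, clipped to [-n, n]."""
    if not math.isfinite(value):
        raise ValueError("cannot quantize a non-finite value")
    if factor <= 0:
        raise ValueError("quantization factor must be positive")
    q = round_half_away(value * factor)
    return max(-n, min(n, q))


def _default_table(n_terms: int = _N_TERMS) -> np.ndarray:
    """Macvicar-Whelan-style PD table: output term index = sat(i + j) with
    term indices i, j in [-3, 3], so a saturated error alone already demands
    the full output.  Positive error (DO below setpoint) yields positive
    output (more air)."""
    half = n_terms // 2
    table = np.empty((n_terms, n_terms), dtype=int)
    for a in range(n_terms):
        for b in range(n_terms):
            i, j = a - half, b - half
            table[a, b] = max(-half, min(half, i + j)) + half
    return table


@dataclass(frozen=True)
class RuleBase:
    """Triangular 7-term partition of [-n, n] plus the 7x7 rule table.

    ``centers`` are the input/membership peaks, evenly spaced so the
    triangles form a partition of unity; ``output_centers`` are the singleton
    positions used in defuzzification (equal to ``centers`` by default, and
    the quantity adjusted by :func:`tune_fnn`).  ``table[a, b]`` is the index
    into :data:`TERMS` of the output term for error term ``a`` and
    error-change term ``b``.
    """

    n: int = 6
    centers: tuple[float, ...] = ()
    output_centers: tuple[float, ...] = ()
    table: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        if not self.centers:
            object.__setattr__(
                self, "centers", tuple(np.linspace(-self.n, self.n, _N_TERMS))
            )
        if not self.output_centers:
            object.__setattr__(self, "output_centers", tuple(self.centers))
        if not self.table:
            object.__setattr__(
                self, "table", tuple(tuple(row) for row in _default_table())
            )
        if len(self.centers) != _N_TERMS or len(self.output_centers) != _N_TERMS:
            raise ValueError(f"need exactly {_N_TERMS} term centers")
        if list(self.centers) != sorted(self.centers):
            raise ValueError("term centers must be nondecreasing")
        tab = np.asarray(self.table)
        if tab.shape != (_N_TERMS, _N_TERMS):
            raise ValueError("rule table must be 7x7")
        if tab.min() < 0 or tab.max() >= _N_TERMS:
            raise ValueError("rule table entries must index the 7 terms")

    @property
    def table_array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=int)

    def table_labels(self) -> list[list[str]]:
        return [[TERMS[k] for k in row] for row in self.table]

    @classmethod
    def from_labels(cls, rows: Sequence[Sequence[str]], n: int = 6) -> "RuleBase":
        idx = {t: k for k, t in enumerate(TERMS)}
        table = tuple(tuple(idx[lbl] for lbl in row) for row in rows)
        return cls(n=n, table=table)


def fuzzify(value: float, rulebase: RuleBase) -> np.ndarray:
    """Membership vector over the 7 terms for a (possibly real) universe value.

    Triangular partition of unity: at most two adjacent terms are active and
    memberships sum to 1.  Out-of-range inputs are clipped and logged.
    """
    centers = np.asarray(rulebase.centers)
    if not math.isfinite(value):
        raise ValueError("cannot fuzzify a non-finite value")
    if value < centers[0] or value > centers[-1]:
        logger.debug("fuzzify input %.3f outside [%g, %g]; clipped", value, centers[0], centers[-1])
        value = float(np.clip(value, centers[0], centers[-1]))
    mu = np.zeros(_N_TERMS)
    k = int(np.searchsorted(centers, value, side="right")) - 1
    k = max(0, min(_N_TERMS - 2, k))
    span = centers[k + 1] - centers[k]
    frac = (value - centers[k]) / span
    mu[k] = 1.0 - frac
    mu[k + 1] = frac
    return mu


def infer(
    e_memberships: np.ndarray, ec_memberships: np.ndarray, rulebase: RuleBase
) -> np.ndarray:
    """Mamdani product inference: output-term weights from the rule table.

    Each rule (a, b) fires with strength mu_e[a] * mu_ec[b] and votes for
    output term table[a, b]; weights over output terms sum to 1 whenever the
    input memberships each sum to 1.
    """
    mu_e = np.asarray(e_memberships, dtype=float)
    mu_ec = np.asarray(ec_memberships, dtype=float)
    for mu in (mu_e, mu_ec):
        if mu.shape != (_N_TERMS,) or mu.min() < 0:
            raise ValueError("memberships must be a nonnegative 7-vector")
    strengths = np.outer(mu_e, mu_ec)
    weights = np.zeros(_N_TERMS)
    np.add.at(weights, rulebase.table_array, strengths)
    return weights


def defuzzify(term_weights: np.ndarray, rulebase: RuleBase, K_u: float) -> float:
    """Centroid of output-term singletons, scaled by K_u."""
    w = np.asarray(term_weights, dtype=float)
    total = w.sum()
    if total <= 0:
        logger.warning("degenerate all-zero rule weights; output forced to 0")
        return 0.0
    centers = np.asarray(rulebase.output_centers)
    return float(K_u * np.dot(w, centers) / total)


@dataclass(frozen=True)
class LoopSignals:
    """Signals of one control step: setpoint, measurement, error, error
    change, their quantized values and the normalized output."""

    y_ref: float
    y: float
    e: float
    ec: float
    E: int
    Ec: int
    u: float


def control_step(
    y_ref: float,
    y: float,
    previous: LoopSignals | None,
    spec: QuantizationSpec,
    rulebase: RuleBase,
) -> tuple[float, LoopSignals]:
    """One pass of the quantized fuzzy pipeline.

    Computes e and its per-step change, quantizes both, fuzzifies, runs the
    rule table and defuzzifies.  On the first call (no previous signals) the
    error change is zero.
    """
    e = y_ref - y
    ec = 0.0 if previous is None else e - previous.e
    E = quantize(e, spec.K_e, spec.n)
    Ec = quantize(ec, spec.K_ec, spec.n)
    weights = infer(fuzzify(E, rulebase), fuzzify(Ec, rulebase), rulebase)
    u = defuzzify(weights, rulebase, spec.K_u)
    u = float(np.clip(u, -spec.u_max, spec.u_max))
    return u, LoopSignals(y_ref=y_ref, y=y, e=e, ec=ec, E=E, Ec=Ec, u=u)


@dataclass
class ActuatorMap:
    """Affine map from normalized command u in [-1, 1] to air flow in m^3/h.

    ``airflow = clip(bias + trim + span * u, 0, mu_max)``.  When
    ``trim_gain > 0`` the bias carries a slow integral trim
    ``trim += trim_gain * e * dt`` (anti-windup clamped) that removes the
    steady-state offset left by the quantization deadband.
    """

    bias: float = 50.0
    span: float = 20.0
    mu_max: float = 100.0
    trim_gain: float = 20.0
    trim_limit: float = 50.0
    trim: float = 0.0

    def reset(self) -> None:
        self.trim = 0.0

    def __call__(self, u: float, e: float, dt: float) -> float:
        if self.trim_gain > 0:
            self.trim += self.trim_gain * e * dt
            self.trim = float(np.clip(self.trim, -self.trim_limit, self.trim_limit))
        return float(np.clip(self.bias + self.trim + self.span * u, 0.0, self.mu_max))


@dataclass
class FuzzyController:
    """Closed-loop policy wrapping the quantized fuzzy pipeline.

    Callable as ``controller(setpoint, measured_DO, t)`` returning an air
    flow in m^3/h, as expected by :func:`aersim.process_model.simulate`.
    ``dt`` is the control interval in hours (used only by the integral trim).
    """

    spec: QuantizationSpec
    rulebase: RuleBase = field(default_factory=RuleBase)
    actuator: ActuatorMap = field(default_factory=ActuatorMap)
    dt: float = 0.02
    _last: LoopSignals | None = field(default=None, repr=False)

    @classmethod
    def default(cls, mu_max: float = 100.0, **kwargs) -> "FuzzyController":
        spec = compute_quantization(n=6, e_max=2.0, ec_max=1.5, u_max=1.0)
        act = ActuatorMap(bias=mu_max / 2, mu_max=mu_max)
        return cls(spec=spec, actuator=act, **kwargs)

    def reset(self) -> None:
        self._last = None
        self.actuator.reset()

    def __call__(self, y_ref: float, y: float, t: float) -> float:
        u, signals = control_step(y_ref, y, self._last, self.spec, self.rulebase)
        self._last = signals
        return self.actuator(u, signals.e, self.dt)


def _episode_cost(
    rulebase: RuleBase,
    scenario: "TuningScenario",
) -> float:
    """Integral squared tracking error of a fixed closed-loop episode."""
    from . import process_model

    ctrl = FuzzyController(
        spec=scenario.spec,
        rulebase=rulebase,
        actuator=replace(scenario.actuator),
        dt=scenario.control_interval,
    )
    ctrl.reset()
    traj = process_model.simulate(
        scenario.initial,
        scenario.params,
        ctrl,
        scenario.setpoint,
        scenario.horizon,
        dt=scenario.dt,
        control_interval=scenario.control_interval,
    )
    err = scenario.setpoint - traj.O
    return float(np.trapezoid(err**2, traj.t))


@dataclass(frozen=True)
class TuningScenario:
    """Fixed closed-loop episode used as the adaptation cost."""

    initial: "object"
    params: "object"
    setpoint: float = 2.0
    horizon: float = 4.0
    dt: float = 0.02
    control_interval: float = 0.02
    spec: QuantizationSpec = field(
        default_factory=lambda: compute_quantization(6, 2.0, 1.5, 1.0)
    )
    # tuning episodes score the raw fuzzy policy: no integral trim to mask a
    # biased zero-term center
    actuator: ActuatorMap = field(default_factory=lambda: ActuatorMap(trim_gain=0.0))


def tune_fnn(
    rulebase: RuleBase,
    scenario: TuningScenario,
    episodes: int = 3,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> tuple[RuleBase, dict]:
    """Adaptive refinement of the output-term centers.

    Seeded coordinate search: every episode visits the output centers in a
    shuffled order, tries +-learning_rate perturbations (keeping centers
    inside [-n, n] and nondecreasing) and accepts a move only if the episode
    cost improves.  The returned rule base therefore never scores worse than
    the input on the training episode.  Returns ``(tuned_rulebase, report)``
    with the cost history in the report.
    """
    if episodes < 1:
        raise ValueError("episodes must be >= 1")
    if learning_rate < 0:
        raise ValueError("learning_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    best = rulebase
    best_cost = _episode_cost(best, scenario)
    history = [best_cost]

    if learning_rate == 0:
        return best, {"cost_history": history, "improved": False}

    n = rulebase.n
    for _ in range(episodes):
        order = rng.permutation(_N_TERMS)
        for idx in order:
            centers = list(best.output_centers)
            for step in (learning_rate, -learning_rate):
                trial = centers.copy()
                trial[idx] = float(np.clip(trial[idx] + step, -n, n))
                if trial != sorted(trial):
                    continue
                candidate = replace(best, output_centers=tuple(trial))
                cost = _episode_cost(candidate, scenario)
                if cost < best_cost:
                    best, best_cost = candidate, cost
                    break
        history.append(best_cost)

    improved = best_cost < history[0]
    if not improved:
        logger.info("adaptive tuning found no improvement; rule base unchanged")
        return rulebase, {"cost_history": history, "improved": False}
    return best, {"cost_history": history, "improved": True}
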