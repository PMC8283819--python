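# Methods

## Plant model

The aeration tank is modeled as completely mixed with three states:
dissolved oxygen `O`, substrate measured as COD `S`, and biomass measured as
MLVSS `X` (all mg/L). Substrate and biomass follow Lawrence–McCarty
kinetics: Monod uptake `K·S·X/(K_s+S)`, growth with yield `η`, first-order
decay `K_d`. The oxygen balance charges 0.57 g O₂ per g of substrate COD
removed at steady loading (written against the influent–tank deficit
`S_o − S`) and 1.1 g O₂ per g of biomass per unit endogenous-respiration
rate `K_e`, classical activated-sludge coefficients. Aeration enters as a
transfer term `k_air·μ·(O_sat − O)`: air flow cannot push DO beyond
saturation, and the tank volume and oxygen-transfer efficiency are absorbed
into the single gain `k_air`. The effluent substrate is identified with the
tank substrate (completely-mixed assumption), which removes any separate
effluent symbol from the model.

Assumptions: constant temperature (saturation fixed at 9.08 mg/L, 20 °C),
no pH dependence, single lumped substrate, no spatial gradients.

### Default parameters

| parameter | value | unit | rationale |
|---|---|---|---|
| η | 0.6 | – | typical heterotrophic yield |
| K | 5 d⁻¹ → 0.2083 h⁻¹ | 1/h | max specific utilization, mid literature range |
| K_s | 60 | mg/L | half-saturation for mixed industrial COD |
| K_d | 0.06 d⁻¹ → 0.0025 h⁻¹ | 1/h | decay |
| K_e | 0.005 | 1/h | endogenous respiration |
| λ | 0.125 | 1/h | 8 h hydraulic fill time |
| S_o | 400 | mg/L | influent COD, matches the bench influent scale |
| O_sat | 9.08 | mg/L | 20 °C |
| μ_max | 100 | m³/h | actuator ceiling |
| k_air | sized | 1/m³ | see below |

Rates quoted per day are converted to hours on construction. `k_air` is
sized so that the design air flow (50 m³/h) holds the design DO (2.0 mg/L)
at the biological steady state — i.e. the nominal operating point is an
exact equilibrium of the loop; with the defaults this gives
`k_air ≈ 0.2661`. At that steady state `S* = K_d·K_s/(η·K − K_d) ≈ 1.22`
mg/L and `X* ≈ 11 960` mg/L, and the oxygen demand is ≈ 94 mg/(L·h), inside
the usual range for high-biomass systems.

### Integration

Fixed-step classical RK4 at `dt = 0.01` h. The controller output is
sampled every 0.02 h (72 s) and held (zero-order hold). The sized `k_air`
makes the DO balance fast — its open-loop time constant at nominal air flow
is `1/(k_air·μ) ≈ 4.5` min — so the control interval must stay well below
it; with a 3-minute hold the loop limit-cycled between 0 and 4 mg/L at full
actuator span, which fixed the 72 s default. Negative excursions (possible
for O at very low DO under a large step) are clipped to zero and counted;
any state magnitude above 10⁶ mg/L aborts with a diagnostic. Halving `dt`
moves a smooth 4 h trajectory by less than 10⁻⁴ mg/L (order check in the
tests).

## Fuzzy controller

Input scaling follows the quantization-factor scheme: `K_e = n/e_max = 3`,
`K_ec = n/ec_max = 4`, `K_u = u_max/n = 1/6` for `n = 6`, `e ∈ [−2, 2]`
mg/L, `ec ∈ [−1.5, 1.5]` mg/L per control step, `u ∈ [−1, 1]`. Scaled
inputs are rounded to integers (ties away from zero) and clipped to
`[−6, 6]`. `ec` is the per-control-step difference of `e`. A legacy
override `kec_override: 3` is available where the rounded-down
error-change factor is wanted.

Seven triangular terms with peaks at `−6, −4, …, 6` form a partition of
unity, so at most two terms are active and memberships sum to one. The
default rule table is the Macvicar-Whelan-style PD pattern
`output term index = sat(i + j)` over signed term indices `i, j ∈ [−3, 3]`:
antisymmetric, monotone, and saturating so that a full-scale error alone
already demands the full output. Inference is Mamdani with product t-norm;
defuzzification is the centroid of output-term singletons scaled by `K_u`.
The whole pipeline is verified in the tests against a literal 49-rule
double loop.

The actuator map is affine around a bias: `airflow = bias + trim + span·u`,
clipped to `[0, μ_max]`, defaults bias 50 m³/h and span 20 m³/h. Because
integer quantization leaves a deadband of `1/(2K_e) ≈ 0.17` mg/L in error,
a pure position-form fuzzy PD parks anywhere inside that band and cannot
track load changes exactly; the bias therefore carries a slow integral trim
(`trim += 20·e·dt`, clamped at ±50 m³/h) — the standard fuzzy-PD-plus-
integral arrangement. Setting `trim_gain: 0` recovers the pure PD form.

### Adaptive layer

The adaptive ("fuzzy-neural") layer is implemented as a seeded,
derivative-free coordinate refinement of the seven output-term centers: per
episode the centers are visited in a shuffled order, ±learning-rate
perturbations are scored by the integral squared tracking error of a fixed
closed-loop episode (2–4 h step scenario, trim disabled so a biased
zero-term is visible to the cost), and a move is accepted only if the cost
improves. The result never scores worse than its input on the training
episode. This is documented as an interpretation of adaptive fuzzy tuning —
reproducible and testable — not as a particular neural architecture, and in
practice it restores a deliberately biased zero-error center and reshapes
the outer centers toward higher loop gain.

## PID baseline

Discrete PID on the same error and the same actuator (without trim — it has
its own integral): `u = kp·e + ki·∫e dt + kd·de/dt`, integral clamped at
±1, output clipped to `[−1, 1]`. Defaults `kp = 0.35`, `ki = 0.7 h⁻¹`,
`kd = 0.01 h` come from a step-response characterization of the default
plant with conservative IMC-style detuning; on the default scenario they
settle cleanly with ~4 % overshoot. Pushing the gains harder (e.g.
`kp = 0.5, ki = 1.0`) still settles later than the fuzzy loop at the cost
of 16 % overshoot, so the comparison outcome is not an artifact of a
deliberately weak baseline.

## Benchmark scenario and metrics

Default experiment: plant at its biological steady state, DO forced to
0.5 mg/L, setpoint step to 2.0 mg/L at `t = 0`, horizon 24 h, influent COD
stepped +25 % at `t = 12` h. Metrics: 10→90 % rise time, overshoot as % of
step size, settling time into a ±2 % (of step) band held to the end,
steady-state error as the mean absolute error over the final 10 % of the
horizon, and IAE. With the disturbance in the scenario the settling time is
dominated by the disturbance recovery, which is the point of the
comparison. All simulations are deterministic: identical configs produce
bit-identical CSVs.

## Dispatch layer

The equipment-coordination layer is a single-process discrete-event
simulation: a plan (device class, quantity, start time per line) becomes a
task list with deterministic ids; tasks are staffed FIFO by start time
(ties by plan order, devices in id order); the influent flow is split over
assigned devices proportionally to capability; completion and failure
feedback arrives on a time-ordered event queue, with one retry before a
task is declared unassignable. Task conservation
(assigned + unassignable = all) and exact flow conservation are invariants
under randomized scenarios. Message schema, FIFO policy, proportional split
and single-retry are this package's choices; the upstream description is a
block diagram.

## Fraction analysis and synthetic experiments

Removal rate is `100·(c_in − c_out)/c_in`; rankings sort fractions by rate
(ties alphabetical); qualitative grades use configurable thresholds
(`++ ≥ 60 %`, `+ ∈ [20, 60) %`, `− < 20 %`). Additivity of adsorption and
biodegradation is scored against the independent-serial null
`1 − (1−r_bio)(1−r_ads)`; the sign of the score says super- or
sub-additive. The packaged tables transcribe published bench measurements
(per-fraction removal percentages and the COD bioaugmentation table); the
time-averaged removal column of the COD table is not recomputable from its
concentration snapshot columns, which is documented in the fixture header
rather than reconciled.

The synthetic generator draws effluent per fraction as
`c_in·(1−r)·(1+ε)`, `ε ~ N(0, sd)` truncated at zero, with the bench
removal probabilities as defaults (biodegradation strong on hydrophilic and
transphilic-neutral fractions, adsorption strong on hydrophobic ones,
relative noise sd 0.02) and the serial model for the combined system. It
emulates the structure of the bench data, not its chemistry: no isotherm
saturation, no inter-fraction competition, no temporal dynamics — so
recovery tests demonstrate the correctness of the analysis arithmetic, not
the behavior of real adsorbent–biomass systems.

## Problem sizes

Default closed-loop runs use a 24 h horizon at `dt = 0.01` h (2 401
points); tuning episodes use 2–4 h at `dt = 0.02`; synthetic-recovery
checks use 50 replicates; dispatch invariants use 100 randomized scenarios.

## Known limitations

- The oxygen-demand coefficients (0.57, 1.1) and all kinetic defaults are
  literature-typical, not fitted to a specific plant.
- The quantized controller's resolution is fixed by `n = 6`; without the
  integral trim the steady-state offset can reach `1/(2K_e)` mg/L.
- The adaptive layer optimizes one episode; it does not generalize across
  scenarios and is not a learned network.
- The dispatch layer models information flow, not hydraulic routing.
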