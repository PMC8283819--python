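# aersim

Simulation sandbox for intelligent control of an activated-sludge aeration
tank treating toxic and refractory organic wastewater, together with the
removal-rate analysis used to evaluate powdered-activated-carbon (PAC)
bioaugmentation of such systems.

It is aimed at environmental-process and control engineers who want a small,
fully reproducible testbed: a nonlinear three-state plant model, a quantized
fuzzy dissolved-oxygen (DO) controller with an adaptive tuning layer, a PID
baseline, a multi-agent task-dispatch simulation for the equipment layer,
and the fraction-level arithmetic (removal rates, rankings, additivity of
adsorption and biodegradation) used in PAC/activated-sludge bench studies.

## The model

The completely mixed aeration tank is described by dissolved oxygen `O`,
substrate (COD) `S` and biomass (MLVSS) `X`, all in mg/L, following a
Lawrence–McCarty substrate/biomass balance coupled to an oxygen balance:

```
dO/dt = k_air·μ·(O_sat − O) − 0.57·λ·(S_o − S) − 1.1·K_e·X
dS/dt = λ·(S_o − S) − K·S·X/(K_s + S)
dX/dt = η·K·S·X/(K_s + S) − K_d·X
```

with `μ` the air flow (m³/h), `λ` the dilution rate, `S_o` the influent COD,
`η` the yield, `K, K_s` the Monod kinetics, `K_d` decay and `K_e` endogenous
respiration. Whenever a steady state with biomass exists its substrate is
`S* = K_d·K_s/(η·K − K_d)`.

The DO loop is closed by a quantized fuzzy controller: error `e = y_ref − y`
and its per-step change `ec` are mapped onto the discrete universe
`[−n, …, n]` by the quantization factors

```
K_e = n/e_max,   K_ec = n/ec_max,   K_u = u_max/n
```

(`n = 6`, `e ∈ [−2, 2]` mg/L, `ec ∈ [−1.5, 1.5]`, `u ∈ [−1, 1]`, hence
`K_e = 3`, `K_u = 1/6`), inference is Mamdani product over a 7-term
(NB…PB) rule table, and the defuzzified `u` is mapped affinely to an air-flow
command. An adaptive layer refines the output-term centers against a
closed-loop tracking cost. A discrete PID on the same actuator is the
comparison baseline.

## Worked example

```
$ aersim compare --outdir out
```

runs fuzzy and PID loops on the identical default scenario — plant started
at its biological steady state with `O = 0.5` mg/L, a 2.0 mg/L DO setpoint
step at `t = 0`, and a +25 % influent-COD disturbance at `t = 12` h — and
prints, among the metrics:

```
"fuzzy": { "rise_time": 0.0835, "overshoot": 8.77, "settling_time": 13.48,
           "steady_state_error": 0.00106, "iae": 0.310, "settled": true }
"pid":   { "rise_time": 0.0924, "overshoot": 4.28, "settling_time": 14.27,
           "steady_state_error": 0.00153, "iae": 0.417, "settled": true }
fuzzy settles faster than PID: True
```

Read: both loops reach the 2.0 mg/L setpoint in a few minutes; the fuzzy
loop re-enters and holds the ±2 % settling band 0.79 h sooner after the load
disturbance, with a ~35 % smaller integrated absolute error and a final DO
within about 0.001 mg/L of setpoint.

The fraction analysis reproduces the bench orderings from the packaged
measurement tables:

```
$ aersim fractions analyze
AS: TPI-N > HPI > HPO-N > HPO-A > TPI-A
PAC: HPO-A > HPO-N > TPI-N > TPI-A > HPI
PAC-AS: TPI-N > HPO-A > HPO-N > HPI > TPI-A
```

i.e. activated sludge removes hydrophilic and transphilic-neutral organics
best, PAC adsorbs hydrophobic ones, and the combined PAC-AS system is
strong across all fractions.

`aersim simulate` (single loop, CSV trajectory), `aersim dispatch`
(task-dispatch scenario with message trace) and `aersim fractions simulate`
(synthetic noisy fraction experiments) cover the other components; every
command accepts a YAML config overriding the defaults in
`aersim.config.default_config()`.

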