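# neuroctrl

Optimal nonlinear network control of brain-like oscillator dynamics.

Alzheimer's disease slows the EEG: power shifts from the alpha band
(8.0–12.5 Hz) into the theta band (4.0–7.5 Hz). `neuroctrl` models a brain
as N coupled Duffing oscillators on a weighted anatomical connectivity
matrix **W** (symmetric connection densities in [0, 1]) and asks: *through
which single region, and at what energetic cost, can an external stimulus
steer pathological theta-band activity onto a healthy alpha-band
reference?* It is aimed at computational neuroscientists studying
closed-loop brain-stimulation design and network controllability.

## Model

Each region *i* carries an excitatory postsynaptic potential `x_i` (mV):

```
ẋ_i = y_i
ẏ_i = −α x_i − γ x_i³ + β Σ_j W_ji x_j
```

`α` sets the natural frequency (f = √α/2π for γ = 0), `γ ≥ 0` is a
hardening cubic nonlinearity, `β` the coupling strength. Two operating
points define the control task: a *pathological* state (α_p = (2π·6.4)²
s⁻², high-amplitude start, theta band) and a *healthy* state
(α_h = (2π·8.0)² s⁻², low-amplitude start, alpha band).

Writing the tracking error **e** = **z**_p − **z**_h, the error dynamics are
factored in state-dependent-coefficient form **ė** = A(**e**)**e** + B·u
(the cubic factors exactly as x_p³ − x_h³ = (x_p² + x_p·x_h + x_h²)·(x_p −
x_h)), with B selecting one region's y-equation. At each gain update the
state-dependent Riccati equation (SDRE) — the pointwise LQR problem

```
AᵀP + PA − PBR⁻¹BᵀP + Q = 0,   K = R⁻¹BᵀP,   u = −K e
```

— is solved with Q = qI, R = r. A task whose Riccati problem has no
acceptable stabilizing solution at some update instant is *uncontrollable*:
its cost is +∞ and its inverse cost 0. Controllable tasks are scored by the
energy E = ∫u² dt; the mean **inverse cost** across subjects ranks candidate
stimulation regions, and weighted graph measures (strength, eccentricity,
closeness, betweenness, Onnela clustering, communicability; path length,
radius, clustering, global efficiency) are regressed against it.

Integration uses the Local Linearization scheme (exact matrix-exponential
steps on the local Jacobian — exact for γ = 0). Real tractography matrices
are read from delimited text; a synthetic-cohort generator (modular
stochastic-block base network, Beta(2,5) weights, per-subject log-normal
perturbations, MST-based backbone masking) stands in for patient data.

## Worked example

```bash
neuroctrl generate-cohort -k 2 -n 10 --density 0.4 -s 7 -o cohort/
neuroctrl control -m cohort/S01.csv --node 3 --gamma 0 -o task.json
```

prints

```
controllable=True cost=37222.3
```

and `task.json` records the full task outcome (model units):

```json
{
  "input_node": 3,
  "gamma": 0.0,
  "controllable": true,
  "success": false,
  "cost_l2sq": 37222.32083190828,
  "cost_l1": 743.501196419961,
  "inverse_cost": 2.686560046902731e-05,
  "tracking_error": 5.9613313741739,
  "uncontrolled_error": 10.045317616090134,
  ...
}
```

Reading: with the stimulus entering region 3 the pointwise Riccati problems
all solve (`controllable`), the feedback uses energy ∫u²dt ≈ 3.7e4 over the
20 s horizon, and the final-window tracking error is 5.96 healthy-RMS units
— far better than the uncontrolled 10.05, but above the strict 5% `success`
tolerance, because the α_p−α_h mismatch keeps driving every region while
the input enters only one (see `docs/methods.md`). Rankings are built from
`inverse_cost` over a cohort:

```bash
neuroctrl sweep --cohort cohort/ -o costs.csv
neuroctrl rank --costs costs.csv --gamma 0.0 -o ranking.csv
neuroctrl analyze --costs costs.csv --cohort cohort/ --gamma 0.0 -o stats.csv
```

The same operations are available as library calls (`neuroctrl.sweep`,
`neuroctrl.rank_regions`, `neuroctrl.correlate_cost_topology`, ...).

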