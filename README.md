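# decfba

Dynamic enzyme-constrained flux balance analysis with **enzyme change
constraints** (decFBAecc), for simulating batch fermentations — diauxic
growth of *E. coli* on glucose and its own overflow acetate in particular —
and comparing the simulated time courses against measured ones.

## The problem and the method

Flux balance analysis (FBA) computes a steady-state flux distribution `v`
of a genome-scale metabolic model by linear programming:

```
max  v_BOF                      (growth rate μ, h⁻¹)
s.t. S·v = 0                    (mass balance)
     lb ≤ v ≤ ub                (exchange/thermodynamic bounds)
     Σᵢ (MWᵢ/kcatᵢ)·vᵢ ≤ P      (enzyme pool, g gCDW⁻¹)
```

The last row is the aggregate enzyme constraint of sMOMENT/GECKO-style
models: each unit of flux through reaction *i* occupies `aᵢ = MWᵢ/kcatᵢ`
grams of enzyme per gCDW, and the total enzyme mass is capped at `P`
(0.0948 g gCDW⁻¹ in the enzyme-constrained *E. coli* model iJO1366\*).
Dynamic FBA (the static optimization approach) wraps this LP in a time
loop: exchange fluxes update a batch reactor's medium concentrations and
biomass each step.

Plain dynamic FBA lets the cell re-tool its entire proteome between two
time steps. decFBAecc adds the missing inertia. The enzyme composition
implied by a flux solution is `mᵢ = aᵢ·vᵢ`; between steps the newly
*acquired* enzyme mass is limited to `γ·Δt` (γ in g gCDW⁻¹ h⁻¹, the
**ecc**). When the reallocation demand `Σ max(m_o − m_{t−1}, 0)` of the
step's unconstrained optimum `m_o` exceeds the budget, the composition is
interpolated,

```
α = γ·Δt / Σ max(m_o − m_{t−1}, 0),     m_t = α·m_o + (1−α)·m_{t−1},
```

turned into per-reaction flux caps `ubᵢ = m_{t,i}/aᵢ`, and the LP is
re-solved under those caps. Sentinels: `γ = −1` leaves composition free
(plain decFBA), `γ = 0` freezes it. The package also provides the
logarithmic acetate-excretion feedback

```
Ex(c) = −ln(c/c_s) / ln(c_s/V_max),  clamped to [0, V_max]
```

(`V_max = 2` mmol gCDW⁻¹ h⁻¹, `c_s = 13` mM), fitting of candidate
feedback forms to rate–concentration data, RMSD scoring against measured
(biomass, glucose, acetate) series, and a grid sweep to fit γ.

## Worked example

The bundled fixture is an 8-reaction enzyme-constrained model with a
high-yield/high-cost respiration route, a cheap fermentation route that
excretes acetate, and an acetate-consumption route — the minimal network
that shows overflow metabolism under a finite enzyme pool. One litre of
10 mM glucose medium, 0.1 gCDW L⁻¹ inoculum, glucose uptake ≤ 10.5 and
oxygen uptake ≤ 15 mmol gCDW⁻¹ h⁻¹:

```python
import numpy as np
from decfba import build_toy_overflow_model, run_simulation
from decfba.reactor_dynamics import ReactorState
from decfba.scenario_config import toy_scenario

model = build_toy_overflow_model()
for mode in ("dFBA", "decFBA", "decFBAecc"):
    sc = toy_scenario(mode)          # pool/ecc presets: 5000/−, 0.0948/−, 0.0948/0.01
    state = ReactorState(0.0, sc.initial_X, sc.initial_V, dict(sc.medium))
    traj = run_simulation(model, sc, state)
    ...
```

prints

```
dFBA       glucose gone 2.68 h | acetate peak 2.83 mM, gone 3.10 h | final biomass 0.932 gCDW/L
decFBA     glucose gone 2.80 h | acetate peak 3.59 mM, gone 3.36 h | final biomass 0.891 gCDW/L
decFBAecc  glucose gone 2.80 h | acetate peak 3.59 mM, gone 5.50 h | final biomass 0.868 gCDW/L
```

Read top to bottom: without the enzyme pool the culture grows fastest and
overflows least; the pool slows glucose consumption and pushes more carbon
out as acetate; the enzyme change constraint leaves the glucose phase
untouched (the culture starts glucose-adapted) but delays acetate
re-consumption by hours — the diauxic lag — and the maintenance flux burns
part of the acetate while the proteome is rebuilt, costing terminal
biomass.

The same is available from the shell:

```
decfba make-fixture --outdir fixture
decfba run --model fixture/toy_model.json --scenario fixture/toy_scenario.toml --out traj.csv
decfba evaluate --trajectory traj.csv --measurements measured.csv
decfba sweep --model fixture/toy_model.json --scenario fixture/toy_scenario.toml \
             --measurements measured.csv --gamma-grid 0.005,0.01,0.02,0.04 --out sweep.csv
```

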