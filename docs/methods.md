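# Methods

## Model and procedure

The simulator advances a batch reactor by the static optimization
approach: at each step of a uniform grid (default Δt = 0.01 h; the bundled
demo scenario uses 0.02 h) it solves one enzyme-constrained FBA problem
and propagates its exchange fluxes into the medium. The LP is

max v_obj subject to S·v = 0, lb ≤ v ≤ ub, Σ aᵢvᵢ ≤ P,

with enzyme costs aᵢ = MWᵢ/kcatᵢ (g gCDW⁻¹ per mmol gCDW⁻¹ h⁻¹) taken
from the sMOMENT pool pseudo-metabolite row of the model (sign-flipped;
the row is all-negative by convention) and P from the pool
pseudo-reaction's upper bound. Cost-bearing reactions must be
unidirectional (lb ≥ 0) so that the enzyme composition mᵢ = aᵢvᵢ is
well defined; reversible cost-bearing reactions in non-sMOMENT inputs
must be split before loading.

### Enzyme change constraint

The stored composition vector m is compared against the composition m_o of
the step's unconstrained optimum. The reallocation demand is the sum of
positive entries of m_o − m: only newly acquired enzyme mass counts;
released mass is free (no degradation cost — data to parameterize one is
lacking). If the demand exceeds the per-step budget γΔt, the composition
is moved by the convex combination m ← αm_o + (1−α)m with
α = γΔt / demand, per-reaction caps ub_i = m_i/a_i are imposed, and the LP
is re-solved. Two deliberate choices where the procedure admits variants:

- **Denominator of α.** The gate and the denominator both use the
  positive-part sum. A signed sum can push α outside [0, 1] whenever much
  enzyme is being released, which contradicts the interpolation's intent;
  the signed variant remains available (`EccPolicy(signed_denominator=True)`)
  for comparison.
- **Stored state after a constrained step** is the interpolated *capacity*
  vector m_t, not the composition implied by the re-solve's realized
  fluxes. The per-step capacity-vs-usage gap is reported in the step
  diagnostics. Storing capacity keeps the budget bookkeeping exact and
  lets idle capacity persist rather than silently evaporating.

γ sentinels: −1 disables tracking entirely (the decFBA path), 0 freezes
the composition (α = 0). The initial composition is read off the first
step's unconstrained optimum — the culture is assumed pre-adapted to its
starting substrate, so the constraint never binds at t = 0 and
constrained and unconstrained runs coincide until the substrate shift.

### Alternate optima

Enzyme composition is read off the flux vector, and FBA optima are
generally degenerate, so by default every solve is followed by a
parsimonious second LP (minimize Σ|vᵢ| at the optimal μ, split-variable
formulation). This makes the tracked composition well defined and
trajectories solver-stable. It applies to all three modes so that the
sentinel equivalences (γ = −1 ≡ decFBA; pool 5000 ≡ dFBA) hold exactly;
it can be disabled per scenario (`pfba = false`), in which case only μ and
exchange fluxes should be treated as reproducible outputs.

### Reactor propagation

Forward Euler on both biomass and medium: X ← X(1 + μΔt),
c_k ← c_k + v_ex,k·X·Δt, negative concentrations clipped to zero with a
logged warning. Euler on both keeps the bookkeeping mutually consistent;
at the default Δt the discretization error in terminal biomass is below
one percent (halving Δt is asserted in the tests to move it by < 1%).
Per-step uptake caps lb_eff = max(lb, −c/(X·Δt)) prevent overdrawing the
medium within a step. Compounds on the non-limiting list (ions, trace
minerals, dissolved oxygen under DO-coupled stirring) are never
decremented; oxygen is instead rate-limited through its exchange lower
bound (−15 mmol gCDW⁻¹ h⁻¹ in the tuned scenarios). An infeasible step —
typically the maintenance flux after substrate exhaustion — records zero
growth and zero exchange fluxes and carries on; the composition still
moves toward the step's unconstrained optimum, so a stalled culture keeps
re-tooling and growth resumes once capacity suffices.

### Acetate-excretion feedback

Ex(c) = −ln(c/c_s)/ln(c_s/V_max), clamped to [0, V_max], applied each step
as an upper bound on the acetate exchange (combined with any static bound
by taking the minimum). Defaults V_max = 2 mmol gCDW⁻¹ h⁻¹, c_s = 13 mM.
Validity requires c_s > V_max; the clamp handles both super-saturation
(c ≥ c_s → 0, never forced uptake) and the low-concentration region where
the raw form exceeds V_max. Candidate feedback families (linear,
polynomials of degree 2–5, logarithmic) are fitted by least squares; the
logarithmic fit is performed in ln c and re-expressed as (V_max, c_s).

### RMSD and ecc fitting

The fit score is a single pooled, unweighted RMSD over every available
(variable, time) observation, biomass in gCDW L⁻¹ and concentrations in
mM, simulated values linearly interpolated onto the sample times. This
definition is an explicit choice of this package — pooled unnormalized
RMSD mixes units, and published RMSD values for such fits rarely state
their variable set and weighting, so external numbers should be reconciled
against this definition before comparison. γ is fitted by a grid sweep,
one deterministic simulation per candidate.

## The fixture generator

`build_toy_overflow_model` emulates, in four metabolites and eight
reactions, the features of a genome-scale enzyme-constrained model that
the method exercises: two glucose routes where the higher-yield one
(0.10 gCDW/mmol, 2 O₂/glc) costs more enzyme per flux (0.013 vs
0.002 g gCDW⁻¹) than the acetate-excreting fermentation route
(0.03 gCDW/mmol), an acetate-oxidation route (0.02 gCDW/mmol, 2 O₂/ac,
0.008 g gCDW⁻¹), exchanges for glucose/acetate/oxygen, a maintenance
drain, and the default pool of 0.0948 g gCDW⁻¹. Yields and costs were
chosen so that (i) with an ample pool the optimum is pure respiration,
(ii) at the default pool the optimum is mixed with acetate overflow,
(iii) acetate growth is several-fold slower than glucose growth —
the qualitative regime of aerobic E. coli batch culture. Its optimum is
verifiable by exhaustive vertex enumeration of the 3-dimensional route
polytope, which the test suite uses as an independent oracle.

What the toy model does **not** emulate: realistic network size and
degeneracy, ATP/redox stoichiometry (maintenance drains biomass precursor
directly), byproducts other than acetate, and measured kcat/MW
distributions. Tests passing on it validate the machinery — LP assembly,
composition bookkeeping, budget enforcement, reactor mass balance,
parameter recovery — not the biological accuracy of any genome-scale
model; quantitative claims about E. coli require the external
enzyme-constrained iJO1366* input described in the README.

The demo scenario (`toy_scenario`) fixes the study conditions: 1 L,
0.1 gCDW L⁻¹ inoculum, 10 mM glucose, glucose uptake ≤ 10.5 and O₂ uptake
≤ 15 mmol gCDW⁻¹ h⁻¹, maintenance flux 0.02 h⁻¹ (biomass-precursor
units), 8 h horizon. The acceptance script runs it at Δt = 0.02 h
(400 steps) and the ecc-recovery sweep at Δt = 0.05 h over 7 h with
half-hourly synthetic observations and σ = 0.05 observation noise.

## Numerical choices

- LP backend: HiGHS (scipy.optimize.linprog), primal and dual feasibility
  tolerances 1e−9. The loose default of 1e−6 produces artifacts when flux
  caps are derived from interpolated compositions (tiny negative
  capacities / spurious infeasibility).
- The parsimonious solve holds μ at its optimum with a 1e−9 relative
  relaxation to absorb round-off; μ and exchange fluxes are reproducible
  to ~1e−8.
- Composition read-off truncates fluxes more negative than −1e−6 on
  cost-bearing reactions as errors, smaller ones as solver noise.
- Composition-derived upper caps can undercut a configured lower bound
  (e.g. a forced maintenance flux); the solver treats that step as
  infeasible rather than crashing, and the freeze policy above applies.
- Ties in the ecc sweep resolve to the first grid point at the minimum.

## Known limitations

- One global γ: per-reaction ecc rates (different enzymes are expressed
  at different speeds) are not supported.
- The ecc budget ignores degradation: releasing enzyme mass is free.
- Forward Euler without substeps; stiff scenarios need a smaller Δt
  rather than adaptive stepping.
- The feedback bound is a single-compound, memoryless cap; no
  thermodynamic mechanism.
- DOA-style whole-horizon optimization, FVA and MILP variants are out of
  scope.
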