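# Methods

## Model class and the forward map

A net is a bipartite multigraph over compartments `S = {x_1,…,x_k}` and
transitions `T = {z_1,…,z_l}` with arc multiplicities `m_ij` (compartment →
transition) and `n_ij` (transition → compartment), a positive rate constant
`r_j` per transition, and optional arc weights.  The induced rate equation
of `x_i` is `Σ_j w_ij r_j (n_ij − m_ij) Π_s x_s^{m_sj}`, stored expanded and
collected so that symbolic equality tests are reproducible.  The effective
weight `w_ij` of a (compartment, transition) pair is the product of the
weights of every arc between them, in either direction; in practice exactly
one arc of a pair carries a non-unit weight (a branching probability), and
this convention puts it in the right place for bifurcations like the
exposed → asymptomatic/infectious split.

Rates must be expressions in declared parameters only.  Standard-incidence
denominators (a mixing total `A = S+I+R`, a population size `N`) are
declared as parameter-like symbols and resolved only when evaluating at an
equilibrium, via explicit DFE substitutions (below).  `validate()` flags a
rate that references a compartment variable instead.

Symbols: parameters are positive reals; compartment variables are
nonnegative (equilibria sit on the boundary of the orthant).  Parameters of
kind `probability` live in (0, 1); sign queries substitute `p → 1/(1+u)`
with `u > 0`, which is exact and keeps sympy's assumption engine decidable
on every expression this package produces.  Parameter orderings needed by a
model (the malaria model assumes disease-induced mortality exceeds infected
immigration) are declared as constraints, e.g. `alpha = delta +
alpha_excess` with a fresh positive excess symbol, and applied only during
sign analysis.

## Inverse map (ODE → net)

Each equation's right-hand side is expanded into monomials `f·α·x^m` with
`f` a signed integer and `α` the remaining parameter function (possibly a
sum, possibly carrying a rational factor; the split takes the signed
integer content via `factor_terms`).  Distinct exponent tuples are ranked
in ascending plain lexicographic order; the term at (equation *i*, column
*j*) becomes transition `z_{i,j}` with rate `α`, inputs `m_s` arcs from
every variable in the monomial, `n_i = f + m_i ≥ 0` output arcs to its own
variable, and catalytic round trips (`m_s` arcs out and back) for every
other variable — so foreign variables enter the monomial without being
consumed.  Constant monomials are admitted as source transitions (`m = 0`,
`n = f`), which every demographic model needs.  A negative `n_i` is a
factorization error reported with the offending term; non-polynomial input
is rejected.

`simplify()` merges transitions that share a rate expression and an input
vector into one transition whose outputs are the inputs plus the summed net
stoichiometry (provably nonnegative for inverse-built nets), and deletes
transitions whose net effect is zero everywhere.  The pass is idempotent,
preserves the rate equations symbolically, and reduces the inverse-built
classic models back to their hand-drawn nets.  Weighted transitions are
left untouched — merging across weights would change monomial structure.

## KM modules and the geometric checks

The partition (susceptible / infection-process / infection compartments and
transitions) is **declared by the modeler**, not inferred: it encodes which
transitions create new infections versus move existing ones, which is
modeling intent.  A heuristic suggester lists candidate contact transitions
(multi-input transitions) but is advisory only.  The declared order of the
infection compartments fixes the row/column order of all matrices.

The structural checks, on the multiplicity matrices:

* **G1** — no arcs between susceptible-module transitions and disease
  compartments, and no inputs to infection-module transitions from outside
  the disease compartments.
* **G2** — a contact transition with no disease input must have no disease
  output (no infected immigration).
* **G3** — contacts return the infectious individual (`n ≥ m` at every
  disease compartment of every infection-process transition); and inside
  the infection module, a transition consuming from one disease compartment
  may not also consume from another without returning it (`n ≥ m` at `x_i`
  whenever the transition has an input from some other disease
  compartment).  The exemption of a transition's own source compartment is
  deliberate: progression *out* of a compartment is the diagonal of V, not a
  disappearance, and without the exemption every recovery transition in
  every textbook model would fail.
* **G4** — positive outflow: for every infection-module transition,
  `Σ_i w_ij (m_ij − n_ij) ≥ 0` over disease compartments, with the weights
  included so that a probability-weighted bifurcation (outputs `p` and
  `1−p` against one input) balances; the inequality is decided symbolically
  under the positivity registry.
* **G5** — the disease-free system `y' = g(0, y)` has a locally
  asymptotically stable equilibrium, checked numerically: 8 parameter
  samples (log-uniform over [10⁻², 10¹] for rates, uniform (0.05, 0.95) for
  probabilities, fixed seed 20250916), Jacobian eigenvalues required below
  −10⁻⁹.  General symbolic stability is undecidable in practice; sampling
  with a witness list is honest and reproducible.

Every checker is a pure function of (m, n, partition) and reports witnesses
(offending compartment/transition pairs) on failure.

The waterborne (SIWR) model genuinely fails G4: with the pathogen reservoir
W counted as a disease compartment, shedding (I → shed → I + W) creates
disease mass without consuming any, and correspondingly the total-outflow
sign condition holds only for parameter ranges with recovery outpacing
shedding.  The fixture records this as `g4_conditional`; tests assert the
checker reports it rather than forcing a pass.

## DFE conventions

Three modes. `keep-symbolic` leaves non-disease compartments as their own
symbols — the convention under which R0 formulas read `βS/α`.
`symbolic-solve` solves `g(0,y) = 0` and requires a unique closed-form
solution (models without demography have a continuum of equilibria; the
solver refuses and asks for a user-supplied point rather than guessing).
`user-supplied` validates the given assignment symbolically.  A DFE may
carry declared-symbol substitutions applied after the assignment: the
second vaccination model substitutes `N → Λ/μ` (the equilibrium population
size), and the quarantine model substitutes `A → 1`, i.e. measures the
susceptible population in units of the DFE mixing total — exactly the
normalization under which its literature F-matrix reads `βS`.

## The three R0 routes

**NGM.**  `𝓕_i` sums the infection-process transitions, `𝓥_i` the
infection-module ones; the implementation verifies the exact splitting
`x_i' = 𝓕_i − 𝓥_i` against the rate equations and raises a
partition-inconsistency error naming the stray term otherwise.  F and V are
the Jacobians over the disease compartments at the DFE.  Structural flags:
F entrywise nonnegative, V with the Z sign pattern, V **column** sums
nonnegative (this, not row sums, is what the positive-outflow condition
G4 delivers: `Σ_i ∂𝓥_i/∂x_j ≥ 0`; a Z-matrix with nonnegative column sums
is an M-matrix by the transpose argument), and V nonsingular (symbolic
determinant).  `r0`: rank-one K returns the trace; otherwise the
eigenvalues are computed symbolically and the dominant root selected under
the positivity assumptions, with a 3-sample numeric tie-break at tolerance
10⁻¹⁰ preferring the positive real (Perron) branch — which resolves the
±√ pair of vector–host transmission.

**Matrix of flows.**  An infection path runs from the introduction
compartment through infection-module transitions and ends with exactly one
infection-process transition depositing the new infection in the
destination; interior compartments are distinct, the destination is
unrestricted (a newly created individual may land anywhere, including a
compartment already traversed — the diagonal loop entries and the
direct-transmission variants need this).  The contact transition is always
last because `K = FV⁻¹` factors as "time spent in j after introduction in
k" times "new infections in i per time in j".  Per path,
`E(γ)` multiplies the traversed progression weights·rates and divides by
each visited compartment's total exit rate, where the exit set `Z_x`
contains the transitions drawn by exactly one arc from `x` with no return
arc — this automatically excludes catalytic contact transitions, whose
return arc cancels their consumption, so they cost no waiting time.
`S(γ)` is the contact transition's new-infection coefficient into the
destination at the DFE (its contribution to the F entry).  Applicability
requires every traversed compartment to have well-formed exponential exit
clocks: single-arc, no-return exits and no susceptible inflow into them.
Nets violating this (the SIWR shedding transition) make the method refuse
with the offending structure named, rather than approximate.

**Fertility loops.**  On `A = F + (I − V)` an edge `j → i` exists per
nonzero entry, tagged fertility (from F) or survival (from I − V), with
parallel edges when both contribute.  Simple vertex cycles come from the
elementary-circuits algorithm (networkx), canonicalized by rotation to the
smallest vertex; each cycle expands over the per-step tag choices, and
loops with at least one fertility edge contribute `L · det(V_∖L̆)/det(V)`.
The formula applies exactly when FV⁻¹ has a single non-zero eigenvalue
(checked via symbolic eigenvalues); outside that class it raises a
dedicated error.  For rank-one K the sum equals the trace.

## Threshold experiment

`threshold_check` integrates the full rate equations (scipy `solve_ivp`,
LSODA, rtol 10⁻⁸) from the DFE with each disease coordinate nudged by 10⁻³
of the DFE scale, over a horizon of 10 divided by the slowest |Re λ| of
F − V.  Verdict *stable* if the final disease norm falls below 10⁻² of the
initial one, *unstable* if it grows; the verdict is cross-checked against
the numeric spectral radius of FV⁻¹ and the eigenvalue criterion on F − V.
The packaged experiment uses an SEIR parameterization (Λ=1, μ=0.1, η=0.5,
α=0.4, S₀=10) and a vaccination parameterization (Λ=1, μ=0.1, ψ=0.2,
γ=0.3, δ=0.4, χ=0.5, N=10) with β solved from the respective closed-form
R0 for targets 0.5 and 2.0 — comfortably inside and outside the threshold,
so the verdict does not hinge on integration tolerances.

## Random-system generator

`random_ode(k, max_degree, n_terms, seed)` draws, per term, an equation
index, an exponent tuple of total degree ≤ `max_degree` (degree uniform,
then balls-into-bins over variables), an integer factor from ±{1,2,3}
constrained to `f + m_i ≥ 0` so the term is representable with nonnegative
arc counts, and a fresh positive parameter.  Defaults (k ≤ 4, degree ≤ 3,
3–8 terms) cover constant sources, decays, catalytic and higher-order
interactions — the monomial shapes that occur in compartmental models —
while staying far from sympy's expression-swell regime.  What it does not
emulate: coefficients that fail the integer/parameter split (e.g.
irrational numeric factors), non-polynomial incidence, or structural
correlations between equations (conservation laws arise only by chance), so
round-trip tests certify the inverse construction's algebra, not its
behavior on non-mass-action models.

## Numerical and symbolic conventions

Symbolic equality is subtract-and-simplify: expand, cancel over a common
denominator, then `powsimp(force=True)` + `simplify` (the forced power
collection is what lets the square-root R0 forms match).  Matrix entries
are normalized to collected-over-common-denominator rational form.  Sign
queries try the assumption engine on the transformed expression and its
cancelled/factored/simplified variants and return indeterminate (`None`)
rather than guessing.  Degenerate inputs: empty nets yield empty matrices;
a transition with zero net stoichiometry contributes nothing and is removed
by `simplify`; an empty exit set along an infection path is an ill-posed
expected time and raises.

## Known limitations

* Token-level (discrete-marking) execution semantics, colored/continuous/
  nested net variants are out of scope; the net is a symbolic carrier for
  the mass-action ODEs.
* Standard-incidence denominators are handled by the declared-symbol
  convention, not by true rational-function rates; the inverse map
  requires polynomial right-hand sides (coefficients may be rational in
  declared parameters, as in `β/N`).
* Partitions with compartments inside the infection-process module are
  accepted and treated as non-disease for G1, but no shipped model
  exercises them.
* The fertility-loop route outside the single-non-zero-eigenvalue class,
  global stability, endemic equilibria and final-size relations are not
  implemented.
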