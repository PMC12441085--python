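# epipetri

Symbolic Petri nets for compartmental epidemic models, and the basic
reproduction number computed three independent ways.

## The problem

A compartmental epidemic model is usually written as a polynomial ODE
system.  The same model can be drawn as a **stochastic Petri net**: circles
for compartments (S, E, I, ...), squares for transitions (infection,
progression, recovery, birth, death), arcs with integer multiplicities, and
a positive rate constant per transition.  The net induces its mass-action
**rate equations**

    x_i'(t) = Σ_j  w_ij · r_j · (n_ij − m_ij) · Π_s x_s^{m_sj}

where `m_ij` / `n_ij` count the arcs from compartment *i* into transition
*j* and back, and optional arc weights `w_ij` carry branching probabilities
(such as the *p* / *1−p* split of an exposed compartment).  `epipetri`
implements this map in both directions — every polynomial ODE system is
inverted into a representing net, which a merge/cancel pass reduces back to
the hand-drawn model — and uses the net structure to organize the
next-generation-matrix (NGM) analysis:

* **KM modules.**  The net is partitioned into *susceptible*,
  *infection-process* and *infection* sub-nets.  Four structural conditions
  G1–G4 on the arc counts (checked symbolically, with witnesses on failure)
  imply the classical sign conditions on the new-infection terms 𝓕 and
  net-outflow terms 𝓥; G5 asks the disease-free system for a locally
  asymptotically stable equilibrium.
* **NGM route.**  F = ∂𝓕/∂x and V = ∂𝓥/∂x at the disease-free equilibrium
  (DFE); `R0 = ρ(FV⁻¹)`, with structural flags (F ≥ 0, Z sign pattern and
  nonnegative column sums of V, nonsingularity).
* **Flow route.**  Each entry of FV⁻¹ is reconstructed as a sum over
  *infection paths*: `M_ik = Σ_γ S(γ)·E(γ)`, the susceptible flow through
  the path's unique contact transition times the expected time to cross the
  path.  Symbolic equality `M = FV⁻¹` is verified entrywise.
* **Loop route.**  On the life-cycle graph of `A = F + (I − V)`,
  `R0 = Σ_L L · det(V_∖L̆)/det(V)` over fertility loops, valid when FV⁻¹
  has a single non-zero eigenvalue (a vector–host model with a square-root
  R0 is correctly refused).

Fifteen classic models ship as fixtures with their literature formulas
(SIR, SIS, SIRS, SEIR, SEAIR, SCIR, SIWR, malaria, two vaccination models,
quarantine, two two-route SEIR variants, plus water formation and a
demographic one-compartment model).

## Worked example

```bash
$ epipetri r0 --fixture sir --method ngm
calF = [I*S*beta]
calV = [I*alpha]
F = [[S*beta]]
V = [[alpha]]
K = [[S*beta/alpha]]
R0[ngm] = S*beta/alpha
```

The infection transition contributes `βSI` new infections, recovery removes
`αI`; at the symbolic DFE the next-generation matrix is the scalar `βS/α`,
the expected number of secondary cases one infectious individual causes.
Cross-checking all three routes on the asymptomatic-carrier model:

```bash
$ epipetri r0 --fixture seair --method all | tail -1
methods agree: True
```

and the same from Python, with the two infection paths behind the E–E entry:

```python
>>> from epipetri import fixture, enumerate_paths
>>> fx = fixture("seair")
>>> for p in enumerate_paths(fx.net, fx.partition, dst="E", src="E"):
...     print(p.compartments, p.transitions)
('E', 'I', 'E') ('progress', 'infect')
('E', 'A', 'E') ('progress', 'infect_a')
```

An exposed individual either becomes infectious (probability *p*) and
transmits at rate β, or asymptomatic (1−p) and transmits at rate qβ; the
two path contributions sum to
`R0 = βη(1−p)qS/((η+μ)(γ+μ)) + βηpS/((η+μ)(α+μ))`.  At the reference point
β=0.3, η=0.5, μ=0.1, γ=0.25, α=0.4, p=0.6, q=0.5, S=1 this evaluates to
**0.442857**.

Other entry points: `epipetri rate-eqs`, `epipetri from-ode` (ODE→net
inversion), `epipetri check-km` (G1–G4 with witnesses), `epipetri simulate`
(numeric integration), `epipetri export-dot` (Graphviz, KM modules as
clusters), `epipetri fixtures`.

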