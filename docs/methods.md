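# Methods

## Model structure and assumptions

All three models are deterministic, discrete-generation, mean-field
recursions on the simplex of four cytotype frequencies `(p, q, r, s)`
(resident/novel mitotype × symbiont-infected/uninfected). Shared
assumptions:

* strict maternal co-transmission of symbiont and mitochondria — no
  paternal leakage, no infectious (horizontal) transfer;
* infinite population size: no drift, no stochastic establishment or
  fadeout of rare lineages;
* a single symbiont strain and a single novel mitotype; equal sex ratio,
  with male cytotype frequencies equal to female frequencies (relevant only
  to the CI model, where the incompatible-cross survival factor for
  offspring of an uninfected mother is `(p + r)(1 − h) + q + s`);
* segregational loss at rate `µ`: a fraction `µ` of an infected mother's
  offspring fail to inherit the symbiont but keep her mitotype — the only
  flow between infection classes, and the channel through which a sweeping
  mitotype crosses from the infected into the uninfected pool;
* in the CI model, segregant offspring of infected mothers are *not*
  protected against incompatible crosses: the `pµ` and `rµ` terms carry the
  CI survival factor exactly as the uninfected classes do. CI model
  conventions differ on this point; we follow the recursion structure as
  stated without asserting a biological claim, and note that the
  alternative (protected segregants) would slightly weaken the positive
  frequency dependence at high prevalence.

The frequency-dependent benefit of Model ii, `B_T = b(1 − (p_T + r_T))`, is
evaluated at the **pre-update** frequencies of generation `T`.

## Parameters

| symbol | meaning | range | typical values used |
|--------|---------|-------|---------------------|
| `B` | net fixed benefit to offspring of infected mothers (dimensionless fitness increment) | `> −1` | 0.075–0.5 |
| `b` | maximum benefit of the symbiont when vanishingly rare | `≥ 0` | 0.1 |
| `c` | fixed cost of symbiont carriage | `0 ≤ c < 1` | 0.01–0.05 |
| `h` | CI strength: incompatible-cross offspring survive at `1 − h` | `[0, 1]` | 0.005–0.25 |
| `µ` | segregational loss rate | `[0, 1]` | 0–0.07 |
| `t` | selective benefit of the novel mitotype | `> −1` | 0.02 (strong mtDNA selection) |
| `ε` | introduction frequency of the mutant | default `1e−5` | — |

Since the dynamics are deterministic, `ε` only sets the length of the
initial transient; it must merely be small enough to sit in the linear
regime around the resident equilibrium and large enough to dominate the
extinction cutoffs below.

## Invasion analysis

The rare `(r, s)` subsystem linearised at the resident equilibrium is
triangular (`r` feeds `s` through segregational loss, never the reverse),
so its growth rates are available in closed form: `λ_r = 1 + t` for all
three models (at the resident equilibrium, mean fitness equals the
effective growth rate of the infected lineage, so the only net advantage of
the novel infected class is `t` itself), and
`λ_s = (1 + t)/W̄` (Models i–ii) or `λ_s = (1 + t)(1 − h p*)/Φ*` (Model
iii). Consequences implemented and tested:

* an infected-origin beneficial mitotype always invades (`λ_r > 1`);
* an uninfected-origin mitotype invades iff `λ_s > 1`, giving the analytic
  thresholds `t = B(1−µ) − µ` (Model i) and
  `t = (1−µ)(1 + b(1−p*) − c) − 1` (Model ii invasion), with
  `t = (1+b−c)(1−µ) − 1` the separate Model-ii displacement threshold;
* at `t = 0` the uninfected-origin growth factor is `1/W̄ < 1` whenever the
  symbiont is net-beneficial at equilibrium: neutral mitotypes arising in
  uninfected hosts are deterministically lost, because the uninfected class
  is demographically subsidised by segregants rather than self-replacing.

Outcomes of full nonlinear runs are classified from the terminal state as
`mitotype_lost`, `mitotype_fixed_symbiont_excluded`,
`mitotype_fixed_symbiont_retained` or `coexistence_partitioned` (the
Model-ii regime in which the infected pool keeps the ancestral mitotype
while the novel one occupies most of the uninfected pool).

## Numerical choices

* **Simplex policing.** After each step, components within `1e−15` below
  zero are clamped to 0; a total off 1 by more than `1e−12` is
  renormalised; more than `1e−9` raises an error instead of being silently
  renormalised away, so formula bugs cannot hide.
* **Fixed-point iteration.** Convergence when the per-generation max-norm
  change drops below `tol = 1e−12`; `max_gen = 1e6` for single runs,
  `3e5` for sweep cells (sweeps retire converged cells from the vectorised
  active set, so a few slow cells near boundaries do not stall the grid).
* **Equilibrium-presence floor (`1e−7`).** The per-generation stopping rule
  freezes a geometrically decaying component at a residual of up to
  `tol/rate` (≈ `1e−8` for rates down to `1e−4`), so extinction/fixation
  cannot be judged against cutoffs below that residual. A compartment
  therefore counts as occupied at equilibrium only above `1e−7` — two
  decades above the worst residual and two below the introduction
  frequency `ε = 1e−5` that any genuinely invading lineage must exceed.
  The raw in-run extinction/fixation cutoffs remain `1e−9`.
* **Boundary honesty.** Runs whose linearised growth factor lies within
  `1e−6` of 1 are reported `indeterminate` rather than forced into a
  class; unconverged polymorphic runs likewise. Closed-form equilibria
  within `1e−9` of 0 or 1 are snapped to the boundary.
* **Degenerate inputs.** A non-positive recursion denominator (impossible
  for valid parameters and states; reachable through misuse) raises a
  dedicated error; parameter validation enforces `1 + B > 0`,
  `1 + b − c > 0` and `1 − c > 0`, `h, µ ∈ [0, 1]`, `t > −1`.

## Problem sizes

Phase diagrams use 50×50 grids for Models i–ii and 26×26 per-`h` panels
for the CI model, whose bistable cells converge more slowly; the shipped
figure configs use 51×51 (26×26 per panel for CI). The CI invasion-ceiling
scan steps `h` by 0.005 over (0, 0.2] with a 26×26 `(µ, t)` grid strictly
inside `(0, (1−√(1−h))/2) × (0, 0.02]` per `h`. The boundary-bisection
checks resolve persistence thresholds to `1e−4` in `µ` using 3×10⁵
generations per probe. Randomised oracle checks draw 100 parameter sets
per model, with `µ` capped at 90% of the persistence bound so fixed-point
iteration converges quickly; the closed forms themselves are exact at the
boundary.

## Design decisions taken where the design was open

* The CI recursions are implemented directly from the four female-frequency
  equations, with male frequencies set equal to female frequencies, rather
  than from an explicit 16-entry mating table; the two are equivalent under
  the stated symmetry assumptions.
* Stability flags come from the analytic criteria where those exist
  (`µ < B/(1+B)`, `µ < (b−c)/(1+b−c)`, E2/E3 roles in the CI model); no
  symbolic stability analysis of the full four-dimensional system is
  attempted — full-system conclusions are established numerically through
  the invasion runs and their agreement with the linearisation
  (sign of `λ − 1` must predict invasion vs loss away from the neutral
  band; the test-suite enforces this).
* The Model-ii invasion curve is computed from the linearisation and
  cross-checked against a numerical root-find on the growth factor and
  against simulated outcome flips (one-grid-cell agreement enforced).
* "Unlikely to invade above weak CI" is operationalised as the largest
  scanned `h` with at least one invading `(µ, t)` cell; cells are counted
  as invading on any outcome other than loss of the mutant, with
  indeterminate (boundary) cells not counted.
* The `(µ, t)` grids for the CI ceiling lie strictly inside the open
  feasibility region: `µ = 0` fixes the symbiont (empty uninfected class)
  and `µ` at the tangency bound has no stable E3, so neither endpoint is a
  valid invasion setting.

## What the synthetic conditions do and do not show

There is no data layer: the models **are** the study system, and every
quantitative claim is a property of the recursions at stated parameter
values. Passing tests show internal consistency (closed forms vs iterated
dynamics, linearisation vs full nonlinear outcomes, analytic vs simulated
boundaries), not external validity. In particular the mean-field
deterministic idealisation ignores drift — a rare mutant with growth factor
barely above 1 would in reality be lost with high probability — as well as
paternal leakage, horizontal symbiont transfer, multiple co-circulating
strains, host suppression and eco-evolutionary feedback on the benefit
terms, any of which can change outcomes in natural populations.

## Known limitations

* Outcome labels near thresholds depend on finite horizons; the
  `indeterminate` class is the honest residue of that, and phase-diagram
  assertions exclude a one-cell band around analytic boundaries.
* The CI model's near-tangency region (`µ` within ~`1e−3` of the
  feasibility bound) mixes extremely slow local dynamics with a shrinking
  basin of attraction; ceiling-type summaries there are grid-resolution
  statements, not limits of the continuum problem.
* Trajectories record every generation in memory; at the default `1e−12`
  tolerance a typical run is a few thousand generations, but pathological
  near-boundary parameter choices can produce very long frames.
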