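# cytosweep

Deterministic population-genetic dynamics of maternally co-inherited
symbionts and mitochondria.

## The problem

Facultative heritable symbionts — *Wolbachia*, *Spiroplasma*, *Rickettsia*
and their like — pass from mother to offspring alongside the mitochondria.
Because the two elements are co-transmitted, selection on one drags the
other along. The classical direction (symbiont sweeps homogenising mtDNA)
is well studied; `cytosweep` models the reverse question: what does
**positive selection on a mitochondrial haplotype** do to the symbiont?

A host individual carries one of four *cytotypes*, tracked as frequencies

| symbol | mitotype | symbiont |
|--------|----------|----------|
| `p` | resident | infected |
| `q` | resident | uninfected |
| `r` | novel | infected |
| `s` | novel | uninfected |

with `p + q + r + s = 1`. A novel mitotype confers benefit `t` (default
focus `t = 0.02`, strong mtDNA selection); the symbiont is lost
segregationally at rate `µ` and maintained by one of three drive regimes,
each a discrete-generation recursion on `(p, q, r, s)`:

* **Model i — fixed benefit.** Offspring of infected mothers gain a net
  factor `1 + B`. Resident equilibrium `p* = 1 − (1+B)µ/B`, symbiont
  persistence iff `µ < B/(1+B)`.
* **Model ii — negative frequency dependence** (e.g. a defensive symbiont):
  realised benefit `B_T = b(1 − (p_T + r_T))` against fixed cost `c`;
  polymorphic equilibrium
  `p* = (b(2−µ) − c − √(c² + bµ(4 + bµ − 2c)))/(2b)`, persistence iff
  `µ < (b−c)/(1+b−c)`.
* **Model iii — cytoplasmic incompatibility**: offspring of uninfected
  mothers crossed to infected fathers survive at `1 − h`. Bistable:
  equilibria `E2/E3 = (h ∓ √(h² − 4hµ(1−µ)))/(2h(1−µ))`, feasible iff
  `µ < (1 − √(1−h))/2`, with E2 the separatrix below which the symbiont is
  lost.

On top of the recursions the package provides closed-form equilibria,
linearised invasion analysis of the rare mutant (growth factors, the
analytic thresholds `t = B(1−µ) − µ` and `t = (1+b−c)(1−µ) − 1`), long-run
outcome classification, and figure-style artifacts: per-generation
trajectories and `(µ, t)` / `(µ, h)` phase-diagram sweeps written as tidy
CSVs.

It is aimed at evolutionary biologists studying symbiont–mitochondria
co-inheritance, mtDNA barcoding discordance, and symbiont turnover.

## Worked example

A 2%-beneficial mitotype in a population where a fixed-benefit symbiont
(`B = 0.075`, `µ = 0.05`) sits at its equilibrium prevalence of 28.3%:

```console
$ cytosweep invade --model i --B 0.075 --mu 0.05 --t 0.02 --origin uninfected
invasion threshold (uninfected origin): t = 0.02125
outcome: mitotype_lost
growth factor: 0.9987760098
baseline symbiont equilibrium: 0.283333
final state after 7687 generations: p=0.283333 q=0.716667 r=0 s=8.15271e-10
```

The mutation arose in an uninfected host, and its benefit (`t = 0.02`) is
below the invasion threshold `B(1−µ) − µ = 0.02125`: each generation the
uninfected lineage multiplies by 0.99878 < 1, so despite being
advantageous the mitotype is deterministically lost and the symbiont is
untouched. The same mutation arising in an *infected* host instead fixes
(growth factor `1 + t = 1.02`) and the symbiont returns to its baseline:

```console
$ cytosweep invade --model i --B 0.075 --mu 0.05 --t 0.02 --origin infected
outcome: mitotype_fixed_symbiont_retained
final state after 1699 generations: p=1.96285e-11 q=4.96487e-11 r=0.283333 s=0.716667
```

Note `r = 0.283333 = p*`: the sweep has replaced the resident mitotype in
both infection classes (erasing mitochondrial *and* symbiont diversity)
without changing symbiont prevalence. For the CI model:

```console
$ cytosweep equilibria --model iii --h 0.25 --mu 0.05
E1: p* = 0 (feasible, stable, trivial)
E2: p* = 0.268475 (feasible, unstable, internal_unstable)
E3: p* = 0.784157 (feasible, stable, internal_stable)
persistence bound: mu < 0.0669873
```

Published-figure runs ship as YAML configs:

```bash
cytosweep run src/cytosweep/configs/fig1.yaml --out fig1_trajectory.csv
```

reproduces the fixed-benefit infected-origin sweep time course
byte-identically on every run (the models are deterministic; configs have
no seed field).

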