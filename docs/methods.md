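# Methods

## Model

A single quantitative trait `z` — a *joint phenotype*, shaped by the
actions of two parties — evolves by successive fixation of new mutations.
Party *i* has Gaussian fitness

    w_i(z) = exp(-ω_i (o_i - z)²),

a phenomenological peak of height 1 at its optimum `o_i` whose width is set
by the shape parameter `ω_i`.  Conflict is parameterised by where the two
curves cross: both parties have fitness `w₀` at the intersection, taken as
the origin, and the shared lag load `L = 1 - w₀` is the conflict intensity.
Given `w₀` and the shapes, the optima are `o_i = ±sqrt(-ln w₀ / ω_i)`;
party 1 holds the positive optimum by convention.  Raising the lag load
pushes the optima apart and raises what each party stands to gain by
dragging `z` toward its own peak.

Evolution is modelled in the strong-selection/weak-mutation regime: the
population is monomorphic between fixations and selection sees one mutation
at a time.  A proposal draws an additive effect `m`, unbiased about zero,
computes the mutant's selection coefficient

    s = w(z + m) / w(z) - 1,

and fixes it with Kimura's probability: `Π = 1 - e^(-2s)` for `s > 0` and
`Π = 0` for `s ≤ 0` in the drift-free (infinite population) limit, or

    Π = (1 - e^(-2s)) / (1 - e^(-4Ns))

for a haploid population of size `N`, where deleterious fixation by drift
is possible.  A fixed mutation shifts `z` by exactly `m`.

## Regimes

**Standard adaptation.**  One party, optimum fixed at `o₁ =
sqrt(-ln w₀ / ω₁)`, walk started at the origin (configurable), one proposal
per iteration.  This is the classic adaptive walk: rapid early fixations,
then quiescence near the optimum.

**Conflict.**  Two parties share `z`.  Each iteration comprises `r`
contiguous proposal rounds for party 1 and one for party 2, with a fair
coin per iteration deciding which block goes first.  `r` is the relative
mutational input (population size × mutation rate × generations folded
into one integer).  Asymmetries: `ω₁ = f·ω₂` (relative selection
strength; the config's `omega` is party 1's shape) and `m̄₁ = κ·m̄₂`
(relative mutation size; the config's `mean_size` is party 2's).

**Magnitude-matched abiotic control.**  For every conflict replicate a
paired single-party run asks: is conflict worse than random environmental
change of the same size?  At each iteration the control's optimum is
displaced by the absolute net change party 2 caused to `z` at the same
iteration of the paired conflict run — zero when party 2 fixed nothing —
in a direction chosen by fair coin, and the focal party (a copy of party 1)
then makes its `r` rounds.  Both runs therefore experience identical
magnitudes of environmental change; only conflict's is systematically
directed away from the focal party's optimum.

The pairing is two-pass: the conflict run completes first, its per-iteration
party-2 net shifts are extracted, and the control runs on an independent
random stream.  The direction coin is drawn every iteration, including
zero-displacement ones, so the control's stream layout does not depend on
the paired run's content.

## Mutation distributions

Effects are `Normal(0, σ_i)` by default, giving mean absolute size
`m̄_i = σ_i √(2/π)`.  Two alternatives are provided at *matched mean
size* so distributions are compared fairly: `Uniform(-b, b)` with
`b = 2 m̄` (since E|U(-b,b)| = b/2), and an exponential magnitude of mean
`m̄` with an independent fair sign.  The matched-mean-size convention is
this package's choice of parameterisation for the non-normal families.

## Summaries

Statistics are computed over a post-burn-in window.  State (distance
`|z - o_i|`, fitness `w_i`) is sampled once per iteration, after all of the
iteration's rounds, so regimes with different round counts are sampled
comparably; in the abiotic regime the distance uses the current (moved)
optimum.  Fixation fraction is each party's fixed/proposed count among its
own window proposals — the only denominator that stays comparable across
`r`.  Mean fixation size is the mean |effect| among fixed events, reported
as missing (never zero) when nothing fixed.  Mean lag load is `1 - mean
fitness` over the same samples, exactly.

Fitness power `P_w1 = 1 - L₁/(L₁+L₂)` is computed per replicate from that
replicate's mean lag loads, then averaged across replicates
(ratio-of-means within replicate, mean-of-ratios across).  It is undefined
(missing) in the measure-zero case `L₁ + L₂ = 0`.  Aggregation across
replicates reports means and standard errors (ddof = 1); missing values
are excluded, not zeroed.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `lag_load` | 0.2 | conflict intensity `1 - w₀` |
| `omega` | 1/2 | party 1 curve shape (party 2: `omega/f`) |
| `mean_size` | 0.1 | party 2 mean absolute mutation effect (party 1: `κ×`) |
| `f`, `kappa`, `r` | 1, 1, 1 | selection / size / input asymmetries |
| `pop_size` | infinite | haploid `N_i`; `None` = drift-free limit |
| `n_iterations` | 5,000 | equilibrium window length |
| `burn_in` | `250/min(ω_i)` | discarded initial adaptation period |
| `n_replicates` | 200 | independent walks per condition |
| `z_init` | 0 | starting phenotype (the curve intersection) |

The defaults are the baseline conditions used throughout the tests and the
acceptance script: lag load 0.2, mean size 0.1, shape 1/2, infinite
populations.  At these values the optima sit at ±0.668; the burn-in
default resolves to 500 iterations, with the *smaller* `ω` (the slower
party) setting the timescale in asymmetric runs.  Simulations run at 200
replicates × (burn-in + 5,000 iterations) — enough for ~0.003 standard
errors on power while keeping a full experiment in seconds on one core;
the machinery supports the 1,000-replicate scale unchanged.

## Numerical choices

- `s = 0` in the drift-free limit fixes with probability 0 (a neutral
  mutation in an infinite population; exact ties only arise from degenerate
  inputs).
- The finite-`N` formula switches to its continuity limit `1/(2N)` when
  `|4Ns| < 1e-8`, and to the asymptotic form `e^(4Ns-2s)(1 - e^(2s))` when
  `4Ns < -700` where the direct expression overflows; strongly deleterious
  probabilities may underflow to exactly 0 in floating point.
- Fitness may underflow to 0 at astronomically large distances; the
  selection-coefficient guard then raises a clear error instead of
  propagating NaN.  Tested parameter ranges never approach this regime.
- Event logs record every proposal; replaying the fixed effects in order
  reproduces the final `z` bit-for-bit (pure sequential addition), and the
  abiotic optimum path likewise replays exactly from the paired run's
  shifts.
- Random streams: `SeedSequence(entropy=seed, spawn_key=(cell, replicate,
  stream))`, stream 0 for standard/conflict, stream 1 for the paired
  control.  Within a run the generator is consumed in a fixed documented
  order (effects, then fixation uniforms, then coins), so identical
  configurations are bit-identical and any grid cell re-runs in isolation.

## Design choices where the design was open

- With `r > 1`, party 1's rounds are a contiguous block and the
  per-iteration coin orders block vs. party 2's single round; contiguity
  keeps the per-iteration abiotic pairing well defined.
- Only party 2's own fixations count toward the abiotic displacement
  (party 1's moves are the focal party's own evolution, not environmental
  change from its viewpoint).
- The control and its paired conflict run use independent mutation
  streams: the match is defined by displacement magnitude per iteration,
  not by shared randomness.
- The fixation-rate cross-check integrates `Π(s(m))` over the mutation
  density by quadrature and compares against the Monte-Carlo per-proposal
  fixation fraction at frozen phenotypes — an independent route through
  the same model used nowhere in the simulator.

## What the simulations do and do not show

The generator emulates the idealised dynamics exactly as specified: one
trait, haploid parties, Gaussian fitness, SSWM fixation, no linkage, no
polymorphism, no demography.  Passing tests therefore demonstrate
properties of this model — equal power under symmetry, the
standard > abiotic > conflict fitness ordering, larger fixed effects under
both kinds of change, power rising and saturating with `f` and `r` — not
claims about any real host–parasite system, where multi-trait pleiotropy,
population dynamics and extinction, co-segregating variation, and
mean-reverting environments all matter and are out of scope here.

One quantitative caveat worth stating: at the baseline parameters the
conflict regime fixes mutations about 6% larger on average than the
matched abiotic control (0.150 vs. 0.142 at 200 replicates, a many-SE
gap).  The two regimes are "alike" only relative to their common, much
larger elevation above the standard regime's 0.066; with enough replication
the residual systematic difference — conflict parties equilibrate roughly
three times farther from their optimum than the control, leaving more room
for large effects — is resolvable, and the suite's equivalence assertion
at a 4-SE band records this honestly as a failure rather than widening the
band.

## Limitations

Single trait only; two parties; Gaussian fitness family only; `r` restricted
to integers (fractional input ratios would need stochastic round counts);
no diploid fixation probabilities; the moving-optimum control drifts
without bound (no mean reversion), which if anything understates how much
worse conflict is than realistic abiotic change.
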