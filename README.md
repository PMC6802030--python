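# fgmconflict

Adaptive walks and two-party evolutionary conflict over a joint phenotype in
a one-trait Fisher's geometric model.

Many antagonistic interactions — host vs. pathogen, predator vs. prey, cuckoo
vs. host — can be summarised by a single *joint phenotype* `z` (for example
the probability of infection) over which the two parties hold different
optima.  `fgmconflict` simulates long-term evolution of such a trait by
successive fixation of new mutations, and quantifies the resulting
*Sisyphean arms race*: both parties keep climbing toward their own fitness
peak while the opponent drags the trait back, producing sustained adaptive
evolution with no lasting fitness gain.  The package is aimed at
evolutionary theorists who want a small, fast, fully reproducible sandbox
for conflict dynamics, moving-optimum controls, and the asymmetries that
let one party win.

## The model

Party *i* (*i* = 1, 2) has Gaussian fitness on the shared trait `z`:

    w_i(z) = exp(-ω_i (o_i - z)²)

with optimum `o_i` and shape `ω_i` (larger `ω` ⇒ narrower curve, stronger
selection).  The two curves intersect at the origin with common fitness
`w₀`; the shared **lag load** `1 - w₀` measures conflict intensity, and the
optima sit at `o_i = ±sqrt(-ln w₀ / ω_i)` (party 1 positive by convention).

Evolution is strong-selection/weak-mutation: each proposal draws an
unbiased mutation `m ~ N(0, σ_i)` (uniform and exponential alternatives are
matched to the same mean absolute size `m̄_i = σ_i √(2/π)`), computes the
selection coefficient `s = w(z + m)/w(z) - 1`, and fixes it with Kimura's
probability `Π = 1 - e^(-2s)` for `s > 0` (else 0) in effectively infinite
populations, or `Π = (1 - e^(-2s))/(1 - e^(-4Ns))` for haploid size `N`.
Fixation shifts `z` additively.

Three regimes share this machinery:

- **standard** — one party, one fixed optimum: the classic adaptive walk;
- **conflict** — both parties mutate each iteration (party 1 makes `r`
  contiguous rounds to party 2's one, a fair coin picks the first mover);
- **abiotic_matched** — a single-party control whose optimum is displaced
  each iteration, in a random direction, by exactly the magnitude that
  party 2 shifted `z` in a paired conflict run: environmental change of
  identical size but without a malevolent direction.

Asymmetries: `f` (relative selection strength, `ω₁ = f·ω₂`), `κ` (relative
mutation size, `m̄₁ = κ·m̄₂`) and `r` (relative mutational input).  Who is
winning is measured by the **fitness power** of party 1,

    P_w1 = 1 - L₁ / (L₁ + L₂),

where `L_i` is party *i*'s mean lag load over the equilibrium window;
0.5 means a dead heat, values near 1 mean party 1 holds `z` near its own
optimum.

## Worked example

```python
import fgmconflict as fc

cfg = fc.ScenarioConfig(
    regime="conflict", lag_load=0.2, omega=0.5, mean_size=0.1,
    n_iterations=5000, burn_in=500, n_replicates=50, seed=42,
)
res = fc.run_replicates(cfg)
print(res.aggregate().round(4).to_string(index=False))
power, se = res.power()
print(f"fitness power of party 1: {power:.3f} +/- {se:.3f} (SE)")
```

prints

```
 party          statistic   mean     se  n_replicates
     1      mean_distance 0.6769 0.0039            50
     1       mean_fitness 0.7834 0.0020            50
     1  fixation_fraction 0.0562 0.0004            50
     1 mean_fixation_size 0.1485 0.0007            50
     1      mean_lag_load 0.2166 0.0020            50
     1       power_party1 0.4893 0.0047            50
     2      mean_distance 0.6593 0.0039            50
     2       mean_fitness 0.7925 0.0020            50
     2  fixation_fraction 0.0560 0.0004            50
     2 mean_fixation_size 0.1491 0.0007            50
     2      mean_lag_load 0.2075 0.0020            50
fitness power of party 1: 0.489 +/- 0.005 (SE)
```

Read this as: two identical parties fight over `z` at conflict intensity
0.2.  Each ends up, on average, 0.66–0.68 trait units from its optimum
(the optima sit at ±0.668, so the trait hovers near the intersection),
holding mean fitness ≈ 0.79 — essentially the intersection fitness `w₀ =
0.8`, the Red Queen running in place.  Both keep fixing ~5.6% of proposed
mutations with mean fixed effect ≈ 0.15 (about twice the average proposed
size of 0.1 — being far from the optimum lets large mutations through),
and the power ≈ 0.5 says neither side is winning, as symmetry demands.
A standard (no-conflict) walk with the same parameters instead reaches and
holds mean fitness ≈ 0.9996 and virtually stops fixing mutations.

The same run from the shell:

```bash
fgmconflict simulate --regime conflict --replicates 50 --seed 42 --out out/
fgmconflict preset figure2 --out out/fig2 --replicates 200   # fitness trajectories
fgmconflict summarize --log out/events_replicate0.tsv --burn-in 500 --window 5000
```

## Layout

- `fgmconflict.core` — fitness curves, optima from lag load, selection
  coefficients, fixation probabilities;
- `fgmconflict.mutation` — matched-mean-size effect distributions;
- `fgmconflict.simulate` — the three walk regimes, event logs, replicate
  runner and seed derivation;
- `fgmconflict.summaries` — equilibrium-window statistics, fitness power,
  replicate aggregation;
- `fgmconflict.experiments` / `fgmconflict.cli` — grids, presets,
  validation, delimited-text outputs and the `fgmconflict` command;
- `fgmconflict.plotting` — optional trajectory/power plots.

See `docs/methods.md` for the full model description, parameter defaults,
numerical choices and known limitations.
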