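# softbreed

A differentiable multi-generation breeding-scheme simulator with
gradient-based optimization of progeny allocation.

## The problem

Recurrent selection improves a population's genetic merit by cyclically
selecting superior individuals and intermating them.  A key design decision
each generation is *progeny allocation*: of the N offspring to be produced,
how many should come from each candidate cross?  Allocating everything to
the best pair maximizes short-term gain but burns genetic diversity;
spreading progeny evenly wastes selection intensity.  Classical simulators
treat the scheme as a black box, so allocation weights can only be tuned by
derivative-free search.

`softbreed` makes the whole scheme differentiable.  Each generation, the n
selected parents form all P = n(n+1)/2 unordered pairs (selfing included),
each pair k gets a feature vector ωₖ ∈ ℝ² — the mean parental **weighted
breeding value** (WBV, allele effects up-weighted by 1/√(minor allele
frequency)) and the **expected genetic variance of progeny** (GVP, from
parental phase and recombination rates) — and progeny are allocated by the
softmax

&nbsp;&nbsp;&nbsp;&nbsp;π_k = exp(ωₖᵀθ) / Σ_k′ exp(ω_k′ᵀθ),

with per-generation weights θ(τ).  Sampling which pair produces each
offspring is relaxed by **Gumbel-Softmax reparameterization**: with i.i.d.
Gumbel(0,1) noise g and temperature c,

&nbsp;&nbsp;&nbsp;&nbsp;y_ik = exp((log π_k + g_ik)/c) / Σ_k′ exp((log π_k′ + g_ik′)/c),

and progeny i's allele-score vector is the y-weighted convex combination of
one meiotically generated candidate offspring from *every* pair.  Meiosis
itself is a crossover-parity gather (Bernoulli crossover indicators η with
per-interval recombination rates from the Haldane map function), which is
constant-index and therefore transparent to differentiation.  The merit
F = mean genotypic value of the top K individuals at generation T is then
smooth in θ given fixed (g, η), and reverse-mode automatic differentiation
(a compact numpy engine shipped in `softbreed.autodiff`) delivers ∂F/∂θ(τ)
exactly.  Stochastic gradient ascent on E[F] over the Monte-Carlo noise
optimizes the allocation weights; a fully discrete simulator (integer
allocation by largest remainder, real meiosis, no relaxation) evaluates
what the optimized policy actually delivers.

Intended users: quantitative geneticists and breeding-program modelers who
want gradient-based rather than black-box optimization of scheme
parameters, and methods researchers studying differentiable relaxations of
discrete biological processes.

## Worked example

```python
import numpy as np
from softbreed import (
    SchemeConfig, build_marker_map, simulate_founders, sample_trait,
    strategy_preset, sgd_optimize, AllocationParams, run_experiment,
)

gmap = build_marker_map([20] * 10, spacing_cM=100.0 / 19)   # 200 QTL, 10 chromosomes
founders = simulate_founders(gmap, 60, seed=1)
trait = sample_trait(gmap, seed=2)
config = SchemeConfig(generations=4, top_k=5, selection="SI2", n_selected=10)

init = strategy_preset("GORA2", config.generations)          # low initial GVP weight
params, trace = sgd_optimize(founders, trait, gmap, init.nu,
                             epochs=30, n_mc=20, config=config, seed=3)
print(f"F_mean: {trace.F_mean[0]:.2f} -> {trace.F_mean[-1]:.2f}")

policies = {"GORA2": params, "EQ": AllocationParams.equal_allocation(4)}
_, summary = run_experiment(founders, trait, gmap, policies, config,
                            n_reps=200, seed=4)
for name, s in summary["strategies"].items():
    print(name, f"mean final gain {s['mean_final_gain']:.2f}")
print(f"improvement: {summary['strategies']['GORA2']['improvement_rate_vs_EQ']:.1f}%")
```

Output from this exact script:

```
F_mean: 45.13 -> 46.47
EQ mean final gain 27.38
GORA2 mean final gain 38.18
improvement: 39.4%
```

`F_mean` is the Monte-Carlo estimate of the expected top-5 *merit* (an
absolute genotypic value) of the final generation under the soft (relaxed)
scheme; it rises as SGD shifts allocation toward high-WBV pairs.  The
evaluation block then runs the *discrete* simulator 200 times per policy
with paired seeds and reports *gain* (merit relative to the founders): the
optimized weights lift the mean four-generation genetic gain by roughly 39%
over equal allocation in this weak-selection, many-QTL configuration.

The same workflows are available from the shell:

```
softbreed simulate-founders --seed 1 --out runs/founders
softbreed optimize  --strategy GORA2 --epochs 30 --mc-reps 20 --seed 1 --out runs/opt
softbreed evaluate  --params runs/opt/params.json --reps 200 --seed 1 --out runs/eval
softbreed grid      --divisions 50 --seed 1 --out runs/grid
softbreed gradcheck --seed 1 --out runs/gc
```

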