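# Methods

## Model

`softbreed` simulates recurrent selection on a diploid crop with `m`
biallelic markers on `C` chromosomes, all of which are QTLs with known
additive effects.  An individual is a phased binary allele-score vector
w ∈ {0,1}^{2m} (maternal haplotype stacked on paternal); its genotypic
value is αᵀw with α the per-marker effects duplicated per haplotype.  A
scheme runs T generations at constant population size N.  Each generation:

1. **Selection.**  One of three predetermined strategies picks n parent
   candidates ranked by weighted breeding value (WBV): plain truncation at
   n = 15 (SI1) or n = 50 (SI3), or Ward clustering of marker dosages into
   n = 25 groups with the top-WBV member of each group (SI2).  Intensities
   order SI1 > SI2 > SI3.
2. **Pair features.**  All P = n(n+1)/2 unordered pairs (selfing included)
   get ωₖ = (mean parental WBV, GVP).  WBV_i = Σ_j α_j p_j^{-1/2} w_ij with
   p the per-marker minor allele frequency; GVP is the expected variance of
   progeny genotypic values, Σ_{jj′} σ_{kjj′} β_j β_{j′} with segregation
   covariance σ_{kjj′} = ¼(1 − 2r_{jj′}) Σ_{parent}(w_j − w_{j+m})(w_{j′} −
   w_{j′+m}).
3. **Allocation.**  π = softmax(ωθ(τ)) over pairs; θ(τ) ∈ ℝ² are the
   weights being optimized.  θ = 0 is exactly equal allocation.
4. **Progeny.**  In the differentiable simulator every pair contributes one
   candidate offspring per progeny slot via the crossover-parity meiosis
   model, and the slot's soft genotype is the Gumbel-Softmax-weighted convex
   combination of all P candidates.  In the evaluation simulator π is
   converted to integer counts (largest remainder) and progeny are generated
   discretely.

The objective is F = mean genotypic value of the top K individuals at
generation T, in expectation over the Gumbel noise g and the segregation
indicators η.  Given fixed (g, η) and fixed selection/ranking index sets,
every map from θ to F is smooth, so reverse-mode differentiation yields
exact per-realization gradients; their Monte-Carlo average estimates
∇E[F].

### Meiosis

Crossover indicators η_j ~ Bernoulli(r_j) flag an exchange between adjacent
markers; the gamete reads the parent haplotype given by the parity of the
cumulative crossover count, l_j = j + m·(Σ_{j′≤j} η_{j′} mod 2).  Adjacent
rates come from the Haldane map function r = ½(1 − e^{−2d/100}) of the cM
gap; the first marker of every chromosome uses the virtual rate ½, so each
chromosome independently re-randomizes its starting haplotype — this
generalizes the single virtual r₀₁ = ½ of a one-sequence layout to multiple
independently segregating chromosomes.  No crossover interference, no
sex-specific maps, no mutation.

### Differentiation without a framework

Gradients come from a compact reverse-mode engine (`softbreed.autodiff`)
written on numpy: a `Tensor` wrapper recording broadcast arithmetic,
matmul, reductions, softmax, sigmoid and constant-index gathers (backward =
`bincount` scatter-add).  Discrete draws (η, Gumbel argmaxes implicit in
ranking, cluster labels, top-K index sets) enter as constants; gradients
flow through selected soft allele scores only — the allocation path is the
differentiated one, matching the scheme's design.  The engine is validated
op-by-op against central finite differences and end-to-end by the
common-random-numbers gradient check (max relative error ~1e-5 on a
two-generation scheme at h = 1e-3).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| temperature c | 0.5 | Gumbel-Softmax smoothness; constant across generations (no annealing). 0.5 keeps weights informative while remaining well away from the flat large-c and the vanishing-gradient small-c regimes. |
| θ bounds | [0.5, 3.5] | allocation weights live in this interval via θ = 0.5 + 3·logistic(ν); SGD runs unconstrained in ν. The equal-allocation baseline bypasses the transform (θ ≡ 0). |
| GORA1 / GORA2 init ν_GVP | +1 / −2 | the two gradient-optimized presets differ only in initial GVP emphasis (GORA1 > GORA2); ν_WBV starts at 0 (θ = 2, mid-interval) for both. |
| lr schedule | 0.1, ×0.5 every 50 epochs | mild step decay; an aggressive scheduler can halt the search before the weights settle. |
| epochs × n_mc | 200 × 100 (full), 30 × 20 (desk) | function-evaluation budget of SGD; the desk profile is the tested configuration. |
| MAF floor | 0.01 | caps p^{-1/2} at monomorphic markers. |
| feature standardization | on | WBV and GVP have incomparable natural scales; z-scoring across pairs each generation puts both on the scale the shared θ domain presumes. |
| maf_range, ld_decay, effect_sd | U(0.05, 0.5), 0.1 /cM, 1.0 | founder-generator knobs, below. |

Minor allele frequencies are recomputed from the current population every
generation — "the" MAF of the allocation step naturally refers to the
population being allocated, and recomputing keeps the rare-allele emphasis
adaptive as frequencies drift.

## Synthetic founders

Founder haplotypes are generated by a Markov copy process per chromosome:
each marker's allele is copied from its left neighbor with probability
exp(−ld_decay·d) and otherwise drawn fresh, with the fresh-draw frequency
adjusted so the marginal allele frequency tracks a per-marker target drawn
from Uniform(0.05, 0.5).  QTL effects are i.i.d. Normal(0, 1).  This
emulates the features the scheme is sensitive to — realistic allele-
frequency spectra and distance-decaying LD — with two interpretable knobs.
It does **not** emulate coalescent genealogy, population structure,
selection footprints, or mutation; passing tests therefore certify the
scheme machinery and its gradients on populations with realistic marginal
structure, not performance on any real crop panel.

## Numerical choices

- Allocation and Gumbel softmaxes subtract the row max (a constant shift)
  before exponentiation; π is floored at 1e-12 before the log in the
  Gumbel-Softmax logits.
- WBV/GVP ties in ranking, remainder ties in integer allocation, and top-K
  ties all break toward the lower index, making every discrete step
  deterministic given its inputs.
- Zero-variance feature columns standardize to 0 rather than NaN.
- Non-finite intermediates abort with the generation named.
- Common random numbers: the finite-difference check and the gradient grid
  freeze one noise bank and reuse it across parameter settings; SGD draws
  fresh noise per epoch (stochastic gradients).
- One global seed expands to per-component seeds via SHA-256 of
  (seed, component name); all derived seeds stay below 2³¹.

## Design choices where the design was open

- **Haldane map function** converts cM gaps to recombination rates; only
  the [0, 0.5] range and the cross-chromosome value 0.5 are forced, and
  Haldane (no interference) matches the meiosis model's independent-
  interval crossovers.
- **Ranking direction**: parents are selected by *descending* WBV —
  selection targets superior individuals.
- **SI2 clustering**: Euclidean distance on dosage vectors with Ward
  linkage; deterministic and scale-appropriate for 0/1/2 dosages.
- **Integer allocation** by largest remainder with index tie-break:
  deterministic, sums exactly to N, and reproduces uniform counts under
  equal allocation when P divides N.
- **Per-slot candidates from every pair**: the relaxed simulator generates
  one offspring from each of the P pairs for each of the N slots (O(N·P·m)
  per generation), trading compute for exactness of the convex-combination
  formulation; desk-scale configurations keep this comfortably in memory.
- **EQ exemption from the θ bounds**: equal allocation is θ = 0, outside
  [0.5, 3.5]; it is a fixed baseline, never optimized, so it bypasses the
  transform rather than forcing the bounded domain to contain it.

## Problem sizes used by the tests and the acceptance script

The full-size study conditions (N = 250, m = 30 or 500, 200 epochs × 100
simulations, 10⁴ evaluation replicates) are available through the `full`
scale profile.  The shipped tests and `scripts/acceptance.py` use the
`desk` profile — N = 60, m = 200 over 10 chromosomes, 10-cluster selection,
T = 4, K = 5, SGD 30 epochs × 20 simulations, 200 paired-seed evaluation
replicates — the package's chosen configuration for routine verification;
gradient checks run on N = 20, m = 12, T = 2 schemes.

## Known limitations

- SGD is a local method; from a poor initialization it can settle far from
  the global optimum (the two presets exist precisely because the initial
  GVP weight materially changes the outcome).
- Gradients are exact per realization but noisy as estimates of ∇E[F];
  small n_mc can stall progress near flat regions.
- The relaxed simulator's soft genotypes are biased relative to hard
  sampling at moderate temperature; all reported gains come from the
  discrete evaluator, never from the relaxation.
- Selection is not differentiated (ranking index sets are constants), so
  the optimizer cannot trade allocation against selection pressure.
- Additive traits only; no dominance, epistasis, or genomic-prediction
  error (marker effects are treated as known).
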