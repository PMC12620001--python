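"""The differentiable multi-generation breeding scheme.

Each generation, parents are selected, every unordered pair (selfing
included) of the ``n`` selected parents becomes a candidate cross, and a
softmax over pair goodness features sets the allocation distribution

    pi_k = exp(omega_k . theta) / sum_k' exp(omega_k' . theta),

with a per-generation weight vector ``theta(tau)``.  Drawing which pair
produces each of the N progeny is made differentiable by the Gumbel-Softmax
reparameterization: per progeny slot i,

    y_ik = exp((log pi_k + g_ik)/c) / sum_k' exp((log pi_k' + g_ik')/c),

with i.i.d. Gumbel(0,1) noise ``g`` and temperature ``c``; the slot's soft
allele-score vector is the y-weighted convex combination of one meiotically
generated offspring from *every* pair.  Repeating this for T generations and
taking the mean genotypic value of the top K individuals yields a merit
F(theta, g, eta) that is smooth in theta given fixed noise, so reverse-mode
differentiation delivers dF/dtheta(tau) exactly.

The two noise sources — Gumbel draws ``g`` and Bernoulli segregation
indicators ``eta`` — are drawn up front per simulation; the expected merit
is their Monte-Carlo average.  A common-random-numbers mode reuses one noise
bank across parameter settings, which is what makes finite-difference
validation of the gradients meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .genome import MarkerMap, Population, TraitArchitecture, genotypic_values
from .meiosis import crossover_source_columns
from .metrics import assemble_features, diallel_pairs
from .selection import STRATEGY_DEFAULT_N, select

__all__ = [
    "SchemeConfig",
    "AllocationParams",
    "NoiseDraws",
    "MeritResult",
    "THETA_BOUNDS",
    "bounded_transform",
    "inverse_bounded_transform",
    "allocation_probs",
    "gumbel_softmax_sample",
    "soft_progeny",
    "merit_topk",
    "draw_noise",
    "draw_noise_bank",
    "forward_scheme",
    "expected_merit",
]

THETA_BOUNDS = (0.5, 3.5)
PI_FLOOR = 1e-12


@dataclass
class SchemeConfig:
    """Scheme constants shared by the soft and hard simulators."""

    generations: int = 4
    top_k: int = 5
    selection: str = "SI2"
    n_selected: int | None = None  # None -> strategy default
    temperature: float = 0.5
    standardize_features: bool = True
    n_features: int = 2

    def __post_init__(self):
        if self.generations < 1 or self.top_k < 1:
            raise ValueError("generations and top_k must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_parents(self) -> int:
        return self.n_selected if self.n_selected is not None else STRATEGY_DEFAULT_N[
            self.selection.upper()
        ]

    @property
    def n_pairs(self) -> int:
        n = self.n_parents
        return n * (n + 1) // 2


@dataclass
class AllocationParams:
    """Per-generation allocation weights.

    ``nu`` (T x d) is the unconstrained pre-image; ``theta`` is its image
    under the bounded transform ``theta = lo + (hi-lo) * logistic(nu)``,
    keeping weights inside (0.5, 3.5) while SGD runs unconstrained.  The
    equal-allocation policy bypasses the transform entirely (``fixed_theta``
    holds the constant weights, typically zero — a uniform softmax).
    """

    nu: np.ndarray | None = None
    fixed_theta: np.ndarray | None = None
    bounds: tuple[float, float] = THETA_BOUNDS

    def __post_init__(self):
        if (self.nu is None) == (self.fixed_theta is None):
            raise ValueError("provide exactly one of nu or fixed_theta")
        if self.nu is not None:
            self.nu = np.atleast_2d(np.asarray(self.nu, dtype=float))
        else:
            self.fixed_theta = np.atleast_2d(np.asarray(self.fixed_theta, dtype=float))

    @property
    def T(self) -> int:
        arr = self.nu if self.nu is not None else self.fixed_theta
        return arr.shape[0]

    @property
    def theta(self) -> np.ndarray:
        if self.fixed_theta is not None:
            return self.fixed_theta
        return bounded_transform(self.nu, self.bounds)

    @staticmethod
    def equal_allocation(T: int, d: int = 2) -> "AllocationParams":
        return AllocationParams(fixed_theta=np.zeros((T, d)))


def bounded_transform(nu, bounds: tuple[float, float] = THETA_BOUNDS):
    """theta = lo + (hi - lo) * logistic(nu); smooth, strictly monotone."""
    lo, hi = bounds
    return lo + (hi - lo) * ad.sigmoid(nu)


def inverse_bounded_transform(theta, bounds: tuple[float, float] = THETA_BOUNDS):
    lo, hi = bounds
    q = (np.asarray(theta, dtype=float) - lo) / (hi - lo)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("theta outside the open bounds has no pre-image")
    return np.log(q / (1.0 - q))


@dataclass
class NoiseDraws:
    """One simulation's stochastic factors.

    ``gumbel``: (T, N, P) Gumbel(0,1) samples; ``eta``: (T, 2, N, P, m)
    Bernoulli segregation indicators (axis 1: maternal/paternal gamete).
    """

    gumbel: np.ndarray
    eta: np.ndarray
    seed: int


def draw_noise(
    gmap: MarkerMap, config: SchemeConfig, n_progeny: int, seed: int
) -> NoiseDraws:
    rng = np.random.default_rng(seed)
    T, P, m = config.generations, config.n_pairs, gmap.m
    g = rng.gumbel(size=(T, n_progeny, P))
    u = rng.random((T, 2, n_progeny, P, m))
    eta = (u < gmap.r_adj).astype(np.int8)
    return NoiseDraws(g, eta, seed)


def draw_noise_bank(
    gmap: MarkerMap, config: SchemeConfig, n_progeny: int, seed: int, n_mc: int
) -> list[NoiseDraws]:
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_mc)
    return [draw_noise(gmap, config, n_progeny, int(s) % (2**31)) for s in seeds]


@dataclass
class MeritResult:
    """Top-K merit of the final population plus allocation-weight gradients."""

    F: float
    K: int
    grads: np.ndarray | None = None  # dF/dtheta(tau), (T, d)
    grads_nu: np.ndarray | None = None  # dF/dnu(tau), (T, d)
    final_w: object = None


def allocation_probs(omega, theta_row):
    """Softmax allocation distribution over the P pairs (Eq-5 style)."""
    scores = omega @ theta_row
    data = scores.data if isinstance(scores, Tensor) else scores
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("non-finite pair scores in allocation softmax")
    return ad.softmax_last(scores)


def gumbel_softmax_sample(pi, g_row, c: float):
    """Temperature-c relaxed categorical sample(s) from pi with noise g.

    ``pi`` broadcasts against ``g_row`` on the last (pair) axis; each row of
    the result is a point on the simplex, one-hot in the c -> 0 limit.
    """
    if c <= 0:
        raise ValueError("temperature must be positive")
    logits = (ad.log(ad.clip_min(pi, PI_FLOOR)) + g_row) * (1.0 / c)
    return ad.softmax_last(logits)


def soft_progeny(y_row, candidates):
    """Convex combination of per-pair candidate offspring, weights y.

    ``y_row``: (..., P) simplex weights; ``candidates``: (..., P, 2m).
    """
    if isinstance(y_row, Tensor) or isinstance(candidates, Tensor):
        y = y_row if isinstance(y_row, Tensor) else Tensor(y_row)
        yc = y.reshape(*y.shape, 1) * candidates
        return yc.sum(axis=-2)
    return (np.asarray(y_row)[..., None] * np.asarray(candidates)).sum(axis=-2)


def merit_topk(values, K: int):
    """Mean of the K largest entries; differentiable through a constant
    top-K index set (ties resolve to the lower index, the mean is unaffected)."""
    data = values.data if isinstance(values, Tensor) else np.asarray(values)
    N = data.shape[0]
    if not (1 <= K <= N):
        raise ValueError(f"K={K} outside 1..{N}")
    order = np.lexsort((np.arange(N), -data))
    idx = order[:K]
    return ad.take_rows(values, idx).mean()


def _candidate_flat_index(
    kM: np.ndarray, kP: np.ndarray, eta_t: np.ndarray, m: int
) -> np.ndarray:
    """Flat gather indices into the (n, 2m) parent matrix for all candidates.

    ``eta_t``: (2, N, P, m) segregation draws of one generation.  Returns an
    (N, P, 2m) integer array: for slot i and pair k, the first m entries read
    the kM-gamete's source columns, the last m the kP-gamete's.
    """
    lM = crossover_source_columns(eta_t[0])  # (N, P, m)
    lP = crossover_source_columns(eta_t[1])
    two_m = 2 * m
    idxM = kM[None, :, None] * two_m + lM
    idxP = kP[None, :, None] * two_m + lP
    return np.concatenate([idxM, idxP], axis=-1)


def forward_scheme(
    founders: Population,
    params: AllocationParams,
    trait: TraitArchitecture,
    gmap: MarkerMap,
    noise: NoiseDraws,
    config: SchemeConfig,
    compute_grads: bool = True,
) -> MeritResult:
    """One differentiable pass through the whole T-generation scheme.

    Selection and top-K ranking index sets are constants of the graph; all
    real-valued maps from theta to F are smooth given the fixed noise, so
    reverse-mode differentiation yields exact dF/dtheta(tau) for this (g,
    eta) realization.
    """
    T = config.generations
    if params.T != T:
        raise ValueError("params cover a different number of generations")
    m = gmap.m
    N = founders.n

    if params.nu is not None:
        nu_t = Tensor(params.nu, requires_grad=compute_grads)
        theta_t = bounded_transform(nu_t, params.bounds)
    else:
        nu_t = None
        theta_t = Tensor(params.fixed_theta, requires_grad=compute_grads)

    w = Tensor(np.asarray(founders.w, dtype=float))
    for tau in range(T):
        sel = select(w, trait, config.selection, config.n_parents)
        feats = assemble_features(
            w, sel.indices, trait, gmap, standardize=config.standardize_features
        )
        pi = allocation_probs(feats.omega, theta_t[tau])
        y = gumbel_softmax_sample(pi, noise.gumbel[tau], config.temperature)
        flat_idx = _candidate_flat_index(feats.kM, feats.kP, noise.eta[tau], m)
        parents = ad.take_rows(w, sel.indices)
        candidates = ad.take_flat(parents.reshape(-1), flat_idx)
        w = soft_progeny(y, candidates)
        if not np.all(np.isfinite(w.data if isinstance(w, Tensor) else w)):
            raise FloatingPointError(
                f"non-finite soft population at generation {tau + 1}"
            )

    values = genotypic_values(w, trait)
    F = merit_topk(values, config.top_k)
    result = MeritResult(F=float(F.data if isinstance(F, Tensor) else F),
                         K=config.top_k, final_w=w)
    if compute_grads and isinstance(F, Tensor) and F.requires_grad:
        F.backward()
        result.grads = np.array(theta_t.grad) if theta_t.grad is not None else np.zeros_like(params.theta)
        if nu_t is not None:
            result.grads_nu = np.array(nu_t.grad) if nu_t.grad is not None else np.zeros_like(params.nu)
    return result


def expected_merit(
    founders: Population,
    params: AllocationParams,
    trait: TraitArchitecture,
    gmap: MarkerMap,
    n_mc: int,
    seed: int,
    config: SchemeConfig,
    noise_bank: list[NoiseDraws] | None = None,
    compute_grads: bool = True,
) -> MeritResult:
    """Monte-Carlo mean of F and its gradients over n_mc (g, eta) draws.

    Pass ``noise_bank`` to reuse frozen draws (common random numbers);
    otherwise a fresh bank is derived from ``seed``.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if noise_bank is None:
        noise_bank = draw_noise_bank(gmap, config, founders.n, seed, n_mc)
    elif len(noise_bank) < n_mc:
        raise ValueError("noise bank smaller than n_mc")
    F_sum = 0.0
    g_theta = None
    g_nu = None
    for rep in range(n_mc):
        res = forward_scheme(
            founders, params, trait, gmap, noise_bank[rep], config,
            compute_grads=compute_grads,
        )
        F_sum += res.F
        if compute_grads and res.grads is not None:
            g_theta = res.grads if g_theta is None else g_theta + res.grads
            if res.grads_nu is not None:
                g_nu = res.grads_nu if g_nu is None else g_nu + res.grads_nu
    out = MeritResult(F=F_sum / n_mc, K=config.top_k)
    if g_theta is not None:
        out.grads = g_theta / n_mc
    if g_nu is not None:
        out.grads_nu = g_nu / n_mc
    return out
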