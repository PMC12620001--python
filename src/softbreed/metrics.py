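"""Pair "goodness" metrics: weighted breeding value and progeny variance.

Two features describe every candidate mating pair (d = 2):

* **WBV** — the weighted breeding value of an individual up-weights each
  allele's effect by the inverse square root of its minor allele frequency,
  ``WBV_i = sum_j alpha_j p_j^{-1/2} w_ij`` (sum over all 2m entries, p
  duplicated per haplotype); a pair's first feature is the mean of its two
  parents' WBVs.  Rare favorable alleles therefore weigh more, which favors
  keeping diversity in long schemes.

* **GVP** — the expected genetic variance among (selfed) progeny of the
  pair, computed from parental phase and pairwise recombination rates:
  ``gvp = sum_jj' sigma_jj' beta_j beta_j'`` with segregation covariance
  ``sigma_jj' = 1/4 (1 - 2 r_jj') sum_{parent} (w_j - w_{j+m})(w_j' - w_{j'+m})``.
  Only markers heterozygous in a parent contribute, and cross-chromosome
  pairs vanish (r = 0.5).

All functions dispatch on input kind: plain ndarrays for the hard simulator,
autodiff Tensors inside the differentiable scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .genome import MarkerMap, Population, TraitArchitecture

__all__ = [
    "PairFeatures",
    "diallel_pairs",
    "minor_allele_freq",
    "wbv_individual",
    "wbv_pair_feature",
    "gvp",
    "gvp_parents",
    "assemble_features",
]

MAF_FLOOR = 0.01  # avoids p^{-1/2} blow-ups at (near-)monomorphic markers


def _as_w(pop):
    if isinstance(pop, Population):
        return pop.w
    return pop


def diallel_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """All unordered pairs (kM <= kP) of n parents, selfing included."""
    kM, kP = np.triu_indices(n)
    return kM, kP


def minor_allele_freq(pop, floor_eps: float = MAF_FLOOR):
    """Per-marker frequency of the rarer allele over all 2N haplotypes.

    Soft populations contribute their mean dosage.  Clamped below at
    ``floor_eps``.
    """
    w = _as_w(pop)
    m = (w.shape[1] if not isinstance(w, Tensor) else w.data.shape[1]) // 2
    f = (w[:, :m].mean(axis=0) + w[:, m:].mean(axis=0)) * 0.5
    minor = ad.minimum2(f, 1.0 - f)
    return ad.clip_min(minor, floor_eps)


def wbv_individual(pop, trait: TraitArchitecture, p):
    """Weighted breeding value per individual (length N)."""
    w = _as_w(pop)
    p_dup = ad.concatenate([p, p])
    weights = trait.alpha * ad.power(p_dup, -0.5)
    return w @ weights


def wbv_pair_feature(wbv, kM: np.ndarray, kP: np.ndarray):
    """Mean parental WBV per pair; equals the parent's WBV for selfings."""
    return (ad.take_rows(wbv, kM) + ad.take_rows(wbv, kP)) * 0.5


def _parent_quadratic(parents_w, trait: TraitArchitecture, gmap: MarkerMap):
    """Per-parent quadratic form q_i = u_i^T Q u_i with Q = 1/4 (1-2r) b b^T.

    ``u_i = w_i[:m] - w_i[m:]`` is the phase-difference vector; a pair's GVP
    is q_kM + q_kP.
    """
    m = gmap.m
    quarter = 0.25 * (1.0 - 2.0 * gmap.r_pair()) * np.outer(trait.beta, trait.beta)
    u = parents_w[:, :m] - parents_w[:, m:]
    return ((u @ quarter) * u).sum(axis=1)


def gvp(w_kM, w_kP, trait: TraitArchitecture, gmap: MarkerMap):
    """Expected progeny genetic variance for one mating pair."""
    w_kM = np.atleast_2d(np.asarray(w_kM, dtype=float))
    w_kP = np.atleast_2d(np.asarray(w_kP, dtype=float))
    if w_kM.shape[1] != 2 * gmap.m or w_kP.shape[1] != 2 * gmap.m:
        raise ValueError("parent vectors must have length 2m")
    qM = _parent_quadratic(w_kM, trait, gmap)
    qP = _parent_quadratic(w_kP, trait, gmap)
    return float(qM[0] + qP[0])


def gvp_parents(parents_w, trait: TraitArchitecture, gmap: MarkerMap,
                kM: np.ndarray, kP: np.ndarray):
    """GVP for every pair of the diallel, from the (n, 2m) parent matrix."""
    q = _parent_quadratic(parents_w, trait, gmap)
    return ad.take_rows(q, kM) + ad.take_rows(q, kP)


def _standardize_columns(col):
    mu = col.mean()
    centered = col - mu
    var = (centered * centered).mean()
    v = var.data if isinstance(var, Tensor) else var
    if v < 1e-24:  # zero-variance column carries no signal
        return centered * 0.0
    return centered * ad.power(var, -0.5)


@dataclass
class PairFeatures:
    """Goodness features for all n(n+1)/2 pairs of the selected parents.

    ``omega`` is (P, 2): column 0 the mean parental WBV, column 1 the GVP.
    May hold a Tensor when built inside the differentiable graph.
    """

    omega: object
    p: object
    kM: np.ndarray
    kP: np.ndarray
    selected: np.ndarray
    standardized: bool

    @property
    def n_pairs(self) -> int:
        om = self.omega
        return om.data.shape[0] if isinstance(om, Tensor) else om.shape[0]


def assemble_features(
    pop,
    selected,
    trait: TraitArchitecture,
    gmap: MarkerMap,
    standardize: bool = True,
) -> PairFeatures:
    """Build the full diallel's feature matrix from the selected parents.

    Minor allele frequencies are recomputed from the *current* population
    (the one being allocated), then WBV and GVP are evaluated on the selected
    parents.  With ``standardize`` each column is z-scored across pairs so
    the two metrics share a scale before entering the allocation softmax
    (zero-variance columns map to 0).
    """
    selected = np.asarray(selected, dtype=np.intp)
    if selected.size == 0:
        raise ValueError("no parents selected")
    w = _as_w(pop)
    p = minor_allele_freq(w)
    parents_w = ad.take_rows(w, selected)
    wbv_sel = wbv_individual(parents_w, trait, p)
    kM, kP = diallel_pairs(len(selected))
    col_wbv = wbv_pair_feature(wbv_sel, kM, kP)
    col_gvp = gvp_parents(parents_w, trait, gmap, kM, kP)
    if standardize:
        col_wbv = _standardize_columns(col_wbv)
        col_gvp = _standardize_columns(col_gvp)
    omega = ad.stack([col_wbv, col_gvp], axis=1)
    return PairFeatures(omega, p, kM, kP, selected, standardize)
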