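"""Gamete and progeny generation via the crossover-parity model.

A gamete inherits, at each marker, the allele from one of the parent's two
haplotypes.  Which haplotype is read follows the parity of the cumulative
count of crossover indicators: ``eta[j] ~ Bernoulli(r_adj[j])`` flags an
exchange between markers ``j-1`` and ``j``, and

    l_j = j + m * (sum_{j' <= j} eta[j'] mod 2)

is the source column within the parent's length-2m allele-score vector.  The
virtual rate at the first marker of every chromosome is 0.5, so each
chromosome independently re-randomizes which haplotype it starts from —
chromosomes segregate independently.

Because ``l`` is a pure function of the (discrete, pre-drawn) ``eta``,
progeny construction is a constant-index gather from the parents' allele
scores: the same code path serves hard binary parents and in-graph soft
parents, and gradients flow through the gathered values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import MarkerMap

__all__ = [
    "SegregationDraws",
    "GameteTrace",
    "sample_segregation",
    "crossover_source_columns",
    "gamete_from_parent",
    "progeny_from_pair",
    "progeny_batch",
]


@dataclass
class SegregationDraws:
    """Bernoulli crossover indicators, shape (n_slots, n_pairs, m)."""

    eta: np.ndarray
    seed: int

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=np.int8)
        if self.eta.ndim != 3:
            raise ValueError("eta must be (n_slots, n_pairs, m)")


@dataclass
class GameteTrace:
    """A single gamete plus the source columns it was read from."""

    l: np.ndarray
    gamete: np.ndarray


def sample_segregation(
    gmap: MarkerMap, n_slots: int, n_pairs: int, seed: int
) -> SegregationDraws:
    """Draw independent crossover indicators at the map's adjacent rates."""
    if n_slots < 1 or n_pairs < 1:
        raise ValueError("n_slots and n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_slots, n_pairs, gmap.m))
    return SegregationDraws((u < gmap.r_adj).astype(np.int8), seed)


def crossover_source_columns(eta: np.ndarray) -> np.ndarray:
    """Source-column indices ``l`` (values in {j, j+m}) from indicators.

    Vectorized over any leading axes; the marker axis is last.
    """
    eta = np.asarray(eta)
    m = eta.shape[-1]
    parity = np.cumsum(eta, axis=-1) % 2
    return np.arange(m) + m * parity


def gamete_from_parent(parent_w: np.ndarray, eta_row: np.ndarray) -> GameteTrace:
    """One gamete from one parent given one row of crossover indicators."""
    parent_w = np.asarray(parent_w)
    eta_row = np.asarray(eta_row)
    m = eta_row.shape[-1]
    if parent_w.shape[-1] != 2 * m:
        raise ValueError("parent vector must have length 2m")
    l = crossover_source_columns(eta_row)
    return GameteTrace(l, parent_w[l])


def progeny_from_pair(
    w_kM: np.ndarray, w_kP: np.ndarray, eta_M: np.ndarray, eta_P: np.ndarray
) -> np.ndarray:
    """One progeny: gamete from kM (first m entries) then gamete from kP."""
    gm = gamete_from_parent(w_kM, eta_M).gamete
    gp = gamete_from_parent(w_kP, eta_P).gamete
    return np.concatenate([gm, gp])


def progeny_batch(
    parents_w: np.ndarray,
    kM: np.ndarray,
    kP: np.ndarray,
    eta_M: np.ndarray,
    eta_P: np.ndarray,
) -> np.ndarray:
    """Vectorized hard progeny generation.

    ``parents_w``: (n, 2m) binary parents; ``kM``/``kP``: per-progeny parent
    row indices, shape (N,); ``eta_M``/``eta_P``: (N, m).  Returns (N, 2m).
    """
    parents_w = np.asarray(parents_w)
    m = eta_M.shape[-1]
    lM = crossover_source_columns(eta_M)
    lP = crossover_source_columns(eta_P)
    kM = np.asarray(kM, dtype=np.intp)
    kP = np.asarray(kP, dtype=np.intp)
    gm = parents_w[kM[:, None], lM]
    gp = parents_w[kP[:, None], lP]
    return np.concatenate([gm, gp], axis=1)
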