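"""Predetermined parent-selection strategies.

Three truncation-style strategies pick the ``n`` parent candidates each
generation, ranked by weighted breeding value (WBV):

* **SI1** — the n (default 15) individuals with the highest WBV; the
  strongest selection intensity.
* **SI2** — hierarchical (Ward) clustering of individual marker dosages into
  n_clusters (default 25) groups, then the top-WBV individual of each group;
  trades intensity for diversity.
* **SI3** — as SI1 with n = 50; the weakest intensity.

Selection is deterministic given the population (ties in WBV break toward
the lower row index).  When invoked on an in-graph soft population the
ranking is computed from the soft dosages but treated as a constant of the
graph — gradients flow through the selected allele scores, not through the
discrete ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .autodiff import Tensor
from .genome import Population, TraitArchitecture
from .metrics import minor_allele_freq, wbv_individual

__all__ = ["SelectionResult", "select_si1", "select_si2", "select_si3", "select"]

STRATEGY_DEFAULT_N = {"SI1": 15, "SI2": 25, "SI3": 50}


@dataclass
class SelectionResult:
    indices: np.ndarray
    n: int
    strategy_id: str


def _hard_w(pop) -> np.ndarray:
    if isinstance(pop, Population):
        return np.asarray(pop.w, dtype=float)
    if isinstance(pop, Tensor):
        return pop.data
    return np.asarray(pop, dtype=float)


def _wbv_constant(pop, trait: TraitArchitecture) -> np.ndarray:
    """WBV used for ranking only — always a detached ndarray."""
    w = _hard_w(pop)
    p = minor_allele_freq(w)
    return wbv_individual(w, trait, p)


def _top_by_wbv(wbv: np.ndarray, candidates: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n largest WBVs among candidates, lower index on ties."""
    order = np.lexsort((candidates, -wbv[candidates]))
    return candidates[order[:n]]


def select_si1(pop, trait: TraitArchitecture, n: int = 15) -> SelectionResult:
    wbv = _wbv_constant(pop, trait)
    if n > len(wbv):
        raise ValueError(f"cannot select {n} parents from {len(wbv)} individuals")
    idx = _top_by_wbv(wbv, np.arange(len(wbv)), n)
    return SelectionResult(idx, n, "SI1")


def select_si2(pop, trait: TraitArchitecture, n_clusters: int = 25) -> SelectionResult:
    w = _hard_w(pop)
    n_ind = w.shape[0]
    if n_clusters > n_ind:
        raise ValueError(f"cannot form {n_clusters} clusters from {n_ind} individuals")
    wbv = _wbv_constant(pop, trait)
    m = w.shape[1] // 2
    dosage = w[:, :m] + w[:, m:]
    labels = AgglomerativeClustering(
        n_clusters=n_clusters, linkage="ward"
    ).fit_predict(dosage)
    picks = [
        _top_by_wbv(wbv, np.flatnonzero(labels == c), 1)[0]
        for c in range(n_clusters)
    ]
    return SelectionResult(np.sort(np.asarray(picks, dtype=np.intp)), n_clusters, "SI2")


def select_si3(pop, trait: TraitArchitecture, n: int = 50) -> SelectionResult:
    res = select_si1(pop, trait, n)
    return SelectionResult(res.indices, n, "SI3")


def select(pop, trait: TraitArchitecture, strategy: str, n: int | None = None) -> SelectionResult:
    """Dispatch on strategy name; ``n`` overrides the full-scale default."""
    strategy = strategy.upper()
    if strategy not in STRATEGY_DEFAULT_N:
        raise ValueError(f"unknown selection strategy {strategy!r}")
    n = STRATEGY_DEFAULT_N[strategy] if n is None else n
    if strategy == "SI2":
        return select_si2(pop, trait, n_clusters=n)
    if strategy == "SI1":
        return select_si1(pop, trait, n)
    return select_si3(pop, trait, n)
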