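"""Gradient-based optimization of the allocation weights (GORA).

The expected final-generation merit is maximized by stochastic gradient
ascent on the unconstrained pre-image ``nu(tau)`` of the allocation weights:
each epoch draws a fresh Monte-Carlo noise bank, averages F and dF/dnu over
``n_mc`` simulations, and steps ``nu <- nu + lr * dF/dnu``.  The bounded
transform keeps ``theta(tau)`` inside (0.5, 3.5) at every epoch.

Two gradient-optimized presets differ only in the initial GVP weight —
GORA1 starts with a larger emphasis on progeny variance than GORA2 — plus
the non-optimized equal-allocation baseline EQ (``theta = 0``, a uniform
softmax, never updated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffscheme import (
    AllocationParams,
    SchemeConfig,
    bounded_transform,
    expected_merit,
)
from .genome import MarkerMap, Population, TraitArchitecture

__all__ = [
    "OptimizationTrace",
    "bounded_transform",
    "strategy_preset",
    "sgd_optimize",
]

# initial nu per preset: (wbv, gvp); the binding constraint is the ordering
# theta_GVP(GORA1) > theta_GVP(GORA2)
PRESET_INIT_NU = {
    "GORA1": (0.0, 1.0),
    "GORA2": (0.0, -2.0),
}


@dataclass
class OptimizationTrace:
    """Per-epoch bookkeeping of an SGD run (epochs + 1 rows)."""

    epoch: list[int] = field(default_factory=list)
    F_mean: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    nu_history: list[np.ndarray] = field(default_factory=list)
    theta_history: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    def append(self, epoch: int, F: float, lr: float, nu: np.ndarray) -> None:
        self.epoch.append(epoch)
        self.F_mean.append(F)
        self.lr.append(lr)
        self.nu_history.append(nu.copy())
        self.theta_history.append(np.asarray(bounded_transform(nu)))

    def to_frame(self) -> pd.DataFrame:
        theta = np.stack(self.theta_history)
        T, d = theta.shape[1], theta.shape[2]
        cols = {
            "epoch": self.epoch,
            "F_mean": self.F_mean,
            "lr": self.lr,
        }
        for tau in range(T):
            for j in range(d):
                cols[f"theta_t{tau}_f{j}"] = theta[:, tau, j]
        return pd.DataFrame(cols)


def strategy_preset(name: str, T: int, d: int = 2) -> AllocationParams:
    """Initial parameters for GORA1/GORA2, or the fixed EQ policy."""
    name = name.upper()
    if name == "EQ":
        return AllocationParams.equal_allocation(T, d)
    if name not in PRESET_INIT_NU:
        raise ValueError(f"unknown strategy preset {name!r}")
    init = PRESET_INIT_NU[name]
    nu = np.tile(np.asarray(init[:d], dtype=float), (T, 1))
    return AllocationParams(nu=nu)


def step_decay_schedule(lr0: float = 0.1, decay: float = 0.5, every: int = 50):
    """Step-decay learning rate: lr0 * decay^(epoch // every)."""

    def schedule(epoch: int) -> float:
        return lr0 * decay ** (epoch // every)

    return schedule


def sgd_optimize(
    founders: Population,
    trait: TraitArchitecture,
    gmap: MarkerMap,
    init_nu: np.ndarray,
    epochs: int,
    n_mc: int,
    config: SchemeConfig,
    seed: int,
    lr0: float = 0.1,
    schedule=None,
) -> tuple[AllocationParams, OptimizationTrace]:
    """Stochastic gradient ascent on the Monte-Carlo expected merit.

    Fresh (g, eta) noise every epoch; returns the final parameters and a
    trace with epochs + 1 rows (the last row evaluates the final parameters
    without updating them).
    """
    if epochs < 1 or n_mc < 1:
        raise ValueError("epochs and n_mc must be >= 1")
    if schedule is None:
        schedule = step_decay_schedule(lr0=lr0)
    nu = np.atleast_2d(np.asarray(init_nu, dtype=float)).copy()
    ss = np.random.SeedSequence(seed)
    epoch_seeds = ss.generate_state(epochs + 1)
    trace = OptimizationTrace(seed=seed)
    for epoch in range(epochs):
        params = AllocationParams(nu=nu)
        res = expected_merit(
            founders, params, trait, gmap, n_mc,
            int(epoch_seeds[epoch]) % (2**31), config,
        )
        if res.grads_nu is None or not np.all(np.isfinite(res.grads_nu)):
            raise FloatingPointError(f"non-finite gradient at epoch {epoch}")
        lr = schedule(epoch)
        trace.append(epoch, res.F, lr, nu)
        nu = nu + lr * res.grads_nu  # ascent: maximize merit
    final_params = AllocationParams(nu=nu)
    res = expected_merit(
        founders, final_params, trait, gmap, n_mc,
        int(epoch_seeds[epochs]) % (2**31), config, compute_grads=False,
    )
    trace.append(epochs, res.F, schedule(epochs), nu)
    return final_params, trace
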