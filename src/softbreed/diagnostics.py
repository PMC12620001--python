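"""Gradient validation utilities.

Two diagnostics probe whether reverse-mode gradients of the stochastic
merit are trustworthy:

* a finite-difference oracle — central differences of the Monte-Carlo mean
  under common random numbers (the same frozen Gumbel and segregation draws
  at nu +/- h), compared component-wise against the averaged reverse-mode
  gradient;
* a two-parameter grid ("optical flow") field — F and dF/dnu evaluated on a
  lattice over two free pre-image coordinates with one frozen noise bank, so
  the field is a deterministic surface whose arrows should point toward
  increasing merit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffscheme import (
    AllocationParams,
    SchemeConfig,
    draw_noise_bank,
    expected_merit,
)
from .genome import MarkerMap, Population, TraitArchitecture

__all__ = ["GradField", "finite_difference_check", "grid_gradient_field"]


def finite_difference_check(
    founders: Population,
    params: AllocationParams,
    trait: TraitArchitecture,
    gmap: MarkerMap,
    h: float,
    n_mc: int,
    seed: int,
    config: SchemeConfig,
    common_random_numbers: bool = True,
) -> dict:
    """Compare reverse-mode dF/dnu with central finite differences.

    Returns the AD gradient, the FD gradient and the max relative error over
    components whose magnitude exceeds 1e-8.  Without common random numbers
    each evaluation redraws noise, which destroys the comparison — exposed
    only to demonstrate why CRN is required.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    if h < 1e-7:
        raise ValueError("h below float central-difference resolution")
    if params.nu is None:
        raise ValueError("finite differences need an unconstrained nu policy")
    bank = draw_noise_bank(gmap, config, founders.n, seed, n_mc)

    def crn_bank(i):
        if common_random_numbers:
            return bank
        return draw_noise_bank(
            gmap, config, founders.n, seed + 1000 + i, n_mc
        )

    base = expected_merit(
        founders, params, trait, gmap, n_mc, seed, config, noise_bank=bank
    )
    ad_grad = base.grads_nu
    nu0 = params.nu
    fd = np.zeros_like(nu0)
    call = 0
    for idx in np.ndindex(*nu0.shape):
        for sign in (+1.0, -1.0):
            nu_pert = nu0.copy()
            nu_pert[idx] += sign * h
            res = expected_merit(
                founders, AllocationParams(nu=nu_pert), trait, gmap, n_mc,
                seed, config, noise_bank=crn_bank(call), compute_grads=False,
            )
            fd[idx] += sign * res.F
            call += 1
        fd[idx] /= 2.0 * h
    mask = np.abs(ad_grad) > 1e-8
    if mask.any():
        rel = np.abs(ad_grad - fd)[mask] / np.abs(ad_grad)[mask]
        max_rel = float(rel.max())
    else:
        max_rel = float(np.abs(ad_grad - fd).max())
    return {
        "ad_grad": ad_grad,
        "fd_grad": fd,
        "max_rel_error": max_rel,
        "F": base.F,
    }


@dataclass
class GradField:
    """Lattice of (nu, F, dF/dnu) over two free pre-image coordinates."""

    axis_specs: list[tuple[int, int, float, float]]  # (tau, feature, lo, hi)
    divisions: int
    table: pd.DataFrame

    @property
    def n_nodes(self) -> int:
        return len(self.table)


def grid_gradient_field(
    founders: Population,
    trait: TraitArchitecture,
    gmap: MarkerMap,
    axis_specs: list[tuple[int, int, float, float]],
    config: SchemeConfig,
    n_mc: int,
    seed: int,
    divisions: int = 50,
    base_nu: np.ndarray | None = None,
) -> GradField:
    """Evaluate F and dF/dnu on a (divisions+1)^2 lattice.

    ``axis_specs`` names exactly two free coordinates as (tau, feature_index,
    lo, hi); all other entries of nu stay at ``base_nu`` (default 0).  One
    frozen noise bank is shared by every node, making the field a
    deterministic surface.
    """
    if len(axis_specs) != 2:
        raise ValueError("exactly two grid axes are required")
    if divisions < 1:
        raise ValueError("divisions must be >= 1")
    for tau, feat, lo, hi in axis_specs:
        if hi <= lo:
            raise ValueError("empty axis domain")
        if not (0 <= tau < config.generations):
            raise ValueError("axis generation outside the scheme")
    d = config.n_features
    nu0 = (
        np.zeros((config.generations, d))
        if base_nu is None
        else np.atleast_2d(np.asarray(base_nu, dtype=float)).copy()
    )
    bank = draw_noise_bank(gmap, config, founders.n, seed, n_mc)
    (t1, f1, lo1, hi1), (t2, f2, lo2, hi2) = axis_specs
    ax1 = np.linspace(lo1, hi1, divisions + 1)
    ax2 = np.linspace(lo2, hi2, divisions + 1)
    rows = []
    for v1 in ax1:
        for v2 in ax2:
            nu = nu0.copy()
            nu[t1, f1] = v1
            nu[t2, f2] = v2
            res = expected_merit(
                founders, AllocationParams(nu=nu), trait, gmap, n_mc, seed,
                config, noise_bank=bank,
            )
            rows.append(
                {
                    "nu1": v1,
                    "nu2": v2,
                    "F": res.F,
                    "dF_dnu1": res.grads_nu[t1, f1],
                    "dF_dnu2": res.grads_nu[t2, f2],
                }
            )
    return GradField(axis_specs, divisions, pd.DataFrame(rows))
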