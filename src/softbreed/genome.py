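"""Marker maps, founder populations, trait architectures and genotypic values.

A scheme is defined over ``m`` biallelic markers laid out on ``C``
chromosomes with genetic positions in centimorgans.  Genetic distances are
converted to recombination rates with the Haldane map function; markers on
different chromosomes recombine freely (r = 0.5).  Every marker is a QTL: an
individual's genotypic value is ``alpha . w`` where ``w`` stacks its two
binary haplotypes (length ``2m``) and ``alpha`` duplicates the per-marker
additive effects.

Founder haplotypes are synthesized by a Markov copy process along each
chromosome: each marker's allele is copied from the previous marker with
probability ``exp(-ld_decay * d)`` (``d`` the gap in cM) and otherwise drawn
fresh, with the fresh-draw frequency adjusted so the marginal allele
frequency tracks a per-marker target drawn from ``Uniform(maf_range)``.  This
produces distance-decaying linkage disequilibrium with two interpretable
knobs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor

__all__ = [
    "MarkerMap",
    "Population",
    "TraitArchitecture",
    "haldane",
    "build_marker_map",
    "simulate_founders",
    "sample_trait",
    "genotypic_values",
    "read_marker_map",
    "write_marker_map",
    "read_haplotypes",
    "write_haplotypes",
    "read_effects",
    "write_effects",
    "write_vcf",
]


def haldane(d_cM):
    """Haldane map function: recombination rate for a gap of ``d_cM``."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass
class MarkerMap:
    """Chromosome layout and derived recombination rates.

    ``r_adj[j]`` is the recombination rate between markers ``j-1`` and ``j``;
    the first marker of each chromosome carries the virtual rate 0.5 so that
    the haplotype choice is re-randomized at every chromosome start (and at
    the very first marker, mirroring the virtual r_01 = 0.5 of the gamete
    model).
    """

    marker_id: list[str]
    chrom: np.ndarray
    pos_cM: np.ndarray
    r_adj: np.ndarray = field(init=False)
    _r_pair: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.intp)
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        m = len(self.marker_id)
        if m < 1:
            raise ValueError("a marker map needs at least one marker")
        if len(self.chrom) != m or len(self.pos_cM) != m:
            raise ValueError("marker_id, chrom and pos_cM must have equal length")
        if np.any(self.pos_cM < 0):
            raise ValueError("genetic positions must be non-negative")
        # within-chromosome positions must be non-decreasing
        for c in np.unique(self.chrom):
            p = self.pos_cM[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions on chromosome {c} are not sorted")
        starts = self.chrom_starts
        gaps = np.diff(self.pos_cM, prepend=self.pos_cM[0])
        r = haldane(gaps)
        r[starts] = 0.5
        self.r_adj = r

    @property
    def m(self) -> int:
        return len(self.marker_id)

    @property
    def n_chrom(self) -> int:
        return len(np.unique(self.chrom))

    @property
    def chrom_starts(self) -> np.ndarray:
        """Boolean mask of markers that begin a chromosome."""
        mask = np.zeros(self.m, dtype=bool)
        mask[0] = True
        mask[1:] = self.chrom[1:] != self.chrom[:-1]
        return mask

    def r_pair(self) -> np.ndarray:
        """Pairwise recombination-rate matrix (m x m), cached.

        Haldane of the position difference within a chromosome, 0.5 across
        chromosomes, 0 on the diagonal.
        """
        if self._r_pair is None:
            d = np.abs(self.pos_cM[:, None] - self.pos_cM[None, :])
            r = haldane(d)
            r[self.chrom[:, None] != self.chrom[None, :]] = 0.5
            self._r_pair = r
        return self._r_pair


@dataclass
class Population:
    """Phased allele scores for N individuals.

    ``w`` has shape (N, 2m): columns ``0..m-1`` are the maternal haplotype,
    ``m..2m-1`` the paternal one.  Hard populations are exactly binary; the
    in-graph soft populations produced by the differentiable scheme live in
    [0, 1] and are carried as Tensors outside this class.
    """

    w: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.w = np.asarray(self.w)
        if self.w.ndim != 2 or self.w.shape[1] % 2 != 0:
            raise ValueError("w must be N x 2m")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def m(self) -> int:
        return self.w.shape[1] // 2

    def dosage(self) -> np.ndarray:
        m = self.m
        return self.w[:, :m] + self.w[:, m:]


@dataclass
class TraitArchitecture:
    """Additive marker effects; ``alpha`` duplicates ``beta`` per haplotype."""

    beta: np.ndarray
    alpha: np.ndarray = field(init=False)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.concatenate([self.beta, self.beta])

    @property
    def m(self) -> int:
        return len(self.beta)


def build_marker_map(
    chrom_sizes: list[int],
    spacing_cM: float | None = None,
    positions: list[np.ndarray] | None = None,
) -> MarkerMap:
    """Lay out markers on chromosomes, evenly spaced or at given positions."""
    if not chrom_sizes or any(s < 1 for s in chrom_sizes):
        raise ValueError("every chromosome must carry at least one marker")
    if positions is None:
        if spacing_cM is None or spacing_cM <= 0:
            raise ValueError("spacing_cM must be positive")
        positions = [np.arange(s, dtype=float) * spacing_cM for s in chrom_sizes]
    if len(positions) != len(chrom_sizes):
        raise ValueError("positions must match chrom_sizes")
    chrom, pos, ids = [], [], []
    for c, (s, p) in enumerate(zip(chrom_sizes, positions), start=1):
        p = np.asarray(p, dtype=float)
        if len(p) != s:
            raise ValueError(f"chromosome {c}: {len(p)} positions for {s} markers")
        chrom.extend([c] * s)
        pos.extend(p.tolist())
        ids.extend(f"M{c}_{j + 1}" for j in range(s))
    return MarkerMap(ids, np.array(chrom), np.array(pos))


def simulate_founders(
    gmap: MarkerMap,
    n_individuals: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_decay: float = 0.1,
) -> Population:
    """Synthesize 2N phased founder haplotypes over the map.

    Per-marker target allele frequencies are drawn from ``Uniform(maf_range)``
    and the Markov copy process (see module docstring) induces LD that decays
    with genetic distance at rate ``ld_decay`` per cM.  Bit-reproducible from
    ``seed``.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if n_individuals < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    m = gmap.m
    target = rng.uniform(lo, hi, size=m)
    hap = np.empty((n_hap, m), dtype=np.int8)
    starts = gmap.chrom_starts
    p_prev = 0.0
    for j in range(m):
        if starts[j]:
            rho = 0.0
        else:
            d = gmap.pos_cM[j] - gmap.pos_cM[j - 1]
            rho = float(np.exp(-ld_decay * d))
        if rho >= 1.0:
            hap[:, j] = hap[:, j - 1]
            p_marg = p_prev
        else:
            # fresh-draw frequency adjusted so the marginal hits the target
            f_eff = np.clip((target[j] - rho * p_prev) / (1.0 - rho), 0.0, 1.0)
            fresh = rng.random(n_hap) < f_eff
            if rho > 0.0:
                copy = rng.random(n_hap) < rho
                hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
            else:
                hap[:, j] = fresh
            p_marg = rho * p_prev + (1.0 - rho) * f_eff
        p_prev = p_marg
    # interleave into (N, 2m): maternal haplotype block then paternal block
    w = np.concatenate([hap[0::2], hap[1::2]], axis=1)
    return Population(w.astype(np.int8), generation=0)


def sample_trait(gmap: MarkerMap, seed: int, effect_sd: float = 1.0) -> TraitArchitecture:
    """Draw i.i.d. Normal(0, effect_sd) additive effects, one per marker."""
    if effect_sd <= 0:
        raise ValueError("effect_sd must be positive")
    rng = np.random.default_rng(seed)
    return TraitArchitecture(rng.normal(0.0, effect_sd, size=gmap.m))


def genotypic_values(pop, trait: TraitArchitecture):
    """``alpha . w_i`` for every individual; accepts hard or soft populations.

    ``pop`` may be a :class:`Population`, an (N, 2m) ndarray, or an in-graph
    Tensor; the return type matches.
    """
    w = pop.w if isinstance(pop, Population) else pop
    ncol = w.shape[1] if not isinstance(w, Tensor) else w.data.shape[1]
    if ncol != 2 * trait.m:
        raise ValueError("population and trait dimensions disagree")
    return w @ trait.alpha


# ----------------------------------------------------------------------
# plain-text formats


def write_marker_map(gmap: MarkerMap, path: str | Path) -> None:
    pd.DataFrame(
        {"marker_id": gmap.marker_id, "chrom": gmap.chrom, "pos_cM": gmap.pos_cM}
    ).to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "chrom", "pos_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker map needs columns {sorted(required)}")
    return MarkerMap(
        df["marker_id"].astype(str).tolist(),
        df["chrom"].to_numpy(dtype=np.intp),
        df["pos_cM"].to_numpy(dtype=float),
    )


def write_haplotypes(pop: Population, gmap: MarkerMap, path: str | Path) -> None:
    """2N rows (individual i's maternal then paternal haplotype), m columns."""
    m = pop.m
    rows = np.empty((2 * pop.n, m), dtype=np.int64)
    rows[0::2] = pop.w[:, :m]
    rows[1::2] = pop.w[:, m:]
    pd.DataFrame(rows, columns=gmap.marker_id).to_csv(path, sep="\t", index=False)


def read_haplotypes(path: str | Path) -> Population:
    df = pd.read_csv(path, sep="\t")
    vals = df.to_numpy()
    bad = np.argwhere((vals != 0) & (vals != 1))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-binary haplotype entry {vals[r, c]!r} at row {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    if vals.shape[0] % 2 != 0:
        raise ValueError("haplotype file must have an even number of rows")
    w = np.concatenate([vals[0::2], vals[1::2]], axis=1)
    return Population(w.astype(np.int8))


def write_effects(trait: TraitArchitecture, gmap: MarkerMap, path: str | Path) -> None:
    pd.DataFrame({"marker_id": gmap.marker_id, "effect": trait.beta}).to_csv(
        path, sep="\t", index=False
    )


def read_effects(path: str | Path, gmap: MarkerMap) -> TraitArchitecture:
    df = pd.read_csv(path, sep="\t")
    if not {"marker_id", "effect"}.issubset(df.columns):
        raise ValueError("effects file needs columns marker_id, effect")
    lookup = dict(zip(df["marker_id"].astype(str), df["effect"].astype(float)))
    unknown = set(lookup) - set(gmap.marker_id)
    if unknown:
        raise ValueError(f"effects file has unknown marker ids: {sorted(unknown)[:5]}")
    missing = [mid for mid in gmap.marker_id if mid not in lookup]
    if missing:
        raise ValueError(f"effects file is missing markers: {missing[:5]}")
    return TraitArchitecture(np.array([lookup[mid] for mid in gmap.marker_id]))


def write_vcf(pop: Population, gmap: MarkerMap, path: str | Path) -> None:
    """Minimal phased-VCF export (GT only) for interoperability.

    Genetic positions are scaled to integer bp (1 cM -> 10 kb) since VCF POS
    is physical; the mapping is documented here and is only for viewing.
    """
    m = pop.m
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    samples = [f"IND{i + 1}" for i in range(pop.n)]
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(samples) + "\n")
    mat, pat = pop.w[:, :m], pop.w[:, m:]
    for j in range(m):
        pos_bp = int(round(gmap.pos_cM[j] * 10000)) + 1
        gts = "\t".join(f"{mat[i, j]}|{pat[i, j]}" for i in range(pop.n))
        buf.write(
            f"{gmap.chrom[j]}\t{pos_bp}\t{gmap.marker_id[j]}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
        )
    Path(path).write_text(buf.getvalue())
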