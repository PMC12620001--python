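"""Run configuration, seed splitting and run manifests.

A single :class:`RunConfig` carries every scheme constant (scenario, sizes,
selection and allocation strategy, SGD and Monte-Carlo settings) plus one
global seed.  Component seeds are derived deterministically from the global
seed and the component name, so any sub-computation is reproducible in
isolation.  Two scale profiles are bundled: ``full`` (the full-size study
conditions) and ``desk`` (reduced sizes for interactive use and testing).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .diffscheme import SchemeConfig

__all__ = ["RunConfig", "split_seed", "write_manifest"]

SCENARIO_M = {1: 30, 2: 500}

SCALE_PROFILES = {
    "full": dict(n_individuals=250, epochs=200, mc_reps=100, n_reps=10000),
    "desk": dict(n_individuals=60, epochs=30, mc_reps=20, n_reps=200),
}


def split_seed(seed: int, component: str) -> int:
    """Deterministic per-component seed derived from (seed, component)."""
    digest = hashlib.sha256(f"{seed}:{component}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    scenario: int = 2
    m: int | None = None  # None -> scenario default
    n_chrom: int = 10
    chrom_length_cM: float = 100.0
    n_individuals: int = 250
    generations: int = 4
    top_k: int = 5
    selection: str = "SI2"
    n_selected: int | None = None
    strategy: str = "GORA2"
    temperature: float = 0.5
    epochs: int = 200
    mc_reps: int = 100
    lr: float = 0.1
    n_reps: int = 10000
    seed: int = 0
    scale_profile: str = "full"

    def __post_init__(self):
        if self.m is None:
            self.m = SCENARIO_M.get(self.scenario)
            if self.m is None:
                raise ValueError(f"unknown scenario {self.scenario}; supply m")
        if min(self.m, self.n_individuals, self.generations, self.top_k) < 1:
            raise ValueError("all counts must be positive")
        if self.top_k > self.n_individuals:
            raise ValueError("top_k cannot exceed the population size")
        if self.scale_profile not in SCALE_PROFILES:
            raise ValueError(f"unknown scale profile {self.scale_profile!r}")

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        base = dict(SCALE_PROFILES["desk"], scale_profile="desk")
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def scheme_config(self) -> SchemeConfig:
        return SchemeConfig(
            generations=self.generations,
            top_k=self.top_k,
            selection=self.selection,
            n_selected=self.n_selected,
            temperature=self.temperature,
        )

    def component_seed(self, component: str) -> int:
        return split_seed(self.seed, component)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def write_manifest(config: RunConfig, path: str | Path, extra: dict | None = None) -> None:
    """Persist everything needed to reproduce a run's outputs exactly."""
    import softbreed

    doc = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "softbreed_version": softbreed.__version__,
    }
    if extra:
        doc["extra"] = extra
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
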