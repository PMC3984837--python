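"""Declarative run configuration.

A run is described by a flat YAML document with sections mirroring the
spec dataclasses (protocol, erp, preproc, swarm), a weights section (a
named preset ``case: case7`` or explicit ``w1``/``w2``) and five
independent seeds (data, split, folds, swarm, master). Unknown keys are
errors, not warnings -- silent misconfiguration of the study constants is
worse than a failed run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .datasets import ErpSpec, ProtocolSpec
from .fitness import WEIGHT_CASES, FitnessWeights
from .preprocessing import PreprocSpec
from .swarm import SwarmConfig

__all__ = ["Seeds", "RunConfig", "load_config", "build_config", "derive_seeds"]

_SECTIONS = ("protocol", "erp", "preproc", "swarm", "weights", "seeds")


@dataclass(frozen=True)
class Seeds:
    data: int = 0
    split: int = 1
    folds: int = 2
    swarm: int = 3
    master: int = 4


@dataclass
class RunConfig:
    protocol: ProtocolSpec
    erp: ErpSpec
    preproc: PreprocSpec
    swarm: SwarmConfig
    weights: FitnessWeights
    seeds: Seeds

    def resolved(self) -> dict:
        """Fully explicit dictionary for the run manifest."""
        out = {
            "protocol": dataclasses.asdict(self.protocol),
            "erp": dataclasses.asdict(self.erp),
            "preproc": dataclasses.asdict(self.preproc),
            "swarm": dataclasses.asdict(self.swarm),
            "weights": {"w1": self.weights.w1, "w2": self.weights.w2},
            "seeds": dataclasses.asdict(self.seeds),
        }
        out["erp"]["informative_channels"] = list(self.erp.informative_channels)
        return out


def derive_seeds(seed: int) -> Seeds:
    """Five independent sub-seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(5)
    # keep within int32 range for portability of serialized manifests
    vals = [int(s) % (2**31) for s in state]
    return Seeds(*vals)


def _build(cls, section: dict | None, name: str):
    section = dict(section or {})
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in section '{name}': {sorted(unknown)}")
    if "informative_channels" in section:
        section["informative_channels"] = tuple(section["informative_channels"])
    for key in ("baseline_window_ms", "feature_window_ms"):
        if key in section:
            section[key] = tuple(section[key])
    return cls(**section)


def _build_weights(section: dict | None) -> FitnessWeights:
    section = dict(section or {})
    if "case" in section:
        case = section.pop("case")
        if section:
            raise ValueError("weights: give either 'case' or 'w1'/'w2', not both")
        if case not in WEIGHT_CASES:
            raise ValueError(f"unknown weight case '{case}'; "
                             f"choose from {sorted(WEIGHT_CASES)}")
        return WEIGHT_CASES[case]
    unknown = set(section) - {"w1", "w2"}
    if unknown:
        raise ValueError(f"unknown keys in section 'weights': {sorted(unknown)}")
    if not section:
        return FitnessWeights(0.5, 0.5)
    return FitnessWeights(float(section["w1"]), float(section["w2"]))


def build_config(raw: dict | None, seed: int | None = None) -> RunConfig:
    """Build a validated RunConfig from a parsed YAML mapping.

    If ``seed`` is given and the document has no seeds section, the five
    run seeds are derived from it deterministically.
    """
    raw = dict(raw or {})
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    if "seeds" in raw and raw["seeds"] is not None:
        seeds = _build(Seeds, raw["seeds"], "seeds")
    elif seed is not None:
        seeds = derive_seeds(seed)
    else:
        seeds = Seeds()
    protocol = _build(ProtocolSpec, raw.get("protocol"), "protocol")
    swarm_section = dict(raw.get("swarm") or {})
    swarm_section.setdefault("n_bits", protocol.n_channels)
    swarm_section.setdefault("seed", seeds.swarm)
    return RunConfig(
        protocol=protocol,
        erp=_build(ErpSpec, raw.get("erp"), "erp"),
        preproc=_build(PreprocSpec, raw.get("preproc"), "preproc"),
        swarm=_build(SwarmConfig, swarm_section, "swarm"),
        weights=_build_weights(raw.get("weights")),
        seeds=seeds,
    )


def load_config(path, seed: int | None = None) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f)
    return build_config(raw, seed=seed)
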