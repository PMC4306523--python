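"""Hypothesis space of DCM structures over the three-region parietal-visual hierarchy.

The network is a strict hierarchy r-V5 -> r-pSPL -> r-aSPL with reciprocal
endogenous coupling only between adjacent levels (no direct V5<->aSPL edge).
Candidate models share that endogenous backbone and differ only in

* which of the four inter-regional connections carry a modulatory (B) effect
  during perceptual-switch events (the same subset for spontaneous and
  stimulus-driven switches), and
* whether r-pSPL and/or r-aSPL receive a direct driving input during switch
  events (r-V5 always does, during visual stimulation and both switch types).

That gives 2**4 x 2**2 = 64 models, partitioned into four families by the
direction class of the modulated connections: no-modulation, bottom-up,
top-down, bidirectional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionSet",
    "Connection",
    "DCMModelSpec",
    "ModelFamily",
    "DEFAULT_REGIONS",
    "MODULABLE_CONNECTIONS",
    "INPUT_LABELS",
    "enumerate_model_space",
    "classify_family",
    "partition_families",
    "model_space_table",
    "save_model_space",
    "load_model_space",
]

#: Input (experimental condition) ordering used everywhere downstream.
INPUT_LABELS = ("fixation", "stimulation", "rivalry_switch", "replay_switch")
#: Indices of the two switch inputs within INPUT_LABELS.
SWITCH_INPUTS = (2, 3)


class ModelSpaceError(ValueError):
    """Structural error in a model specification or enumeration."""


@dataclass(frozen=True)
class RegionSet:
    """Ordered regions, bottom of the hierarchy first.

    The position in ``labels`` is the hierarchy level (0 = lowest). Endogenous
    connections are allowed only between adjacent levels.
    """

    labels: tuple[str, ...] = ("r-V5", "r-pSPL", "r-aSPL")

    def __post_init__(self) -> None:
        if len(self.labels) != 3:
            raise ModelSpaceError(
                f"expected exactly 3 regions, got {len(self.labels)}"
            )
        if len(set(self.labels)) != 3:
            raise ModelSpaceError("region labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    def level(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ModelSpaceError(f"unknown region {label!r}") from None

    def index(self, label: str) -> int:
        return self.level(label)

    def a_mask(self) -> np.ndarray:
        """Endogenous adjacency (target, source): self-loops + adjacent levels."""
        n = self.n
        mask = np.eye(n, dtype=bool)
        for i in range(n - 1):
            mask[i, i + 1] = True
            mask[i + 1, i] = True
        return mask


DEFAULT_REGIONS = RegionSet()


@dataclass(frozen=True, order=True)
class Connection:
    """A directed inter-regional connection."""

    source: str
    target: str

    def direction_class(self, regions: RegionSet = DEFAULT_REGIONS) -> str:
        ls, lt = regions.level(self.source), regions.level(self.target)
        if ls == lt:
            raise ModelSpaceError(f"self-connection {self} has no direction class")
        return "bottom-up" if ls < lt else "top-down"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.source}->{self.target}"


def _modulable_connections(regions: RegionSet) -> tuple[Connection, ...]:
    """The four switch-modulable connections, in canonical bit order."""
    v5, pspl, aspl = regions.labels
    return (
        Connection(aspl, pspl),
        Connection(pspl, aspl),
        Connection(pspl, v5),
        Connection(v5, pspl),
    )


MODULABLE_CONNECTIONS = _modulable_connections(DEFAULT_REGIONS)


def _free_input_regions(regions: RegionSet) -> tuple[str, str]:
    """Regions whose switch-event driving input is a free bit (pSPL, aSPL)."""
    return (regions.labels[1], regions.labels[2])


@dataclass(frozen=True)
class DCMModelSpec:
    """Binary structure of one candidate model.

    ``model_id`` is the canonical 6-bit integer: bits 0-3 select modulated
    connections (order of :data:`MODULABLE_CONNECTIONS`), bits 4-5 select
    switch-event driving input to pSPL and aSPL respectively. The same
    b-subset and c-bits apply to both switch inputs.
    """

    model_id: int
    b_connections: tuple[Connection, ...]
    c_regions_switch: tuple[str, ...]
    regions: RegionSet = field(default=DEFAULT_REGIONS)

    def __post_init__(self) -> None:
        modulable = set(_modulable_connections(self.regions))
        for conn in self.b_connections:
            if conn not in modulable:
                raise ModelSpaceError(
                    f"connection {conn} is not modulable in this region set"
                )
        v5 = self.regions.labels[0]
        if v5 not in self.c_regions_switch:
            raise ModelSpaceError(
                f"driving input to {v5} during switches is fixed and must be present"
            )

    # -- mask views -------------------------------------------------------
    @property
    def a_mask(self) -> np.ndarray:
        return self.regions.a_mask()

    @property
    def b_mask(self) -> np.ndarray:
        """(n_inputs, n, n) modulation support; identical for both switch inputs."""
        n = self.regions.n
        mask = np.zeros((len(INPUT_LABELS), n, n), dtype=bool)
        for conn in self.b_connections:
            i = self.regions.index(conn.target)
            j = self.regions.index(conn.source)
            for k in SWITCH_INPUTS:
                mask[k, i, j] = True
        return mask

    @property
    def c_mask(self) -> np.ndarray:
        """(n, n_inputs) driving-input support; fixation drives nothing."""
        n = self.regions.n
        mask = np.zeros((n, len(INPUT_LABELS)), dtype=bool)
        v5 = self.regions.index(self.regions.labels[0])
        mask[v5, 1] = True  # visual stimulation -> V5
        for label in self.c_regions_switch:
            i = self.regions.index(label)
            for k in SWITCH_INPUTS:
                mask[i, k] = True
        return mask

    @property
    def n_free_parameters(self) -> int:
        """Free A (off-diagonal), B and C entries (self-loops are fixed)."""
        a_free = int(self.a_mask.sum()) - self.regions.n
        return a_free + int(self.b_mask.sum()) + int(self.c_mask.sum())

    def to_record(self) -> dict:
        return {
            "model_id": self.model_id,
            "b_connections": [str(c) for c in self.b_connections],
            "c_regions_switch": list(self.c_regions_switch),
        }

    @classmethod
    def from_record(cls, rec: dict, regions: RegionSet = DEFAULT_REGIONS) -> "DCMModelSpec":
        conns = []
        for s in rec["b_connections"]:
            src, tgt = s.split("->")
            conns.append(Connection(src, tgt))
        return cls(
            model_id=int(rec["model_id"]),
            b_connections=tuple(conns),
            c_regions_switch=tuple(rec["c_regions_switch"]),
            regions=regions,
        )


@dataclass(frozen=True)
class ModelFamily:
    """A named group of models sharing a modulation direction class."""

    name: str
    member_ids: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.member_ids)


FAMILY_NAMES = ("no-modulation", "bottom-up", "top-down", "bidirectional")


def enumerate_model_space(
    regions: RegionSet = DEFAULT_REGIONS,
    modulable: Sequence[Connection] | None = None,
    free_input_regions: Sequence[str] | None = None,
) -> list[DCMModelSpec]:
    """Enumerate every b-subset x free-c-bit combination, ordered by model_id.

    With the default three-region hierarchy this yields the full 64-model
    space (2**4 modulation subsets x 2**2 switch-input patterns).
    """
    if modulable is None:
        modulable = _modulable_connections(regions)
    if free_input_regions is None:
        free_input_regions = _free_input_regions(regions)
    nb, nc = len(modulable), len(free_input_regions)
    v5 = regions.labels[0]
    models = []
    for mid in range(2 ** (nb + nc)):
        b_conns = tuple(modulable[i] for i in range(nb) if mid >> i & 1)
        c_extra = tuple(
            free_input_regions[i] for i in range(nc) if mid >> (nb + i) & 1
        )
        models.append(
            DCMModelSpec(
                model_id=mid,
                b_connections=b_conns,
                c_regions_switch=(v5, *c_extra),
                regions=regions,
            )
        )
    return models


def classify_family(model: DCMModelSpec) -> str:
    """Family of one model by the direction classes of its modulated connections."""
    classes = {c.direction_class(model.regions) for c in model.b_connections}
    if not classes:
        return "no-modulation"
    if classes == {"bottom-up"}:
        return "bottom-up"
    if classes == {"top-down"}:
        return "top-down"
    return "bidirectional"


def partition_families(models: Iterable[DCMModelSpec]) -> list[ModelFamily]:
    """Partition the enumerated space into the four modulation families."""
    models = list(models)
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise ModelSpaceError("duplicate model_id in model list")
    members: dict[str, set[int]] = {name: set() for name in FAMILY_NAMES}
    for m in models:
        members[classify_family(m)].add(m.model_id)
    return [ModelFamily(name, frozenset(members[name])) for name in FAMILY_NAMES]


def model_space_table(models: Sequence[DCMModelSpec]) -> pd.DataFrame:
    """One row per model: id, modulated connections, switch inputs, family."""
    rows = []
    for m in models:
        rows.append(
            {
                "model_id": m.model_id,
                "family": classify_family(m),
                "b_connections": ";".join(str(c) for c in m.b_connections),
                "c_regions_switch": ";".join(m.c_regions_switch),
                "n_free_parameters": m.n_free_parameters,
            }
        )
    return pd.DataFrame(rows)


def save_model_space(models: Sequence[DCMModelSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_record() for m in models], fh, indent=1)


def load_model_space(path, regions: RegionSet = DEFAULT_REGIONS) -> list[DCMModelSpec]:
    with open(path) as fh:
        recs = json.load(fh)
    return [DCMModelSpec.from_record(r, regions) for r in recs]
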