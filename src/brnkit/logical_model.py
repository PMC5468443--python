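"""Multivalued logical (kinetic-logic) regulatory networks.

A biological regulatory network (BRN) is a directed graph of entities
(genes/proteins) with signed, thresholded regulations.  The dynamics of an
entity ``x`` are governed by *logical parameters* ``K_x(omega)``: the focal
(attracting) level of ``x`` when its set of *resources* is ``omega``.  A
regulator is a resource when it is currently "helping" its target — an
activator at or above its threshold, or an inhibitor below its threshold.

This module holds the static network description (entities, interactions,
parameter specifications and concrete parameterizations) and the model-file
schema; the asynchronous dynamics live in :mod:`brnkit.state_dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Entity",
    "Interaction",
    "ParameterSpec",
    "Parameterization",
    "LogicalNetwork",
    "regulators",
    "resources",
    "focal",
    "snoussi_holds",
    "read_model",
    "write_model",
    "network_to_dot",
]

ACTIVATION = "+"
INHIBITION = "-"

#: A resource set is a frozenset of regulator names of a given target.
ResourceSet = frozenset

#: A qualitative state is a tuple of integer levels following ``entity_order``.
State = tuple


class ModelError(ValueError):
    """Raised for malformed networks, states or parameterizations."""


@dataclass(frozen=True)
class Entity:
    """A network entity with a maximal qualitative expression level."""

    name: str
    max_level: int = 1

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise ModelError(f"entity {self.name!r}: max_level must be >= 1")


@dataclass(frozen=True)
class Interaction:
    """A signed, thresholded regulation ``source -> target``.

    ``sign`` is ``"+"`` (activation) or ``"-"`` (inhibition); the regulation
    is active once the source level reaches ``threshold``.
    """

    source: str
    target: str
    sign: str
    threshold: int = 1

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ModelError(f"interaction {self.source}->{self.target}: "
                             f"sign must be '+' or '-', got {self.sign!r}")
        if self.threshold < 1:
            raise ModelError(f"interaction {self.source}->{self.target}: "
                             f"threshold must be >= 1")


@dataclass(frozen=True)
class ParameterSpec:
    """Admissible focal levels for one (target, resource set) pair."""

    target: str
    resources: ResourceSet
    range: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.range:
            raise ModelError(f"K_{self.target}({set(self.resources) or '{}'}): "
                             "empty range")
        object.__setattr__(self, "resources", frozenset(self.resources))
        object.__setattr__(self, "range", tuple(sorted(set(self.range))))


class Parameterization(dict):
    """A complete map ``(target, resource set) -> focal level``.

    Keys are ``(target_name, frozenset_of_regulator_names)`` pairs.  Plain
    dict subclass so that candidate enumeration and JSON round-trips stay
    cheap and obvious.
    """

    def level(self, target: str, resource_set: Iterable[str]) -> int:
        key = (target, frozenset(resource_set))
        try:
            return self[key]
        except KeyError:
            raise ModelError(
                f"missing parameter K_{target}({set(key[1]) or '{}'})"
            ) from None


@dataclass
class LogicalNetwork:
    """A multivalued logical regulatory network.

    ``entity_order`` fixes the coordinate order of qualitative state vectors;
    it defaults to the declaration order of ``entities``.
    """

    entities: list[Entity]
    interactions: list[Interaction]
    parameter_specs: list[ParameterSpec] = field(default_factory=list)
    entity_order: tuple[str, ...] = ()
    selected: Parameterization | None = None

    def __post_init__(self) -> None:
        names = [e.name for e in self.entities]
        if len(set(names)) != len(names):
            raise ModelError("duplicate entity names")
        if not self.entity_order:
            self.entity_order = tuple(names)
        if sorted(self.entity_order) != sorted(names):
            raise ModelError("entity_order is not a permutation of entity names")
        by_name = {e.name: e for e in self.entities}
        seen_pairs = set()
        for ia in self.interactions:
            if ia.source not in by_name or ia.target not in by_name:
                raise ModelError(f"interaction {ia.source}->{ia.target}: "
                                 "unknown endpoint")
            if ia.threshold > by_name[ia.source].max_level:
                raise ModelError(f"interaction {ia.source}->{ia.target}: "
                                 "threshold exceeds source max_level")
            if (ia.source, ia.target) in seen_pairs:
                raise ModelError(f"duplicate interaction {ia.source}->{ia.target}")
            seen_pairs.add((ia.source, ia.target))
        self._by_name = by_name
        self._index = {n: i for i, n in enumerate(self.entity_order)}
        self._regulators = {
            e.name: tuple(sorted(ia.source for ia in self.interactions
                                 if ia.target == e.name))
            for e in self.entities
        }
        self._edge = {(ia.source, ia.target): ia for ia in self.interactions}
        for spec in self.parameter_specs:
            if spec.target not in by_name:
                raise ModelError(f"parameter spec for unknown target {spec.target!r}")
            if not spec.resources <= set(self._regulators[spec.target]):
                raise ModelError(
                    f"K_{spec.target}({set(spec.resources)}): resources are "
                    "not a subset of the target's regulators")
            if max(spec.range) > by_name[spec.target].max_level:
                raise ModelError(f"K_{spec.target}: range exceeds max_level")

    # -- accessors -------------------------------------------------------

    def entity(self, name: str) -> Entity:
        try:
            return self._by_name[name]
        except KeyError:
            raise ModelError(f"unknown entity {name!r}") from None

    def index(self, name: str) -> int:
        self.entity(name)
        return self._index[name]

    def interaction(self, source: str, target: str) -> Interaction:
        return self._edge[(source, target)]

    def max_levels(self) -> tuple[int, ...]:
        return tuple(self._by_name[n].max_level for n in self.entity_order)

    def n_states(self) -> int:
        n = 1
        for m in self.max_levels():
            n *= m + 1
        return n

    def check_state(self, state: Sequence[int]) -> State:
        if len(state) != len(self.entity_order):
            raise ModelError(f"state {state!r}: expected "
                             f"{len(self.entity_order)} levels")
        for name, lvl in zip(self.entity_order, state):
            if not 0 <= lvl <= self._by_name[name].max_level:
                raise ModelError(f"state {state!r}: level of {name} out of range")
        return tuple(state)

    def spec_for(self, target: str, resource_set: Iterable[str]) -> ParameterSpec:
        key = frozenset(resource_set)
        for spec in self.parameter_specs:
            if spec.target == target and spec.resources == key:
                return spec
        raise ModelError(f"no parameter spec K_{target}({set(key) or '{}'})")

    def complete_specs(self) -> None:
        """Check that specs cover every subset of regulators of every target."""
        have = {(s.target, s.resources) for s in self.parameter_specs}
        for name in self.entity_order:
            regs = self._regulators[name]
            for r in range(len(regs) + 1):
                for combo in combinations(regs, r):
                    if (name, frozenset(combo)) not in have:
                        raise ModelError(
                            f"missing parameter spec K_{name}({set(combo) or '{}'})")


def regulators(network: LogicalNetwork, target: str) -> list[str]:
    """Sources of all interactions into ``target``, sorted by name."""
    network.entity(target)
    return list(network._regulators[target])


def resources(network: LogicalNetwork, state: Sequence[int],
              target: str) -> ResourceSet:
    """The resource set of ``target`` in ``state``.

    A regulator ``u`` is a resource iff it currently pushes the target up:
    an activator with ``state[u] >= threshold``, or an inhibitor with
    ``state[u] < threshold`` (absence of an inhibitor is a resource).
    """
    state = network.check_state(state)
    members = set()
    for u in regulators(network, target):
        ia = network.interaction(u, target)
        level = state[network.index(u)]
        if (ia.sign == ACTIVATION) == (level >= ia.threshold):
            members.add(u)
    return frozenset(members)


def focal(network: LogicalNetwork, K: Parameterization,
          state: Sequence[int], target: str) -> int:
    """Focal level of ``target`` in ``state``: ``K_target(resources(state))``."""
    return K.level(target, resources(network, state, target))


def snoussi_holds(network: LogicalNetwork, K: Parameterization) -> bool:
    """Monotonicity of K over resource-set inclusion.

    ``omega ⊆ omega'`` implies ``K(omega) <= K(omega')`` for every target.
    Gaining a resource may never lower the focal level.
    """
    for target in network.entity_order:
        regs = regulators(network, target)
        subsets = [frozenset(c) for r in range(len(regs) + 1)
                   for c in combinations(regs, r)]
        for a in subsets:
            # checking immediate supersets suffices by transitivity
            for extra in set(regs) - a:
                if K.level(target, a) > K.level(target, a | {extra}):
                    return False
    return True


# -- model file schema ---------------------------------------------------

def _resources_key(names: Iterable[str]) -> list[str]:
    return sorted(names)


def network_to_dict(network: LogicalNetwork) -> dict:
    doc: dict = {
        "entities": [{"name": e.name, "max": e.max_level}
                     for e in network.entities],
        "interactions": [
            {"source": ia.source, "target": ia.target, "sign": ia.sign,
             "threshold": ia.threshold}
            for ia in network.interactions
        ],
        "parameters": [
            {"target": s.target, "resources": _resources_key(s.resources),
             "range": list(s.range)}
            for s in network.parameter_specs
        ],
    }
    if network.entity_order != tuple(e.name for e in network.entities):
        doc["order"] = list(network.entity_order)
    if network.selected is not None:
        doc["selected"] = [
            {"target": t, "resources": _resources_key(res), "value": v}
            for (t, res), v in sorted(
                network.selected.items(),
                key=lambda kv: (kv[0][0], sorted(kv[0][1])))
        ]
    return doc


def network_from_dict(doc: Mapping) -> LogicalNetwork:
    try:
        entities = [Entity(d["name"], int(d.get("max", 1)))
                    for d in doc["entities"]]
        interactions = [
            Interaction(d["source"], d["target"], str(d["sign"]),
                        int(d.get("threshold", 1)))
            for d in doc.get("interactions", [])
        ]
        specs = [
            ParameterSpec(d["target"], frozenset(d.get("resources", [])),
                          tuple(int(v) for v in d["range"]))
            for d in doc.get("parameters", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ModelError(f"malformed model document: {exc}") from exc
    order = tuple(doc.get("order", ()))
    net = LogicalNetwork(entities, interactions, specs,
                         entity_order=order or ())
    if "selected" in doc:
        K = Parameterization()
        for d in doc["selected"]:
            K[(d["target"], frozenset(d.get("resources", [])))] = int(d["value"])
        for key in K:
            spec = net.spec_for(*key)
            if K[key] not in spec.range:
                raise ModelError(
                    f"selected K_{key[0]}({set(key[1]) or '{}'}) = {K[key]} "
                    f"outside its declared range {list(spec.range)}")
        net.selected = K
    return net


def read_model(path: str | Path) -> LogicalNetwork:
    """Read a network from a YAML model file (see the packaged ``mtor.yaml``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ModelError(f"{path}: model file must be a mapping")
    return network_from_dict(doc)


def write_model(network: LogicalNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(network), fh, sort_keys=False)


def network_to_dot(network: LogicalNetwork) -> str:
    """Render the regulatory topology as a DOT digraph (activation = normal
    arrowhead, inhibition = tee)."""
    lines = ["digraph brn {"]
    for name in network.entity_order:
        lines.append(f'  "{name}";')
    for ia in network.interactions:
        head = "normal" if ia.sign == ACTIVATION else "tee"
        lines.append(f'  "{ia.source}" -> "{ia.target}" '
                     f'[arrowhead={head}, label="{ia.threshold}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
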