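"""Reading-network definition and rule-constrained model-space enumeration.

The effective-connectivity analysis operates on a six-source network: occipital
cortex (OCC), ventral occipitotemporal cortex (vOT) and inferior frontal gyrus
(IFG), bilaterally.  Sources are arranged in a three-level hierarchy
(OCC < vOT < IFG).  Directed connections between sources are classified purely
from their endpoints:

* forward   — same hemisphere, up the hierarchy;
* backward  — same hemisphere, down the hierarchy;
* lateral   — between hemispheres, same level;
* diagonal  — between hemispheres, different levels (excluded from models);
* self      — identical endpoints.

Condition-specific modulation is not free per connection.  Three rules
constrain the space: diagonal connections are disallowed; every forward or
backward connection is switched together with its mirror in the opposite
hemisphere; every lateral connection is switched together with its reciprocal.
For the standard six-source network this leaves nine independent connection
groups and a model space of 2^9 = 512 binary modulation patterns.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SourceNode",
    "Connection",
    "ConnectionGroup",
    "NetworkSpec",
    "ModelSpace",
    "build_standard_network",
    "build_test_network",
    "enumerate_connections",
    "classify_connection",
    "independent_groups",
    "enumerate_model_space",
]

#: MNI prior locations (mm) for the standard network, left-hemisphere sign.
STANDARD_LOCATIONS_MM = {
    "OCC": (-15.0, -95.0, 2.0),
    "vOT": (-44.0, -58.0, -15.0),
    "IFG": (-48.0, 28.0, 0.0),
}

STANDARD_LEVELS = {"OCC": 1, "vOT": 2, "IFG": 3}


@dataclass(frozen=True)
class SourceNode:
    """One modelled cortical source."""

    label: str
    hemisphere: str  # "left" | "right"
    level: int
    prior_location_mm: tuple[float, float, float]

    @property
    def name(self) -> str:
        return f"{self.hemisphere[0].upper()}{self.label}"


@dataclass(frozen=True)
class Connection:
    """Directed connection between two sources, with its class."""

    source: str  # node name, e.g. "LOCC"
    target: str
    klass: str  # forward | backward | lateral | diagonal | self

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class ConnectionGroup:
    """Set of connections whose condition modulation is switched together."""

    members: tuple[Connection, ...]
    kind: str  # mirrored-pair | reciprocal-lateral | singleton | self-group
    name: str


@dataclass
class NetworkSpec:
    """A set of sources plus name-based lookup helpers."""

    nodes: list[SourceNode]

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names in network")
        self._by_name = {n.name: n for n in self.nodes}

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> SourceNode:
        return self._by_name[name]

    def index(self, name: str) -> int:
        return self.node_names.index(name)

    def to_json(self) -> dict:
        return {
            "nodes": [
                {
                    "label": n.label,
                    "hemisphere": n.hemisphere,
                    "level": n.level,
                    "prior_location_mm": list(n.prior_location_mm),
                }
                for n in self.nodes
            ]
        }

    @classmethod
    def from_json(cls, obj: dict) -> "NetworkSpec":
        return cls(
            [
                SourceNode(
                    d["label"],
                    d["hemisphere"],
                    int(d["level"]),
                    tuple(float(x) for x in d["prior_location_mm"]),
                )
                for d in obj["nodes"]
            ]
        )


@dataclass
class ModelSpace:
    """Enumerated binary modulation patterns over connection groups.

    ``patterns[m][g]`` is 1 when model ``m`` lets the experimental condition
    modulate every connection in group ``g``.  Ordering is little-endian
    binary counting over the documented group order, so model indices are
    stable across runs.
    """

    network: NetworkSpec
    groups: list[ConnectionGroup]
    patterns: np.ndarray  # (n_models, n_groups) uint8

    @property
    def n_models(self) -> int:
        return self.patterns.shape[0]

    def modulated_connections(self, model_index: int) -> list[Connection]:
        out: list[Connection] = []
        for g, on in zip(self.groups, self.patterns[model_index]):
            if on:
                out.extend(g.members)
        return out

    def to_json(self) -> dict:
        return {
            "network": self.network.to_json(),
            "groups": [
                {"name": g.name, "kind": g.kind, "members": [c.name for c in g.members]}
                for g in self.groups
            ],
            "n_models": int(self.n_models),
            "patterns": self.patterns.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


def build_standard_network() -> NetworkSpec:
    """The bilateral six-source reading network with MNI prior locations."""
    nodes = []
    for hemisphere, sign in (("left", -1.0), ("right", 1.0)):
        for label, loc in STANDARD_LOCATIONS_MM.items():
            x, y, z = loc
            nodes.append(
                SourceNode(
                    label=label,
                    hemisphere=hemisphere,
                    level=STANDARD_LEVELS[label],
                    prior_location_mm=(sign * abs(x), y, z),
                )
            )
    return NetworkSpec(nodes)


def build_test_network(n_levels: int = 2, hemispheres: Sequence[str] = ("left",)) -> NetworkSpec:
    """Small networks for desk-scale tests: ``n_levels`` sources per hemisphere.

    Levels reuse the standard labels (OCC, vOT, IFG) and locations.
    """
    if not 1 <= n_levels <= 3:
        raise ValueError("n_levels must be in 1..3")
    labels = list(STANDARD_LOCATIONS_MM)[:n_levels]
    nodes = []
    for hemisphere in hemispheres:
        sign = -1.0 if hemisphere == "left" else 1.0
        for label in labels:
            x, y, z = STANDARD_LOCATIONS_MM[label]
            nodes.append(
                SourceNode(label, hemisphere, STANDARD_LEVELS[label], (sign * abs(x), y, z))
            )
    return NetworkSpec(nodes)


def classify_connection(a: SourceNode, b: SourceNode) -> str:
    """Class of the directed connection a -> b (pure function of endpoints)."""
    if a.name == b.name:
        return "self"
    if a.hemisphere == b.hemisphere:
        return "forward" if b.level > a.level else "backward"
    return "lateral" if a.level == b.level else "diagonal"


def enumerate_connections(network: NetworkSpec) -> list[Connection]:
    """All ordered pairs of distinct nodes, classified; count = n(n-1)."""
    if len(network.nodes) < 2:
        raise ValueError("need at least 2 nodes")
    out = []
    for a, b in itertools.permutations(network.nodes, 2):
        out.append(Connection(a.name, b.name, classify_connection(a, b)))
    return out


def _mirror_name(network: NetworkSpec, name: str) -> str | None:
    node = network.node(name)
    other = "right" if node.hemisphere == "left" else "left"
    cand = f"{other[0].upper()}{node.label}"
    return cand if cand in network.node_names else None


def independent_groups(
    network: NetworkSpec, include_self_group: bool = False
) -> list[ConnectionGroup]:
    """Partition admissible (non-diagonal, non-self) connections into the
    switch groups implied by the mirroring rules.

    Forward/backward connections are bundled with their opposite-hemisphere
    mirror; homotopic lateral connections are bundled bidirectionally.  A
    connection whose endpoints lack homologues forms a flagged singleton.
    With ``include_self_group`` a single extra group switches condition
    modulation of every self-connection jointly — used for small desk-scale
    model spaces; in the standard space self-connection gains are estimated
    in every model instead.
    """
    conns = {c.name: c for c in enumerate_connections(network) if c.klass not in ("diagonal",)}
    groups: list[ConnectionGroup] = []
    seen: set[str] = set()
    for c in conns.values():
        if c.name in seen:
            continue
        ms = _mirror_name(network, c.source)
        mt = _mirror_name(network, c.target)
        if c.klass in ("forward", "backward"):
            if ms is None or mt is None:
                groups.append(ConnectionGroup((c,), "singleton", c.name))
                seen.add(c.name)
            else:
                mirror = conns[f"{ms}->{mt}"]
                members = tuple(sorted({c, mirror}, key=lambda x: x.name))
                groups.append(
                    ConnectionGroup(members, "mirrored-pair", "+".join(m.name for m in members))
                )
                seen.update(m.name for m in members)
        elif c.klass == "lateral":
            recip = conns[f"{c.target}->{c.source}"]
            members = tuple(sorted({c, recip}, key=lambda x: x.name))
            groups.append(
                ConnectionGroup(members, "reciprocal-lateral", "<->".join(
                    sorted({c.source, c.target})))
            )
            seen.update(m.name for m in members)
    groups.sort(key=lambda g: g.name)
    if include_self_group:
        selfs = tuple(Connection(n, n, "self") for n in network.node_names)
        groups.append(ConnectionGroup(selfs, "self-group", "self"))
    return groups


def enumerate_model_space(
    network: NetworkSpec,
    groups: list[ConnectionGroup] | None = None,
    max_groups: int = 16,
    include_self_group: bool = False,
) -> ModelSpace:
    """Every binary modulation assignment over the groups, in little-endian
    binary-counting order (model 0 is the null-modulation model)."""
    if groups is None:
        groups = independent_groups(network, include_self_group=include_self_group)
    k = len(groups)
    if k > max_groups:
        raise ValueError(
            f"{k} groups would enumerate 2^{k} = {2 ** k} models, above the cap "
            f"of 2^{max_groups}; raise max_groups explicitly to proceed"
        )
    n = 2 ** k
    patterns = np.zeros((n, k), dtype=np.uint8)
    for m in range(n):
        for g in range(k):
            patterns[m, g] = (m >> g) & 1
    return ModelSpace(network=network, groups=groups, patterns=patterns)
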