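"""Tissue-compartment network model.

The switch analysis maps lipid variables onto a graph of tissue compartments
whose edges encode direct metabolic exchange (traffic).  The default network
for a diet-driven metabolic study is a serum-centred star: serum exchanges
lipids with liver (synthesis), heart and skeletal muscle (fatty-acid
oxidation), adipose (storage) and brain/CNS (structural use).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = ["TissueNetwork", "NetworkConfigError", "default_network", "edge_key"]


class NetworkConfigError(ValueError):
    """Raised for malformed or disconnected network configurations."""


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) representation of an undirected edge."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class TissueNetwork:
    """Undirected, connected graph of tissue compartments.

    Attributes
    ----------
    compartments:
        Compartment labels, in declaration order.
    edges:
        Unordered adjacent pairs, stored as sorted 2-tuples.
    termini:
        Optional free-text role annotation per compartment
        (e.g. ``{"adipose": "storage"}``).
    """

    compartments: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    termini: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        comps = set(self.compartments)
        if len(comps) != len(self.compartments):
            raise NetworkConfigError("duplicate compartment labels")
        if len(comps) < 2:
            raise NetworkConfigError("a network needs at least 2 compartments")
        norm = []
        for a, b in self.edges:
            if a == b:
                raise NetworkConfigError(f"self-loop on {a!r}")
            for c in (a, b):
                if c not in comps:
                    raise NetworkConfigError(
                        f"edge ({a!r}, {b!r}) references undeclared compartment {c!r}"
                    )
            norm.append(edge_key(a, b))
        if len(set(norm)) != len(norm):
            raise NetworkConfigError("duplicate edges")
        object.__setattr__(self, "edges", tuple(norm))
        for c in self.termini:
            if c not in comps:
                raise NetworkConfigError(f"terminus for undeclared compartment {c!r}")
        if not nx.is_connected(self.to_graph()):
            raise NetworkConfigError("network graph is not connected")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compartments)
        g.add_edges_from(self.edges)
        return g

    def neighbours(self, compartment: str) -> tuple[str, ...]:
        return tuple(
            sorted(b if a == compartment else a
                   for a, b in self.edges if compartment in (a, b))
        )


def default_network() -> TissueNetwork:
    """The packaged six-compartment network (serum-centred star)."""
    comps = ("serum", "liver", "heart", "vastus", "adipose", "brain")
    return TissueNetwork(
        compartments=comps,
        edges=tuple(edge_key("serum", c) for c in comps if c != "serum"),
        termini={
            "liver": "synthesis; fatty acid oxidation",
            "brain": "structural (CNS)",
            "heart": "fatty acid oxidation",
            "vastus": "fatty acid oxidation",
            "adipose": "storage",
            "serum": "transport hub",
        },
    )
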