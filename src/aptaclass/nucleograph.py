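"""Hydrogen-suppressed molecular graphs of loop nucleotide fragments.

Each base has a fixed deoxyribonucleoside template (heavy atoms of base +
2'-deoxyribose) shipped as a plain-text atom/bond table.  A loop fragment is
assembled 5'→3' by joining consecutive residues with a phosphodiester
bridge: O3'—P, P—O5', plus the two non-bridging phosphate oxygens.  Termini
are 5'-OH / 3'-OH (no terminal phosphate).  Construction is deterministic
with a canonical atom order, so rebuilt graphs are identical.

Descriptor computations downstream use the simple unweighted graph; bond
orders in the template file are chemical annotation only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path


class GraphError(ValueError):
    """Raised for invalid fragment sequences or malformed graphs."""


@dataclass(frozen=True)
class NucleotideTemplate:
    base: str
    atoms: tuple[tuple[str, str], ...]  # (atom_name, element)
    bonds: tuple[tuple[str, str, int], ...]  # (atom_1, atom_2, order)


@lru_cache(maxsize=1)
def load_templates() -> dict[str, NucleotideTemplate]:
    """Parse the shipped template table (cached)."""
    atoms: dict[str, list] = {b: [] for b in "ACGT"}
    bonds: dict[str, list] = {b: [] for b in "ACGT"}
    text = resources.files("aptaclass.data").joinpath("nucleotide_templates.txt").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "ATOM":
            _, base, name, element = parts
            atoms[base].append((name, element))
        elif parts[0] == "BOND":
            _, base, a1, a2, order = parts
            bonds[base].append((a1, a2, int(order)))
        else:
            raise GraphError(f"unrecognized template line: {line}")
    out = {}
    for b in "ACGT":
        tpl = NucleotideTemplate(b, tuple(atoms[b]), tuple(bonds[b]))
        names = {n for n, _ in tpl.atoms}
        for a1, a2, _ in tpl.bonds:
            if a1 not in names or a2 not in names:
                raise GraphError(f"template {b}: bond references unknown atom")
        out[b] = tpl
    return out


@dataclass
class MolecularGraph:
    """Connected hydrogen-suppressed graph with derived matrices."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise GraphError("empty graph")
        if not nx.is_connected(self.graph):
            raise GraphError("molecular graph must be connected")
        if any(self.graph.has_edge(v, v) for v in self.graph):
            raise GraphError("self-loops are not allowed")

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self.graph.number_of_edges()

    def adjacency_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=sorted(self.graph.nodes), weight=None)

    def degrees(self) -> np.ndarray:
        return self.adjacency_matrix().sum(axis=1)

    def distance_matrix(self) -> np.ndarray:
        return distance_matrix(self)

    def edge_list(self) -> list[tuple]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


def build_loop_graph(loop_sequence: str) -> MolecularGraph:
    """Assemble the molecular graph of a loop fragment, 5'→3'.

    Node labels are ``(residue_index, atom_name)``; linkage atoms carry the
    index of the downstream (3') residue.
    """
    seq = loop_sequence.strip().upper()
    if not seq:
        raise GraphError("empty loop sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise GraphError(f"non-ACGT character(s) in loop: {sorted(bad)}")
    templates = load_templates()
    g = nx.Graph()
    for idx, base in enumerate(seq):
        tpl = templates[base]
        for name, element in tpl.atoms:
            g.add_node((idx, name), element=element)
        for a1, a2, order in tpl.bonds:
            g.add_edge((idx, a1), (idx, a2), order=order)
        if idx > 0:
            # phosphodiester bridge between residue idx-1 and idx
            p, op1, op2 = (idx, "P"), (idx, "OP1"), (idx, "OP2")
            g.add_node(p, element="P")
            g.add_node(op1, element="O")
            g.add_node(op2, element="O")
            g.add_edge((idx - 1, "O3'"), p, order=1)
            g.add_edge(p, (idx, "O5'"), order=1)
            g.add_edge(p, op1, order=2)
            g.add_edge(p, op2, order=1)
    return MolecularGraph(g)


def distance_matrix(graph: MolecularGraph | nx.Graph) -> np.ndarray:
    """Topological distance matrix (shortest-path edge counts)."""
    g = graph.graph if isinstance(graph, MolecularGraph) else graph
    if not nx.is_connected(g):
        raise GraphError("distance matrix requires a connected graph")
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes), weight=None)
    return shortest_path(a, method="D", unweighted=True)
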