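"""Topological descriptor families on molecular graphs.

Implemented families (all on the simple, unweighted, hydrogen-suppressed
graph; vertex degree is the number of adjacent heavy atoms):

* ``XkA`` — average connectivity (Randić chi) index of order k: the sum over
  k-edge simple paths of the inverse square root of the product of vertex
  degrees along the path, divided by the number of such paths.
* ``GGIk`` / ``JGIk`` — Gálvez topological charge indices: from the charge
  term matrix CT (diagonal = degrees; off-diagonal = antisymmetric part of
  A·Q with Q the reciprocal square distance matrix), GGIk is the half-sum of
  |CT_ij| over ordered vertex pairs at topological distance k, and JGIk is
  GGIk per unordered pair at that distance.
* ``PWk`` — Randić path/walk shape index: the average over atoms of (simple
  k-paths starting at the atom) / (k-walks starting at the atom).

The per-aptamer descriptor vector is (PW4, X3A, JGI2, E) where E is the MFE
free energy from the folding module.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np

from .nucleograph import MolecularGraph, build_loop_graph

if TYPE_CHECKING:  # pragma: no cover
    from .folding import LoopRegion, SecondaryStructure
    from .pool_io import SequenceRecord


@dataclass(frozen=True)
class DescriptorVector:
    """The four selected structure descriptors of one aptamer."""

    PW4: float
    X3A: float
    JGI2: float
    E: float

    def as_array(self) -> np.ndarray:
        return np.array([self.PW4, self.X3A, self.JGI2, self.E])


def _adjacency(graph) -> np.ndarray:
    if isinstance(graph, MolecularGraph):
        return graph.adjacency_matrix()
    if isinstance(graph, nx.Graph):
        return nx.to_numpy_array(graph, nodelist=sorted(graph.nodes), weight=None)
    a = np.asarray(graph, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency matrix must be square")
    return a


def _sp(a: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components, shortest_path

    if connected_components(a, directed=False, return_labels=False) != 1:
        raise ValueError("descriptors require a connected graph")
    return shortest_path(a, method="D", unweighted=True)


def _neighbors(a: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(a[i]) for i in range(a.shape[0])]


def _directed_path_stats(a: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Per-vertex counts of k-edge simple paths starting there, and the
    total chi sum over directed paths (inverse sqrt degree products)."""
    nbrs = _neighbors(a)
    deg = a.sum(axis=1)
    n = a.shape[0]
    counts = np.zeros(n)
    chi_sum = 0.0

    def dfs(v: int, depth: int, visited: list[int], prod: float):
        nonlocal chi_sum, count_v
        if depth == k:
            count_v += 1
            chi_sum += prod ** -0.5
            return
        for w in nbrs[v]:
            if w not in visited:
                visited.append(w)
                dfs(w, depth + 1, visited, prod * deg[w])
                visited.pop()

    for start in range(n):
        count_v = 0
        dfs(start, 0, [start], deg[start])
        counts[start] = count_v
    return counts, chi_sum


def chi_average(graph, k: int) -> float:
    """Average connectivity index XkA of order k (0 if no k-path exists)."""
    if k < 1:
        raise ValueError("order k must be >= 1")
    a = _adjacency(graph)
    counts, chi_directed = _directed_path_stats(a, k)
    n_paths = counts.sum() / 2  # each undirected path seen from both ends
    if n_paths == 0:
        return 0.0
    return (chi_directed / 2) / n_paths


def charge_term_matrix(graph) -> np.ndarray:
    """Gálvez charge term matrix CT.

    Diagonal: vertex degrees.  Off-diagonal: CT_ij = m_ij − m_ji with
    M = A·Q and Q the reciprocal square distance matrix (Q_ii = 0).
    """
    a = _adjacency(graph)
    d = _sp(a)
    with np.errstate(divide="ignore"):
        q = np.where(d > 0, 1.0 / d**2, 0.0)
    m = a @ q
    ct = m - m.T
    np.fill_diagonal(ct, a.sum(axis=1))
    return ct


def topological_charge(graph, k: int) -> tuple[float, float]:
    """(GGIk, JGIk): charge index of order k and its per-pair mean."""
    if k < 1:
        raise ValueError("order k must be >= 1")
    a = _adjacency(graph)
    d = _sp(a)
    ct = charge_term_matrix(graph)
    mask = d == k
    np.fill_diagonal(mask, False)
    n_pairs = int(mask.sum()) // 2
    if n_pairs == 0:
        return 0.0, 0.0
    ggi = 0.5 * np.abs(ct[mask]).sum()
    return float(ggi), float(ggi / n_pairs)


def path_walk_shape(graph, k: int) -> float:
    """Randić path/walk shape index PWk (atoms with no k-walk contribute 0)."""
    if k < 1:
        raise ValueError("order k must be >= 1")
    a = _adjacency(graph)
    counts, _ = _directed_path_stats(a, k)
    walks = np.linalg.matrix_power(a, k).sum(axis=1)
    ratios = np.divide(counts, walks, out=np.zeros_like(counts), where=walks > 0)
    return float(ratios.mean())


@lru_cache(maxsize=4096)
def loop_descriptors(loop_seq: str) -> tuple[float, float, float]:
    """(PW4, X3A, JGI2) of a loop fragment's molecular graph (cached)."""
    g = build_loop_graph(loop_seq)
    return (
        path_walk_shape(g, 4),
        chi_average(g, 3),
        topological_charge(g, 2)[1],
    )


def descriptor_vector(
    record: "SequenceRecord",
    structure: "SecondaryStructure",
    loop: "LoopRegion",
    include_closing_pair: bool = False,
) -> DescriptorVector:
    """Assemble (PW4, X3A, JGI2, E) for one aptamer.

    ``include_closing_pair`` extends the fragment with the loop's closing
    base pair nucleotides (off by default: loop-only fragment).
    """
    positions = sorted(loop.positions)
    if include_closing_pair:
        lo, hi = positions[0] - 1, positions[-1] + 1
        if lo >= 0 and hi < len(structure.sequence):
            positions = [lo] + positions + [hi]
    frag = "".join(structure.sequence[p] for p in positions)
    pw4, x3a, jgi2 = loop_descriptors(frag)
    return DescriptorVector(PW4=pw4, X3A=x3a, JGI2=jgi2, E=structure.energy_E)


@lru_cache(maxsize=4096)
def _family_values(loop_seq: str) -> dict[str, float]:
    g = build_loop_graph(loop_seq)
    vals: dict[str, float] = {}
    for k in range(1, 5):
        vals[f"X{k}A"] = chi_average(g, k)
    for k in range(1, 6):
        vals[f"JGI{k}"] = topological_charge(g, k)[1]
    for k in range(2, 6):
        vals[f"PW{k}"] = path_walk_shape(g, k)
    return vals


def family_table(records, structures, loops) -> "pd.DataFrame":
    """Descriptor-family table (XkA, JGIk, PWk families + E) for a pool.

    ``structures`` and ``loops`` map ``record.key`` to the folded structure
    and the selected loop.  Used as the candidate pool for stepwise
    selection.
    """
    import pandas as pd

    from .folding import loop_sequence

    rows = []
    for rec in records:
        st = structures[rec.key]
        frag = loop_sequence(st, loops[rec.key])
        row = {"id": rec.key, "round": rec.round_index}
        row.update(_family_values(frag))
        row["E"] = st.energy_E
        rows.append(row)
    return pd.DataFrame(rows)


def descriptor_table(records, structures, loops, include_closing_pair: bool = False):
    """Four-descriptor table (id, round, PW4, X3A, JGI2, E) for a pool."""
    import pandas as pd

    rows = []
    for rec in records:
        vec = descriptor_vector(rec, structures[rec.key], loops[rec.key], include_closing_pair)
        rows.append(
            {
                "id": rec.key,
                "round": rec.round_index,
                "PW4": vec.PW4,
                "X3A": vec.X3A,
                "JGI2": vec.JGI2,
                "E": vec.E,
            }
        )
    return pd.DataFrame(rows)
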