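"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written with different algorithms/libraries than the package:
hand-rolled BFS distances, definitional loop-based charge terms, networkx
simple-path enumeration, recursive walk counting, exhaustive secondary-
structure enumeration, and an SLSQP solve of the SVM dual.
"""

from collections import deque
from functools import lru_cache

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from aptaclass import folding


# --- graph oracles ---------------------------------------------------------

def bfs_distances(g: nx.Graph) -> np.ndarray:
    nodes = sorted(g.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    for src in nodes:
        d[pos[src], pos[src]] = 0
        q = deque([src])
        while q:
            v = q.popleft()
            for w in g.neighbors(v):
                if np.isinf(d[pos[src], pos[w]]):
                    d[pos[src], pos[w]] = d[pos[src], pos[v]] + 1
                    q.append(w)
    return d


def simple_paths_of_length(g: nx.Graph, k: int):
    """All undirected simple paths with exactly k edges, each once."""
    nodes = sorted(g.nodes)
    seen = set()
    out = []
    for s in nodes:
        for t in nodes:
            if s >= t and k > 0:
                continue
            for p in nx.all_simple_paths(g, s, t, cutoff=k):
                if len(p) == k + 1:
                    key = tuple(p) if tuple(p) <= tuple(reversed(p)) else tuple(reversed(p))
                    if key not in seen:
                        seen.add(key)
                        out.append(list(p))
    return out


def chi_average_oracle(g: nx.Graph, k: int) -> float:
    deg = dict(g.degree)
    paths = simple_paths_of_length(g, k)
    if not paths:
        return 0.0
    chi = sum(np.prod([deg[v] for v in p]) ** -0.5 for p in paths)
    return chi / len(paths)


def walk_count_oracle(g: nx.Graph, start, k: int) -> int:
    @lru_cache(maxsize=None)
    def w(v, steps):
        if steps == 0:
            return 1
        return sum(w(u, steps - 1) for u in g.neighbors(v))

    return w(start, k)


def path_walk_oracle(g: nx.Graph, k: int) -> float:
    nodes = sorted(g.nodes)
    total = 0.0
    for v in nodes:
        n_paths = sum(
            1
            for t in nodes
            if t != v
            for p in nx.all_simple_paths(g, v, t, cutoff=k)
            if len(p) == k + 1
        )
        n_walks = walk_count_oracle(g, v, k)
        if n_walks > 0:
            total += n_paths / n_walks
    return total / len(nodes)


def charge_terms_oracle(g: nx.Graph) -> np.ndarray:
    nodes = sorted(g.nodes)
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v in g.edges:
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = 1
    d = bfs_distances(g)
    q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                q[i, j] = 1.0 / d[i, j] ** 2
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            m[i, j] = sum(a[i, l] * q[l, j] for l in range(n))
    ct = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ct[i, j] = g.degree[nodes[i]] if i == j else m[i, j] - m[j, i]
    return ct


def topological_charge_oracle(g: nx.Graph, k: int) -> tuple[float, float]:
    ct = charge_terms_oracle(g)
    d = bfs_distances(g)
    n = len(ct)
    ggi = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] == k:
                ggi += abs(ct[i, j])
                n_pairs += 1
    return (ggi, ggi / n_pairs) if n_pairs else (0.0, 0.0)


def random_connected_graph(rng: np.random.Generator, max_n: int = 12) -> nx.Graph:
    while True:
        n = int(rng.integers(3, max_n + 1))
        p = float(rng.uniform(0.25, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return g


# --- folding oracle --------------------------------------------------------

def enumerate_structures(seq: str, wobble: bool = True):
    """All non-crossing pair sets (minimum hairpin 3) of a sequence."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if j - i < folding.MIN_HAIRPIN + 1:
            return (frozenset(),)
        out = [frozenset({(i, k)} | a | b)
               for k in range(i + folding.MIN_HAIRPIN + 1, j + 1)
               if folding.pairable(seq[i], seq[k], wobble)
               for a in rec(i + 1, k - 1)
               for b in rec(k + 1, j)]
        out.extend(rec(i + 1, j))
        return tuple(out)

    return rec(0, n - 1)


def mfe_oracle(seq: str, params=None, wobble: bool = True) -> float:
    best = 0.0
    for pairs in enumerate_structures(seq, wobble):
        if pairs:
            best = min(best, folding.evaluate_energy(seq, pairs, params, wobble))
    return best


# --- SVM dual oracle -------------------------------------------------------

def svm_dual_optimum(Xs: np.ndarray, ypm: np.ndarray, C: float, gamma: float) -> float:
    """Max of the soft-margin RBF dual, solved generically with SLSQP."""
    n = len(ypm)
    d2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-gamma * d2)
    Q = (ypm[:, None] * ypm[None, :]) * K

    def neg_obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    cons = {"type": "eq", "fun": lambda a: a @ ypm, "jac": lambda a: ypm.astype(float)}
    best = -np.inf
    for x0 in (np.zeros(n), np.full(n, min(C, 1.0) / 2)):
        res = minimize(
            neg_obj,
            x0,
            jac=grad,
            bounds=[(0.0, C)] * n,
            constraints=[cons],
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-12},
        )
        best = max(best, -res.fun)
    return best
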