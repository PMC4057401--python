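"""Minimum-free-energy secondary-structure prediction for DNA aptamers.

A Zuker-style dynamic program over a nearest-neighbor model: stacked base
pairs contribute tabulated stack free energies, and hairpin / bulge /
internal / multibranch loops contribute length-dependent penalties.  The
parameter table (37 °C, kcal/mol) ships as a plain-text file and can be
swapped.  The model is deliberately simple — no dangling ends, no coaxial
stacking, no pseudoknots — because the downstream descriptor ``E`` only
requires a consistent MFE value across the pool.

``evaluate_energy`` is the model definition (energy of a given structure);
``fold_mfe`` returns the exact optimum of that model over all non-crossing
structures with interior loops up to :data:`MAX_INTERIOR` unpaired
nucleotides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

INF = float("inf")
#: minimum unpaired nucleotides in a hairpin loop
MIN_HAIRPIN = 3
#: largest interior (bulge+internal) loop considered by the DP
MAX_INTERIOR = 14

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}
#: Jacobson–Stockmayer prefactor 1.75·R·T at 310 K (kcal/mol)
_JS = 1.08


class FoldingError(ValueError):
    """Raised for invalid sequences or structures."""


@dataclass
class EnergyParameters:
    """Nearest-neighbor parameter set loaded from a TSV table."""

    stack: dict[str, float]
    wobble_stack: float
    hairpin: dict[int, float]
    bulge: dict[int, float]
    internal: dict[int, float]
    multi_a: float
    multi_b: float
    multi_c: float
    source: str = "builtin"

    @classmethod
    def from_file(cls, path: str | Path) -> "EnergyParameters":
        stack: dict[str, float] = {}
        loops: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}
        multi: dict[str, float] = {}
        wobble = -0.3
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                kind, key, value = line.split("\t")
                if kind == "stack":
                    stack[key] = float(value)
                elif kind == "wobble_stack":
                    wobble = float(value)
                elif kind in loops:
                    loops[kind][int(key)] = float(value)
                elif kind == "multibranch":
                    multi[key] = float(value)
                else:
                    raise FoldingError(f"unknown parameter kind {kind!r} in {path}")
        return cls(
            stack=stack,
            wobble_stack=wobble,
            hairpin=loops["hairpin"],
            bulge=loops["bulge"],
            internal=loops["internal"],
            multi_a=multi["a"],
            multi_b=multi["b"],
            multi_c=multi["c"],
            source=str(path),
        )

    def stack_energy(self, x: str, y: str, w: str, z: str) -> float:
        """Free energy of the stack 5'-xy-3' / 3'-wz-5' (outer pair x:w)."""
        key = f"{x}{y}/{w}{z}"
        if key in self.stack:
            return self.stack[key]
        sym = f"{z}{w}/{y}{x}"  # same duplex read from the other strand
        if sym in self.stack:
            return self.stack[sym]
        if (x, w) in _WOBBLE or (y, z) in _WOBBLE:
            return self.wobble_stack
        raise FoldingError(f"no stack entry for {key}")

    def _loop(self, table: dict[int, float], size: int) -> float:
        if size in table:
            return table[size]
        m = max(table)
        return table[m] + _JS * math.log(size / m)

    def hairpin_energy(self, size: int) -> float:
        if size < MIN_HAIRPIN:
            raise FoldingError(f"hairpin of size {size} below minimum {MIN_HAIRPIN}")
        return self._loop(self.hairpin, size)

    def bulge_energy(self, size: int) -> float:
        return self._loop(self.bulge, size)

    def internal_energy(self, size: int) -> float:
        return self._loop(self.internal, size)


_default_params: EnergyParameters | None = None


def default_parameters() -> EnergyParameters:
    global _default_params
    if _default_params is None:
        with resources.as_file(
            resources.files("aptaclass.data").joinpath("dna_nn.tsv")
        ) as p:
            _default_params = EnergyParameters.from_file(p)
        _default_params.source = "builtin dna_nn v1"
    return _default_params


def pairable(a: str, b: str, wobble: bool = True) -> bool:
    return (a, b) in _WC or (wobble and (a, b) in _WOBBLE)


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing base-pair map with its free energy E (kcal/mol)."""

    sequence: str
    pairs: frozenset[tuple[int, int]]
    energy_E: float

    def partner_map(self) -> dict[int, int]:
        pm: dict[int, int] = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    def dot_bracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)

    @classmethod
    def from_dot_bracket(cls, sequence: str, db: str, energy: float = 0.0) -> "SecondaryStructure":
        stack: list[int] = []
        pairs = set()
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise FoldingError(f"unbalanced bracket at {i}")
                pairs.add((stack.pop(), i))
        if stack:
            raise FoldingError("unbalanced dot-bracket string")
        return cls(sequence, frozenset(pairs), energy)


@dataclass(frozen=True)
class LoopRegion:
    """One loop of a secondary structure.

    ``kind`` is hairpin, bulge, internal, or multi (unpaired stretches of a
    multibranch loop).  ``positions`` are the unpaired indices, 5'→3'.
    """

    kind: str
    positions: tuple[int, ...]

    @property
    def n_nucleotides(self) -> int:
        return len(self.positions)

    @property
    def start(self) -> int:
        return min(self.positions)


# ---------------------------------------------------------------------------
# structure decomposition and energy evaluation (the model definition)
# ---------------------------------------------------------------------------

def _check_pairs(n: int, pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    used: set[int] = set()
    for i, j in plist:
        if i == j or not (0 <= i < j < n):
            raise FoldingError(f"invalid pair ({i},{j})")
        if i in used or j in used:
            raise FoldingError(f"index in multiple pairs: ({i},{j})")
        used.update((i, j))
    for a in range(len(plist)):
        for b in range(a + 1, len(plist)):
            i, j = plist[a]
            k, l = plist[b]
            if i < k < j < l:
                raise FoldingError(f"crossing pairs ({i},{j}) and ({k},{l})")
    return plist


def _children(lo: int, hi: int, partner: dict[int, int]) -> list[tuple[int, int]]:
    """Directly nested pairs inside the open interval positions lo..hi."""
    out = []
    k = lo
    while k <= hi:
        j = partner.get(k)
        if j is not None and j > k:
            out.append((k, j))
            k = j + 1
        else:
            k += 1
    return out


def decompose(sequence: str, pairs: Iterable[tuple[int, int]]):
    """Decompose a structure into loop elements.

    Yields tuples ``(kind, closing, inner, positions)`` where kind is one of
    ``exterior | hairpin | stack | bulge | internal | multi``; ``closing`` is
    the closing pair (None for exterior), ``inner`` the list of directly
    nested pairs, ``positions`` the unpaired indices belonging to the element.
    """
    n = len(sequence)
    plist = _check_pairs(n, pairs)
    partner: dict[int, int] = {}
    for i, j in plist:
        partner[i] = j
        partner[j] = i

    top = _children(0, n - 1, partner)
    ext_unpaired = tuple(k for k in range(n) if k not in partner and not any(i < k < j for i, j in top))
    yield ("exterior", None, top, ext_unpaired)

    for i, j in plist:
        inner = _children(i + 1, j - 1, partner)
        inner_span = set()
        for k, l in inner:
            inner_span.update(range(k, l + 1))
        positions = tuple(p for p in range(i + 1, j) if p not in inner_span)
        if not inner:
            yield ("hairpin", (i, j), inner, positions)
        elif len(inner) == 1:
            k, l = inner[0]
            if k == i + 1 and l == j - 1:
                yield ("stack", (i, j), inner, positions)
            elif k == i + 1 or l == j - 1:
                yield ("bulge", (i, j), inner, positions)
            else:
                yield ("internal", (i, j), inner, positions)
        else:
            yield ("multi", (i, j), inner, positions)


def evaluate_energy(
    sequence: str,
    pairs: Iterable[tuple[int, int]],
    params: EnergyParameters | None = None,
    wobble: bool = True,
) -> float:
    """Free energy of a given structure under the nearest-neighbor model."""
    params = params or default_parameters()
    s = sequence.upper()
    total = 0.0
    for kind, closing, inner, positions in decompose(s, pairs):
        if kind == "exterior":
            continue
        i, j = closing
        if not pairable(s[i], s[j], wobble):
            raise FoldingError(f"non-pairable closing pair {s[i]}{s[j]} at ({i},{j})")
        if kind == "hairpin":
            total += params.hairpin_energy(len(positions))
        elif kind == "stack":
            total += params.stack_energy(s[i], s[i + 1], s[j], s[j - 1])
        elif kind == "bulge":
            total += params.bulge_energy(len(positions))
        elif kind == "internal":
            total += params.internal_energy(len(positions))
        else:  # multi
            total += params.multi_a + params.multi_b * (1 + len(inner)) + params.multi_c * len(positions)
    return total


# ---------------------------------------------------------------------------
# MFE dynamic program
# ---------------------------------------------------------------------------

def fold_mfe(
    sequence: str,
    params: EnergyParameters | None = None,
    wobble: bool = True,
) -> SecondaryStructure:
    """Exact MFE structure of the configured nearest-neighbor model.

    The open chain (zero pairs, E = 0) is always admissible, so the returned
    energy is ≤ 0.  Sequences shorter than 5 nt cannot form a hairpin and
    return the open chain with a warning.
    """
    params = params or default_parameters()
    s = sequence.strip().upper()
    if not s:
        raise FoldingError("empty sequence")
    bad = set(s) - set("ACGT")
    if bad:
        raise FoldingError(f"non-ACGT character(s): {sorted(bad)}")
    n = len(s)
    if n < MIN_HAIRPIN + 2:
        logger.warning("sequence of length %d cannot fold; returning open chain", n)
        return SecondaryStructure(s, frozenset(), 0.0)

    a, b, c = params.multi_a, params.multi_b, params.multi_c
    can = [[pairable(s[i], s[j], wobble) for j in range(n)] for i in range(n)]

    V = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            # --- V(i,j): i,j paired ---
            if can[i][j]:
                best = params.hairpin_energy(j - i - 1)
                Vi1 = V[i + 1]
                # stacks / bulges / internal loops
                kmax = min(i + MAX_INTERIOR + 1, j - MIN_HAIRPIN - 2)
                for k in range(i + 1, kmax + 1):
                    s1 = k - i - 1
                    Vk = V[k]
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERIOR - s1))
                    for l in range(lmin, j):
                        v = Vk[l]
                        if v == INF:
                            continue
                        s2 = j - l - 1
                        if s1 == 0 and s2 == 0:
                            e = v + params.stack_energy(s[i], s[k], s[j], s[l])
                        elif s1 == 0 or s2 == 0:
                            e = v + params.bulge_energy(s1 + s2)
                        else:
                            e = v + params.internal_energy(s1 + s2)
                        if e < best:
                            best = e
                # multibranch closure: two WM parts, each with >= 1 branch
                if span >= 2 * (MIN_HAIRPIN + 2) + 1:
                    WMi1 = WM[i + 1]
                    base = a + b
                    for k in range(i + 2, j - 1):
                        left = WMi1[k]
                        if left == INF:
                            continue
                        right = WM[k + 1][j - 1]
                        if right == INF:
                            continue
                        e = base + left + right
                        if e < best:
                            best = e
                V[i][j] = best
            # --- WM(i,j): multiloop segment with >= 1 branch ---
            best = INF
            if V[i][j] < INF:
                best = V[i][j] + b
            if WM[i + 1][j] < INF:
                best = min(best, WM[i + 1][j] + c)
            if WM[i][j - 1] < INF:
                best = min(best, WM[i][j - 1] + c)
            WMi = WM[i]
            for k in range(i + 1, j + 1):
                left = WMi[k - 1]
                if left == INF:
                    continue
                right = WM[k][j]
                if right < INF and left + right < best:
                    best = left + right
            WM[i][j] = best

    # exterior loop
    W = [0.0] * (n + 1)  # W[j+1] = best energy of prefix 0..j
    for j in range(n):
        best = W[j]
        for i in range(0, j - MIN_HAIRPIN):
            if V[i][j] < INF:
                e = W[i] + V[i][j]
                if e < best:
                    best = e
        W[j + 1] = best

    pairs: set[tuple[int, int]] = set()
    _traceback_exterior(n, s, params, wobble, V, WM, W, pairs)
    return SecondaryStructure(s, frozenset(pairs), W[n])


_EPS = 1e-9


def _traceback_exterior(n, s, params, wobble, V, WM, W, pairs) -> None:
    j = n - 1
    while j >= 0:
        if abs(W[j + 1] - W[j]) < _EPS:
            j -= 1
            continue
        found = False
        for i in range(0, j - MIN_HAIRPIN):
            if V[i][j] < INF and abs(W[j + 1] - (W[i] + V[i][j])) < _EPS:
                _traceback_V(i, j, s, params, wobble, V, WM, pairs)
                j = i - 1
                found = True
                break
        if not found:  # pragma: no cover - numerical safety net
            raise FoldingError("exterior traceback failed")


def _traceback_V(i, j, s, params, wobble, V, WM, pairs) -> None:
    pairs.add((i, j))
    target = V[i][j]
    if abs(target - params.hairpin_energy(j - i - 1)) < _EPS:
        return
    kmax = min(i + MAX_INTERIOR + 1, j - MIN_HAIRPIN - 2)
    for k in range(i + 1, kmax + 1):
        s1 = k - i - 1
        lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERIOR - s1))
        for l in range(lmin, j):
            v = V[k][l]
            if v == INF:
                continue
            s2 = j - l - 1
            if s1 == 0 and s2 == 0:
                e = v + params.stack_energy(s[i], s[k], s[j], s[l])
            elif s1 == 0 or s2 == 0:
                e = v + params.bulge_energy(s1 + s2)
            else:
                e = v + params.internal_energy(s1 + s2)
            if abs(target - e) < _EPS:
                _traceback_V(k, l, s, params, wobble, V, WM, pairs)
                return
    base = params.multi_a + params.multi_b
    for k in range(i + 2, j - 1):
        left, right = WM[i + 1][k], WM[k + 1][j - 1]
        if left < INF and right < INF and abs(target - (base + left + right)) < _EPS:
            _traceback_WM(i + 1, k, s, params, wobble, V, WM, pairs)
            _traceback_WM(k + 1, j - 1, s, params, wobble, V, WM, pairs)
            return
    raise FoldingError("V traceback failed")  # pragma: no cover


def _traceback_WM(i, j, s, params, wobble, V, WM, pairs) -> None:
    target = WM[i][j]
    if V[i][j] < INF and abs(target - (V[i][j] + params.multi_b)) < _EPS:
        _traceback_V(i, j, s, params, wobble, V, WM, pairs)
        return
    if WM[i + 1][j] < INF and abs(target - (WM[i + 1][j] + params.multi_c)) < _EPS:
        _traceback_WM(i + 1, j, s, params, wobble, V, WM, pairs)
        return
    if WM[i][j - 1] < INF and abs(target - (WM[i][j - 1] + params.multi_c)) < _EPS:
        _traceback_WM(i, j - 1, s, params, wobble, V, WM, pairs)
        return
    for k in range(i + 1, j + 1):
        left, right = WM[i][k - 1], WM[k][j]
        if left < INF and right < INF and abs(target - (left + right)) < _EPS:
            _traceback_WM(i, k - 1, s, params, wobble, V, WM, pairs)
            _traceback_WM(k, j, s, params, wobble, V, WM, pairs)
            return
    raise FoldingError("WM traceback failed")  # pragma: no cover


def fold_pool(records, params: EnergyParameters | None = None, wobble: bool = True) -> dict:
    """Fold every record of a pool; returns ``{record.key: SecondaryStructure}``.

    Identical sequence strings are folded once (pools are redundant).
    """
    cache: dict[str, SecondaryStructure] = {}
    out = {}
    for rec in records:
        if rec.sequence not in cache:
            cache[rec.sequence] = fold_mfe(rec.sequence, params, wobble)
        st = cache[rec.sequence]
        out[rec.key] = SecondaryStructure(rec.sequence, st.pairs, st.energy_E)
    return out


# ---------------------------------------------------------------------------
# loop enumeration and the 5-7-nt selection rule
# ---------------------------------------------------------------------------

def enumerate_loops(structure: SecondaryStructure) -> list[LoopRegion]:
    """All loops (hairpin/bulge/internal/multi) of a structure, 5'→3'.

    Exterior unpaired nucleotides belong to no loop.  Together the loops and
    the exterior partition the unpaired positions.
    """
    loops = []
    for kind, closing, inner, positions in decompose(structure.sequence, structure.pairs):
        if kind in ("exterior", "stack") or not positions:
            continue
        loops.append(LoopRegion(kind, positions))
    loops.sort(key=lambda lp: lp.start)
    return loops


def select_loop(loops: list[LoopRegion]) -> LoopRegion:
    """Pick the descriptor loop: 5–7-nt loops have priority.

    Among in-range loops, hairpins are preferred, then the 5'-most wins.  If
    no loop has 5–7 nt, the loop whose size is nearest to 6 is taken (ties:
    smaller size, then 5'-most).
    """
    if not loops:
        raise FoldingError("no pair structure: sequence has no loops")
    in_range = [lp for lp in loops if 5 <= lp.n_nucleotides <= 7]
    if in_range:
        hairpins = [lp for lp in in_range if lp.kind == "hairpin"]
        pool = hairpins or in_range
        return min(pool, key=lambda lp: lp.start)
    return min(loops, key=lambda lp: (abs(lp.n_nucleotides - 6), lp.n_nucleotides, lp.start))


def loop_sequence(structure: SecondaryStructure, loop: LoopRegion) -> str:
    """Nucleotides of a loop, 5'→3'."""
    return "".join(structure.sequence[p] for p in sorted(loop.positions))
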