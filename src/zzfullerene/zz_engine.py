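"""Zhang-Zhang (Clar covering) polynomials by memoized recursive decomposition.

The ZZ polynomial of a plane graph B is ``ZZ(B, x) = sum_k c_k x^k`` where
``c_k`` counts the Clar covers of order k: spanning subgraphs whose components
are single edges (K2, double bonds) or 6-cycles (C6, aromatic sextets), with k
sextets.  Evaluations recover the classical invariants: the Kekule count
``K = ZZ(B, 0)``, the Clar count ``C = ZZ(B, 1)``, the Clar number
``Cl = deg ZZ`` and the Clar-formula count (the leading coefficient).

The computation branches on a pivot vertex u: u is covered either by a double
bond to one of its neighbours or by one of the 6-cycles through it, so

    ZZ(G[S]) = sum_{v in N(u) & S} ZZ(G[S - {u, v}])
             + x * sum_{rings h with u in h, h ⊆ S} ZZ(G[S - V(h)])

Every recursion state is an induced subgraph of the input, so the memo key is
simply the bit-set of live vertices; coefficients are exact Python integers.

Independent oracles (:func:`zz_via_enumeration`, :func:`matching_count_oracle`)
recompute the same quantities by exhaustive backtracking and by memo-free edge
branching, and share no code path with the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "ZZPolynomial",
    "ClarCover",
    "InvariantRecord",
    "ZZEngine",
    "sextet_candidates",
    "zz",
    "kekule_count",
    "clar_count",
    "clar_number",
    "clar_formula_count",
    "enumerate_clar_covers",
    "zz_via_enumeration",
    "matching_count_oracle",
    "invariant_record",
]

DEFAULT_SIZE_LIMIT = 120


class ZZPolynomial:
    """Integer-coefficient polynomial ``c0 + c1 x + ... + cCl x^Cl``.

    The zero polynomial (graphs with no Clar cover at all) has an empty
    coefficient tuple and reports Clar number -1.
    """

    __slots__ = ("coeffs",)

    def __init__(self, coeffs):
        cs = list(coeffs)
        while cs and cs[-1] == 0:
            cs.pop()
        self.coeffs = tuple(cs)

    def __call__(self, x):
        acc = 0
        for c in reversed(self.coeffs):
            acc = acc * x + c
        return acc

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    @property
    def kekule_count(self) -> int:
        return self.coeffs[0] if self.coeffs else 0

    @property
    def clar_count(self) -> int:
        return sum(self.coeffs)

    @property
    def clar_number(self) -> int:
        return self.degree  # -1 for the zero polynomial ("no cover")

    @property
    def clar_formula_count(self) -> int:
        return self.coeffs[-1] if self.coeffs else 0

    def __eq__(self, other):
        if isinstance(other, ZZPolynomial):
            return self.coeffs == other.coeffs
        return NotImplemented

    def __hash__(self):
        return hash(self.coeffs)

    def __bool__(self):
        return bool(self.coeffs)

    def text(self) -> str:
        """Plain coefficient list: ``"11 15 5"``."""
        return " ".join(str(c) for c in self.coeffs) if self.coeffs else "0"

    def __str__(self) -> str:
        if not self.coeffs:
            return "0"
        terms = []
        for k, c in enumerate(self.coeffs):
            if c == 0:
                continue
            if k == 0:
                terms.append(str(c))
            elif k == 1:
                terms.append(f"{c} x")
            else:
                terms.append(f"{c} x^{k}")
        return " + ".join(terms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ZZPolynomial({self})"


@dataclass(frozen=True)
class ClarCover:
    """One explicit Clar cover: disjoint double bonds plus sextet rings."""

    double_bonds: frozenset  # frozenset of (u, v) with u < v
    sextets: frozenset       # frozenset of canonical 6-cycles (vertex tuples)

    @property
    def order(self) -> int:
        return len(self.sextets)

    def vertices(self) -> frozenset:
        vs = {v for e in self.double_bonds for v in e}
        vs |= {v for h in self.sextets for v in h}
        return frozenset(vs)


@dataclass(frozen=True)
class InvariantRecord:
    """Per-isomer bundle of the ZZ-derived invariants."""

    name: str
    n: int
    m: int | None
    kekule: int
    clar_count: int
    clar_number: int
    clar_formulas: int
    coeffs: tuple[int, ...]

    @property
    def polynomial(self) -> ZZPolynomial:
        return ZZPolynomial(self.coeffs)


def _as_nx(graph) -> nx.Graph:
    return graph.to_nx() if hasattr(graph, "to_nx") else graph


def _canonical_cycle(cycle) -> tuple[int, ...]:
    """Rotate/reflect a vertex cycle into a canonical tuple."""
    n = len(cycle)
    best = None
    for seq in (list(cycle), list(reversed(cycle))):
        i = seq.index(min(seq))
        rot = tuple(seq[i:] + seq[:i])
        if best is None or rot < best:
            best = rot
    return best


def sextet_candidates(graph) -> list[tuple[int, ...]]:
    """All simple 6-cycles of the graph, as canonical vertex tuples.

    For fullerene cages these are exactly the hexagonal faces (no accidental
    non-facial 6-cycles exist in a cage of girth 5); for corannulene-like
    molecules they are the hexagonal rings.
    """
    g = _as_nx(graph)
    out = {
        _canonical_cycle(c)
        for c in nx.simple_cycles(g, length_bound=6)
        if len(c) == 6
    }
    return sorted(out)


class ZZEngine:
    """Decomposition engine bound to one graph; memo shared across queries.

    Queries take a bit-mask of live vertices, so induced-subgraph invariants
    (as needed for Pauling bond orders) reuse the cache of the parent graph.
    """

    def __init__(self, graph, pivot: str = "min_degree",
                 size_limit: int = DEFAULT_SIZE_LIMIT):
        g = _as_nx(graph)
        self.nodes = sorted(g.nodes)
        self.n = len(self.nodes)
        if self.n > size_limit:
            raise ValueError(
                f"graph with {self.n} vertices exceeds size limit {size_limit}"
            )
        if pivot not in ("min_degree", "min_index"):
            raise ValueError(f"unknown pivot policy {pivot!r}")
        self.pivot = pivot
        idx = {v: i for i, v in enumerate(self.nodes)}
        self.index = idx
        self.adj = [0] * self.n
        for u, v in g.edges:
            self.adj[idx[u]] |= 1 << idx[v]
            self.adj[idx[v]] |= 1 << idx[u]
        self.rings: list[int] = []
        self.rings_by_vertex: list[list[int]] = [[] for _ in range(self.n)]
        for cyc in sextet_candidates(g):
            mask = 0
            for v in cyc:
                mask |= 1 << idx[v]
            self.rings.append(mask)
            for v in cyc:
                self.rings_by_vertex[idx[v]].append(mask)
        self.full_mask = (1 << self.n) - 1
        self._memo: dict[int, tuple[int, ...]] = {}
        self._memo_k: dict[int, int] = {}

    # -- helpers -----------------------------------------------------------

    def mask_without(self, vertices) -> int:
        m = self.full_mask
        for v in vertices:
            m &= ~(1 << self.index[v])
        return m

    def _pick(self, live: int) -> int:
        if self.pivot == "min_index":
            return (live & -live).bit_length() - 1
        best_u, best_d = -1, 99
        m = live
        while m:
            lsb = m & -m
            u = lsb.bit_length() - 1
            d = (self.adj[u] & live).bit_count()
            if d < best_d:
                best_u, best_d = u, d
                if d == 0:
                    break
            m ^= lsb
        return best_u

    # -- ZZ polynomial on an induced subgraph ------------------------------

    def poly(self, live: int) -> tuple[int, ...]:
        """Coefficient tuple of ZZ on the induced subgraph ``live`` (bit-mask)."""
        if live == 0:
            return (1,)
        memo = self._memo
        hit = memo.get(live)
        if hit is not None:
            return hit
        u = self._pick(live)
        ubit = 1 << u
        acc: list[int] = []
        m = self.adj[u] & live
        rest = live & ~ubit
        while m:
            lsb = m & -m
            sub = self.poly(rest & ~lsb)
            if len(sub) > len(acc):
                acc.extend([0] * (len(sub) - len(acc)))
            for i, c in enumerate(sub):
                acc[i] += c
            m ^= lsb
        for ring in self.rings_by_vertex[u]:
            if ring & live == ring:
                sub = self.poly(live & ~ring)
                if len(sub) + 1 > len(acc):
                    acc.extend([0] * (len(sub) + 1 - len(acc)))
                for i, c in enumerate(sub):
                    acc[i + 1] += c
        while acc and acc[-1] == 0:
            acc.pop()
        res = tuple(acc)
        memo[live] = res
        return res

    # -- Kekule (perfect-matching) count, no sextet branching --------------

    def match_count(self, live: int) -> int:
        """Perfect-matching count of the induced subgraph ``live``."""
        if live == 0:
            return 1
        memo = self._memo_k
        hit = memo.get(live)
        if hit is not None:
            return hit
        u = self._pick(live)
        ubit = 1 << u
        total = 0
        m = self.adj[u] & live
        rest = live & ~ubit
        while m:
            lsb = m & -m
            total += self.match_count(rest & ~lsb)
            m ^= lsb
        memo[live] = total
        return total

    def zz(self) -> ZZPolynomial:
        return ZZPolynomial(self.poly(self.full_mask))


def zz(graph, pivot: str = "min_degree",
       size_limit: int = DEFAULT_SIZE_LIMIT) -> ZZPolynomial:
    """The Zhang-Zhang polynomial of ``graph`` (exact integer coefficients)."""
    g = _as_nx(graph)
    if g.number_of_nodes() == 0:
        return ZZPolynomial((1,))
    if g.number_of_nodes() % 2:
        return ZZPolynomial(())
    return ZZEngine(g, pivot=pivot, size_limit=size_limit).zz()


def kekule_count(graph, size_limit: int = DEFAULT_SIZE_LIMIT) -> int:
    """Number of Kekule structures (perfect matchings): ``ZZ(B, 0)``."""
    g = _as_nx(graph)
    if g.number_of_nodes() == 0:
        return 1
    if g.number_of_nodes() % 2:
        return 0
    return ZZEngine(g, size_limit=size_limit).match_count((1 << len(g)) - 1)


def clar_count(graph, **kw) -> int:
    """Total number of Clar covers: ``ZZ(B, 1)``."""
    return zz(graph, **kw)(1)


def clar_number(graph, **kw) -> int:
    """Maximal sextet order ``Cl = deg ZZ``; -1 if no cover exists."""
    return zz(graph, **kw).clar_number


def clar_formula_count(graph, **kw) -> int:
    """Number of Clar formulas (covers of maximal order): leading coefficient."""
    return zz(graph, **kw).clar_formula_count


def invariant_record(graph, name: str = "", n: int | None = None,
                     m: int | None = None, **kw) -> InvariantRecord:
    """Compute the ZZ polynomial once and bundle all derived invariants."""
    p = zz(graph, **kw)
    g = _as_nx(graph)
    return InvariantRecord(
        name=name or getattr(graph, "name", ""),
        n=n if n is not None else g.number_of_nodes(),
        m=m,
        kekule=p.kekule_count,
        clar_count=p.clar_count,
        clar_number=p.clar_number,
        clar_formulas=p.clar_formula_count,
        coeffs=p.coeffs,
    )


# -- independent oracles -----------------------------------------------------


def enumerate_clar_covers(graph, guard: int = 32) -> list[ClarCover]:
    """Exhaustively enumerate all Clar covers by backtracking (oracle).

    Covers the lowest-index uncovered vertex by each incident edge or each
    candidate 6-cycle through it; duplicate-free by construction.  Guarded to
    small graphs, exponential on purpose.
    """
    g = _as_nx(graph)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n > guard:
        raise ValueError(f"enumeration guard: {n} vertices > {guard}")
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [[] for _ in range(n)]
    for u, v in g.edges:
        adj[idx[u]].append(idx[v])
        adj[idx[v]].append(idx[u])
    rings = []
    for cyc in sextet_candidates(g):
        mask = 0
        for v in cyc:
            mask |= 1 << idx[v]
        rings.append((mask, cyc))
    rings_by_vertex = [[] for _ in range(n)]
    for mask, cyc in rings:
        for v in cyc:
            rings_by_vertex[idx[v]].append((mask, cyc))
    covers: list[ClarCover] = []

    def rec(live, bonds, sexts):
        if live == 0:
            covers.append(ClarCover(frozenset(bonds), frozenset(sexts)))
            return
        u = (live & -live).bit_length() - 1
        for v in adj[u]:
            vbit = 1 << v
            if live & vbit:
                a, b = nodes[u], nodes[v]
                bonds.append((min(a, b), max(a, b)))
                rec(live & ~(1 << u) & ~vbit, bonds, sexts)
                bonds.pop()
        for mask, cyc in rings_by_vertex[u]:
            if mask & live == mask:
                sexts.append(cyc)
                rec(live & ~mask, bonds, sexts)
                sexts.pop()

    rec((1 << n) - 1, [], [])
    return covers


def zz_via_enumeration(graph, guard: int = 32) -> ZZPolynomial:
    """ZZ polynomial as the order histogram of the exhaustive enumeration."""
    covers = enumerate_clar_covers(graph, guard=guard)
    if not covers:
        return ZZPolynomial(())
    top = max(c.order for c in covers)
    hist = [0] * (top + 1)
    for c in covers:
        hist[c.order] += 1
    return ZZPolynomial(hist)


def matching_count_oracle(graph) -> int:
    """Perfect-matching count by memo-free edge branching (oracle).

    Uses the deletion/contraction split M(G) = M(G - e) + M(G - u - v) with no
    caching and no sextet logic -- an implementation path fully independent of
    the ZZ decomposition.  Practical up to cage sizes around C70 because the
    branch count is bounded by the number of matchings.
    """
    g = _as_nx(graph)
    adj = {v: set(g.neighbors(v)) for v in g.nodes}

    def rec(adj):
        if not adj:
            return 1
        u = min(adj, key=lambda v: len(adj[v]))
        d = len(adj[u])
        if d == 0:
            return 0
        if d == 1:
            (v,) = adj[u]
            sub = {
                w: {x for x in nb if x != u and x != v}
                for w, nb in adj.items()
                if w != u and w != v
            }
            return rec(sub)
        v = min(adj[u])
        # G - e
        minus_e = {w: set(nb) for w, nb in adj.items()}
        minus_e[u].discard(v)
        minus_e[v].discard(u)
        # G - u - v
        minus_uv = {
            w: {x for x in nb if x != u and x != v}
            for w, nb in adj.items()
            if w != u and w != v
        }
        return rec(minus_e) + rec(minus_uv)

    return rec(adj)
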