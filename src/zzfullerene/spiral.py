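"""Ring-spiral encoding and exhaustive generation of (5,6)-fullerene isomers.

A fullerene cage is encoded as a face spiral: a linear sequence of its
``n/2 + 2`` pentagonal/hexagonal faces such that each new face is attached to
the previous face and to the oldest boundary face of the partially wound cage.
The twelve 1-based positions of the pentagons in that sequence identify the
isomer.  The canonical code of a cage is the lexicographically smallest
pentagon-position tuple over all successful spiral starts, and the isomer
label ``n:m`` ranks the canonical codes of Cn lexicographically -- the
Fowler-Manolopoulos Atlas numbering.

The windup works entirely in the dual (the triangulation whose vertices are
faces): each new face connects to the spiral head and tail, absorbing
saturated boundary faces at both ends; a mismatch at any step is a
:class:`WindupFailure` with the failing face index.  Enumeration is a
depth-first search over face-size sequences with this incremental windup
pruning subtrees; a completed spiral is kept only if it equals its own
canonical form, which deduplicates isomorphic cages without storing graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .graph_core import FullereneGraph, GraphError, PlaneMolecularGraph, \
    _embedding_rotation, validate_fullerene

__all__ = [
    "SpiralCode",
    "IsomerLabel",
    "WindupFailure",
    "WindupError",
    "windup",
    "try_windup",
    "canonical_spiral",
    "generate_spiral_codes",
    "generate_isomers",
    "isomer",
    "isomer_count",
]

SPIRAL_COMPLETE_MAX_N = 70


@dataclass(frozen=True)
class SpiralCode:
    """Pentagon positions (1-based, strictly increasing) in the face spiral."""

    n: int
    positions: tuple[int, ...]

    def __post_init__(self):
        if self.n < 20 or self.n % 2:
            raise ValueError(f"atom count n={self.n} must be even and >= 20")
        pos = tuple(int(p) for p in self.positions)
        object.__setattr__(self, "positions", pos)
        if len(pos) != 12:
            raise ValueError(f"need exactly 12 pentagon positions, got {len(pos)}")
        nf = self.n // 2 + 2
        if list(pos) != sorted(set(pos)):
            raise ValueError("pentagon positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > nf:
            raise ValueError(f"pentagon positions must lie in 1..{nf}")

    @property
    def face_count(self) -> int:
        return self.n // 2 + 2

    def face_sizes(self) -> list[int]:
        pents = set(self.positions)
        return [5 if k + 1 in pents else 6 for k in range(self.face_count)]

    @classmethod
    def from_string(cls, text: str) -> "SpiralCode":
        """Parse ``"60: 1 7 9 11 13 15 18 20 22 24 26 32"`` (colon optional)."""
        toks = text.replace(":", " ").split()
        if len(toks) != 13:
            raise ValueError(
                f"expected 'n p1 .. p12' (13 integers), got {len(toks)} tokens"
            )
        try:
            nums = [int(t) for t in toks]
        except ValueError as exc:
            raise ValueError(f"non-integer token in spiral string: {exc}") from exc
        return cls(nums[0], tuple(nums[1:]))

    def __str__(self) -> str:
        return f"{self.n}: " + " ".join(map(str, self.positions))


@dataclass(frozen=True)
class IsomerLabel:
    """Atlas-style label n:m — the m-th isomer of Cn in lexicographic spiral order."""

    n: int
    m: int

    def __str__(self) -> str:
        return f"{self.n}:{self.m}"


@dataclass(frozen=True)
class WindupFailure:
    """Diagnostic for a spiral that does not close into a cage."""

    step: int  # 1-based index of the face at which the boundary mismatched
    reason: str

    def __bool__(self) -> bool:
        return False


class WindupError(GraphError):
    """Raised by :func:`windup` when the spiral code is unrealizable."""

    def __init__(self, code: SpiralCode, failure: WindupFailure):
        super().__init__(f"spiral {code} fails to wind up at face {failure.step}: "
                         f"{failure.reason}")
        self.code = code
        self.failure = failure


# ---------------------------------------------------------------------------
# windup core: face-size sequence -> dual triangulation adjacency
# ---------------------------------------------------------------------------


def _windup_dual(sizes):
    """Wind a face-size sequence into dual adjacency lists.

    Returns ``(adj, None)`` on success or ``(None, failed_step)`` (0-based face
    index) when the boundary bookkeeping cannot continue.
    """
    nf = len(sizes)
    c = [0] * nf  # open (unused) valences per face
    adj = [[] for _ in range(nf)]
    c[0], c[1] = sizes[0] - 1, sizes[1] - 1
    adj[0].append(1)
    adj[1].append(0)
    j = 0  # tail face
    for i in range(2, nf - 1):
        ci = sizes[i]
        head = i - 1
        if c[head] == 0 or j == head:
            return None, i
        adj[i].append(head)
        adj[head].append(i)
        c[head] -= 1
        ci -= 1
        adj[i].append(j)
        adj[j].append(i)
        c[j] -= 1
        ci -= 1
        if c[j] < 0:
            return None, i
        while c[j] == 0:
            j += 1
            if j >= head:
                return None, i
            adj[i].append(j)
            adj[j].append(i)
            c[j] -= 1
            ci -= 1
            if ci < 0 or c[j] < 0:
                return None, i
        h = head
        while c[h] == 0:
            h -= 1
            if h <= j:
                return None, i
            adj[i].append(h)
            adj[h].append(i)
            c[h] -= 1
            ci -= 1
            if ci < 0 or c[h] < 0:
                return None, i
        if ci <= 0:
            return None, i
        c[i] = ci
    # final face must pick up every remaining open valence, one per face
    i = nf - 1
    need = [k for k in range(j, i) if c[k] > 0]
    if len(need) != sizes[i] or any(c[k] != 1 for k in need):
        return None, i
    for k in need:
        adj[i].append(k)
        adj[k].append(i)
        c[k] = 0
    return adj, None


def _dual_to_fullerene(adj, name: str = "") -> FullereneGraph:
    """Convert a wound dual triangulation to the primal cubic cage.

    Primal vertices are the triangles of the dual; two vertices are adjacent
    when their triangles share a dual edge.
    """
    nf = len(adj)
    adjset = [set(a) for a in adj]
    triangles = []
    for f in range(nf):
        for g in adjset[f]:
            if g <= f:
                continue
            for h in adjset[f] & adjset[g]:
                if h > g:
                    triangles.append((f, g, h))
    n = 2 * (nf - 2)
    if len(triangles) != n:
        raise GraphError(
            f"dual has {len(triangles)} triangles, expected {n}; windup inconsistent"
        )
    by_pair: dict[tuple[int, int], list[int]] = {}
    for t_id, tri in enumerate(triangles):
        for a, b in combinations(tri, 2):
            by_pair.setdefault((a, b), []).append(t_id)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for pair, ts in by_pair.items():
        if len(ts) != 2:
            raise GraphError("dual edge not shared by exactly two triangles")
        g.add_edge(ts[0], ts[1])
    return FullereneGraph(_embedding_rotation(g), name=name)


def try_windup(code: SpiralCode):
    """Wind up a spiral code; return a :class:`FullereneGraph` or a
    :class:`WindupFailure` diagnostic."""
    adj, failed = _windup_dual(code.face_sizes())
    if adj is None:
        return WindupFailure(failed + 1, "boundary mismatch while closing the cage")
    return _dual_to_fullerene(adj, name=str(code))


def windup(code: SpiralCode) -> FullereneGraph:
    """Wind up a spiral code into a validated fullerene graph (or raise)."""
    res = try_windup(code)
    if isinstance(res, WindupFailure):
        raise WindupError(code, res)
    return res


# ---------------------------------------------------------------------------
# unwind: extract the spiral starting from a chosen face pair + direction
# ---------------------------------------------------------------------------


def _unwind(adjset, deg, f1, f2, f3, ref):
    """Mirror of the windup driven by an existing dual triangulation.

    Walks the spiral that starts with adjacent faces ``f1, f2`` and turns
    towards ``f3``; each subsequent face is the unused common neighbour of the
    spiral head and tail, and every forced boundary connection is checked
    against the true adjacency.  Returns the pentagon-position tuple, or None
    if the spiral jams or (when ``ref`` is given) is lexicographically worse
    than ``ref``.
    """
    nf = len(deg)
    used = bytearray(nf)
    c = [0] * nf
    ord_ = [f1, f2]
    used[f1] = used[f2] = 1
    c[f1] = deg[f1] - 1
    c[f2] = deg[f2] - 1
    pos = []
    better = ref is None
    ri = 0
    for k, f in ((1, f1), (2, f2)):
        if deg[f] == 5:
            pos.append(k)
            if not better:
                r = ref[ri]
                if k > r:
                    return None
                if k < r:
                    better = True
                ri += 1
        elif not better and ri < 12 and ref[ri] == k:
            return None
    j = 0
    for i in range(2, nf):
        head = ord_[i - 1]
        if i == 2:
            g = f3
        else:
            tail = ord_[j]
            tset = adjset[tail]
            g = None
            for cand in adjset[head]:
                if not used[cand] and cand in tset:
                    g = cand
                    break
            if g is None:
                return None
        s = deg[g]
        k = i + 1
        if s == 5:
            pos.append(k)
            if not better:
                r = ref[ri]
                if k > r:
                    return None
                if k < r:
                    better = True
                ri += 1
        elif not better and ri < 12 and ref[ri] == k:
            return None
        used[g] = 1
        if i < nf - 1:
            if c[head] == 0 or j == i - 1:
                return None
            ci = s - 1
            c[head] -= 1
            gset = adjset[g]
            tail = ord_[j]
            if tail not in gset:
                return None
            c[tail] -= 1
            ci -= 1
            if c[tail] < 0:
                return None
            while c[ord_[j]] == 0:
                j += 1
                if j >= i - 1:
                    return None
                t = ord_[j]
                if t not in gset:
                    return None
                c[t] -= 1
                ci -= 1
                if ci < 0 or c[t] < 0:
                    return None
            h = i - 1
            while c[ord_[h]] == 0:
                h -= 1
                if h <= j:
                    return None
                t = ord_[h]
                if t not in gset:
                    return None
                c[t] -= 1
                ci -= 1
                if ci < 0 or c[t] < 0:
                    return None
            if ci <= 0:
                return None
            c[g] = ci
        else:
            gset = adjset[g]
            cnt = 0
            for idx in range(j, i):
                t = ord_[idx]
                if c[t] == 0:
                    continue
                if c[t] != 1 or t not in gset:
                    return None
                cnt += 1
            if cnt != s:
                return None
        ord_.append(g)
    return tuple(pos)


def _spiral_starts(adjset):
    """All (f1, f2, f3) spiral starts: ordered adjacent pair + direction."""
    for f1 in range(len(adjset)):
        for f2 in adjset[f1]:
            for f3 in adjset[f1] & adjset[f2]:
                yield f1, f2, f3


def _lex_min_spiral(adjset, deg, ref=None):
    """Lexicographically smallest pentagon tuple over all spiral starts.

    With ``ref`` given, starts are pruned against the best tuple found so far
    (initially ``ref``); returns the overall minimum (<= ref) or None if no
    spiral at all succeeds.
    """
    best = ref
    found = ref is not None
    for f1, f2, f3 in _spiral_starts(adjset):
        res = _unwind(adjset, deg, f1, f2, f3, best)
        if res is not None:
            if best is None or res < best:
                best = res
            found = True
    return best if found else None


def _is_canonical(adjset, deg, positions) -> bool:
    for f1, f2, f3 in _spiral_starts(adjset):
        res = _unwind(adjset, deg, f1, f2, f3, positions)
        if res is not None and res < positions:
            return False
    return True


def _graph_dual(graph: PlaneMolecularGraph):
    """Face adjacency (as sets) and face sizes of a fullerene graph."""
    report = validate_fullerene(graph)
    if not report.is_valid:
        raise GraphError(f"not a fullerene graph: {'; '.join(report.violations)}")
    faces = graph.faces()
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for e in f.edges:
            edge_faces.setdefault(e, []).append(fi)
    adjset = [set() for _ in faces]
    for fs in edge_faces.values():
        a, b = fs
        adjset[a].add(b)
        adjset[b].add(a)
    deg = [f.size for f in faces]
    return adjset, deg


def canonical_spiral(graph: PlaneMolecularGraph) -> SpiralCode:
    """The lexicographically smallest successful spiral code of a fullerene.

    Deterministic and invariant under vertex relabelling: every face, boundary
    edge and winding direction is tried as a spiral start.
    """
    adjset, deg = _graph_dual(graph)
    best = _lex_min_spiral(adjset, deg)
    if best is None:
        raise GraphError(
            "no face spiral exists for this cage (cannot occur for n <= 70)"
        )
    return SpiralCode(graph.n_vertices, best)


# ---------------------------------------------------------------------------
# exhaustive lexicographic generation
# ---------------------------------------------------------------------------


def _canonical_duals(n):
    """DFS over face-size sequences with incremental windup.

    Yields ``(positions, adj)`` for every canonical spiral code of Cn in
    lexicographic order; ``adj`` is the completed dual adjacency.  The windup
    state is updated in place; all connections of face i are made at step i,
    so undoing a step only touches ``partners[i]``.  Iterative with an
    explicit stack -- this loop is the hot path of exhaustive generation.
    """
    nf = n // 2 + 2
    c = [0] * nf                       # open valences per face
    partners = [[] for _ in range(nf)]  # earlier faces each face connected to
    sizes = [0] * nf
    j_at = [0] * nf      # tail face before placing face i
    pents_at = [0] * nf  # pentagons still to place before face i
    stage = [0] * nf     # 0: try pentagon next, 1: try hexagon, 2: exhausted
    last = nf - 1
    pents_at[0] = 12
    i = 0
    while i >= 0:
        if i == last:
            pents_left = pents_at[i]
            if pents_left <= 1:
                s = 5 if pents_left == 1 else 6
                j = j_at[i]
                need = [k for k in range(j, i) if c[k] > 0]
                if len(need) == s and all(c[k] == 1 for k in need):
                    sizes[i] = s
                    partners[i] = need
                    adj = [[] for _ in range(nf)]
                    for a in range(nf):
                        for b in partners[a]:
                            adj[a].append(b)
                            adj[b].append(a)
                    partners[i] = []
                    positions = tuple(
                        k + 1 for k in range(nf) if sizes[k] == 5
                    )
                    if _is_canonical([set(a) for a in adj], sizes, positions):
                        yield positions, adj
            i -= 1
            pl = partners[i]
            for b in pl:
                c[b] += 1
            pl.clear()
            c[i] = 0
            continue
        st = stage[i]
        if st >= 2:
            i -= 1
            if i >= 0:
                pl = partners[i]
                for b in pl:
                    c[b] += 1
                pl.clear()
                c[i] = 0
            continue
        stage[i] = st + 1
        s = 5 if st == 0 else 6
        pents_left = pents_at[i]
        faces_left = nf - i
        if s == 5:
            if pents_left == 0:
                continue
        elif faces_left <= pents_left:
            continue
        j = j_at[i]
        if i == 0:
            c[0] = s
            nj = 0
        elif i == 1:
            c[1] = s - 1
            c[0] -= 1
            partners[1].append(0)
            nj = 0
        else:
            head = i - 1
            if c[head] == 0 or j == head:
                continue
            pl = partners[i]
            ci = s - 1
            c[head] -= 1
            pl.append(head)
            c[j] -= 1
            pl.append(j)
            ci -= 1
            nj = j
            ok = True
            while c[nj] == 0:  # absorb saturated tail faces
                nj += 1
                if nj >= head:
                    ok = False
                    break
                c[nj] -= 1
                pl.append(nj)
                ci -= 1
                if ci < 0:
                    ok = False
                    break
            if ok:
                h = head
                while c[h] == 0:  # absorb saturated head faces
                    h -= 1
                    if h <= nj:
                        ok = False
                        break
                    c[h] -= 1
                    pl.append(h)
                    ci -= 1
                    if ci < 0:
                        ok = False
                        break
            if not ok or ci <= 0:
                for b in pl:
                    c[b] += 1
                pl.clear()
                continue
            c[i] = ci
        sizes[i] = s
        i += 1
        j_at[i] = nj
        pents_at[i] = pents_left - (s == 5)
        stage[i] = 0


def _check_generation_n(n):
    if n < 20 or n % 2:
        raise ValueError(f"atom count n={n} must be even and >= 20")
    if n > SPIRAL_COMPLETE_MAX_N:
        warnings.warn(
            f"n={n} > {SPIRAL_COMPLETE_MAX_N}: face spirals are only guaranteed "
            "complete up to C70; some isomers may be missed",
            stacklevel=3,
        )


def generate_spiral_codes(n, limit: int | None = None, fast: bool = True):
    """Canonical spiral codes of Cn in lexicographic order (no graph built).

    Uses the JIT-compiled enumeration when numba is importable (``fast=True``);
    ``fast=False`` forces the pure-Python reference DFS, which yields the same
    codes in the same order.
    """
    _check_generation_n(n)
    from ._spiral_fast import HAVE_NUMBA, enumerate_codes_fast

    if fast and HAVE_NUMBA:
        for row in enumerate_codes_fast(n, limit):
            yield SpiralCode(n, tuple(int(p) for p in row))
        return
    count = 0
    for positions, _adj in _canonical_duals(n):
        count += 1
        yield SpiralCode(n, positions)
        if limit is not None and count >= limit:
            return


def generate_isomers(n, limit: int | None = None, fast: bool = True):
    """Yield ``(IsomerLabel, SpiralCode, FullereneGraph)`` for all distinct
    isomers of Cn, deduplicated via canonical spirals, in lexicographic order."""
    for m, code in enumerate(generate_spiral_codes(n, limit=limit, fast=fast), 1):
        yield IsomerLabel(n, m), code, windup(code)


def isomer(n: int, m: int) -> FullereneGraph:
    """The m-th isomer of Cn in lexicographic spiral order (early-terminating)."""
    if m < 1:
        raise ValueError(f"isomer rank m={m} must be >= 1")
    codes = list(generate_spiral_codes(n, limit=m))
    if len(codes) < m:
        raise ValueError(f"C{n} has fewer than {m} isomers")
    graph = windup(codes[m - 1])
    graph.name = f"{n}:{m}"
    return graph


def isomer_count(n: int) -> int:
    """Number of distinct (5,6)-fullerene isomers of Cn."""
    return sum(1 for _ in generate_spiral_codes(n))
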