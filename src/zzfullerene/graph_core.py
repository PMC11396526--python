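"""Plane molecular graphs with pentagon and hexagon faces.

A (5,6)-fullerene is modelled as a 2-connected cubic plane graph whose faces
are exactly 12 pentagons and ``n/2 - 10`` hexagons; corannulene-like
polycyclics are the same object with implicit-hydrogen CH positions showing up
as degree-2 vertices and one large outer face.  The plane structure is carried
as a rotation system (cyclic neighbour order around every vertex), from which
faces are traced combinatorially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "GraphError",
    "Face",
    "PlaneMolecularGraph",
    "FullereneGraph",
    "FullereneValidation",
    "build_from_adjacency",
    "read_xyz",
    "write_xyz",
    "read_graph",
    "write_graph",
    "trace_faces",
    "validate_fullerene",
    "pentagon_adjacency_count",
    "naive_spherical_layout",
    "fixture_corannulene",
    "fixture_dodecahedron",
    "fixture_truncated_icosahedron",
]


class GraphError(ValueError):
    """Raised when an input cannot be interpreted as a pentagon/hexagon plane graph."""


@dataclass(frozen=True)
class Face:
    """A face of the plane embedding: a simple cycle of vertices."""

    vertices: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.vertices)

    @property
    def kind(self) -> str:
        return {5: "pentagon", 6: "hexagon"}.get(self.size, "other")

    @property
    def is_pentagon(self) -> bool:
        return self.size == 5

    @property
    def is_hexagon(self) -> bool:
        return self.size == 6

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        cyc = self.vertices
        return tuple(
            (min(a, b), max(a, b)) for a, b in zip(cyc, cyc[1:] + cyc[:1])
        )


class PlaneMolecularGraph:
    """A 2-connected plane graph with vertex degrees 2 or 3.

    Parameters
    ----------
    rotation
        Mapping ``vertex -> cyclic neighbour order``; vertices must be the
        contiguous integers ``0 .. n-1``.  The rotation system defines the
        plane embedding and hence the faces.
    coords
        Optional ``(n, 3)`` array of Cartesian coordinates in Angstrom.
    name
        Optional label carried through I/O.
    """

    def __init__(self, rotation, coords=None, name: str = ""):
        n = len(rotation)
        if sorted(rotation) != list(range(n)):
            raise GraphError("vertex ids must be contiguous integers 0..n-1")
        self.rotation: dict[int, tuple[int, ...]] = {
            v: tuple(nbrs) for v, nbrs in rotation.items()
        }
        for v, nbrs in self.rotation.items():
            if len(set(nbrs)) != len(nbrs):
                raise GraphError(f"repeated neighbour in rotation of vertex {v}")
            if not 2 <= len(nbrs) <= 3 and n > 2:
                raise GraphError(f"vertex {v} has degree {len(nbrs)}, need 2 or 3")
            for u in nbrs:
                if v not in rotation[u]:
                    raise GraphError(f"edge {v}-{u} not symmetric")
        self.name = name
        self.coords = None if coords is None else np.asarray(coords, dtype=float)
        if self.coords is not None and self.coords.shape != (n, 3):
            raise GraphError("coords must have shape (n, 3)")
        g = self.to_nx()
        if not nx.is_connected(g):
            raise GraphError("graph is disconnected")
        if n > 2 and not nx.is_biconnected(g):
            raise GraphError("graph is not 2-connected")
        self._faces: list[Face] | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.rotation)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (v, u) for v, nbrs in self.rotation.items() for u in nbrs if v < u
        )

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.rotation.values()) // 2

    def degree(self, v: int) -> int:
        return len(self.rotation[v])

    def neighbors(self, v: int) -> tuple[int, ...]:
        return self.rotation[v]

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges)
        return g

    # -- faces -------------------------------------------------------------

    def faces(self) -> list[Face]:
        """All faces of the embedding (sphere convention: no face is special)."""
        if self._faces is None:
            self._faces = trace_faces(self)
        return self._faces

    @property
    def pentagons(self) -> list[Face]:
        return [f for f in self.faces() if f.is_pentagon]

    @property
    def hexagons(self) -> list[Face]:
        return [f for f in self.faces() if f.is_hexagon]

    def outer_face(self) -> Face | None:
        """The unique face larger than a hexagon, if any (disk-shaped molecules)."""
        big = [f for f in self.faces() if f.size > 6]
        return big[0] if len(big) == 1 else None

    def validate_pentagon_hexagon(self) -> None:
        """Raise unless every face is a pentagon or hexagon, allowing one outer face."""
        if self.n_vertices <= 2:  # a lone bond has no ring faces to validate
            return
        small = [f for f in self.faces() if f.size < 5]
        big = [f for f in self.faces() if f.size > 6]
        if small:
            raise GraphError(
                f"face of size {small[0].size} found; only pentagons/hexagons allowed"
            )
        if len(big) > 1:
            raise GraphError(
                f"{len(big)} faces larger than hexagons; at most one outer face allowed"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" {self.name!r}" if self.name else ""
        return (
            f"<{type(self).__name__}{tag} V={self.n_vertices} "
            f"E={self.n_edges} F={len(self.faces())}>"
        )


class FullereneGraph(PlaneMolecularGraph):
    """A cubic pentagon/hexagon cage: 12 pentagons, ``n/2 - 10`` hexagons."""

    def __init__(self, rotation, coords=None, name: str = ""):
        super().__init__(rotation, coords=coords, name=name)
        report = validate_fullerene(self)
        if not report.is_valid:
            raise GraphError(f"not a fullerene graph: {'; '.join(report.violations)}")

    @property
    def n_atoms(self) -> int:
        return self.n_vertices


@dataclass
class FullereneValidation:
    """Outcome of checking the (5,6)-fullerene structure conditions."""

    n_vertices: int
    pentagon_count: int
    hexagon_count: int
    other_face_count: int
    cubic: bool
    two_connected: bool
    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations


def _embedding_rotation(g: nx.Graph) -> dict[int, tuple[int, ...]]:
    ok, emb = nx.check_planarity(g)
    if not ok:
        raise GraphError("graph is not planar")
    return {v: tuple(emb.neighbors_cw_order(v)) for v in g.nodes}


def trace_faces(graph: PlaneMolecularGraph) -> list[Face]:
    """Trace all faces of the rotation system.

    Each directed edge (dart) is used exactly once; the traced faces satisfy
    Euler's relation V - E + F = 2 for a valid spherical embedding.
    """
    rotation = graph.rotation
    index = {
        (u, v): i for v, nbrs in rotation.items() for i, u in enumerate(nbrs)
    }
    seen: set[tuple[int, int]] = set()
    faces: list[Face] = []
    for start in index:
        if start in seen:
            continue
        cycle: list[int] = []
        dart = start
        while dart not in seen:
            seen.add(dart)
            u, v = dart
            cycle.append(u)
            nbrs = rotation[v]
            w = nbrs[(index[(u, v)] + 1) % len(nbrs)]
            dart = (v, w)
        if dart != start:
            raise GraphError("inconsistent rotation system: face trace did not close")
        faces.append(Face(tuple(cycle)))
    v, e, f = graph.n_vertices, graph.n_edges, len(faces)
    if v - e + f != 2:
        raise GraphError(f"Euler relation violated: V-E+F = {v - e + f} != 2")
    return faces


def build_from_adjacency(adjacency, coords=None, name: str = "", strict: bool = True):
    """Build a :class:`PlaneMolecularGraph` from adjacency data.

    ``adjacency`` may be a symmetric 0/1 matrix, an ``nx.Graph``, or a mapping /
    sequence of neighbour lists.  A planar embedding is computed; with
    ``strict=True`` every face must be a pentagon or hexagon (one larger outer
    face is tolerated for disk-shaped molecules such as corannulene).
    """
    if isinstance(adjacency, nx.Graph):
        g = adjacency
    elif isinstance(adjacency, dict):
        g = nx.Graph((v, u) for v, nbrs in adjacency.items() for u in nbrs)
    else:
        arr = np.asarray(adjacency)
        if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
            if not np.array_equal(arr, arr.T):
                raise GraphError("adjacency matrix is not symmetric")
            if np.any(np.diag(arr) != 0):
                raise GraphError("adjacency matrix has nonzero diagonal")
            g = nx.from_numpy_array(arr)
        else:
            g = nx.Graph(
                (v, u) for v, nbrs in enumerate(adjacency) for u in nbrs
            )
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    if g.number_of_nodes() == 0:
        raise GraphError("empty graph")
    degs = {d for _, d in g.degree}
    if g.number_of_nodes() > 2 and not degs <= {2, 3}:
        raise GraphError(f"vertex degrees {sorted(degs)} outside {{2, 3}}")
    if not nx.is_connected(g):
        raise GraphError("graph is disconnected")
    rotation = _embedding_rotation(g)
    pg = PlaneMolecularGraph(rotation, coords=coords, name=name)
    if strict:
        pg.validate_pentagon_hexagon()
    return pg


def validate_fullerene(graph: PlaneMolecularGraph) -> FullereneValidation:
    """Check the (5,6)-fullerene conditions and report every violation.

    A valid cage is cubic and 2-connected with exactly 12 pentagonal faces and
    ``n/2 - 10`` hexagonal faces (all faces counted, sphere convention).
    """
    n = graph.n_vertices
    faces = graph.faces()
    pent = sum(f.is_pentagon for f in faces)
    hexa = sum(f.is_hexagon for f in faces)
    other = len(faces) - pent - hexa
    cubic = all(graph.degree(v) == 3 for v in range(n))
    two_conn = True  # enforced at construction
    violations = []
    if not cubic:
        violations.append("not all vertices have degree 3")
    if other:
        violations.append(f"{other} faces are neither pentagons nor hexagons")
    if pent != 12:
        violations.append(f"pentagon count {pent} != 12")
    if cubic and hexa != n // 2 - 10:
        violations.append(f"hexagon count {hexa} != n/2 - 10 = {n // 2 - 10}")
    return FullereneValidation(n, pent, hexa, other, cubic, two_conn, violations)


def pentagon_adjacency_count(graph: PlaneMolecularGraph) -> int:
    """Number of edges shared by two pentagonal faces (0 iff the cage is IPR)."""
    edge_faces: dict[tuple[int, int], list[Face]] = {}
    for f in graph.faces():
        for e in f.edges:
            edge_faces.setdefault(e, []).append(f)
    return sum(
        1
        for fs in edge_faces.values()
        if len(fs) == 2 and fs[0].is_pentagon and fs[1].is_pentagon
    )


# -- file I/O ----------------------------------------------------------------


def read_xyz(path, bond_cutoff: float = 1.70, name: str | None = None):
    """Read an XYZ file and perceive C-C bonds by a distance cutoff (Angstrom).

    Hydrogens are dropped (CH positions appear as degree-2 carbons).  An edge
    is drawn between two carbons closer than ``bond_cutoff``.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    try:
        count = int(lines[0].split()[0])
        comment = lines[1] if len(lines) > 1 else ""
        rows = [ln.split() for ln in lines[2 : 2 + count]]
        elements = [r[0] for r in rows]
        xyz = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    except (IndexError, ValueError) as exc:
        raise GraphError(f"unparsable XYZ file {path!r}: {exc}") from exc
    if len(rows) != count:
        raise GraphError(f"XYZ file {path!r} declares {count} atoms, has {len(rows)}")
    keep = [i for i, el in enumerate(elements) if el.upper() != "H"]
    xyz = xyz[keep]
    m = len(xyz)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    adj = (d < bond_cutoff) & ~np.eye(m, dtype=bool)
    g = nx.from_numpy_array(adj.astype(int))
    if not nx.is_connected(g):
        raise GraphError(
            f"bond perception with cutoff {bond_cutoff} A gives a disconnected "
            "graph (cutoff too small?)"
        )
    return build_from_adjacency(
        g, coords=xyz, name=name if name is not None else comment.strip()
    )


def write_xyz(graph: PlaneMolecularGraph, path) -> None:
    if graph.coords is None:
        raise GraphError("graph has no coordinates")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{graph.n_vertices}\n{graph.name}\n")
        for x, y, z in graph.coords:
            fh.write(f"C {x:.6f} {y:.6f} {z:.6f}\n")


def write_graph(graph: PlaneMolecularGraph, path) -> None:
    """Write the adjacency-list text format: header ``n <count>``, then line i
    listing the 1-based neighbours of vertex i."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"n {graph.n_vertices}\n")
        for v in range(graph.n_vertices):
            fh.write(" ".join(str(u + 1) for u in graph.rotation[v]) + "\n")


def read_graph(path, name: str = "", strict: bool = True) -> PlaneMolecularGraph:
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("n "):
        raise GraphError(f"malformed graph file {path!r}: missing 'n <count>' header")
    try:
        n = int(lines[0].split()[1])
        nbrs = [[int(tok) - 1 for tok in ln.split()] for ln in lines[1 : 1 + n]]
    except (IndexError, ValueError) as exc:
        raise GraphError(f"malformed graph file {path!r}: {exc}") from exc
    if len(nbrs) != n:
        raise GraphError(f"graph file {path!r} declares {n} vertices, has {len(nbrs)}")
    return build_from_adjacency(dict(enumerate(nbrs)), name=name, strict=strict)


def naive_spherical_layout(
    graph: PlaneMolecularGraph, bond_length: float = 1.4
) -> np.ndarray:
    """Crude spherical coordinates from the top adjacency eigenvectors.

    Rows of the three eigenvectors following the Perron vector are projected
    onto the unit sphere and scaled so the shortest bond is ``bond_length``
    Angstrom.  Good enough for XYZ round-trip tests on small cages; this is
    not a geometry optimiser.
    """
    a = nx.to_numpy_array(graph.to_nx())
    w, vecs = np.linalg.eigh(a)
    order = np.argsort(w)[::-1]
    pts = vecs[:, order[1:4]]
    norms = np.linalg.norm(pts, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise GraphError("degenerate spectral layout")
    pts = pts / norms
    dmin = min(
        np.linalg.norm(pts[u] - pts[v]) for u, v in graph.edges
    )
    return pts * (bond_length / dmin)


# -- fixtures ----------------------------------------------------------------


def fixture_dodecahedron() -> FullereneGraph:
    """The C20 cage: 20 vertices, 30 edges, 12 pentagonal faces."""
    g = nx.dodecahedral_graph()
    rotation = _embedding_rotation(g)
    return FullereneGraph(rotation, name="C20 dodecahedron")


def fixture_truncated_icosahedron() -> FullereneGraph:
    """The icosahedral C60 cage (soccer ball), built from exact coordinates.

    Vertices are the cyclic permutations of (0, +-1, +-3phi), (+-1, +-(2+phi),
    +-2phi) and (+-phi, +-2, +-(2phi+1)); nearest neighbours (distance 2) are
    bonded and the cage is scaled to 1.4 A bonds.
    """
    phi = (1 + math.sqrt(5)) / 2
    base = [
        (0.0, 1.0, 3 * phi),
        (1.0, 2 + phi, 2 * phi),
        (phi, 2.0, 2 * phi + 1),
    ]
    pts = set()
    for b in base:
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    p = (sx * b[0], sy * b[1], sz * b[2])
                    for k in range(3):
                        pts.add((p[k % 3], p[(k + 1) % 3], p[(k + 2) % 3]))
    coords = np.array(sorted(pts)) * (1.4 / 2.0)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    adj = (d < 1.5) & (d > 0.1)
    return FullereneGraph(
        _embedding_rotation(nx.from_numpy_array(adj.astype(int))),
        coords=coords,
        name="C60 truncated icosahedron",
    )


def fixture_corannulene() -> PlaneMolecularGraph:
    """Corannulene C20H10 as an implicit-hydrogen carbon skeleton.

    A central pentagon (hub) fused to five hexagons; the rim carries the ten
    CH positions as degree-2 vertices.  20 vertices, 25 edges.
    """
    edges = []
    hub = list(range(5))           # 0..4
    rim = list(range(5, 20))       # 5..19, cycle of 15
    edges += [(hub[i], hub[(i + 1) % 5]) for i in range(5)]
    edges += [(rim[i], rim[(i + 1) % 15]) for i in range(15)]
    edges += [(hub[i], rim[3 * i]) for i in range(5)]  # spokes
    g = nx.Graph(edges)
    return build_from_adjacency(g, name="corannulene C20H10")
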