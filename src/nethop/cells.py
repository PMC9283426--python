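"""Polyhedral network cells and their bead-spring realizations.

A network cell is modelled as a convex polyhedron whose edges are polymer
strands and whose vertices are cross-links.  The catalog is keyed by the
topology label ``g`` (the face count of the polyhedron): 4 tetrahedron,
6 cube, 8 octahedron, 12 dodecahedron, 20 icosahedron, 32 truncated
icosahedron.  All lengths are expressed in units of the mesh size ``a_x``,
the root-mean-square end-to-end distance of a strand; every edge of a cell
has length exactly ``a_x``.

Three characteristic radii classify how a hard particle of radius ``R``
interacts with a cell: the inradius ``r_in`` (sphere tangent to the faces),
the midradius ``r_mid`` (tangent to the edges) and the circumradius
``r_out`` (through the vertices).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull

__all__ = [
    "PolyhedralCell",
    "RadiiTriple",
    "MEPFrame",
    "BeadSpringNetwork",
    "CATALOG_LABELS",
    "build_cell",
    "radii_eq1",
    "radii_geometric",
    "mep_frame",
    "to_bead_network",
    "reflect_through_face",
]

_PHI = (1.0 + math.sqrt(5.0)) / 2.0

#: catalog of topology labels -> polyhedron name
CATALOG_LABELS = {
    4: "tetrahedron",
    6: "cube",
    8: "octahedron",
    12: "dodecahedron",
    20: "icosahedron",
    32: "truncated icosahedron",
}

# dihedral angles (exact closed forms); None for cells with two face classes
_DIHEDRAL = {
    4: math.acos(1.0 / 3.0),
    6: math.pi / 2.0,
    8: math.acos(-1.0 / 3.0),
    12: math.acos(-1.0 / math.sqrt(5.0)),
    20: math.acos(-math.sqrt(5.0) / 3.0),
    32: None,
}

# polygon degree of the faces; for g=32 the per-face degrees are stored on the cell
_DEGREE = {4: 3, 6: 4, 8: 3, 12: 5, 20: 3, 32: None}

# vertex functionality (strands per cross-link)
_FUNCTIONALITY = {4: 3, 6: 3, 8: 4, 12: 3, 20: 5, 32: 3}


class CatalogError(KeyError):
    """Unknown cell-topology label."""


class GeometryError(ValueError):
    """Degenerate or non-physical geometry."""


@dataclass(frozen=True)
class RadiiTriple:
    """Inradius, midradius and circumradius of a cell (units of ``a_x``)."""

    r_in: float
    r_mid: float
    r_out: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r_in <= self.r_mid <= self.r_out):
            raise GeometryError(
                f"radii must satisfy 0 < r_in <= r_mid <= r_out, got {self}"
            )

    def scaled(self, factor: float) -> "RadiiTriple":
        return RadiiTriple(self.r_in * factor, self.r_mid * factor, self.r_out * factor)


@dataclass(frozen=True)
class MEPFrame:
    """Axis frame of the minimum-energy path through one face.

    The MEP runs from the free-energy minimum at the cell center to the
    local minimum at a face center; ``period`` is the center-to-center
    distance of the two cells sharing that face (twice ``z_face``).
    """

    origin: np.ndarray
    axis: np.ndarray
    z_face: float

    @property
    def period(self) -> float:
        return 2.0 * self.z_face


@dataclass
class PolyhedralCell:
    """A convex polyhedral network cell with unit-``a_x`` edges."""

    g_label: int
    name: str
    n: int | None
    k: int
    theta: float | None
    a_x: float
    vertices: np.ndarray  # (V, 3)
    edges: list[tuple[int, int]]
    faces: list[list[int]]

    @property
    def V(self) -> int:
        return len(self.vertices)

    @property
    def E(self) -> int:
        return len(self.edges)

    @property
    def F(self) -> int:
        return len(self.faces)

    @property
    def face_degrees(self) -> list[int]:
        return [len(f) for f in self.faces]

    def face_centroid(self, face_index: int) -> np.ndarray:
        return self.vertices[self.faces[face_index]].mean(axis=0)

    def validate(self, rtol: float = 1e-9) -> None:
        """Check the structural invariants of a catalog cell."""
        if self.V - self.E + self.F != 2:
            raise GeometryError("Euler relation V - E + F = 2 violated")
        lengths = np.array(
            [np.linalg.norm(self.vertices[i] - self.vertices[j]) for i, j in self.edges]
        )
        if not np.allclose(lengths, self.a_x, rtol=rtol, atol=0.0):
            raise GeometryError("edge lengths deviate from a_x")
        deg = np.zeros(self.V, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        if not np.all(deg == self.k):
            raise GeometryError("vertex functionality mismatch")
        if self.n is not None and any(len(f) != self.n for f in self.faces):
            raise GeometryError("face degree mismatch")


def _tetrahedron() -> np.ndarray:
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    return v / (2.0 * math.sqrt(2.0))


def _cube() -> np.ndarray:
    return 0.5 * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )


def _octahedron() -> np.ndarray:
    e = np.eye(3) / math.sqrt(2.0)
    return np.vstack([e, -e])


def _icosahedron() -> np.ndarray:
    v = []
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            v.append([0.0, s1 * 1.0, s2 * _PHI])
            v.append([s1 * 1.0, s2 * _PHI, 0.0])
            v.append([s2 * _PHI, 0.0, s1 * 1.0])
    return np.array(v) / 2.0  # edge length 2 before scaling


def _dodecahedron() -> np.ndarray:
    v = [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            v.append([0.0, s1 / _PHI, s2 * _PHI])
            v.append([s1 / _PHI, s2 * _PHI, 0.0])
            v.append([s2 * _PHI, 0.0, s1 / _PHI])
    return np.array(v, dtype=float) * (_PHI / 2.0)  # edge length 2/phi before scaling


def _truncated_icosahedron() -> np.ndarray:
    """Vertex 1/3-truncation of the icosahedron (all edges equal)."""
    ico = _icosahedron()  # unit edge
    edges = _edges_from_hull(ico)
    pts = []
    for i, j in edges:
        a, b = ico[i], ico[j]
        pts.append(a + (b - a) / 3.0)
        pts.append(b + (a - b) / 3.0)
    return np.array(pts) * 3.0  # truncation edge = 1/3 of parent edge


def _edges_from_hull(vertices: np.ndarray) -> list[tuple[int, int]]:
    hull = ConvexHull(vertices)
    edges = set()
    for simplex in hull.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            edges.add((min(i, j), max(i, j)))
    # keep only edges of minimal length (hull triangulation adds face diagonals)
    lens = {e: np.linalg.norm(vertices[e[0]] - vertices[e[1]]) for e in edges}
    lmin = min(lens.values())
    return sorted(e for e, l in lens.items() if l < lmin * (1.0 + 1e-6))


def _faces_from_hull(vertices: np.ndarray) -> list[list[int]]:
    """Merge coplanar hull triangles into polygonal faces (ordered cycles)."""
    hull = ConvexHull(vertices)
    groups: dict[tuple, list[int]] = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        key = tuple(np.round(eq, 7))
        groups.setdefault(key, []).extend(simplex.tolist())
    faces = []
    for key, idx in groups.items():
        idx = sorted(set(idx))
        normal = np.array(key[:3])
        centroid = vertices[idx].mean(axis=0)
        # order around the centroid in the face plane
        u = vertices[idx[0]] - centroid
        u -= np.dot(u, normal) * normal
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise GeometryError("degenerate face")
        u /= nu
        w = np.cross(normal, u)
        ang = [
            math.atan2(np.dot(vertices[i] - centroid, w), np.dot(vertices[i] - centroid, u))
            for i in idx
        ]
        faces.append([i for _, i in sorted(zip(ang, idx))])
    return faces


_BUILDERS = {
    4: _tetrahedron,
    6: _cube,
    8: _octahedron,
    12: _dodecahedron,
    20: _icosahedron,
    32: _truncated_icosahedron,
}


def build_cell(g_label: int, a_x: float = 1.0) -> PolyhedralCell:
    """Construct the catalog cell with topology label ``g_label``.

    The cell is centered at the origin with every edge of length ``a_x``.
    """
    if g_label not in _BUILDERS:
        raise CatalogError(
            f"unknown g label {g_label!r}; valid labels: {sorted(_BUILDERS)}"
        )
    verts = _BUILDERS[g_label]() * a_x
    verts = verts - verts.mean(axis=0)
    edges = _edges_from_hull(verts)
    faces = _faces_from_hull(verts)
    cell = PolyhedralCell(
        g_label=g_label,
        name=CATALOG_LABELS[g_label],
        n=_DEGREE[g_label],
        k=_FUNCTIONALITY[g_label],
        theta=_DIHEDRAL[g_label],
        a_x=a_x,
        vertices=verts,
        edges=edges,
        faces=faces,
    )
    cell.validate()
    return cell


def radii_eq1(n: int, theta: float, a_x: float = 1.0) -> RadiiTriple:
    """Closed-form characteristic radii of a regular cell.

    For a cell with regular ``n``-gon faces meeting at dihedral angle
    ``theta``::

        r_in  = (a_x/2) cot(pi/n) tan(theta/2)
        r_mid = (a_x/2) cot(pi/n) sec(theta/2)
        r_out = (a_x/2) cot(pi/n) sqrt(sec^2(theta/2) + tan^2(pi/n))

    Cells with a single face class (the Platonic ones) satisfy these
    exactly; for mixed-face cells apply them per face class or use
    :func:`radii_geometric`.
    """
    if n < 3:
        raise GeometryError(f"polygon degree n must be >= 3, got {n}")
    if not (0.0 < theta < math.pi):
        raise GeometryError(f"dihedral angle must lie in (0, pi), got {theta}")
    cot = 1.0 / math.tan(math.pi / n)
    half = 0.5 * a_x * cot
    sec = 1.0 / math.cos(theta / 2.0)
    r_in = half * math.tan(theta / 2.0)
    r_mid = half * sec
    r_out = half * math.sqrt(sec * sec + math.tan(math.pi / n) ** 2)
    return RadiiTriple(r_in, r_mid, r_out)


def radii_geometric(cell: PolyhedralCell) -> RadiiTriple:
    """Characteristic radii measured directly from the cell coordinates.

    ``r_in`` is the minimum center-to-face-plane distance, ``r_mid`` the
    minimum center-to-edge distance and ``r_out`` the maximum
    center-to-vertex distance.
    """
    v = cell.vertices
    r_out = float(np.max(np.linalg.norm(v, axis=1)))
    r_mid = math.inf
    for i, j in cell.edges:
        a, b = v[i], v[j]
        t = -np.dot(a, b - a) / np.dot(b - a, b - a)
        t = min(max(t, 0.0), 1.0)
        r_mid = min(r_mid, float(np.linalg.norm(a + t * (b - a))))
    r_in = math.inf
    for f in cell.faces:
        pts = v[f]
        centroid = pts.mean(axis=0)
        normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        nn = np.linalg.norm(normal)
        if nn < 1e-12:
            raise GeometryError("degenerate face (collinear vertices)")
        r_in = min(r_in, abs(float(np.dot(centroid, normal / nn))))
    return RadiiTriple(r_in, r_mid, r_out)


def mep_frame(cell: PolyhedralCell, face_index: int = 0) -> MEPFrame:
    """Frame of the minimum-energy path through face ``face_index``.

    The axis points from the cell center through the face centroid; the
    neighbor cell center is the reflection of the origin through the face
    plane, so the landscape period along the axis is ``2 * z_face``.
    """
    if not (0 <= face_index < cell.F):
        raise IndexError(f"face index {face_index} out of range [0, {cell.F})")
    c = cell.face_centroid(face_index)
    z_face = float(np.linalg.norm(c))
    return MEPFrame(origin=np.zeros(3), axis=c / z_face, z_face=z_face)


def reflect_through_face(cell: PolyhedralCell, face_index: int) -> np.ndarray:
    """Vertex set of the mirror-image cell across one face plane."""
    pts = cell.vertices[cell.faces[face_index]]
    centroid = pts.mean(axis=0)
    normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    normal /= np.linalg.norm(normal)
    d = (cell.vertices - centroid) @ normal
    return cell.vertices - 2.0 * d[:, None] * normal


@dataclass
class BeadSpringNetwork:
    """Discrete Gaussian-chain realization of one or more cells.

    Each strand of contour ``a_x = sqrt(N) * b`` is discretized into ``N``
    harmonic springs of energy ``(3/2) k_B T |dr|^2 / b^2`` joining ``N-1``
    interior beads; cross-links sit at the polyhedron vertices.  ``free``
    marks sites that move during sampling (image-shell cross-links are
    pinned to provide the boundary condition).
    """

    positions: np.ndarray          # (n_sites, 3)
    springs: np.ndarray            # (n_springs, 2) site indices
    b: float
    N: int
    a_x: float
    is_crosslink: np.ndarray       # (n_sites,) bool
    free: np.ndarray               # (n_sites,) bool
    strands: list[tuple[int, int, list[int]]] = field(default_factory=list)
    # (site index of endpoint i, of endpoint j, interior bead site indices)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def spring_stiffness(self) -> float:
        """Spring prefactor 3/(2 b^2) in k_B T per a_x^2."""
        return 1.5 / (self.b * self.b)


def _dedupe_key(p: np.ndarray, q: np.ndarray) -> tuple:
    ka = tuple(np.round(p, 8))
    kb = tuple(np.round(q, 8))
    return (ka, kb) if ka <= kb else (kb, ka)


def to_bead_network(
    cell: PolyhedralCell,
    N: int = 4,
    b: float | None = None,
    replicate_neighbors: bool = False,
) -> BeadSpringNetwork:
    """Discretize a cell (optionally plus its first image shell) into beads.

    ``b`` defaults to ``a_x / sqrt(N)`` so that the ideal-chain mesh size
    ``sqrt(N) * b`` equals the geometric edge length; passing an
    inconsistent ``b`` (off by more than 1%) raises.
    """
    if N < 1:
        raise ValueError("need at least one spring per strand")
    if b is None:
        b = cell.a_x / math.sqrt(N)
    if abs(math.sqrt(N) * b - cell.a_x) > 0.01 * cell.a_x:
        raise GeometryError(
            f"sqrt(N)*b = {math.sqrt(N) * b:.4g} deviates from a_x = {cell.a_x:.4g}"
        )

    # collect unique cross-link positions and unique strands (by endpoints)
    xl_pos: list[np.ndarray] = []
    xl_key: dict[tuple, int] = {}
    xl_central: list[bool] = []

    def add_crosslink(p: np.ndarray, central: bool) -> int:
        key = tuple(np.round(p, 8))
        if key in xl_key:
            idx = xl_key[key]
            xl_central[idx] = xl_central[idx] or central
            return idx
        xl_key[key] = len(xl_pos)
        xl_pos.append(np.asarray(p, dtype=float))
        xl_central.append(central)
        return xl_key[key]

    strand_keys: set[tuple] = set()
    strand_pairs: list[tuple[int, int]] = []

    def add_strands(verts: np.ndarray, edges: Sequence[tuple[int, int]], central: bool):
        for i, j in edges:
            key = _dedupe_key(verts[i], verts[j])
            if key in strand_keys:
                continue
            strand_keys.add(key)
            a = add_crosslink(verts[i], central)
            bidx = add_crosslink(verts[j], central)
            strand_pairs.append((a, bidx))

    add_strands(cell.vertices, cell.edges, central=True)
    if replicate_neighbors:
        for f in range(cell.F):
            add_strands(reflect_through_face(cell, f), cell.edges, central=False)

    n_xl = len(xl_pos)
    positions = list(xl_pos)
    springs: list[tuple[int, int]] = []
    strands: list[tuple[int, int, list[int]]] = []
    for a, bidx in strand_pairs:
        pa, pb = xl_pos[a], xl_pos[bidx]
        interior: list[int] = []
        prev = a
        for kk in range(1, N):
            p = pa + (pb - pa) * (kk / N)
            interior.append(len(positions))
            positions.append(p)
            springs.append((prev, interior[-1]))
            prev = interior[-1]
        springs.append((prev, bidx))
        strands.append((a, bidx, interior))

    positions_arr = np.array(positions)
    n_sites = len(positions)
    is_xl = np.zeros(n_sites, dtype=bool)
    is_xl[:n_xl] = True
    free = np.ones(n_sites, dtype=bool)
    for idx in range(n_xl):
        if not xl_central[idx]:
            free[idx] = False  # image-shell cross-links are pinned
    return BeadSpringNetwork(
        positions=positions_arr,
        springs=np.array(springs, dtype=np.int64),
        b=b,
        N=N,
        a_x=cell.a_x,
        is_crosslink=is_xl,
        free=free,
        strands=strands,
    )
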