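"""Blastomere mesh primitives, scaling and pairwise overlap detection.

A blastomere is represented by a closed triangle surface mesh.  Contact
between two blastomeres is decided by scaling each mesh radially about its
own volume centroid by a small factor (default 1.05) and testing whether
the scaled closed volumes intersect.  Intersection is detected as any edge
of one surface crossing a triangle of the other, plus a mutual
centroid-containment check that catches full engulfment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .errors import InvalidMeshError, InvalidParameterError

__all__ = [
    "BlastomereMesh",
    "Embryo",
    "ContactNetwork",
    "scale_mesh",
    "meshes_overlap",
    "contact_network",
    "mesh_volume",
    "mesh_centroid",
    "point_in_mesh",
    "DEFAULT_SCALE_FACTOR",
]

DEFAULT_SCALE_FACTOR = 1.05

_EPS = 1e-12


@dataclass(frozen=True)
class BlastomereMesh:
    """One closed triangle surface per cell.

    Parameters
    ----------
    cell_id : str
        Short label unique within an embryo.
    vertices : (n, 3) float array
        Vertex coordinates (units arbitrary but consistent within an embryo).
    faces : (m, 3) int array
        Vertex-index triples; every edge must be shared by exactly two faces.
    """

    cell_id: str
    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidMeshError(f"{self.cell_id}: vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise InvalidMeshError(f"{self.cell_id}: faces must be (m, 3) triangles")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`InvalidMeshError` unless the mesh is a closed,
        positive-volume triangle surface."""
        v, f = self.vertices, self.faces
        if len(v) < 4:
            raise InvalidMeshError(f"{self.cell_id}: fewer than 4 vertices")
        if f.size == 0:
            raise InvalidMeshError(f"{self.cell_id}: no faces")
        if f.min() < 0 or f.max() >= len(v):
            raise InvalidMeshError(f"{self.cell_id}: face references invalid vertex index")
        edges = np.sort(f[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise InvalidMeshError(f"{self.cell_id}: surface is not closed")
        if abs(self.volume) <= _EPS * float(np.ptp(v)) ** 3:
            raise InvalidMeshError(f"{self.cell_id}: degenerate mesh (zero enclosed volume)")

    # -- integral properties --------------------------------------------

    @property
    def volume(self) -> float:
        return mesh_volume(self.vertices, self.faces)

    @property
    def centroid(self) -> np.ndarray:
        return mesh_centroid(self.vertices, self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def edge_segments(self) -> np.ndarray:
        """(k, 2, 3) array of unique undirected edges as point pairs."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        edges = np.unique(edges, axis=0)
        return self.vertices[edges]


def mesh_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume by signed-tetrahedron decomposition (divergence theorem)."""
    tri = vertices[faces]
    det = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
    return float(abs(det.sum()) / 6.0)


def mesh_centroid(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Volume centroid via signed tetrahedra from the origin.

    Independent of global face orientation (numerator and denominator flip
    sign together) and of vertex density, unlike a plain vertex average.
    """
    tri = vertices[faces]
    det = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
    vol6 = det.sum()
    if abs(vol6) <= _EPS:
        raise InvalidMeshError("degenerate mesh: zero enclosed volume")
    centers = tri.sum(axis=1) / 4.0  # tetra (0, a, b, c) centroid
    return (det[:, None] * centers).sum(axis=0) / vol6


@dataclass(frozen=True)
class Embryo:
    """A collection of blastomere meshes plus optional clinical metadata."""

    embryo_id: str
    blastomeres: tuple
    stage: int = 0
    metadata: object | None = None

    def __post_init__(self):
        blasto = tuple(self.blastomeres)
        object.__setattr__(self, "blastomeres", blasto)
        stage = self.stage or len(blasto)
        if stage != len(blasto):
            raise InvalidParameterError(
                f"{self.embryo_id}: stage {stage} != number of blastomeres {len(blasto)}"
            )
        object.__setattr__(self, "stage", stage)
        ids = [m.cell_id for m in blasto]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError(f"{self.embryo_id}: duplicate cell_ids")


@dataclass(frozen=True)
class ContactNetwork:
    """Simple undirected graph of blastomere adjacency."""

    n_nodes: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise InvalidParameterError("self-loop in contact network")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise InvalidParameterError("edge index out of range")
            canon.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def scale_mesh(mesh: BlastomereMesh, factor: float) -> BlastomereMesh:
    """Scale a mesh radially about its own volume centroid.

    The centroid is unchanged, topology is unchanged, and the enclosed
    volume is multiplied by ``factor**3``.
    """
    if not np.isfinite(factor) or factor <= 0:
        raise InvalidParameterError(f"scale factor must be positive, got {factor}")
    mesh.validate()
    c = mesh.centroid
    return BlastomereMesh(
        cell_id=mesh.cell_id,
        vertices=c + factor * (mesh.vertices - c),
        faces=mesh.faces,
    )


def _segments_cross_triangles(segments: np.ndarray, triangles: np.ndarray) -> bool:
    """True if any segment intersects any triangle (Moller-Trumbore, t in [0,1]).

    AABB pruning keeps the broadcast small; near-parallel (coplanar) pairs are
    skipped — a genuine surface crossing is always caught by a transversal pair
    unless the configuration is measure-zero.
    """
    smin = segments.min(axis=1)
    smax = segments.max(axis=1)
    tmin = triangles.min(axis=1)
    tmax = triangles.max(axis=1)
    pad = 1e-9 * max(float(np.ptp(segments)), float(np.ptp(triangles)), 1.0)
    hit = np.all(
        (smin[:, None, :] <= tmax[None, :, :] + pad)
        & (smax[:, None, :] >= tmin[None, :, :] - pad),
        axis=2,
    )
    si, ti = np.nonzero(hit)
    if si.size == 0:
        return False

    p0 = segments[si, 0]
    d = segments[si, 1] - p0
    v0 = triangles[ti, 0]
    e1 = triangles[ti, 1] - v0
    e2 = triangles[ti, 2] - v0

    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = p0 - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * np.einsum("ij,ij->i", d, q)
        t = f * np.einsum("ij,ij->i", e2, q)
    inside = ok & (u >= 0.0) & (u <= 1.0) & (v >= 0.0) & (u + v <= 1.0)
    inside &= (t >= 0.0) & (t <= 1.0)
    return bool(inside.any())


def point_in_mesh(point: np.ndarray, mesh: BlastomereMesh) -> bool:
    """Containment test by generalized winding number (solid-angle sum)."""
    tri = mesh.triangles - np.asarray(point, dtype=np.float64)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(c, axis=1)
    num = np.einsum("ij,ij->i", a, np.cross(b, c))
    den = (
        la * lb * lc
        + np.einsum("ij,ij->i", a, b) * lc
        + np.einsum("ij,ij->i", b, c) * la
        + np.einsum("ij,ij->i", c, a) * lb
    )
    winding = np.arctan2(num, den).sum() / (2.0 * np.pi)
    return bool(abs(winding) > 0.5)


def meshes_overlap(a: BlastomereMesh, b: BlastomereMesh) -> bool:
    """True iff the closed volumes of ``a`` and ``b`` intersect.

    Symmetric in its arguments.  Surfaces touching at a single point
    (measure-zero tangency) are not counted as overlapping.
    """
    a.validate()
    b.validate()
    amin, amax = a.vertices.min(axis=0), a.vertices.max(axis=0)
    bmin, bmax = b.vertices.min(axis=0), b.vertices.max(axis=0)
    if np.any(amin > bmax) or np.any(bmin > amax):
        return False
    if _segments_cross_triangles(a.edge_segments(), b.triangles):
        return True
    if _segments_cross_triangles(b.edge_segments(), a.triangles):
        return True
    # full engulfment: surfaces disjoint but one volume inside the other
    return point_in_mesh(a.centroid, b) or point_in_mesh(b.centroid, a)


def contact_network(
    embryo: Embryo, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> ContactNetwork:
    """Build the blastomere contact network of an embryo.

    Edge (i, j) is present iff the meshes of cells i and j, each scaled by
    ``scale_factor`` about its own volume centroid, overlap.
    """
    if not embryo.blastomeres:
        raise InvalidParameterError(f"{embryo.embryo_id}: embryo has no blastomeres")
    scaled = []
    for mesh in embryo.blastomeres:
        try:
            scaled.append(scale_mesh(mesh, scale_factor))
        except InvalidMeshError as exc:
            raise InvalidMeshError(f"cell {mesh.cell_id!r}: {exc}") from exc
    n = len(scaled)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if meshes_overlap(scaled[i], scaled[j]):
                edges.add((i, j))
    return ContactNetwork(n_nodes=n, edges=frozenset(edges))


def tessellation_tolerance(mesh: BlastomereMesh) -> float:
    """Maximum chord deviation: how far inside the circumscribed surface the
    flat triangles can sag.  Used to define the near-tangency band where a
    faceted sphere may disagree with the analytic sphere criterion."""
    c = mesh.centroid
    tri = mesh.triangles - c
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1)
    plane_dist = np.abs(np.einsum("ij,ij->i", tri[:, 0], normals)) / np.maximum(norms, _EPS)
    r = np.linalg.norm(mesh.vertices - c, axis=1).max()
    return float(r - plane_dist.min())
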