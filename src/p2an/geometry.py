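"""Synthetic heart/torso geometry and the equivalent-double-layer forward model.

The forward problem of electrocardiographic imaging is linear,

    Omega = H U,

where ``U`` (M x L) holds transmembrane potentials (TMP) at M cardiac surface
nodes over L time samples, ``Omega`` (N x L) holds body-surface potentials
(BSP) at N electrodes, and ``H`` (N x M) is the transfer matrix.  Under the
equivalent double layer (EDL) source model the potential an electrode sees
from a uniformly activated surface patch is proportional to the signed solid
angle the patch subtends at the electrode.  ``H`` is therefore assembled from
analytic per-triangle solid angles, vertex-lumped (each face contributes one
third of its solid angle to each of its three vertices) in an infinite
homogeneous medium.

Because every observation point outside a closed surface subtends a total
solid angle of zero (Gauss), the rows of ``H`` sum to ~0, so a spatially
uniform TMP produces no body-surface signal -- only spatial *differences* of
TMP are visible, which is what makes the inverse problem ill-posed.

Geometry here is synthetic: a Fibonacci-lattice sphere for the heart surface
(default 128 nodes, radius 50 mm) and a quasi-uniform electrode shell on a
larger torso sphere (default 64 electrodes, radius 200 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import ConvexHull


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric configurations."""


@dataclass
class TriMesh:
    """Closed triangulated surface; vertex coordinates in mm.

    Invariants (checked by :meth:`validate`): every edge is shared by exactly
    two faces, winding is consistently outward, and for sphere topology
    V - E + F = 2.
    """

    vertices: np.ndarray  # (V, 3) float, mm
    faces: np.ndarray     # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    @property
    def vertex_faces(self) -> list[np.ndarray]:
        """Per-vertex incident face indices."""
        out: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for f, (a, b, c) in enumerate(self.faces):
            out[a].append(f)
            out[b].append(f)
            out[c].append(f)
        return [np.array(v, dtype=np.int64) for v in out]

    def euler_characteristic(self) -> int:
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = np.unique(edges, axis=0).shape[0]
        return self.n_vertices - n_edges + self.n_faces

    def validate(self) -> None:
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise GeometryError("mesh is not closed (open edges present)")
        if not tm.is_winding_consistent:
            raise GeometryError("inconsistent face winding")
        if self.euler_characteristic() != 2:
            raise GeometryError("Euler characteristic != 2 (not sphere topology)")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def edge_graph(self):
        """Sparse symmetric matrix of Euclidean edge lengths (for geodesics)."""
        from scipy import sparse

        e = np.unique(
            np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1),
            axis=0,
        )
        w = np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
        )
        g = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(self.n_vertices, self.n_vertices),
        )
        return g.tocsr()


@dataclass
class ElectrodeArray:
    """Electrode positions (mm) on the torso surface."""

    positions: np.ndarray  # (N, 3) float, mm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def count(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class TransferMatrix:
    """Vertex-lumped EDL transfer matrix (dimensionless solid-angle weights)."""

    entries: np.ndarray                 # (N, M)
    mesh: TriMesh | None = None
    electrodes: ElectrodeArray | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if not np.all(np.isfinite(self.entries)):
            raise GeometryError("transfer matrix has non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.entries.shape)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# mesh / electrode construction
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points via the Fibonacci (golden-angle) lattice."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_sphere_mesh(
    n_nodes: int, radius: float = 50.0, center=(0.0, 0.0, 0.0)
) -> TriMesh:
    """Closed outward-oriented triangulation of a sphere with ``n_nodes`` vertices.

    Fibonacci-lattice points triangulated by their convex hull.  Exact vertex
    count is preserved; all vertices lie exactly at ``radius`` from ``center``.
    """
    if n_nodes < 4:
        raise ValueError(f"n_nodes must be >= 4, got {n_nodes}")
    center = np.asarray(center, dtype=float)
    if n_nodes == 4:
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(3.0)
    else:
        pts = fibonacci_sphere(n_nodes)
    hull = ConvexHull(pts)
    faces = hull.simplices.copy()
    # orient all faces outward (normal . centroid direction > 0)
    tri = pts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centroids = tri.mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, centroids) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    mesh = TriMesh(vertices=center + radius * pts, faces=faces)
    mesh.validate()
    return mesh


def generate_electrodes(
    n: int,
    torso_radius: float = 200.0,
    center=(0.0, 0.0, 0.0),
    seed: int = 0,
) -> ElectrodeArray:
    """Quasi-uniform electrode shell on a torso sphere.

    A Fibonacci lattice is rotated by a seeded random rotation so distinct
    seeds give distinct (deterministic) layouts that never coincide with the
    heart-mesh lattice axes.
    """
    if n < 1:
        raise ValueError(f"electrode count must be >= 1, got {n}")
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    pts = fibonacci_sphere(n) @ q.T
    return ElectrodeArray(positions=center + torso_radius * pts)


# ---------------------------------------------------------------------------
# solid angles and the transfer matrix
# ---------------------------------------------------------------------------

def triangle_solid_angle(v1, v2, v3, obs) -> float:
    """Signed solid angle (sr) of triangle (v1,v2,v3) seen from ``obs``.

    Analytic arctangent formula (Van Oosterom & Strackee): with
    r_i = v_i - obs,

        tan(omega/2) = det(r1 r2 r3) /
            (|r1||r2||r3| + (r1.r2)|r3| + (r1.r3)|r2| + (r2.r3)|r1|)

    The sign follows the triangle winding as seen from the observation point
    (counter-clockwise from obs => positive).
    """
    r = np.asarray([v1, v2, v3], dtype=float) - np.asarray(obs, dtype=float)
    n = np.linalg.norm(r, axis=1)
    if np.any(n < 1e-12):
        raise GeometryError("observation point coincides with a triangle vertex")
    num = np.linalg.det(r)
    den = (
        n[0] * n[1] * n[2]
        + np.dot(r[0], r[1]) * n[2]
        + np.dot(r[0], r[2]) * n[1]
        + np.dot(r[1], r[2]) * n[0]
    )
    return 2.0 * np.arctan2(num, den)


def _solid_angles_all_faces(mesh: TriMesh, obs: np.ndarray) -> np.ndarray:
    """Vectorized signed solid angle of every face from a single point."""
    r = mesh.vertices[mesh.faces] - np.asarray(obs, dtype=float)  # (F,3,3)
    n = np.linalg.norm(r, axis=2)  # (F,3)
    if np.any(n < 1e-12):
        raise GeometryError("observation point coincides with a mesh vertex")
    num = np.linalg.det(r)
    r0, r1, r2 = r[:, 0], r[:, 1], r[:, 2]
    den = (
        n[:, 0] * n[:, 1] * n[:, 2]
        + np.einsum("ij,ij->i", r0, r1) * n[:, 2]
        + np.einsum("ij,ij->i", r0, r2) * n[:, 1]
        + np.einsum("ij,ij->i", r1, r2) * n[:, 0]
    )
    return 2.0 * np.arctan2(num, den)


def total_solid_angle(mesh: TriMesh, obs) -> float:
    """Sum of signed face solid angles: 4*pi inside a closed mesh, 0 outside."""
    return float(_solid_angles_all_faces(mesh, np.asarray(obs, float)).sum())


def build_transfer_matrix(
    heart: TriMesh, electrodes: ElectrodeArray
) -> TransferMatrix:
    """Vertex-lumped EDL transfer matrix.

    H[i, j] = -(1/4pi) * sum over faces incident to node j of
              (1/3) * solid_angle(face, electrode i).

    Every electrode must lie strictly outside the heart surface; by Gauss'
    theorem each row then sums to ~0.  Insideness itself is decided with the
    same solid-angle machinery (total angle ~4pi inside, ~0 outside).
    """
    inside = [
        abs(total_solid_angle(heart, p)) > 2.0 * np.pi
        for p in electrodes.positions
    ]
    if np.any(inside):
        raise GeometryError(
            f"electrodes {np.nonzero(inside)[0].tolist()} lie inside the heart mesh"
        )
    M = heart.n_vertices
    N = electrodes.count
    H = np.zeros((N, M))
    faces = heart.faces
    for i in range(N):
        omega = _solid_angles_all_faces(heart, electrodes.positions[i])
        contrib = -omega / (4.0 * np.pi) / 3.0
        np.add.at(H[i], faces[:, 0], contrib)
        np.add.at(H[i], faces[:, 1], contrib)
        np.add.at(H[i], faces[:, 2], contrib)
    return TransferMatrix(entries=H, mesh=heart, electrodes=electrodes)


def forward_bsp(H: TransferMatrix | np.ndarray, U: np.ndarray) -> np.ndarray:
    """Forward map Omega = H U (mV in, mV out)."""
    Hm = H.entries if isinstance(H, TransferMatrix) else np.asarray(H, float)
    U = np.asarray(U, dtype=float)
    if Hm.shape[1] != U.shape[0]:
        raise ValueError(
            f"shape mismatch: H has {Hm.shape[1]} columns, U has {U.shape[0]} rows"
        )
    return Hm @ U
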