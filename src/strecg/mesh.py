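"""Closed triangle-surface meshes: data structure, sphere generator, solid angles, I/O.

Meshes are the geometric substrate of the boundary-element forward model:
both the heart and the body surface are closed, outward-oriented triangle
meshes with potentials collocated at the vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import ConvexHull


class MeshValidationError(ValueError):
    """Raised when a surface is not a closed orientable manifold.

    Carries the offending (boundary or over-shared) edges in ``edges``.
    """

    def __init__(self, message: str, edges=None):
        super().__init__(message)
        self.edges = edges or []


class SingularGeometryError(ValueError):
    """Observation point lies on the element being integrated."""


@dataclass
class TriangleMesh:
    """A closed, outward-oriented triangulated surface.

    Parameters
    ----------
    vertices : (N, 3) float array
        Node coordinates, consistent length units.
    triangles : (F, 3) int array
        Vertex index triples, counter-clockwise as seen from outside
        (0-based).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    _neighbors: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (F, 3) array")

    # -- basic counts -------------------------------------------------
    @property
    def node_count(self) -> int:
        return len(self.vertices)

    @property
    def triangle_count(self) -> int:
        return len(self.triangles)

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted (i, j) pairs."""
        e = np.vstack([self.triangles[:, [0, 1]],
                       self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def euler_characteristic(self) -> int:
        return self.node_count - self.edge_count + self.triangle_count

    # -- adjacency ----------------------------------------------------
    def neighbor(self, i: int) -> set:
        """Set of vertex indices sharing an edge with node ``i``."""
        return set(self.neighbors()[i])

    def neighbors(self) -> list:
        """Per-node sorted arrays of edge-adjacent vertices (cached)."""
        if self._neighbors is None:
            adj = [set() for _ in range(self.node_count)]
            for a, b in self.edges:
                adj[a].add(int(b))
                adj[b].add(int(a))
            self._neighbors = [np.array(sorted(s), dtype=np.int64) for s in adj]
        return self._neighbors

    def edge_length(self, i: int, j: int) -> float:
        """Euclidean distance between adjacent nodes i and j."""
        if j not in self.neighbor(i):
            raise ValueError(f"nodes {i} and {j} are not adjacent")
        return float(np.linalg.norm(self.vertices[i] - self.vertices[j]))

    # -- geometry -----------------------------------------------------
    def triangle_vertices(self) -> np.ndarray:
        """(F, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.triangles]

    def triangle_normals(self, normalized: bool = True) -> np.ndarray:
        tv = self.triangle_vertices()
        n = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
        if normalized:
            n = n / np.linalg.norm(n, axis=1, keepdims=True)
        return n

    def triangle_areas(self) -> np.ndarray:
        tv = self.triangle_vertices()
        return 0.5 * np.linalg.norm(
            np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0]), axis=1)

    def signed_volume(self) -> float:
        """Total signed volume; positive for outward-oriented closed surfaces."""
        tv = self.triangle_vertices()
        return float(np.einsum("ij,ij->", tv[:, 0], np.cross(tv[:, 1], tv[:, 2])) / 6.0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        """Check the closed-orientable-manifold invariants.

        Raises
        ------
        MeshValidationError
            If any edge is not shared by exactly two triangles, if the
            orientation is inward, or if a triangle is degenerate.
        """
        directed = np.vstack([self.triangles[:, [0, 1]],
                              self.triangles[:, [1, 2]],
                              self.triangles[:, [2, 0]]])
        und = np.sort(directed, axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        bad = uniq[counts != 2]
        if len(bad):
            raise MeshValidationError(
                f"surface is not closed: {len(bad)} edge(s) not shared by exactly "
                f"2 triangles, e.g. {bad[:5].tolist()}",
                edges=[tuple(e) for e in bad])
        # consistent orientation: each undirected edge must appear once per direction
        d_uniq, d_counts = np.unique(directed, axis=0, return_counts=True)
        flipped = d_uniq[d_counts != 1]
        if len(flipped):
            raise MeshValidationError(
                f"inconsistent triangle orientation around {len(flipped)} edge(s)",
                edges=[tuple(e) for e in flipped])
        areas = self.triangle_areas()
        tiny = areas < 1e-12 * areas.mean()
        if tiny.any():
            raise MeshValidationError(
                f"degenerate triangle(s) at indices {np.flatnonzero(tiny).tolist()}")
        if self.signed_volume() <= 0:
            raise MeshValidationError("triangle normals point inward (signed volume <= 0)")


# ---------------------------------------------------------------------------
# sphere generation
# ---------------------------------------------------------------------------

def _fibonacci_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_sphere_mesh(radius: float, target_nodes: int) -> TriangleMesh:
    """Closed genus-0 sphere mesh with exactly ``target_nodes`` vertices.

    Vertices are placed on a Fibonacci lattice (seedless, reproducible
    bit-for-bit) and triangulated by their convex hull, so a request for
    184 nodes yields the 184-node / 364-triangle / 546-edge discretization
    used throughout the two-sphere study (any vertex count n gives
    2n - 4 triangles on a genus-0 hull).

    Parameters
    ----------
    radius : float
        Sphere radius (> 0); every vertex lies at this distance from the
        origin to machine precision.
    target_nodes : int
        Number of mesh nodes (>= 4).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if target_nodes < 4:
        raise ValueError("target_nodes must be at least 4")
    pts = _fibonacci_sphere_points(target_nodes)
    hull = ConvexHull(pts)
    if len(hull.vertices) != target_nodes:
        raise ValueError(
            f"requested node count {target_nodes} unachievable; nearest achievable "
            f"count is {len(hull.vertices)}")
    tris = hull.simplices.astype(np.int64)
    # orient each hull facet outward (hull simplices are not consistently wound)
    tv = pts[tris]
    n = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    inward = np.einsum("ij,ij->i", n, tv.mean(axis=1)) < 0
    tris[inward] = tris[inward][:, [0, 2, 1]]
    mesh = TriangleMesh(radius * pts, tris)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# solid angles
# ---------------------------------------------------------------------------

def solid_angle(observation_point, triangle) -> float:
    """Signed solid angle (steradians) subtended by an oriented triangle.

    Uses the van Oosterom-Strackee formula.  The sign is positive when the
    observation point is on the side the triangle's normal points away
    from, i.e. summing over an outward-oriented closed mesh gives 4*pi for
    an interior point and 0 for an exterior point.

    Raises
    ------
    SingularGeometryError
        If the observation point lies in the triangle's plane within the
        triangle (the angle is undefined there).
    """
    p = np.asarray(observation_point, dtype=float)
    tri = np.asarray(triangle, dtype=float)
    r = tri - p
    norms = np.linalg.norm(r, axis=1)
    if np.any(norms == 0.0):
        raise SingularGeometryError("observation point coincides with a triangle vertex")
    numer = np.dot(r[0], np.cross(r[1], r[2]))
    denom = (norms[0] * norms[1] * norms[2]
             + np.dot(r[0], r[1]) * norms[2]
             + np.dot(r[1], r[2]) * norms[0]
             + np.dot(r[2], r[0]) * norms[1])
    if numer == 0.0 and denom <= 0.0:
        # in-plane: undefined inside the triangle, zero outside (denom > 0)
        raise SingularGeometryError("observation point lies on the triangle")
    return float(2.0 * np.arctan2(numer, denom))


def solid_angles_batch(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """(P, F) signed solid angles of every mesh triangle from every point.

    Vectorized van Oosterom-Strackee; points lying exactly on a triangle
    produce the principal value 0 (used by the BEM assembly, where
    vertex-incident flat triangles subtend zero angle).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tv = mesh.triangle_vertices()  # (F, 3, 3)
    r = tv[None, :, :, :] - pts[:, None, None, :]  # (P, F, 3, 3)
    n = np.linalg.norm(r, axis=3)  # (P, F, 3)
    numer = np.einsum("pfi,pfi->pf", r[:, :, 0], np.cross(r[:, :, 1], r[:, :, 2]))
    dot01 = np.einsum("pfi,pfi->pf", r[:, :, 0], r[:, :, 1])
    dot12 = np.einsum("pfi,pfi->pf", r[:, :, 1], r[:, :, 2])
    dot20 = np.einsum("pfi,pfi->pf", r[:, :, 2], r[:, :, 0])
    denom = n.prod(axis=2) + dot01 * n[:, :, 2] + dot12 * n[:, :, 0] + dot20 * n[:, :, 1]
    out = 2.0 * np.arctan2(numer, denom)
    out[(numer == 0.0) & (denom <= 0.0)] = 0.0
    return out


# ---------------------------------------------------------------------------
# file I/O (ASCII OFF and PLY; 0-based indices internally)
# ---------------------------------------------------------------------------

def write_mesh(mesh: TriangleMesh, path, format: str | None = None) -> None:
    """Write a mesh as ASCII OFF or PLY.

    OFF is written natively with 17-significant-digit floats so a
    write/read round trip reproduces vertices bitwise; PLY goes through
    trimesh.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.node_count} {mesh.triangle_count} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    elif fmt == "ply":
        tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
        tm.export(path, file_type="ply", encoding="ascii")
    else:
        raise ValueError(f"unsupported mesh format: {fmt!r}")


def read_mesh(path, format: str | None = None, validate: bool = True,
              one_based: bool = False) -> TriangleMesh:
    """Read an ASCII OFF or PLY mesh into a :class:`TriangleMesh`.

    Parameters
    ----------
    one_based : bool
        Set for OFF dialects whose face indices start at 1; indices are
        converted to the internal 0-based convention.
    validate : bool
        Reject open or non-manifold surfaces (with the offending edges
        listed in the error).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "off":
        with open(path) as fh:
            tokens: list[str] = []
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    tokens.extend(line.split())
        if tokens[0].upper() != "OFF":
            raise ValueError(f"{path} is not an OFF file")
        nv, nf = int(tokens[1]), int(tokens[2])
        cur = 4
        verts = np.array(tokens[cur:cur + 3 * nv], dtype=float).reshape(nv, 3)
        cur += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(tokens[cur])
            if k != 3:
                raise ValueError("only triangle faces are supported")
            faces.append([int(t) for t in tokens[cur + 1:cur + 4]])
            cur += k + 1
        tris = np.asarray(faces, dtype=np.int64)
        if one_based:
            tris = tris - 1
        mesh = TriangleMesh(verts, tris)
    elif fmt == "ply":
        tm = _trimesh.load(path, file_type="ply", process=False,
                           maintain_order=True)
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces, dtype=np.int64))
    else:
        raise ValueError(f"unsupported mesh format: {fmt!r}")
    if validate:
        mesh.validate()
    return mesh
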