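"""Shared fixtures: small meshes and controlled streamline builders."""

from __future__ import annotations

import numpy as np
import pytest

from surfconn import SurfaceMesh, Tractogram, make_icosphere


@pytest.fixture(scope="session")
def icosphere_small() -> SurfaceMesh:
    """Level-2 icosphere, radius 50 mm (162 vertices, ~13 mm edges)."""
    return make_icosphere(2, 50.0)


@pytest.fixture(scope="session")
def icosphere_medium() -> SurfaceMesh:
    """Level-3 icosphere, radius 50 mm (642 vertices)."""
    return make_icosphere(3, 50.0)


@pytest.fixture
def tetrahedron() -> SurfaceMesh:
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh(verts, faces)


def grid_mesh(nx: int = 8, ny: int = 3, spacing: float = 6.0) -> SurfaceMesh:
    """Flat triangulated grid in the z=0 plane; vertex (i, j) at index i*ny+j."""
    xx, yy = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing,
                         indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b = i * ny + j, (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh(verts, np.array(faces))


def make_streamline(p0: np.ndarray, p1: np.ndarray, length: float) -> np.ndarray:
    """3-point polyline from p0 to p1 with exactly the requested arc length.

    The midpoint is lifted perpendicular to the chord so that
    2 * sqrt((d/2)^2 + h^2) = length; requires length >= chord distance.
    """
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = np.linalg.norm(p1 - p0)
    if length < d - 1e-12:
        raise ValueError("length must be >= chord distance")
    h = np.sqrt(max((length / 2.0) ** 2 - (d / 2.0) ** 2, 0.0))
    chord = (p1 - p0) / d if d > 0 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(chord, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(chord, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    mid = (p0 + p1) / 2.0 + h * perp
    return np.stack([p0, mid, p1])


def tractogram_at_vertices(mesh: SurfaceMesh, pairs: list[tuple[int, int, float]]
                           ) -> Tractogram:
    """Streamlines with extremities exactly on vertices: (start, end, length)."""
    return Tractogram([
        make_streamline(mesh.vertices[a], mesh.vertices[b], length)
        for a, b, length in pairs
    ])


def brute_force_assignment(tractogram: Tractogram, mesh: SurfaceMesh,
                           radius: float):
    """Exhaustive all-pairs endpoint assignment (the independent oracle).

    Returns the flat (vertex, streamline, extremity, ending_vertex) rows
    sorted by (vertex, streamline, extremity).
    """
    rows = []
    ends = tractogram.endpoints
    for v in range(mesh.n_vertices):
        pv = mesh.vertices[v]
        for s in range(len(tractogram)):
            for e in (0, 1):
                if np.linalg.norm(ends[s, e] - pv) <= radius:
                    other = ends[s, 1 - e]
                    dists = np.linalg.norm(mesh.vertices - other, axis=1)
                    rows.append((v, s, e, int(np.argmin(dists))))
    rows.sort()
    return np.array(rows, dtype=np.int64).reshape(-1, 4)


def brute_force_assignment_vectorized(tractogram: Tractogram, mesh: SurfaceMesh,
                                      radius: float) -> np.ndarray:
    """All-pairs oracle via dense distance matrices (chunked), for larger
    configurations than the triple-loop version can handle."""
    from scipy.spatial.distance import cdist

    flat_ends = tractogram.endpoints.reshape(-1, 3)
    rows = []
    chunk = 512
    ending_lookup = np.empty(flat_ends.shape[0], dtype=np.int64)
    other_idx = (np.arange(flat_ends.shape[0]) ^ 1)  # 2s+e <-> 2s+(1-e)
    for lo in range(0, flat_ends.shape[0], chunk):
        d = cdist(flat_ends[other_idx[lo:lo + chunk]], mesh.vertices)
        ending_lookup[lo:lo + chunk] = np.argmin(d, axis=1)
    for lo in range(0, mesh.n_vertices, chunk):
        d = cdist(mesh.vertices[lo:lo + chunk], flat_ends)
        vv, ff = np.nonzero(d <= radius)
        for v, f in zip(vv + lo, ff):
            rows.append((v, f // 2, f % 2, ending_lookup[f]))
    rows.sort()
    return np.array(rows, dtype=np.int64).reshape(-1, 4)


def assignment_rows(assignment) -> np.ndarray:
    """Flat sorted rows of an EndpointAssignment, comparable with the oracle."""
    rows = np.column_stack([
        assignment.vertex, assignment.streamline,
        assignment.extremity, assignment.ending_vertex,
    ])
    order = np.lexsort(rows[:, ::-1].T)
    return rows[order]
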