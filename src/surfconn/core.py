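"""Core geometric containers: cortical surface mesh, tractogram, per-vertex maps.

All coordinates are in millimetres in a single world space (the surface
file's native space).  Streamlines are undirected 3-D polylines; each
carries a length (sum of segment norms) and a reconstruction-bias
correction weight equal to the inverse of its length, so that longer
fibers — which deterministic tractography reconstructs more often — do
not dominate per-vertex counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import sparse


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class SurfaceMesh:
    """A triangulated cortical surface in millimetre world space.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in mm.
    faces : (F, 3) int array
        Vertex indices of each triangle.

    Derived quantities (vertex normals, per-vertex Voronoi-style areas,
    1-ring adjacency) are computed lazily and cached.  Per-vertex area is
    one third of the summed area of the incident triangles, so vertex
    areas always sum to the total surface area.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _normals: np.ndarray | None = field(default=None, repr=False, compare=False)
    _areas: np.ndarray | None = field(default=None, repr=False, compare=False)
    _adjacency: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError(
                f"vertices must be (V, 3), got {self.vertices.shape}"
            )
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError(f"faces must be (F, 3), got {self.faces.shape}")
        self._validate()

    def _validate(self) -> None:
        V = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= V):
            bad = np.unique(self.faces[(self.faces < 0) | (self.faces >= V)])
            raise MeshValidationError(
                f"face indices out of range [0, {V}): {bad[:10].tolist()}"
            )
        # edge-manifold: every undirected edge belongs to at most 2 triangles
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if counts.size and counts.max() > 2:
            uniq, cnt = np.unique(e, axis=0, return_counts=True)
            offenders = uniq[cnt > 2]
            raise MeshValidationError(
                f"non-manifold edges (shared by >2 triangles): {offenders[:5].tolist()}"
            )
        tri = self.vertices[self.faces]
        double_area = np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if np.any(double_area <= 0):
            raise MeshValidationError(
                f"{int(np.sum(double_area <= 0))} degenerate (zero-area) triangles"
            )

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def triangle_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    @property
    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area in mm²: one third of incident triangle areas."""
        if self._areas is None:
            areas = np.zeros(self.n_vertices)
            third = self.triangle_areas / 3.0
            for k in range(3):
                np.add.at(areas, self.faces[:, k], third)
            self._areas = areas
        return self._areas

    @property
    def vertex_normals(self) -> np.ndarray:
        """Unit outward normals, area-weighted average of incident face normals."""
        if self._normals is None:
            tri = self.vertices[self.faces]
            fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            vn = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(vn, self.faces[:, k], fn)
            norm = np.linalg.norm(vn, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._normals = vn / norm
        return self._normals

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 1-ring vertex adjacency (boolean CSR, no self-loops)."""
        if self._adjacency is None:
            i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
            j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
            a = sparse.coo_matrix(
                (np.ones(i.size, dtype=np.int8), (i, j)),
                shape=(self.n_vertices, self.n_vertices),
            ).tocsr()
            a = a + a.T
            a.data[:] = 1
            self._adjacency = a
        return self._adjacency

    def neighbors(self, vertex: int) -> np.ndarray:
        """Sorted 1-ring neighbor indices of ``vertex``."""
        a = self.adjacency
        return a.indices[a.indptr[vertex] : a.indptr[vertex + 1]]

    def edge_length_graph(self) -> sparse.csr_matrix:
        """Adjacency weighted by Euclidean edge length, for geodesic estimates."""
        a = self.adjacency.tocoo()
        w = np.linalg.norm(self.vertices[a.row] - self.vertices[a.col], axis=1)
        return sparse.csr_matrix((w, (a.row, a.col)), shape=a.shape)


@dataclass
class Tractogram:
    """An ordered collection of streamline polylines in mm.

    ``lengths`` and ``weights`` are derived: length is the sum of segment
    norms; weight is 1/length, the standard correction for the
    length-proportional reconstruction bias of streamline counts.
    """

    streamlines: list[np.ndarray]
    space_affine: np.ndarray | None = None
    _lengths: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.streamlines = [
            np.ascontiguousarray(s, dtype=np.float64) for s in self.streamlines
        ]
        for k, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(
                    f"streamline {k}: expected (n>=2, 3) points, got {s.shape}"
                )

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.streamlines)

    @property
    def lengths(self) -> np.ndarray:
        """Streamline lengths in mm (sum of segment norms)."""
        if self._lengths is None:
            self._lengths = np.array(
                [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines]
            )
        return self._lengths

    @property
    def weights(self) -> np.ndarray:
        """Length-bias correction weights, 1/length per streamline."""
        return 1.0 / self.lengths

    @property
    def endpoints(self) -> np.ndarray:
        """(N, 2, 3) array of first and last points of each streamline."""
        if len(self.streamlines) == 0:
            return np.empty((0, 2, 3))
        return np.stack([[s[0], s[-1]] for s in self.streamlines])


@dataclass
class VertexMap:
    """One scalar per mesh vertex with an explicit validity mask.

    Invalid vertices (e.g. no streamline attributed) carry NaN and are
    excluded from every downstream statistic; they are never zero-filled.
    """

    values: np.ndarray
    valid: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).copy()
        self.valid = np.asarray(self.valid, dtype=bool).copy()
        if self.values.shape != self.valid.shape or self.values.ndim != 1:
            raise ValueError("values and valid must be equal-length 1-D arrays")
        self.values[~self.valid] = np.nan

    @classmethod
    def full(cls, n_vertices: int, value: float = np.nan, name: str = "",
             units: str = "") -> "VertexMap":
        valid = np.full(n_vertices, not np.isnan(value))
        return cls(np.full(n_vertices, value), valid, name=name, units=units)

    @classmethod
    def from_values(cls, values: Sequence[float], name: str = "",
                    units: str = "") -> "VertexMap":
        """Build a map, marking NaN entries invalid."""
        v = np.asarray(values, dtype=np.float64)
        return cls(v, ~np.isnan(v), name=name, units=units)

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def copy(self) -> "VertexMap":
        return VertexMap(self.values, self.valid, name=self.name, units=self.units)
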