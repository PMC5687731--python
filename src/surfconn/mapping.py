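"""Attribution of streamline extremities to cortical surface vertices.

A streamline is attributed to ("starts from") a vertex when one of its two
extremities lies within the selection radius (default 5 mm, Euclidean) of
that vertex.  Streamlines are undirected, so both extremities are eligible
independently; a streamline whose two extremities both fall within the
radius of the same vertex contributes two entries there.  The streamline's
"ending vertex" for a given selected extremity is the mesh vertex closest
to its *other* extremity, with equidistant ties broken by lowest vertex
index.  Streamlines shorter than the minimum length (default 3 mm) are
removed before any attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import SurfaceMesh, Tractogram

FIRST, LAST = 0, 1

DEFAULT_SELECTION_RADIUS = 5.0  # mm
DEFAULT_MIN_LENGTH = 3.0  # mm


def apply_affine(tractogram: Tractogram, affine: np.ndarray) -> Tractogram:
    """Map every streamline point through a 4x4 affine (homogeneous coords).

    Lengths and weights are recomputed from the transformed points.
    """
    affine = np.asarray(affine, dtype=np.float64)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular (non-invertible linear part)")
    A, t = affine[:3, :3], affine[:3, 3]
    moved = [s @ A.T + t for s in tractogram.streamlines]
    return Tractogram(moved, space_affine=None)


def filter_streamlines(tractogram: Tractogram, min_length: float) -> Tractogram:
    """Drop streamlines strictly shorter than ``min_length`` mm, keeping order."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    keep = tractogram.lengths >= min_length
    return Tractogram(
        [s for s, k in zip(tractogram.streamlines, keep) if k],
        space_affine=tractogram.space_affine,
    )


@dataclass
class EndpointAssignment:
    """The vertex <- (streamline, extremity) selection table.

    Stored as flat parallel arrays sorted by (vertex, streamline,
    extremity), with a CSR-style ``indptr`` over vertices, plus the
    per-(streamline, extremity) ending-vertex lookup.
    """

    n_vertices: int
    n_streamlines: int
    vertex: np.ndarray       # (E,) selecting vertex of each entry
    streamline: np.ndarray   # (E,)
    extremity: np.ndarray    # (E,) FIRST or LAST
    ending_vertex: np.ndarray  # (E,) nearest vertex to the other extremity
    selection_radius: float
    min_length: float
    indptr: np.ndarray = field(repr=False)  # (V+1,) entry range per vertex

    @property
    def n_entries(self) -> int:
        return self.vertex.shape[0]

    def entries_for_vertex(self, v: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(streamline, extremity, ending_vertex) arrays of vertex ``v``'s entries."""
        lo, hi = self.indptr[v], self.indptr[v + 1]
        return self.streamline[lo:hi], self.extremity[lo:hi], self.ending_vertex[lo:hi]

    @property
    def counts(self) -> np.ndarray:
        """Number of selected entries per vertex."""
        return np.diff(self.indptr)

    @property
    def vertex_has_selection(self) -> np.ndarray:
        return self.counts > 0

    def to_table(self):
        """Sparse triplet export: one row per (vertex, streamline, extremity)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "vertex": self.vertex,
                "streamline": self.streamline,
                "extremity": self.extremity,
                "ending_vertex": self.ending_vertex,
            }
        )

    def save(self, path) -> None:
        np.savez(
            path,
            n_vertices=self.n_vertices,
            n_streamlines=self.n_streamlines,
            vertex=self.vertex,
            streamline=self.streamline,
            extremity=self.extremity,
            ending_vertex=self.ending_vertex,
            selection_radius=self.selection_radius,
            min_length=self.min_length,
            indptr=self.indptr,
        )

    @classmethod
    def load(cls, path) -> "EndpointAssignment":
        z = np.load(path)
        return cls(
            n_vertices=int(z["n_vertices"]),
            n_streamlines=int(z["n_streamlines"]),
            vertex=z["vertex"],
            streamline=z["streamline"],
            extremity=z["extremity"],
            ending_vertex=z["ending_vertex"],
            selection_radius=float(z["selection_radius"]),
            min_length=float(z["min_length"]),
            indptr=z["indptr"],
        )


def _nearest_vertex_lowest_tie(tree: cKDTree, vertices: np.ndarray,
                               points: np.ndarray) -> np.ndarray:
    """Globally nearest mesh vertex per point; exact ties -> lowest index."""
    if points.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    dist, idx = tree.query(points)
    # re-examine a small ball around the nearest distance so that exact
    # equidistant ties resolve to the lowest vertex index, matching argmin
    out = np.asarray(idx, dtype=np.int64).copy()
    balls = tree.query_ball_point(points, dist + 1e-9)
    for k, cand in enumerate(balls):
        if len(cand) > 1:
            cand = np.asarray(cand)
            d = np.linalg.norm(vertices[cand] - points[k], axis=1)
            out[k] = cand[d == d.min()].min()
    return out


def assign_endpoints(
    tractogram: Tractogram,
    mesh: SurfaceMesh,
    selection_radius: float = DEFAULT_SELECTION_RADIUS,
) -> EndpointAssignment:
    """Select, for every vertex, the streamline extremities within the radius.

    The tractogram must already be in surface space and length-filtered.
    Uses a KD-tree but produces exactly the same assignment as the
    exhaustive all-pairs search (closed-ball radius test, ties on the
    ending vertex broken by lowest index).
    """
    if mesh.n_vertices == 0:
        raise ValueError("mesh has no vertices")
    n_s = len(tractogram)
    if n_s == 0:
        empty = np.empty(0, dtype=np.int64)
        return EndpointAssignment(
            n_vertices=mesh.n_vertices, n_streamlines=0,
            vertex=empty, streamline=empty, extremity=empty, ending_vertex=empty,
            selection_radius=selection_radius, min_length=np.nan,
            indptr=np.zeros(mesh.n_vertices + 1, dtype=np.int64),
        )

    ends = tractogram.endpoints                  # (N, 2, 3)
    flat_ends = ends.reshape(-1, 3)              # endpoint e of streamline s at 2s+e
    end_tree = cKDTree(flat_ends)
    vert_tree = cKDTree(mesh.vertices)

    # selection: closed ball of radius r around each vertex
    hits = vert_tree.query_ball_tree(end_tree, selection_radius)
    counts = np.fromiter((len(h) for h in hits), count=mesh.n_vertices, dtype=np.int64)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    flat = np.concatenate([np.sort(h) for h in hits if h]) if counts.sum() else \
        np.empty(0, dtype=np.int64)
    flat = flat.astype(np.int64)
    vertex = np.repeat(np.arange(mesh.n_vertices, dtype=np.int64), counts)
    streamline = flat // 2
    extremity = flat % 2

    # ending vertex of (s, FIRST) is nearest vertex to the LAST point & vice versa
    other = np.stack([ends[:, 1], ends[:, 0]], axis=1).reshape(-1, 3)
    end_vertex_lookup = _nearest_vertex_lowest_tie(vert_tree, mesh.vertices, other)
    ending_vertex = end_vertex_lookup[flat]

    return EndpointAssignment(
        n_vertices=mesh.n_vertices,
        n_streamlines=n_s,
        vertex=vertex,
        streamline=streamline,
        extremity=extremity,
        ending_vertex=ending_vertex,
        selection_radius=selection_radius,
        min_length=np.nan,
        indptr=indptr,
    )
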