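"""Per-vertex white-matter connectivity metrics.

For every cortical vertex with at least one attributed streamline:

* **mean tracts' length** — the (optionally 1/length-weighted) mean length
  of the streamlines starting from that vertex;
* **CI_short(T)** — 100 x (count of attributed streamlines with length
  <= T) / (count of all attributed streamlines);
* **CI_long(T)** — the same with length > T.

Counts are 1/length-weighted by default, correcting the bias that longer
streamlines are reconstructed more often.  With the half-open convention
(short: L <= T, long: L > T) the two indices partition every vertex's
fibers, so CI_short(T) + CI_long(T) = 100 exactly.  The default cut-off is
30 mm (a group-average mean tract length), with sweeps 5-30 mm for
CI_short and 30-60 mm for CI_long in 5 mm steps probing the sensitivity
to that choice.

Vertices with no attributed streamline are invalid — never zero-filled —
so they are excluded from smoothing and statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import SurfaceMesh, Tractogram, VertexMap
from .mapping import EndpointAssignment

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 30.0  # mm
DEFAULT_SHORT_THRESHOLDS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
DEFAULT_LONG_THRESHOLDS = (30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0)

SULCUS, GYRUS = 1.0, 0.0


def _entry_weights(assignment: EndpointAssignment, tractogram: Tractogram,
                   weighted: bool) -> np.ndarray:
    if weighted:
        return tractogram.weights[assignment.streamline]
    return np.ones(assignment.n_entries)


def mean_tract_length(assignment: EndpointAssignment, tractogram: Tractogram,
                      weighted: bool = False) -> VertexMap:
    """Mean length (mm) of the streamlines attributed to each vertex.

    With ``weighted=True`` each streamline contributes with weight
    1/length, which makes the result the harmonic mean of the lengths.
    """
    L = tractogram.lengths[assignment.streamline]
    w = _entry_weights(assignment, tractogram, weighted)
    num = np.bincount(assignment.vertex, weights=w * L, minlength=assignment.n_vertices)
    den = np.bincount(assignment.vertex, weights=w, minlength=assignment.n_vertices)
    valid = assignment.vertex_has_selection
    values = np.full(assignment.n_vertices, np.nan)
    values[valid] = num[valid] / den[valid]
    return VertexMap(values, valid, name="mean_tract_length", units="mm")


def connectivity_index(assignment: EndpointAssignment, tractogram: Tractogram,
                       threshold: float = DEFAULT_CUTOFF, mode: str = "short",
                       weighted: bool = True) -> VertexMap:
    """Percentage of attributed streamlines below/above a length threshold.

    ``mode='short'`` counts streamlines with length <= threshold,
    ``mode='long'`` those with length > threshold, each divided by all
    attributed streamlines and scaled to percent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 mm")
    if mode not in ("short", "long"):
        raise ValueError(f"mode must be 'short' or 'long', got {mode!r}")
    L = tractogram.lengths[assignment.streamline]
    w = _entry_weights(assignment, tractogram, weighted)
    qual = (L <= threshold) if mode == "short" else (L > threshold)
    num = np.bincount(assignment.vertex, weights=w * qual,
                      minlength=assignment.n_vertices)
    den = np.bincount(assignment.vertex, weights=w, minlength=assignment.n_vertices)
    valid = assignment.vertex_has_selection
    values = np.full(assignment.n_vertices, np.nan)
    values[valid] = 100.0 * num[valid] / den[valid]
    return VertexMap(values, valid, name=f"ci_{mode}_{threshold:g}mm", units="%")


def threshold_sweep(assignment: EndpointAssignment, tractogram: Tractogram,
                    thresholds, mode: str = "short",
                    weighted: bool = True) -> dict[float, VertexMap]:
    """One CI map per threshold of an ascending sweep."""
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted strictly ascending")
    return {
        t: connectivity_index(assignment, tractogram, t, mode, weighted)
        for t in thresholds
    }


@dataclass
class ConnectivityProfile:
    """The full per-vertex metric set: mean length plus CI sweeps."""

    mean_length: VertexMap
    ci: dict[tuple[str, float], VertexMap]
    thresholds_short: tuple = DEFAULT_SHORT_THRESHOLDS
    thresholds_long: tuple = DEFAULT_LONG_THRESHOLDS
    cutoff: float = DEFAULT_CUTOFF
    weighted_counts: bool = True


def compute_profile(assignment: EndpointAssignment, tractogram: Tractogram,
                    thresholds_short=DEFAULT_SHORT_THRESHOLDS,
                    thresholds_long=DEFAULT_LONG_THRESHOLDS,
                    cutoff: float = DEFAULT_CUTOFF,
                    weighted_counts: bool = True,
                    weighted_mean_length: bool = False) -> ConnectivityProfile:
    ci: dict[tuple[str, float], VertexMap] = {}
    for t, m in threshold_sweep(assignment, tractogram, thresholds_short,
                                "short", weighted_counts).items():
        ci[("short", t)] = m
    for t, m in threshold_sweep(assignment, tractogram, thresholds_long,
                                "long", weighted_counts).items():
        ci[("long", t)] = m
    return ConnectivityProfile(
        mean_length=mean_tract_length(assignment, tractogram, weighted_mean_length),
        ci=ci,
        thresholds_short=tuple(thresholds_short),
        thresholds_long=tuple(thresholds_long),
        cutoff=cutoff,
        weighted_counts=weighted_counts,
    )


@dataclass
class TerminationMap:
    seed_vertex: int
    proportions: VertexMap


def termination_map(assignment: EndpointAssignment, mesh: SurfaceMesh,
                    seed_vertex: int, tractogram: Tractogram,
                    weighted: bool = True) -> TerminationMap:
    """Where the streamlines starting from one vertex end on the surface.

    proportions[v] is the (weighted) fraction of the seed's attributed
    streamlines whose ending vertex is v; proportions sum to 1.
    """
    if not 0 <= seed_vertex < assignment.n_vertices:
        raise ValueError(f"seed vertex {seed_vertex} out of range")
    streamlines, _, ending = assignment.entries_for_vertex(seed_vertex)
    if streamlines.size == 0:
        log.warning("seed vertex %d has no attributed streamlines", seed_vertex)
        return TerminationMap(
            seed_vertex,
            VertexMap.full(assignment.n_vertices, np.nan, name="terminations"),
        )
    w = tractogram.weights[streamlines] if weighted else np.ones(streamlines.size)
    props = np.bincount(ending, weights=w, minlength=assignment.n_vertices)
    props /= w.sum()
    return TerminationMap(
        seed_vertex,
        VertexMap(props, np.ones(assignment.n_vertices, bool), name="terminations"),
    )


def classify_sulcal_gyral(mesh: SurfaceMesh, curvature: VertexMap) -> VertexMap:
    """Label each vertex sulcus (curvature > 0) or gyrus (curvature <= 0).

    Follows the FreeSurfer sign convention: signed mean curvature is
    positive in sulcal folds, negative on gyral crowns.
    """
    if curvature is None:
        raise ValueError("per-vertex curvature is required")
    if curvature.n_vertices != mesh.n_vertices:
        raise ValueError("curvature map does not match the mesh")
    if not curvature.valid.all():
        raise ValueError("curvature must be defined at every vertex")
    labels = np.where(curvature.values > 0, SULCUS, GYRUS)
    return VertexMap(labels, np.ones(mesh.n_vertices, bool),
                     name="sulcus_gyrus", units="1=sulcus,0=gyrus")


def termination_class_proportions(assignment: EndpointAssignment,
                                  tractogram: Tractogram, labels: VertexMap,
                                  weighted: bool = True) -> dict[str, float]:
    """Weighted fraction of all endings landing in sulci vs gyri."""
    if labels.n_vertices != assignment.n_vertices:
        raise ValueError("label map does not match the assignment")
    w = _entry_weights(assignment, tractogram, weighted)
    end_labels = labels.values[assignment.ending_vertex]
    total = w.sum()
    if total == 0:
        return {"sulcus": np.nan, "gyrus": np.nan}
    sulcus = w[end_labels == SULCUS].sum() / total
    return {"sulcus": float(sulcus), "gyrus": float(1.0 - sulcus)}


def termination_angle(tractogram: Tractogram, mesh: SurfaceMesh,
                      assignment: EndpointAssignment) -> np.ndarray:
    """Angle between each terminating fiber segment and the surface normal.

    For every unique selected (streamline, extremity) pair, takes the
    terminal segment at the *ending* side (last two polyline points of
    that end) and the vertex normal at the ending vertex, and returns the
    angle folded to [0, 90] degrees (fibers are undirected).  Rows are
    (streamline, extremity, angle_deg); degenerate zero-length terminal
    segments are skipped with a logged count.
    """
    if assignment.n_entries == 0:
        return np.empty((0, 3))
    pairs = np.unique(
        np.stack([assignment.streamline, assignment.extremity], axis=1), axis=0
    )
    # ending vertex depends only on (streamline, extremity); take any entry
    lookup = {}
    for s, e, ev in zip(assignment.streamline, assignment.extremity,
                        assignment.ending_vertex):
        lookup[(int(s), int(e))] = int(ev)
    rows = []
    n_skipped = 0
    for s, e in pairs:
        poly = tractogram.streamlines[s]
        # ending side is the extremity opposite the selected one
        seg = (poly[-1] - poly[-2]) if e == 0 else (poly[0] - poly[1])
        norm = np.linalg.norm(seg)
        if norm == 0:
            n_skipped += 1
            continue
        n_vec = mesh.vertex_normals[lookup[(int(s), int(e))]]
        cosang = np.clip(abs(np.dot(seg / norm, n_vec)), 0.0, 1.0)
        rows.append((s, e, np.degrees(np.arccos(cosang))))
    if n_skipped:
        log.warning("skipped %d degenerate terminal segments", n_skipped)
    return np.array(rows) if rows else np.empty((0, 3))
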