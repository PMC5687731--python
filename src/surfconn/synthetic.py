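"""Synthetic meshes, tractograms and cohorts for end-to-end testing.

Nothing here aims at anatomical realism.  The generator reproduces the
*statistical* structure the metrics operate on: a closed genus-0 mesh (or
a folded sheet with an analytic sulcus/gyrus curvature field), streamline
polylines whose extremities lie on or near mesh vertices, a two-component
mixture of short and long fiber lengths, and — for group analyses — a
spatially confined patch where the short/long mixture differs between
patients and controls.  Streamline paths follow jittered graph-geodesic
chords: the metrics depend only on extremities and lengths, so path shape
is irrelevant by construction.

All randomness flows from a single integer seed through per-component
substreams, so each piece can be regenerated independently and every
output is bit-identical across runs with the same seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse.csgraph import dijkstra

from .core import SurfaceMesh, Tractogram, VertexMap
from .mapping import assign_endpoints, filter_streamlines
from .metrics import connectivity_index, mean_tract_length

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    The length mixture is chosen so the overall mean tract length sits
    near the 30 mm short/long cut-off: 60% short fibers at 15 +/- 5 mm and
    40% long fibers at 45 +/- 10 mm.  Ages span 6-28 years and sex is
    balanced, mirroring a developmental clinical cohort.
    """

    # mesh
    subdivisions: int = 3
    radius: float = 50.0          # mm, hemisphere-like scale
    # tractogram
    n_streamlines: int = 5000
    p_short: float = 0.6
    short_length: tuple[float, float] = (15.0, 5.0)   # mean, sd in mm
    long_length: tuple[float, float] = (45.0, 10.0)
    min_length: float = 3.0       # generated lengths never fall below this
    endpoint_jitter: float = 1.0  # mm, extremity displacement off the surface
    path_jitter: float = 0.2      # mm, interior polyline wobble
    # group effect
    patch_center: int | None = None
    patch_radius: float = 15.0    # mm geodesic
    delta_p_short: float = 0.0
    # cohort
    n_subjects_per_group: int = 20
    age_range: tuple[float, float] = (6.0, 28.0)
    # direct map simulation variance components (CI percent scale)
    baseline_ci: float = 60.0
    sigma_subject: float = 4.0    # between-subject SD, shared across vertices
    sigma_vertex: float = 6.0     # independent per-vertex noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_short <= 1.0:
            raise ValueError("p_short must be in [0, 1]")
        if self.short_length[1] < 0 or self.long_length[1] < 0:
            raise ValueError("length SDs must be >= 0")
        if self.delta_p_short and self.patch_radius <= 0:
            raise ValueError("patch_radius must be > 0 when an effect is present")

    def rng(self, component: int) -> np.random.Generator:
        """Independent substream for one generator component."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(component,))
        )


_RNG_MESH, _RNG_TRACT, _RNG_COHORT, _RNG_RELIABILITY = 0, 1, 2, 3


def make_icosphere(subdivisions: int = 3, radius: float = 50.0) -> SurfaceMesh:
    """Closed genus-0 icosphere: 42 vertices at level 1, x4 faces per level."""
    if subdivisions < 1:
        raise ValueError("subdivision level must be >= 1")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(m.vertices), np.asarray(m.faces))


def make_folded_sheet(nx: int = 40, ny: int = 20, extent: float = 60.0,
                      amplitude: float = 3.0, wavelength: float = 15.0
                      ) -> tuple[SurfaceMesh, VertexMap]:
    """Sinusoidally folded sheet with its analytic curvature sign field.

    Height z = A sin(2 pi x / lambda).  The returned curvature is the
    second derivative d2z/dx2, which is positive in the valleys (sulci)
    and negative on the crests (gyri) — the FreeSurfer sign convention.
    """
    x = np.linspace(0, extent, nx)
    y = np.linspace(0, extent * ny / nx, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    k = 2.0 * np.pi / wavelength
    zz = amplitude * np.sin(k * xx)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    mesh = SurfaceMesh(verts, np.array(faces))
    curv = -amplitude * k * k * np.sin(k * verts[:, 0])  # d2z/dx2
    return mesh, VertexMap(curv, np.ones(len(verts), bool), name="curv")


def make_mesh(config: SimulationConfig) -> SurfaceMesh:
    return make_icosphere(config.subdivisions, config.radius)


def geodesic_patch(mesh: SurfaceMesh, center: int, radius: float) -> np.ndarray:
    """Vertex indices within a graph-geodesic radius of ``center``."""
    d = dijkstra(mesh.edge_length_graph(), directed=False, indices=center)
    return np.flatnonzero(d <= radius)


def make_tractogram(
    mesh: SurfaceMesh, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Tractogram, pd.DataFrame]:
    """Sample streamlines with a short/long length mixture on the mesh.

    Each streamline starts at a uniformly sampled vertex, draws its class
    (short/long) from ``p_short`` — patch-modified where an effect is
    configured — draws a target length from the class distribution, walks
    the graph-geodesic path to the vertex whose geodesic distance best
    matches the target, and jitters the resulting polyline.  Returns the
    tractogram and a ground-truth table (class, target and realized
    length, start/end vertices).
    """
    if rng is None:
        rng = config.rng(_RNG_TRACT)
    V = mesh.n_vertices
    graph = mesh.edge_length_graph()

    starts = rng.integers(0, V, size=config.n_streamlines)
    uniq = np.unique(starts)
    dist, pred = dijkstra(graph, directed=False, indices=uniq,
                          return_predecessors=True)
    row_of = {int(v): i for i, v in enumerate(uniq)}

    p_short_vertex = np.full(V, config.p_short)
    if config.delta_p_short and config.patch_center is not None:
        patch = geodesic_patch(mesh, config.patch_center, config.patch_radius)
        p_short_vertex[patch] = np.clip(
            config.p_short + config.delta_p_short, 0.0, 1.0
        )

    streamlines: list[np.ndarray] = []
    records = []
    n_resampled = 0
    floor = config.min_length + 0.5
    for s_idx in range(config.n_streamlines):
        start = int(starts[s_idx])
        row = row_of[start]
        d = dist[row]
        reachable_max = d[np.isfinite(d)].max()
        is_short = rng.random() < p_short_vertex[start]
        mean, sd = config.short_length if is_short else config.long_length
        target = rng.normal(mean, sd)
        while target < floor or target > reachable_max:
            n_resampled += 1
            target = rng.normal(mean, sd)
        # end vertex whose geodesic distance best matches the target length;
        # exclude the start itself so every path has >= 2 points
        gap = np.abs(d - target)
        gap[start] = np.inf
        gap[~np.isfinite(d)] = np.inf
        end = int(np.argmin(gap))

        path = [end]
        while path[-1] != start:
            path.append(int(pred[row, path[-1]]))
        path.reverse()
        poly = mesh.vertices[path].copy()
        if config.path_jitter > 0 and len(path) > 2:
            poly[1:-1] += rng.normal(0.0, config.path_jitter,
                                     size=(len(path) - 2, 3))
        if config.endpoint_jitter > 0:
            for which in (0, -1):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                r = config.endpoint_jitter * rng.random() ** (1.0 / 3.0)
                poly[which] += r * u
        realized = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
        streamlines.append(poly)
        records.append({
            "streamline": s_idx,
            "true_class": "short" if is_short else "long",
            "target_length": float(target),
            "length": realized,
            "start_vertex": start,
            "end_vertex": end,
        })
    if n_resampled:
        log.info("resampled %d out-of-range target lengths", n_resampled)
    return Tractogram(streamlines), pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# cohorts


def _design_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = 2 * config.n_subjects_per_group
    lo, hi = config.age_range
    return pd.DataFrame({
        "subject": [f"sub-{i:03d}" for i in range(n)],
        "group": np.repeat([0, 1], config.n_subjects_per_group),
        "age": rng.uniform(lo, hi, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
    })


def make_cohort_maps(
    mesh: SurfaceMesh, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VertexMap], pd.DataFrame, np.ndarray]:
    """Direct per-subject CI map simulation with stated variance components.

    subject map = baseline + subject offset N(0, sigma_subject)
    + per-vertex noise N(0, sigma_vertex), and for patients an additive
    shift of 100 x delta_p_short CI points inside the effect patch.
    With delta_p_short = 0 the two groups are exchangeable by
    construction.  Returns (maps, design table, patch vertex indices).
    """
    if rng is None:
        rng = config.rng(_RNG_COHORT)
    design = _design_table(config, rng)
    V = mesh.n_vertices
    patch = np.empty(0, dtype=int)
    if config.delta_p_short and config.patch_center is not None:
        patch = geodesic_patch(mesh, config.patch_center, config.patch_radius)
    maps = []
    for _, row in design.iterrows():
        vals = np.full(V, config.baseline_ci)
        vals += rng.normal(0.0, config.sigma_subject)
        vals += rng.normal(0.0, config.sigma_vertex, size=V)
        if row["group"] == 1 and patch.size:
            vals[patch] += 100.0 * config.delta_p_short
        maps.append(VertexMap(vals, np.ones(V, bool), name="ci_short"))
    return maps, design, patch


def make_cohort_pipeline(
    mesh: SurfaceMesh, config: SimulationConfig,
    metric: str = "ci_short", selection_radius: float = 5.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[VertexMap], pd.DataFrame, np.ndarray]:
    """Full per-subject tractogram -> endpoint mapping -> metric pipeline.

    Each subject gets an independent tractogram; patients carry the
    patch-confined shift of the short/long mixture.  Slower than
    :func:`make_cohort_maps` but exercises the whole chain.
    """
    if rng is None:
        rng = config.rng(_RNG_COHORT)
    design = _design_table(config, rng)
    patch = np.empty(0, dtype=int)
    if config.delta_p_short and config.patch_center is not None:
        patch = geodesic_patch(mesh, config.patch_center, config.patch_radius)
    maps = []
    for _, row in design.iterrows():
        subj_cfg = SimulationConfig(**{
            **config.__dict__,
            "delta_p_short": config.delta_p_short if row["group"] == 1 else 0.0,
        })
        tract, _ = make_tractogram(mesh, subj_cfg, rng=rng)
        tract = filter_streamlines(tract, config.min_length)
        assign = assign_endpoints(tract, mesh, selection_radius)
        if metric == "ci_short":
            maps.append(connectivity_index(assign, tract, mode="short"))
        elif metric == "ci_long":
            maps.append(connectivity_index(assign, tract, mode="long"))
        elif metric == "mean_length":
            maps.append(mean_tract_length(assign, tract))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return maps, design, patch


def make_replicate_stacks(
    n_subjects: int, n_vertices: int, n_replicates: int,
    sigma_between: float, sigma_within: float, mean: float = 50.0,
    rng: np.random.Generator | None = None, seed: int = 0,
) -> list[list[VertexMap]]:
    """Replicate map stacks with known variance components for ICC/CV checks.

    value[subject, vertex, replicate] = mean + b[subject, vertex]
    + e[subject, vertex, replicate] with b ~ N(0, sigma_between) and
    e ~ N(0, sigma_within); the population ICC is
    sigma_between^2 / (sigma_between^2 + sigma_within^2).
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(_RNG_RELIABILITY,))
        )
    b = rng.normal(0.0, sigma_between, size=(n_subjects, n_vertices))
    stacks = []
    for _ in range(n_replicates):
        e = rng.normal(0.0, sigma_within, size=(n_subjects, n_vertices))
        stacks.append([
            VertexMap(mean + b[i] + e[i], np.ones(n_vertices, bool))
            for i in range(n_subjects)
        ])
    return stacks
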