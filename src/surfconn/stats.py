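"""Vertex-wise group statistics on surface maps.

The group comparison is an ordinary-least-squares general linear model at
every vertex (group indicator plus age, sex and optionally white-matter
volume as covariates), followed by cluster-level family-wise-error
correction: supra-threshold vertices are grouped into connected
components on the mesh, each cluster's area (mm², sum of vertex areas) is
compared against the permutation null distribution of the *maximum*
cluster area, obtained by Freedman–Lane residual permutation so that
covariate effects are respected.  Cluster effect sizes are Cohen's d of
the per-subject cluster-mean values.  Reliability across repeated
acquisitions is summarised per vertex by the two-way random-effects
single-measure absolute-agreement intraclass correlation, ICC(2,1), and
the coefficient of variation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps
from scipy.sparse.csgraph import connected_components

from .core import SurfaceMesh, VertexMap

log = logging.getLogger(__name__)

DEFAULT_CLUSTERWISE_P = 0.01
DEFAULT_FORMING_P = 0.001
DEFAULT_N_PERMUTATIONS = 1000


@dataclass
class DesignMatrix:
    """GLM design: intercept, binary group, covariates, and the group contrast.

    ``group`` is coded 0 = controls, 1 = patients; the contrast tests the
    group column, so a *negative* group beta (patients lower) yields a
    negative t, and reported effect sizes are positive when controls
    exceed patients.
    """

    subjects: list[str]
    group: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=np.float64)
        if set(np.unique(self.group)) - {0.0, 1.0}:
            raise ValueError("group must be coded 0/1")
        if len(self.subjects) != self.group.shape[0]:
            raise ValueError("subjects and group lengths differ")
        if len(self.covariates) not in (0, len(self.subjects)):
            raise ValueError("covariate rows must match subjects")

    @classmethod
    def from_table(cls, table: pd.DataFrame, group_col: str = "group",
                   subject_col: str = "subject",
                   covariate_cols: list[str] | None = None) -> "DesignMatrix":
        if covariate_cols is None:
            covariate_cols = [c for c in table.columns
                              if c not in (group_col, subject_col)]
        return cls(
            subjects=table[subject_col].astype(str).tolist(),
            group=table[group_col].to_numpy(float),
            covariates=table[covariate_cols].astype(float).reset_index(drop=True),
        )

    @property
    def n_subjects(self) -> int:
        return self.group.shape[0]

    @property
    def column_names(self) -> list[str]:
        return ["intercept", "group", *self.covariates.columns.tolist()]

    def matrix(self) -> np.ndarray:
        cols = [np.ones(self.n_subjects), self.group]
        for c in self.covariates.columns:
            cols.append(self.covariates[c].to_numpy(float))
        X = np.column_stack(cols)
        zero = [n for n, col in zip(self.column_names, X.T) if np.all(col == 0)]
        if zero:
            raise ValueError(f"constant-zero design columns: {zero}")
        return X

    def reduced_matrix(self) -> np.ndarray:
        """Design without the group column (for residual permutation)."""
        return np.delete(self.matrix(), 1, axis=1)

    @property
    def contrast(self) -> np.ndarray:
        c = np.zeros(2 + self.covariates.shape[1])
        c[1] = 1.0
        return c


def stack_maps(maps: list[VertexMap]) -> tuple[np.ndarray, np.ndarray]:
    """Stack subject maps into (n_subjects, V); valid = valid in *every* subject."""
    Y = np.vstack([m.values for m in maps])
    valid = np.all(np.vstack([m.valid for m in maps]), axis=0)
    return Y, valid


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            fit, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            if np.allclose(others @ fit, X[:, j], atol=1e-8):
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


@dataclass
class GlmResult:
    beta: VertexMap
    t: VertexMap
    p: VertexMap
    df: int


def _glm_t(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray,
           pinvX: np.ndarray, c_var: float, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Contrast beta and t per column of Y (no validity handling)."""
    beta = pinvX @ Y                      # (p, V)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    # perfect fits leave residuals that are pure rounding noise; there
    # t is 0 for a null contrast and +/-inf for exact separation, never
    # a ratio of float dust
    scale = np.einsum("ij,ij->j", Y, Y) / df
    degenerate = sigma2 <= 1e-20 * np.maximum(scale, 1e-300)
    cbeta = contrast @ beta
    null_beta = np.abs(cbeta) <= 1e-10 * np.sqrt(np.maximum(scale, 1e-300))
    se = np.sqrt(np.maximum(sigma2 * c_var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((se > 0) & ~degenerate, cbeta / se, 0.0)
    t = np.where(degenerate & ~null_beta, np.sign(cbeta) * np.inf, t)
    return cbeta, t


def fit_glm(maps: list[VertexMap], design: DesignMatrix) -> GlmResult:
    """Per-vertex OLS of the subject map stack on the design.

    A vertex enters the model only if valid in every subject.  Returns the
    contrast (group) beta, its t statistic with df = n - rank(X), and the
    two-sided p-value.
    """
    X = design.matrix()
    _check_rank(X, design.column_names)
    for g in (0, 1):
        if np.sum(design.group == g) < 2:
            raise ValueError("need at least 2 subjects per group")
    Y, valid = stack_maps(maps)
    if Y.shape[0] != design.n_subjects:
        raise ValueError("number of maps does not match the design")
    df = X.shape[0] - np.linalg.matrix_rank(X)
    pinvX = np.linalg.pinv(X)
    xtx_inv = pinvX @ pinvX.T
    c = design.contrast
    c_var = float(c @ xtx_inv @ c)

    V = Y.shape[1]
    beta = np.full(V, np.nan)
    t = np.full(V, np.nan)
    cbeta_v, t_v = _glm_t(Y[:, valid], X, c, pinvX, c_var, df)
    beta[valid] = cbeta_v
    t[valid] = t_v
    p = np.full(V, np.nan)
    p[valid] = 2.0 * sps.t.sf(np.abs(t[valid]), df)
    return GlmResult(
        beta=VertexMap(beta, valid, name="group_beta"),
        t=VertexMap(t, valid, name="group_t"),
        p=VertexMap(p, valid, name="group_p"),
        df=df,
    )


def forming_threshold_from_p(p: float, df: int) -> float:
    """Two-sided vertex-wise p-value -> |t| cluster-forming threshold."""
    return float(sps.t.isf(p / 2.0, df))


@dataclass
class ClusterResult:
    vertex_set: np.ndarray
    area: float               # mm^2
    peak_vertex: int
    peak_stat: float
    sign: int                 # +1 controls<patients direction of t>0 coding
    corrected_p: float = np.nan
    effect_size: float = np.nan


def find_clusters(stat_map: VertexMap, mesh: SurfaceMesh,
                  forming_threshold: float, sign: int = 0) -> list[ClusterResult]:
    """Connected supra-threshold components with area in mm².

    ``sign`` +1 keeps t > threshold, -1 keeps t < -threshold, 0 both
    (positive and negative clusters are detected separately and never
    merged).  Clusters are sorted by descending area.
    """
    if forming_threshold <= 0:
        raise ValueError("forming threshold must be > 0")
    if stat_map.n_vertices != mesh.n_vertices:
        raise ValueError("stat map does not match the mesh")
    signs = (1, -1) if sign == 0 else (sign,)
    out: list[ClusterResult] = []
    areas = mesh.vertex_areas
    adj = mesh.adjacency
    vals = stat_map.values
    for s in signs:
        mask = stat_map.valid & (s * vals > forming_threshold)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for k in range(n_comp):
            vset = idx[labels == k]
            stat_vals = vals[vset]
            peak_local = int(np.argmax(np.abs(stat_vals)))
            out.append(ClusterResult(
                vertex_set=vset,
                area=float(areas[vset].sum()),
                peak_vertex=int(vset[peak_local]),
                peak_stat=float(stat_vals[peak_local]),
                sign=s,
            ))
    out.sort(key=lambda c: -c.area)
    return out


def _max_cluster_area(t: np.ndarray, valid: np.ndarray, adj: sparse.csr_matrix,
                      areas: np.ndarray, threshold: float) -> float:
    best = 0.0
    for s in (1, -1):
        idx = np.flatnonzero(valid & (s * t > threshold))
        if idx.size == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        best = max(best, np.bincount(labels, weights=areas[idx]).max())
    return best


def permutation_cluster_correction(
    maps: list[VertexMap],
    design: DesignMatrix,
    mesh: SurfaceMesh,
    forming_threshold: float | None = None,
    forming_p: float = DEFAULT_FORMING_P,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> tuple[list[ClusterResult], GlmResult, np.ndarray]:
    """Cluster-wise FWE correction by max-cluster-area permutation.

    Freedman–Lane scheme: the reduced model (covariates only) is fitted,
    its residuals are row-permuted and added back to the reduced fit, and
    the full-model t map of each permuted dataset contributes its largest
    supra-threshold cluster area (either sign) to the null.  Each observed
    cluster gets corrected_p = (1 + #{null >= area}) / (1 + n_permutations).
    Deterministic for a given seed.

    Returns (clusters with corrected_p and effect_size, observed GLM
    result, null max-area distribution).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    n = design.n_subjects
    if math.factorial(n) < 10 * n_permutations:
        log.warning(
            "only %d distinct permutations exist; attainable minimum "
            "corrected p is limited", math.factorial(n),
        )
    glm = fit_glm(maps, design)
    if forming_threshold is None:
        forming_threshold = forming_threshold_from_p(forming_p, glm.df)
    clusters = find_clusters(glm.t, mesh, forming_threshold, sign=0)

    X = design.matrix()
    Z = design.reduced_matrix()
    Y, valid = stack_maps(maps)
    Yv = Y[:, valid]
    pinvZ = np.linalg.pinv(Z)
    fitted_red = Z @ (pinvZ @ Yv)
    resid_red = Yv - fitted_red

    df = X.shape[0] - np.linalg.matrix_rank(X)
    pinvX = np.linalg.pinv(X)
    xtx_inv = pinvX @ pinvX.T
    c = design.contrast
    c_var = float(c @ xtx_inv @ c)
    adj = mesh.adjacency
    areas = mesh.vertex_areas

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    t_full = np.full(mesh.n_vertices, np.nan)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        Ystar = fitted_red + resid_red[perm]
        _, t_star = _glm_t(Ystar, X, c, pinvX, c_var, df)
        t_full[valid] = t_star
        null_max[b] = _max_cluster_area(t_full, valid, adj, areas,
                                        forming_threshold)

    for cl in clusters:
        cl.corrected_p = float(
            (1 + np.sum(null_max >= cl.area)) / (1 + n_permutations)
        )
        cl.effect_size = cluster_effect_size(maps, design, cl)
    return clusters, glm, null_max


def cluster_effect_size(maps: list[VertexMap], design: DesignMatrix,
                        cluster: ClusterResult) -> float:
    """Cohen's d of per-subject cluster-mean values, controls minus patients."""
    if cluster.vertex_set.size == 0:
        raise ValueError("cluster is empty")
    Y, _ = stack_maps(maps)
    sub_means = np.nanmean(Y[:, cluster.vertex_set], axis=1)
    g = design.group.astype(bool)
    a, b = sub_means[~g], sub_means[g]   # controls, patients
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        log.warning("zero pooled SD in cluster; effect size undefined")
        return np.nan
    return float((a.mean() - b.mean()) / pooled)


def clusters_to_table(clusters: list[ClusterResult],
                      mesh: SurfaceMesh) -> pd.DataFrame:
    """Cluster summary: area (mm²), peak vertex and its mm coordinates,
    peak t, corrected p, Cohen's d, direction of the group difference."""
    rows = []
    for cl in clusters:
        x, y, z = mesh.vertices[cl.peak_vertex]
        rows.append({
            "n_vertices": cl.vertex_set.size,
            "area_mm2": cl.area,
            "peak_vertex": cl.peak_vertex,
            "peak_x": x, "peak_y": y, "peak_z": z,
            "peak_t": cl.peak_stat,
            "corrected_p": cl.corrected_p,
            "cohens_d": cl.effect_size,
            "direction": "Contr>Pat" if cl.effect_size >= 0 else "Pat>Contr",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reliability


@dataclass
class ReliabilityMaps:
    icc: VertexMap
    cv: VertexMap


def reliability(replicate_stacks: list[list[VertexMap]]) -> ReliabilityMaps:
    """Per-vertex ICC(2,1) and coefficient of variation across replicates.

    ``replicate_stacks[r][i]`` is subject i's map from replicate r; all
    replicates must cover the same subjects in the same order.  ICC(2,1)
    is the two-way random-effects, absolute-agreement, single-measure
    intraclass correlation; CV is 100 x (within-subject SD / within-subject
    mean), averaged over subjects.
    """
    k = len(replicate_stacks)
    if k < 2:
        raise ValueError("need at least 2 replicates")
    stacked = []
    valids = []
    for reps in replicate_stacks:
        Y, valid = stack_maps(reps)
        stacked.append(Y)
        valids.append(valid)
    ns = {Y.shape for Y in stacked}
    if len(ns) != 1:
        raise ValueError("replicates differ in subjects or vertex count")
    data = np.stack(stacked, axis=-1)        # (n_subjects, V, k)
    valid = np.all(np.vstack(valids), axis=0)
    n = data.shape[0]

    grand = data.mean(axis=(0, 2))                       # (V,)
    row_means = data.mean(axis=2)                        # subjects x V
    col_means = data.mean(axis=0)                        # V x k
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_means - grand[:, None]) ** 2).sum(axis=1)
    ss_tot = ((data - grand[None, :, None]) ** 2).sum(axis=(0, 2))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = np.maximum(ss_err, 0.0) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - mse) / denom, np.nan)
    undef = valid & ~(denom > 0)
    if undef.any():
        log.warning("ICC undefined (zero variance) at %d vertices", undef.sum())

    within_sd = data.std(axis=2, ddof=1)                 # subjects x V
    within_mean = data.mean(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_subj = np.where(within_mean != 0, 100.0 * within_sd / np.abs(within_mean),
                           np.nan)
    cv = np.nanmean(cv_subj, axis=0)

    icc_valid = valid & np.isfinite(icc)
    cv_valid = valid & np.isfinite(cv)
    return ReliabilityMaps(
        icc=VertexMap(np.where(icc_valid, icc, np.nan), icc_valid, name="icc"),
        cv=VertexMap(np.where(cv_valid, cv, np.nan), cv_valid, name="cv", units="%"),
    )
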