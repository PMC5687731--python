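# surfconn

Surface-based mapping of short- and long-range white-matter connectivity
from tractography.

Classical tractography post-processing aggregates streamlines per lobe or
per parcel, discarding the spatial detail the cortical surface provides.
`surfconn` instead attributes streamlines to individual cortical surface
vertices and computes fine-grained per-vertex connectivity measures, with
the statistical machinery needed to compare them between groups — the
kind of analysis used to localize altered short- vs long-range
connectivity in clinical populations such as 22q11.2 deletion syndrome.

## The measures

A streamline (an undirected 3-D polyline of length *L* = Σ‖segment‖) is
attributed to vertex *v* when one of its extremities lies within a 5 mm
radius of *v*; streamlines shorter than 3 mm are discarded. Each
streamline carries a weight *w* = 1/*L*, correcting the bias that longer
fibers are reconstructed more often. At each vertex:

* **mean tracts' length** — the mean *L* of the attributed streamlines;
* **short-range connectivity index**
  CI_short(T) = 100 · Σ w·1{L ≤ T} / Σ w;
* **long-range connectivity index**
  CI_long(T) = 100 · Σ w·1{L > T} / Σ w,

with cut-off T = 30 mm by default and sensitivity sweeps at 5–30 mm
(short) and 30–60 mm (long) in 5 mm steps. CI_short + CI_long = 100
exactly at every vertex. Maps are smoothed on the mesh by iterated
nearest-neighbor averaging calibrated to a target FWHM (default 10 mm),
and groups are compared vertex-wise with an OLS GLM (age/sex covariates)
followed by cluster-wise correction against a max-cluster-area
permutation null (Freedman–Lane). Termination maps, sulcus/gyrus
termination fractions, termination angles, and ICC/CV reliability maps
round out the toolkit. See `docs/methods.md` for the full model
description and design rationale.

Supported formats: FreeSurfer binary surfaces / curv, GIFTI, OFF, TRK,
TCK, CSV maps, plain-text 4×4 affines. A synthetic-data module generates
meshes, tractograms with a known short/long length mixture, and cohorts
with planted, spatially confined group effects, so the entire pipeline is
testable without any imaging data.

## Worked example

```python
import numpy as np
from surfconn import (SimulationConfig, make_icosphere, make_tractogram,
                      filter_streamlines, assign_endpoints, mean_tract_length,
                      connectivity_index)

mesh = make_icosphere(3, radius=50.0)          # 642-vertex closed surface
cfg = SimulationConfig(subdivisions=3, n_streamlines=5000, seed=42)
tract, truth = make_tractogram(mesh, cfg)      # 60/40 short/long mixture
tract = filter_streamlines(tract, min_length=3.0)
assign = assign_endpoints(tract, mesh, selection_radius=5.0)

ml = mean_tract_length(assign, tract)
ci_short = connectivity_index(assign, tract, threshold=30.0, mode="short")
print(f"vertices with fibers: {assign.vertex_has_selection.sum()}/{mesh.n_vertices}")
print(f"mean tracts' length:  {np.nanmean(ml.values):.1f} mm "
      f"(range {np.nanmin(ml.values):.1f}-{np.nanmax(ml.values):.1f})")
print(f"CI_short(30 mm):      {np.nanmean(ci_short.values):.1f} % on average")
```

```
vertices with fibers: 642/642
mean tracts' length:  27.5 mm (range 10.9-42.8)
CI_short(30 mm):      82.8 % on average
```

The mean length sits near the 30 mm cut-off by construction of the
generator's length mixture; CI_short exceeds the 60% short-fiber
proportion because the 1/length weights up-weight short streamlines.

Group comparison with a planted patch of reduced short-range
connectivity (patients' short-fiber probability lowered by 0.2 inside a
15 mm patch, 20 subjects per group):

```python
from surfconn import (DesignMatrix, make_cohort_maps,
                      permutation_cluster_correction, clusters_to_table)

cfg = SimulationConfig(subdivisions=3, n_subjects_per_group=20,
                       patch_center=100, patch_radius=15.0,
                       delta_p_short=-0.2, seed=42)
maps, design, patch = make_cohort_maps(mesh, cfg)
dm = DesignMatrix.from_table(design, covariate_cols=["age", "sex"])
clusters, glm, null = permutation_cluster_correction(
    maps, dm, mesh, n_permutations=1000, seed=42)
print(clusters_to_table(clusters, mesh)[
    ["n_vertices", "area_mm2", "peak_t", "corrected_p", "cohens_d", "direction"]
].to_string(index=False))
```

```
 n_vertices   area_mm2     peak_t  corrected_p  cohens_d direction
         13 617.430706 -12.497694     0.000999  5.004231 Contr>Pat
```

One significant cluster (corrected p = 1/1001, the permutation minimum)
recovers the planted patch; negative peak t with positive Cohen's d means
controls have the higher CI_short, i.e. patients lost short-range
connectivity there.

A `surfconn` command-line tool wraps the same functionality
(`surfconn simulate / map / metrics / smooth / glm`; see `--help`).

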