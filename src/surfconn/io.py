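"""Readers and writers for surface, streamline, scalar-map and affine files.

Supported formats
-----------------
surfaces      : FreeSurfer binary geometry, GIFTI (.surf.gii), OFF
tractograms   : TRK, TCK (points always returned in RAS+ mm world space)
per-vertex maps : FreeSurfer curv, GIFTI (.func.gii), CSV
affines       : 4-line whitespace-separated text

Everything downstream of this module is format-agnostic.  Vertex indexing
is 0-based everywhere, including CSV output.  The invalid-vertex sentinel
is NaN in floating-point formats and an empty field in CSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.freesurfer import io as fsio

from .core import SurfaceMesh, Tractogram, VertexMap

log = logging.getLogger(__name__)

_SURFACE_FORMATS = ("freesurfer_binary", "gifti", "off")
_MAP_FORMATS = ("freesurfer_curv", "gifti", "csv")


def _guess_surface_format(path: Path) -> str:
    if path.suffix == ".gii":
        return "gifti"
    if path.suffix == ".off":
        return "off"
    return "freesurfer_binary"


def read_surface(path: str | Path, format: str | None = None) -> SurfaceMesh:
    """Read a triangulated surface into a validated :class:`SurfaceMesh`.

    Coordinates are interpreted as millimetres in the file's native space.
    """
    path = Path(path)
    fmt = format or _guess_surface_format(path)
    if fmt not in _SURFACE_FORMATS:
        raise ValueError(f"unknown surface format {fmt!r}; expected {_SURFACE_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "freesurfer_binary":
        vertices, faces = fsio.read_geometry(str(path))
    elif fmt == "gifti":
        img = nib.load(str(path))
        vertices = img.darrays[0].data
        faces = img.darrays[1].data
    else:  # off
        vertices, faces = _read_off(path)
    return SurfaceMesh(np.asarray(vertices, float), np.asarray(faces, int))


def write_surface(mesh: SurfaceMesh, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _guess_surface_format(path)
    if fmt == "freesurfer_binary":
        fsio.write_geometry(str(path), mesh.vertices, mesh.faces)
    elif fmt == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif fmt == "off":
        _write_off(mesh, path)
    else:
        raise ValueError(f"unknown surface format {fmt!r}")
    return path


def _read_off(path: Path) -> tuple[np.ndarray, np.ndarray]:
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file (missing 'OFF' header token)")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4  # OFF nv nf ne
    verts = np.array(tokens[pos : pos + 3 * nv], float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise ValueError(f"{path}: only triangular faces supported, got {k}-gon")
        faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
        pos += 1 + k
    return verts, np.array(faces, int)


def _write_off(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ---------------------------------------------------------------------------
# tractograms


def read_tractogram(path: str | Path, format: str | None = None) -> Tractogram:
    """Read a TRK/TCK tractogram; points are returned in RAS+ mm.

    TRK voxel/ras header information is honored by nibabel so downstream
    code never sees voxel units.  Streamlines with fewer than two points
    are dropped (with a logged count), not treated as an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tf = nib.streamlines.load(str(path))
    raw = [np.asarray(s, float) for s in tf.streamlines]
    kept = [s for s in raw if s.shape[0] >= 2]
    if len(kept) < len(raw):
        log.warning("dropped %d streamlines with <2 points", len(raw) - len(kept))
    return Tractogram(kept)


def write_tractogram(tractogram: Tractogram, path: str | Path) -> Path:
    """Write streamlines (assumed already in RAS+ mm) to TRK or TCK."""
    path = Path(path)
    nt = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(nt, str(path))
    return path


# ---------------------------------------------------------------------------
# per-vertex scalar maps


def write_vertex_map(vmap: VertexMap, path: str | Path, format: str | None = None,
                     n_vertices: int | None = None) -> Path:
    """Write a per-vertex scalar map.

    ``n_vertices``, when given, is checked against the map length so a map
    cannot silently be written against the wrong mesh.
    """
    path = Path(path)
    if n_vertices is not None and vmap.n_vertices != n_vertices:
        raise ValueError(
            f"map has {vmap.n_vertices} vertices but mesh declares {n_vertices}"
        )
    fmt = format or ("gifti" if path.suffix == ".gii"
                     else "csv" if path.suffix == ".csv" else "freesurfer_curv")
    if fmt == "freesurfer_curv":
        fsio.write_morph_data(str(path), vmap.values)
    elif fmt == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[nib.gifti.GiftiDataArray(vmap.values.astype(np.float32),
                                              intent="NIFTI_INTENT_NONE")]
        )
        img.meta["Name"] = vmap.name
        img.meta["Units"] = vmap.units
        nib.save(img, str(path))
    elif fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# name={vmap.name} units={vmap.units};"
                     " 0-based vertex index; empty value = invalid vertex\n")
            fh.write("vertex,value\n")
            for i, (v, ok) in enumerate(zip(vmap.values, vmap.valid)):
                fh.write(f"{i},{v:.17g}\n" if ok else f"{i},\n")
    else:
        raise ValueError(f"unknown map format {fmt!r}; expected {_MAP_FORMATS}")
    return path


def read_vertex_map(path: str | Path, format: str | None = None) -> VertexMap:
    path = Path(path)
    fmt = format or ("gifti" if path.suffix == ".gii"
                     else "csv" if path.suffix == ".csv" else "freesurfer_curv")
    if fmt == "freesurfer_curv":
        values = fsio.read_morph_data(str(path)).astype(float)
    elif fmt == "gifti":
        values = nib.load(str(path)).darrays[0].data.astype(float)
    elif fmt == "csv":
        values_list = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("vertex"):
                    continue
                _, _, val = line.strip().partition(",")
                values_list.append(float(val) if val else np.nan)
        values = np.array(values_list)
    else:
        raise ValueError(f"unknown map format {fmt!r}; expected {_MAP_FORMATS}")
    return VertexMap.from_values(values, name=path.stem)


# ---------------------------------------------------------------------------
# affines


def read_affine(path: str | Path) -> np.ndarray:
    """Read a 4x4 affine stored as 4 whitespace-separated text lines."""
    aff = np.loadtxt(path)
    if aff.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got shape {aff.shape}")
    return aff


def write_affine(affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(affine, float).reshape(4, 4), fmt="%.12g")
    return path
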