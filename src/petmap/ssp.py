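"""3-D stereotactic surface projections (3D-SSP) and projection z-scores.

The cortical surface is sampled at the boundary voxels of the brain
mask.  At every surface vertex the activity is the *maximum* trilinear
sample along the inward surface normal over a fixed cortical depth
(default 13.5 mm in 2.25 mm steps) — taking the ray maximum, rather than
the surface value, makes the projection robust to mild atrophy and small
surface misregistration.  Projections are grouped into the eight
standard views (left/right lateral, left/right medial, anterior,
posterior, superior, inferior) and can be rasterized orthographically.

A projection-space normal database (per-vertex mean and n-1 SD with a
variance floor) supports pixel-wise z-scoring of single subjects,
mirroring the volumetric database but on the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .grid import BrainMask, BrainVolume, GridError, VolumeGrid

DEFAULT_DEPTH_MM = 13.5
DEFAULT_STEP_MM = 2.25
DEFAULT_SD_FLOOR_FRACTION = 0.01

VIEWS = ("left_lateral", "right_lateral", "left_medial", "right_medial",
         "anterior", "posterior", "superior", "inferior")

# Orthographic raster geometry per view: (u axis, v axis, depth axis, depth
# sign).  u/v index world axes (0=x, 1=y, 2=z); the viewer looks along the
# depth axis with the given sign, so smaller signed depth is nearer.
_VIEW_GEOMETRY = {
    "left_lateral":  (1, 2, 0, +1),
    "right_lateral": (1, 2, 0, -1),
    "left_medial":   (1, 2, 0, -1),
    "right_medial":  (1, 2, 0, +1),
    "anterior":      (0, 2, 1, -1),
    "posterior":     (0, 2, 1, +1),
    "superior":      (0, 1, 2, -1),
    "inferior":      (0, 1, 2, +1),
}


class SurfaceError(ValueError):
    pass


@dataclass
class SurfaceModel:
    """Surface vertices, inward normals, and their view assignment."""

    grid: VolumeGrid
    vertices_mm: np.ndarray        # (V, 3) world coordinates
    inward_normals: np.ndarray     # (V, 3) unit vectors pointing into the brain
    view_of_vertex: np.ndarray     # (V,) index into VIEWS

    def __post_init__(self):
        v = np.asarray(self.vertices_mm, dtype=float)
        n = np.asarray(self.inward_normals, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or n.shape != v.shape:
            raise SurfaceError("vertices and normals must be (V, 3) arrays")
        norms = np.linalg.norm(n, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise SurfaceError("normals must be unit length")
        self.vertices_mm = v
        self.inward_normals = n
        self.view_of_vertex = np.asarray(self.view_of_vertex, dtype=int)

    @property
    def n_vertices(self):
        return self.vertices_mm.shape[0]

    def vertices_in_view(self, view):
        idx = VIEWS.index(view)
        return np.flatnonzero(self.view_of_vertex == idx)


@dataclass
class SurfaceProjection:
    """Per-vertex projected values on a :class:`SurfaceModel`."""

    model: SurfaceModel
    values: np.ndarray
    scaling: str = "none"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.model.n_vertices,):
            raise SurfaceError("projection length does not match the model")
        if not np.all(np.isfinite(values)):
            raise SurfaceError("projection contains non-finite values")
        self.values = values

    def with_values(self, values, scaling=None):
        return SurfaceProjection(self.model, values,
                                 scaling if scaling is not None else self.scaling)


def _assign_views(vertices_mm, outward_normals):
    """Assign each vertex to one of the eight standard views.

    Dominant-axis rule on the outward normal; x-dominant vertices split
    into lateral (normal pointing away from the midline) and medial
    (normal pointing toward/across the midline, i.e. fissure walls).
    """
    out = np.empty(vertices_mm.shape[0], dtype=int)
    dom = np.argmax(np.abs(outward_normals), axis=1)
    x = vertices_mm[:, 0]
    nx, ny, nz = outward_normals.T
    left = x < 0
    for i in range(vertices_mm.shape[0]):
        if dom[i] == 0:
            outward_lateral = (nx[i] < 0) if left[i] else (nx[i] > 0)
            if left[i]:
                out[i] = VIEWS.index("left_lateral" if outward_lateral
                                     else "left_medial")
            else:
                out[i] = VIEWS.index("right_lateral" if outward_lateral
                                     else "right_medial")
        elif dom[i] == 1:
            out[i] = VIEWS.index("anterior" if ny[i] > 0 else "posterior")
        else:
            out[i] = VIEWS.index("superior" if nz[i] > 0 else "inferior")
    return out


def build_surface_model(mask, normal_smoothing_mm=6.0):
    """Surface model from the boundary voxels of a single connected mask.

    Vertices sit at the centres of mask voxels that touch the outside
    through a face (6-neighbourhood).  Inward normals are the normalized
    gradient of a Gaussian-smoothed indicator of the mask, which points
    from outside to inside.
    """
    labeled, n_comp = ndimage.label(mask.data,
                                    structure=np.ones((3, 3, 3), dtype=int))
    if n_comp == 0:
        raise SurfaceError("mask is empty")
    if n_comp > 1:
        raise SurfaceError(f"mask has {n_comp} connected components; expected 1")
    eroded = ndimage.binary_erosion(mask.data,
                                    structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    boundary = mask.data & ~eroded
    idx = np.argwhere(boundary)
    grid = mask.grid
    vertices = (idx - np.asarray(grid.origin_voxel)) * np.asarray(grid.voxel_size_mm)

    sigma = normal_smoothing_mm / np.asarray(grid.voxel_size_mm)
    smooth = ndimage.gaussian_filter(mask.data.astype(float), sigma,
                                     mode="constant", cval=0.0)
    grads = np.gradient(smooth, *grid.voxel_size_mm)
    g = np.stack([gr[tuple(idx.T)] for gr in grads], axis=1)
    norms = np.linalg.norm(g, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    inward = g / norms[:, None]      # gradient of the indicator points inward

    views = _assign_views(vertices, -inward)
    return SurfaceModel(grid, vertices, inward, views)


def project_ssp(volume, model, depth_mm=DEFAULT_DEPTH_MM,
                step_mm=DEFAULT_STEP_MM, scaling="none"):
    """Maximum-along-inward-ray surface projection of ``volume``.

    Samples at depths 0, step, 2*step, ... up to and including
    ``depth_mm`` (trilinear interpolation); the vertex value is the
    maximum sample.  ``depth_mm = 0`` reduces to surface sampling.
    """
    if depth_mm < 0:
        raise ValueError("depth_mm must be nonnegative")
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    if volume.grid != model.grid:
        raise GridError("volume grid does not match the surface model")
    depths = np.arange(0.0, depth_mm + 1e-9, step_mm)
    vs = np.asarray(volume.grid.voxel_size_mm)
    org = np.asarray(volume.grid.origin_voxel)
    best = np.full(model.n_vertices, -np.inf)
    for d in depths:
        pts = model.vertices_mm + d * model.inward_normals
        vox = (pts / vs + org).T
        samples = ndimage.map_coordinates(volume.data, vox, order=1,
                                          mode="constant", cval=0.0)
        best = np.maximum(best, samples)
    return SurfaceProjection(model, best, scaling)


@dataclass
class SSPReference:
    """Per-vertex normal database: mean, (floored) SD, cohort size."""

    model: SurfaceModel
    mean: np.ndarray
    stddev: np.ndarray
    n: int
    scaling: str = "none"


def build_ssp_reference(projections, floor_fraction=DEFAULT_SD_FLOOR_FRACTION):
    """Per-vertex mean and n-1 SD (with variance floor) of control SSPs."""
    if len(projections) < 2:
        raise ValueError("need at least 2 projections")
    model = projections[0].model
    scaling = projections[0].scaling
    for p in projections[1:]:
        if p.model is not model and (
                p.model.n_vertices != model.n_vertices
                or not np.array_equal(p.model.vertices_mm, model.vertices_mm)):
            raise SurfaceError("projections use different surface models")
        if p.scaling != scaling:
            raise SurfaceError("projections use different intensity scalings")
    stack = np.stack([p.values for p in projections])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    floor = max(floor_fraction * float(sd.mean()), np.finfo(float).tiny)
    sd = np.maximum(sd, floor)
    return SSPReference(model, mean, sd, len(projections), scaling)


def ssp_zscores(patient_projection, reference):
    """Pixel-wise z = (mean - patient) / sd (positive = hypometabolism)."""
    model = patient_projection.model
    ref = reference.model
    if model is not ref and (model.n_vertices != ref.n_vertices
                             or not np.array_equal(model.vertices_mm,
                                                   ref.vertices_mm)):
        raise SurfaceError("patient projection is on a different surface model")
    if patient_projection.scaling != reference.scaling:
        raise SurfaceError("patient projection uses a different scaling")
    z = (reference.mean - patient_projection.values) / reference.stddev
    return patient_projection.with_values(z, scaling=reference.scaling)


def render_views(projection, pixel_mm=DEFAULT_STEP_MM, background=np.nan):
    """Rasterize a projection into the eight standard orthographic views.

    Each view projects its vertices onto the view plane at ``pixel_mm``
    resolution with a depth buffer (nearest vertex to the viewer wins;
    ties broken by vertex order).  Always returns all eight rasters; a
    view with no vertices yields an all-background raster.
    """
    model = projection.model
    verts = model.vertices_mm
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    rasters = {}
    for view in VIEWS:
        ua, va, da, dsign = _VIEW_GEOMETRY[view]
        nu = int(np.floor((hi[ua] - lo[ua]) / pixel_mm)) + 1
        nv = int(np.floor((hi[va] - lo[va]) / pixel_mm)) + 1
        img = np.full((nu, nv), background, dtype=float)
        depth = np.full((nu, nv), np.inf)
        sel = model.vertices_in_view(view)
        for i in sel:
            u = int(round((verts[i, ua] - lo[ua]) / pixel_mm))
            v = int(round((verts[i, va] - lo[va]) / pixel_mm))
            d = dsign * verts[i, da]
            if d < depth[u, v]:
                depth[u, v] = d
                img[u, v] = projection.values[i]
        rasters[view] = img
    return rasters


def view_table(projection):
    """Per-vertex table (view, x, y, z, value) as a pandas DataFrame."""
    import pandas as pd
    model = projection.model
    return pd.DataFrame({
        "view": [VIEWS[i] for i in model.view_of_vertex],
        "x_mm": model.vertices_mm[:, 0],
        "y_mm": model.vertices_mm[:, 1],
        "z_mm": model.vertices_mm[:, 2],
        "value": projection.values,
    })
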