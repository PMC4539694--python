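"""Spatial normalization: affine registration and nonlinear refinement.

The registration stack mirrors a typical PET-to-template normalization:

* a 12-parameter affine (translation, rotation, scale, shear) estimated by
  derivative-free Powell search over a multi-resolution pyramid;
* a two-step cubic b-spline refinement (coarse control spacing, then half
  spacing), as used by locally-optimal b-spline elastic registration;
* a discrete-cosine-basis refinement (7x9x7 low-frequency basis functions,
  16 outer iterations by default), as used by SPM-style normalization.

All transforms use the pull-back convention: a transform maps *target-grid*
world coordinates to *source* world coordinates, so resampling the moving
image onto the target grid never leaves holes.  The similarity metric is
the mean squared intensity difference after median normalization of both
volumes — both images are same-modality FDG, so no mutual-information
machinery is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .grid import BrainVolume, GridError, VolumeGrid


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Affine parameters
# ---------------------------------------------------------------------------

def _rotation_matrix(rotation_deg):
    rx, ry, rz = np.deg2rad(np.asarray(rotation_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class AffineParams:
    """12-parameter affine: translation (mm), rotation (deg), scale, shear.

    The linear part is composed as ``R @ Shear @ diag(scale)`` and applied
    about the world origin:  ``y = L @ w + t``.
    """

    translation_mm: tuple = (0.0, 0.0, 0.0)
    rotation_deg: tuple = (0.0, 0.0, 0.0)
    scale: tuple = (1.0, 1.0, 1.0)
    shear: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        for name in ("translation_mm", "rotation_deg", "scale", "shear"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 3:
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scale entries must be positive, got {self.scale}")

    @classmethod
    def identity(cls):
        return cls()

    @property
    def is_identity(self):
        return (self.translation_mm == (0.0, 0.0, 0.0)
                and self.rotation_deg == (0.0, 0.0, 0.0)
                and self.scale == (1.0, 1.0, 1.0)
                and self.shear == (0.0, 0.0, 0.0))

    def matrix(self):
        """Homogeneous 4x4 world-to-world matrix."""
        R = _rotation_matrix(self.rotation_deg)
        hx, hy, hz = self.shear
        Sh = np.array([[1.0, hx, hy], [0.0, 1.0, hz], [0.0, 0.0, 1.0]])
        L = R @ Sh @ np.diag(self.scale)
        M = np.eye(4)
        M[:3, :3] = L
        M[:3, 3] = self.translation_mm
        if not np.isfinite(np.linalg.det(M)) or abs(np.linalg.det(M)) < 1e-12:
            raise ValueError("affine parameters compose to a singular matrix")
        return M

    # packing for the optimizer -------------------------------------------
    def to_vector(self):
        return np.concatenate([
            self.translation_mm, self.rotation_deg,
            np.log(self.scale), self.shear])

    @classmethod
    def from_vector(cls, x):
        x = np.asarray(x, dtype=float)
        return cls(tuple(x[0:3]), tuple(x[3:6]),
                   tuple(np.exp(x[6:9])), tuple(x[9:12]))


def _apply_matrix(M, coords):
    """Apply a 4x4 matrix to coords shaped (3, ...)."""
    out = np.einsum("ij,j...->i...", M[:3, :3], coords)
    return out + M[:3, 3].reshape(3, *([1] * (coords.ndim - 1)))


# ---------------------------------------------------------------------------
# Warp parameterizations.  Bases are defined in *world* millimetres so that
# coefficients fitted on a working grid evaluate identically on any grid.
# ---------------------------------------------------------------------------

def _cubic_bspline(t):
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    out[m1] = 2.0 / 3.0 - at[m1] ** 2 + 0.5 * at[m1] ** 3
    m2 = (at >= 1) & (at < 2)
    out[m2] = (2.0 - at[m2]) ** 3 / 6.0
    return out


def _bspline_axis_basis(axis_world, origin_mm, spacing_mm, n_ctrl):
    """(n_ctrl, n_vox) cubic b-spline weights along one axis."""
    ks = np.arange(n_ctrl) - 1  # one control point of margin below the domain
    t = (axis_world[None, :] - origin_mm) / spacing_mm - ks[:, None]
    return _cubic_bspline(t)


def _dct_axis_basis(axis_world, origin_mm, extent_mm, n_basis):
    """(n_basis, n_vox) cosine basis along one axis, on [0, 1] of the domain."""
    s = (axis_world[None, :] - origin_mm) / extent_mm
    ms = np.arange(n_basis)[:, None]
    return np.cos(np.pi * ms * s)


def _tensor_field(Ws, coeff):
    """Expand coefficients (3, Kx, Ky, Kz) into a field (3, Nx, Ny, Nz)."""
    u = np.tensordot(coeff, Ws[0], axes=([1], [0]))   # (3, Ky, Kz, Nx)
    u = np.tensordot(u, Ws[1], axes=([1], [0]))       # (3, Kz, Nx, Ny)
    u = np.tensordot(u, Ws[2], axes=([1], [0]))       # (3, Nx, Ny, Nz)
    return u


def _tensor_project(Ws, f):
    """Adjoint of :func:`_tensor_field`: project (3, Nx, Ny, Nz) onto the basis."""
    g = np.tensordot(f, Ws[0], axes=([1], [1]))       # (3, Ny, Nz, Kx)
    g = np.tensordot(g, Ws[1], axes=([1], [1]))       # (3, Nz, Kx, Ky)
    g = np.tensordot(g, Ws[2], axes=([1], [1]))       # (3, Kx, Ky, Kz)
    return g


@dataclass
class BSplineStep:
    spacing_mm: float
    origin_mm: tuple            # world position of control index k=0 per axis
    n_ctrl: tuple               # control points per axis (includes margins)
    coefficients: np.ndarray    # (3, Kx, Ky, Kz) displacements in mm

    def basis(self, grid):
        axes = grid.world_axes()
        return [_bspline_axis_basis(axes[d], self.origin_mm[d],
                                    self.spacing_mm, self.n_ctrl[d])
                for d in range(3)]


def _bspline_layout(grid, spacing_mm):
    axes = grid.world_axes()
    origin = tuple(float(a[0]) for a in axes)
    n_ctrl = tuple(int(np.ceil((a[-1] - a[0]) / spacing_mm)) + 3 for a in axes)
    return origin, n_ctrl


@dataclass
class BSplineWarp:
    """Sum of one or more cubic b-spline displacement fields (mm)."""

    grid: VolumeGrid
    steps: list
    converged: bool = True

    def displacement(self, grid=None):
        grid = grid or self.grid
        shape = (3,) + tuple(grid.shape)
        u = np.zeros(shape)
        for step in self.steps:
            u += _tensor_field(step.basis(grid), step.coefficients)
        return u

    @property
    def rms_mm(self):
        u = self.displacement()
        return float(np.sqrt(np.mean(np.sum(u ** 2, axis=0))))


@dataclass
class DCTWarp:
    """Low-frequency discrete-cosine displacement field (mm)."""

    grid: VolumeGrid
    basis_counts: tuple = (7, 9, 7)
    coefficients: np.ndarray = None   # (3, Mx, My, Mz)
    converged: bool = True

    def __post_init__(self):
        if self.coefficients is None:
            self.coefficients = np.zeros((3,) + tuple(self.basis_counts))

    def _domain(self):
        axes = self.grid.world_axes()
        return ([float(a[0]) for a in axes],
                [float(a[-1] - a[0]) for a in axes])

    def basis(self, grid):
        origin, extent = self._domain()
        axes = grid.world_axes()
        return [_dct_axis_basis(axes[d], origin[d], extent[d],
                                self.basis_counts[d]) for d in range(3)]

    def displacement(self, grid=None):
        grid = grid or self.grid
        return _tensor_field(self.basis(grid), self.coefficients)

    @property
    def rms_mm(self):
        u = self.displacement()
        return float(np.sqrt(np.mean(np.sum(u ** 2, axis=0))))


@dataclass
class SpatialTransform:
    """Pull-back map from target-grid world coordinates to source world."""

    affine: AffineParams
    target_grid: VolumeGrid
    warp: Optional[object] = None   # BSplineWarp | DCTWarp | raw (3,*shape) array

    def source_world(self):
        """Source world coordinate for every target voxel, shape (3, *shape)."""
        ax = self.target_grid.world_axes()
        W = np.stack(np.meshgrid(*ax, indexing="ij"))
        out = _apply_matrix(self.affine.matrix(), W)
        if self.warp is not None:
            if isinstance(self.warp, np.ndarray):
                if self.warp.shape != out.shape:
                    raise RegistrationError("raw displacement field shape mismatch")
                out = out + self.warp
            else:
                out = out + self.warp.displacement(self.target_grid)
        return out


def apply_transform(volume, transform, interpolation="trilinear"):
    """Resample ``volume`` onto ``transform.target_grid``.

    Values sampled outside the source support are zero.  Trilinear
    interpolation forms convex combinations, so the output range is
    contained in the input range.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0
    src_world = transform.source_world()
    vs = np.asarray(volume.grid.voxel_size_mm).reshape(3, 1, 1, 1)
    org = np.asarray(volume.grid.origin_voxel).reshape(3, 1, 1, 1)
    src_vox = src_world / vs + org
    data = ndimage.map_coordinates(volume.data, src_vox, order=order,
                                   mode="constant", cval=0.0)
    return BrainVolume(transform.target_grid, data)


# ---------------------------------------------------------------------------
# Similarity metric helpers
# ---------------------------------------------------------------------------

def _median_normalize(data):
    pos = data[data > 0.05 * data.max()]
    med = float(np.median(pos)) if pos.size else 0.0
    if med <= 0:
        raise RegistrationError("cannot median-normalize a nonpositive volume")
    return data / med


def _downsample(volume, target_mm):
    """Antialias + subsample to roughly ``target_mm`` voxels (world-aligned)."""
    vs = np.asarray(volume.grid.voxel_size_mm)
    factors = np.maximum(np.asarray(target_mm, dtype=float) / vs, 1.0)
    if np.all(factors <= 1.0 + 1e-9):
        return volume
    sigma = np.sqrt(np.maximum(factors ** 2 - 1.0, 0.0)) / 2.0
    data = ndimage.gaussian_filter(volume.data, sigma, mode="constant")
    new_shape = tuple(int(np.ceil(n / f)) for n, f in zip(volume.grid.shape, factors))
    coords = np.meshgrid(*[np.arange(n) * f for n, f in zip(new_shape, factors)],
                         indexing="ij")
    out = ndimage.map_coordinates(data, np.stack(coords), order=1,
                                  mode="constant", cval=0.0)
    grid = VolumeGrid(new_shape, tuple(vs * factors), volume.grid.space,
                      tuple(np.asarray(volume.grid.origin_voxel) / factors))
    return BrainVolume(grid, out)


def _resample_through(data_src, src_grid, src_world, order=1):
    vs = np.asarray(src_grid.voxel_size_mm).reshape(3, 1, 1, 1)
    org = np.asarray(src_grid.origin_voxel).reshape(3, 1, 1, 1)
    return ndimage.map_coordinates(data_src, src_world / vs + org, order=order,
                                   mode="constant", cval=0.0)


@dataclass
class AffineOptions:
    pyramid_mm: tuple = (8.0, 4.0)
    maxfev: tuple = (4000, 1200)
    mask_fraction: float = 0.05
    xtol: float = 1e-3
    # Penalty weight on log-zooms and shears.  The mean-squared data term
    # has a shallow valley in which a small shear plus a compensating
    # rotation fits marginally better than the true rigid pose (the gain
    # is of the order of the interpolation-error floor); regularizing the
    # non-rigid parameters toward identity removes that degeneracy without
    # biasing genuinely sheared fits, whose data-term gain is far larger.
    reg_scale_shear: float = 1.0


def register_affine(moving, template, opts=None):
    """Estimate the 12-parameter affine aligning ``moving`` to ``template``.

    Minimizes the mean squared difference of median-normalized intensities
    by Powell search over a coarse-to-fine resolution pyramid.  The returned
    transform resamples the moving image onto the template grid, so for a
    moving image generated as ``template∘A`` the recovered parameters
    approximate ``A⁻¹``.
    """
    from scipy.optimize import minimize

    opts = opts or AffineOptions()
    for vol, name in ((moving, "moving"), (template, "template")):
        if np.ptp(vol.data) == 0:
            raise RegistrationError(f"{name} volume is constant")
    mov_n = BrainVolume(moving.grid, _median_normalize(moving.data))
    tpl_n = BrainVolume(template.grid, _median_normalize(template.data))

    x = AffineParams.identity().to_vector()
    for level_mm, maxfev in zip(opts.pyramid_mm, opts.maxfev):
        mov_l = _downsample(mov_n, (level_mm,) * 3)
        tpl_l = _downsample(tpl_n, (level_mm,) * 3)
        ax = tpl_l.grid.world_axes()
        W = np.stack(np.meshgrid(*ax, indexing="ij"))
        mask = tpl_l.data > opts.mask_fraction * tpl_l.data.max()
        tpl_m = tpl_l.data[mask]

        def objective(xv):
            try:
                params = AffineParams.from_vector(xv)
            except ValueError:
                return 1e12
            warped = _resample_through(mov_l.data, mov_l.grid,
                                       _apply_matrix(params.matrix(), W))
            penalty = opts.reg_scale_shear * (
                np.sum(np.square(np.log(params.scale)))
                + np.sum(np.square(params.shear)))
            val = float(np.mean((tpl_m - warped[mask]) ** 2) + penalty)
            if not np.isfinite(val):
                raise RegistrationError("non-finite registration objective")
            return val

        res = minimize(objective, x, method="Powell",
                       options={"maxfev": int(maxfev), "xtol": opts.xtol,
                                "ftol": 1e-8})
        if objective(res.x) <= objective(x):
            x = res.x

        # never return something worse than the identity at this level
        if objective(x) > objective(AffineParams.identity().to_vector()):
            x = AffineParams.identity().to_vector()
    return AffineParams.from_vector(x)


# ---------------------------------------------------------------------------
# Warp refinement (shared gradient-descent core)
# ---------------------------------------------------------------------------

@dataclass
class WarpOptions:
    control_spacing_mm: tuple = (30.0, 15.0)   # b-spline steps: coarse, fine
    basis_counts: tuple = (7, 9, 7)            # DCT basis per axis
    n_iter: int = 40                           # per b-spline step
    n_iter_dct: int = 16                       # outer iterations (DCT)
    inner_iter: int = 5                        # gradient steps per outer iteration
    reg_weight: float = 0.01                   # displacement-magnitude penalty
    reg_length_mm: float = 10.0                # displacement scale of the penalty
    mask_fraction: float = 0.05
    working_mm: Optional[float] = None         # fit on a downsampled grid


def _descend(mov, tpl, mask, base_world, Ws, coeff, n_iter, reg_weight):
    """Accept-if-better gradient descent on warp coefficients.

    ``reg_weight`` here is the effective penalty per mm^2 of displacement
    (already divided by the squared regularization length).  Returns
    (coefficients, final objective, converged).
    """
    n_mask = int(mask.sum())
    n_vox = tpl.data.size
    vs = np.asarray(mov.grid.voxel_size_mm)
    grad_mov = np.stack(np.gradient(mov.data, *vs))  # intensity per mm

    def warp_eval(c):
        u = _tensor_field(Ws, c)
        src = base_world + u
        warped = _resample_through(mov.data, mov.grid, src)
        data_term = float(np.sum((warped[mask] - tpl.data[mask]) ** 2)) / n_mask
        reg_term = reg_weight * float(np.sum(u ** 2)) / n_vox
        return u, src, warped, data_term + reg_term

    u, src, warped, obj = warp_eval(coeff)
    step = None
    converged = False
    for _ in range(n_iter):
        resid = np.where(mask, warped - tpl.data, 0.0)
        vsr = vs.reshape(3, 1, 1, 1)
        org = np.asarray(mov.grid.origin_voxel).reshape(3, 1, 1, 1)
        src_vox = src / vsr + org
        force = np.empty_like(u)
        for d in range(3):
            gd = ndimage.map_coordinates(grad_mov[d], src_vox, order=1,
                                         mode="constant", cval=0.0)
            force[d] = 2.0 * resid * gd / n_mask
        force += 2.0 * reg_weight * u / n_vox
        g = _tensor_project(Ws, force)
        gmax = np.abs(g).max()
        if gmax == 0:
            converged = True
            break
        if step is None:
            step = 1.0 / gmax   # first trial moves coefficients by <= 1 mm
        improved = False
        for _ in range(12):
            cand = coeff - step * g
            u_c, src_c, warped_c, obj_c = warp_eval(cand)
            if obj_c < obj:
                coeff, u, src, warped = cand, u_c, src_c, warped_c
                rel = (obj - obj_c) / max(obj, 1e-30)
                obj = obj_c
                step *= 1.5
                improved = True
                if rel < 1e-7:
                    converged = True
                break
            step *= 0.5
        if not improved:
            converged = True
            break
        if converged:
            break
    return coeff, obj, converged


def _prepare_working(moving, template, affine, opts):
    mov_n = BrainVolume(moving.grid, _median_normalize(moving.data))
    tpl_n = BrainVolume(template.grid, _median_normalize(template.data))
    if opts.working_mm is not None:
        mov_n = _downsample(mov_n, (opts.working_mm,) * 3)
        tpl_n = _downsample(tpl_n, (opts.working_mm,) * 3)
    ax = tpl_n.grid.world_axes()
    W = np.stack(np.meshgrid(*ax, indexing="ij"))
    base_world = _apply_matrix(affine.matrix(), W)
    mask = tpl_n.data > opts.mask_fraction * tpl_n.data.max()
    return mov_n, tpl_n, base_world, mask


def refine_bspline(moving, template, affine, opts=None):
    """Two-step b-spline refinement after an affine pre-alignment.

    Step one fits a coarse control grid (default 30 mm spacing); step two
    fits a second field at half the spacing on top of the first.  Each step
    only ever accepts coefficient updates that lower the regularized
    objective, so the objective is non-increasing through the pipeline.
    """
    opts = opts or WarpOptions()
    mov, tpl, base_world, mask = _prepare_working(moving, template, affine, opts)
    steps = []
    converged_all = True
    base = base_world
    for spacing in opts.control_spacing_mm:
        origin, n_ctrl = _bspline_layout(template.grid, spacing)
        step_obj = BSplineStep(spacing, origin, n_ctrl,
                               np.zeros((3,) + tuple(n_ctrl)))
        Ws = step_obj.basis(tpl.grid)
        reg_eff = opts.reg_weight / opts.reg_length_mm ** 2
        coeff, _, conv = _descend(mov, tpl, mask, base, Ws,
                                  step_obj.coefficients, opts.n_iter, reg_eff)
        step_obj.coefficients = coeff
        converged_all &= conv
        steps.append(step_obj)
        base = base + _tensor_field(Ws, coeff)
    return BSplineWarp(template.grid, steps, converged=converged_all)


def refine_dct(moving, template, affine, opts=None):
    """Discrete-cosine-basis refinement after an affine pre-alignment."""
    opts = opts or WarpOptions()
    mov, tpl, base_world, mask = _prepare_working(moving, template, affine, opts)
    warp = DCTWarp(template.grid, tuple(opts.basis_counts))
    Ws = warp.basis(tpl.grid)
    reg_eff = opts.reg_weight / opts.reg_length_mm ** 2
    coeff, _, conv = _descend(mov, tpl, mask, base_world, Ws,
                              warp.coefficients,
                              opts.n_iter_dct * opts.inner_iter, reg_eff)
    warp.coefficients = coeff
    warp.converged = conv
    return warp


# ---------------------------------------------------------------------------
# Space-to-space resampling.  The two phantom spaces share one world
# coordinate frame by construction, so the declared inter-space affine is
# the identity; only the voxel lattice changes.
# ---------------------------------------------------------------------------

MNI_TO_TAL_AFFINE = AffineParams.identity()


def mni_to_tal(volume, interpolation="trilinear"):
    """Resample an MNI-like volume onto the Talairach-like 128x128x60 grid."""
    if volume.grid.space != "MNI_LIKE":
        raise GridError(f"expected an MNI_LIKE volume, got {volume.grid.space}")
    tf = SpatialTransform(MNI_TO_TAL_AFFINE, VolumeGrid.tal_like())
    return apply_transform(volume, tf, interpolation)


def tal_to_mni(volume, interpolation="trilinear"):
    """Resample a Talairach-like volume onto the MNI-like 91x109x91 grid."""
    if volume.grid.space != "TAL_LIKE":
        raise GridError(f"expected a TAL_LIKE volume, got {volume.grid.space}")
    tf = SpatialTransform(MNI_TO_TAL_AFFINE, VolumeGrid.mni_like())
    return apply_transform(volume, tf, interpolation)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def transform_to_dict(transform):
    d = {
        "affine": {
            "translation_mm": transform.affine.translation_mm,
            "rotation_deg": transform.affine.rotation_deg,
            "scale": transform.affine.scale,
            "shear": transform.affine.shear,
        },
        "target_grid": {
            "shape": transform.target_grid.shape,
            "voxel_size_mm": transform.target_grid.voxel_size_mm,
            "space": transform.target_grid.space,
            "origin_voxel": transform.target_grid.origin_voxel,
        },
        "warp": None,
    }
    w = transform.warp
    if isinstance(w, BSplineWarp):
        d["warp"] = {"type": "bspline",
                     "steps": [{"spacing_mm": s.spacing_mm,
                                "origin_mm": list(s.origin_mm),
                                "n_ctrl": list(s.n_ctrl),
                                "coefficients": s.coefficients.tolist()}
                               for s in w.steps]}
    elif isinstance(w, DCTWarp):
        d["warp"] = {"type": "dct",
                     "basis_counts": list(w.basis_counts),
                     "coefficients": w.coefficients.tolist()}
    return d


def transform_from_dict(d):
    a = d["affine"]
    affine = AffineParams(tuple(a["translation_mm"]), tuple(a["rotation_deg"]),
                          tuple(a["scale"]), tuple(a["shear"]))
    g = d["target_grid"]
    grid = VolumeGrid(tuple(g["shape"]), tuple(g["voxel_size_mm"]),
                      g["space"], tuple(g["origin_voxel"]))
    warp = None
    w = d.get("warp")
    if w is not None and w["type"] == "bspline":
        steps = [BSplineStep(s["spacing_mm"], tuple(s["origin_mm"]),
                             tuple(s["n_ctrl"]), np.asarray(s["coefficients"]))
                 for s in w["steps"]]
        warp = BSplineWarp(grid, steps)
    elif w is not None and w["type"] == "dct":
        warp = DCTWarp(grid, tuple(w["basis_counts"]),
                       np.asarray(w["coefficients"]))
    return SpatialTransform(affine, grid, warp)
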