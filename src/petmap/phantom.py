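"""Synthetic brain FDG phantom: template, cohorts, and lesions.

The template is an analytic, left-right symmetric head model built from
ellipsoids in world millimetres, so the same anatomy renders consistently
on any grid and every shape membership can be re-evaluated exactly:

* a cortical grey-matter shell of nominal uptake 100,
* a white-matter interior of 60,
* bright striatal and thalamic nuclei (95),
* near-zero lateral ventricles and an interhemispheric fissure,
* zero background.

Cohorts emulate inter-subject variability with a random rigid+scale pose,
a smooth random displacement field, a global multiplicative metabolic
factor, optional multiplicative "hypometabolic" lesions, and additive
Gaussian noise.  Every subject carries a ground-truth record of the exact
transforms, factor and lesion voxel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .grid import BrainMask, BrainVolume, GridError, VolumeGrid
from .registration import AffineParams, SpatialTransform, apply_transform

# ---------------------------------------------------------------------------
# Analytic anatomy (world mm; all x-extents symmetric about the midline).
# ---------------------------------------------------------------------------

BRAIN_SEMI_AXES = (65.0, 80.0, 60.0)
CORTEX_INNER_FRACTION = 0.88

STRIATUM = {"center": (22.0, 8.0, 2.0), "semi_axes": (9.0, 12.0, 9.0)}
THALAMUS = {"center": (10.0, -18.0, 4.0), "semi_axes": (8.0, 10.0, 8.0)}
VENTRICLE = {"center": (14.0, 10.0, 8.0), "semi_axes": (7.0, 22.0, 10.0)}
FISSURE_HALF_WIDTH = 2.5
CALLOSAL_BRIDGE = {"center_yz": (0.0, 5.0), "semi_axes_yz": (38.0, 32.0)}

INTENSITY = {
    "background": 0.0,
    "white_matter": 60.0,
    "cortex": 100.0,
    "nuclei": 95.0,
    "fissure": 5.0,
    "ventricle": 2.0,
}

ATLAS_LABELS = {
    0: "outside",
    1: "cortex",
    2: "white matter",
    3: "striatum",
    4: "thalamus",
    5: "ventricle",
    6: "interhemispheric fissure",
}


def _in_ellipsoid(x, y, z, center, semi_axes):
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _region_masks(x, y, z):
    """Boolean membership of every anatomic compartment at world (x, y, z).

    Works elementwise on arrays or scalars; later entries take precedence.
    """
    outer = _in_ellipsoid(x, y, z, (0, 0, 0), BRAIN_SEMI_AXES)
    inner = _in_ellipsoid(x, y, z, (0, 0, 0),
                          tuple(a * CORTEX_INNER_FRACTION for a in BRAIN_SEMI_AXES))
    cortex = outer & ~inner
    nuclei = np.zeros_like(outer)
    for blob in (STRIATUM, THALAMUS):
        cx, cy, cz = blob["center"]
        for sx in (+1, -1):
            nuclei = nuclei | _in_ellipsoid(x, y, z, (sx * cx, cy, cz),
                                            blob["semi_axes"])
    nuclei = nuclei & inner
    by, bz = CALLOSAL_BRIDGE["semi_axes_yz"]
    oy, oz = CALLOSAL_BRIDGE["center_yz"]
    bridge = ((y - oy) / by) ** 2 + ((z - oz) / bz) ** 2 <= 1.0
    fissure = outer & (np.abs(x) <= FISSURE_HALF_WIDTH) & ~bridge
    vent = np.zeros_like(outer)
    vx, vy, vz = VENTRICLE["center"]
    for sx in (+1, -1):
        vent = vent | _in_ellipsoid(x, y, z, (sx * vx, vy, vz),
                                    VENTRICLE["semi_axes"])
    vent = vent & inner
    return {"outer": outer, "inner": inner, "cortex": cortex,
            "nuclei": nuclei, "fissure": fissure, "ventricle": vent}


def template_value_at(point_mm):
    """Template intensity at a single world point (scalar reference path)."""
    x, y, z = (np.asarray(float(v)) for v in point_mm)
    m = _region_masks(x, y, z)
    if m["ventricle"]:
        return INTENSITY["ventricle"]
    if m["fissure"]:
        return INTENSITY["fissure"]
    if m["nuclei"]:
        return INTENSITY["nuclei"]
    if m["cortex"]:
        return INTENSITY["cortex"]
    if m["inner"]:
        return INTENSITY["white_matter"]
    return INTENSITY["background"]


def make_template(grid, seed=0, texture_amplitude=0.0):
    """Render the analytic symmetric FDG template on ``grid``.

    With ``texture_amplitude > 0`` a smooth, mirror-symmetrized random
    texture (seeded by ``seed``) is added inside the brain; the default of
    zero keeps the template exactly equal to the analytic shape model.
    """
    if not isinstance(grid, VolumeGrid):
        raise GridError("make_template requires a VolumeGrid")
    x, y, z = grid.world_coords()
    m = _region_masks(x, y, z)
    data = np.zeros(grid.shape)
    data[np.broadcast_to(m["inner"], grid.shape)] = INTENSITY["white_matter"]
    data[np.broadcast_to(m["cortex"], grid.shape)] = INTENSITY["cortex"]
    data[np.broadcast_to(m["nuclei"], grid.shape)] = INTENSITY["nuclei"]
    data[np.broadcast_to(m["fissure"], grid.shape)] = INTENSITY["fissure"]
    data[np.broadcast_to(m["ventricle"], grid.shape)] = INTENSITY["ventricle"]
    if texture_amplitude > 0:
        rng = np.random.default_rng(np.random.SeedSequence(abs(int(seed))))
        noise = rng.standard_normal(grid.shape)
        sig = 10.0 / np.asarray(grid.voxel_size_mm)
        tex = ndimage.gaussian_filter(noise, sig, mode="constant")
        tex = 0.5 * (tex + tex[::-1])   # enforce mirror symmetry in x
        sd = tex.std()
        if sd > 0:
            tex *= texture_amplitude / sd
        data = data + np.where(np.broadcast_to(m["inner"], grid.shape), tex, 0.0)
        data = np.maximum(data, 0.0)
    return BrainVolume(grid, data)


def make_gm_wm_mask(template, threshold_fraction=0.4):
    """Grey+white matter mask: voxels >= threshold_fraction of the maximum.

    Ventricles and the interhemispheric fissure sit far below any sensible
    threshold and are thereby excluded.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    top = float(template.data.max())
    if top <= 0:
        raise ValueError("cannot build a mask from a nonpositive template")
    mask = template.data >= threshold_fraction * top
    if not mask.any():
        raise ValueError("grey/white matter mask is empty")
    return BrainMask(template.grid, mask)


def make_atlas(grid):
    """Integer phantom atlas on ``grid``; names in :data:`ATLAS_LABELS`."""
    x, y, z = grid.world_coords()
    m = _region_masks(x, y, z)
    labels = np.zeros(grid.shape, dtype=int)
    labels[np.broadcast_to(m["inner"], grid.shape)] = 2
    labels[np.broadcast_to(m["cortex"], grid.shape)] = 1
    labels[np.broadcast_to(m["nuclei"], grid.shape)] = 3
    thal = np.zeros(grid.shape, dtype=bool)
    cx, cy, cz = THALAMUS["center"]
    for sx in (+1, -1):
        thal |= np.broadcast_to(
            _in_ellipsoid(x, y, z, (sx * cx, cy, cz), THALAMUS["semi_axes"]),
            grid.shape)
    labels[thal & (labels == 3)] = 4
    labels[np.broadcast_to(m["fissure"], grid.shape)] = 6
    labels[np.broadcast_to(m["ventricle"], grid.shape)] = 5
    return BrainVolume(grid, labels.astype(float))


def cortical_point(direction, shell_fraction=0.94):
    """World point inside the cortical shell along a radial direction.

    ``direction`` is any nonzero 3-vector; the point lies on the ellipsoid
    scaled by ``shell_fraction`` (mid-shell by default, since the shell
    spans fractions 0.88..1.0 of the brain ellipsoid).
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be nonzero")
    d = d / n
    return tuple(shell_fraction * d[k] * BRAIN_SEMI_AXES[k] for k in range(3))


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """A focal multiplicative intensity reduction (hypometabolic lesion).

    The reduction profile is ``k(d) = 1`` for distance ``d <= radius_mm``
    from the centre and a Gaussian falloff ``exp(-(d-r)^2 / (2 sigma^2))``
    outside; voxel intensities are multiplied by ``1 - reduction * k(d)``.
    """

    center_mm: tuple
    radius_mm: float
    reduction: float
    edge_sigma_mm: float = 2.0
    label: str = "lesion"

    def __post_init__(self):
        object.__setattr__(self, "center_mm",
                           tuple(float(c) for c in self.center_mm))
        if not (0.0 <= self.reduction < 1.0):
            raise ValueError("lesion reduction must lie in [0, 1)")
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.edge_sigma_mm < 0:
            raise ValueError("edge_sigma_mm must be nonnegative")

    def profile(self, d_mm):
        """Reduction weight k(d) as a function of distance from the centre."""
        d = np.asarray(d_mm, dtype=float)
        if self.edge_sigma_mm > 0:
            outside = np.exp(-((d - self.radius_mm) ** 2)
                             / (2.0 * self.edge_sigma_mm ** 2))
        else:
            outside = np.zeros_like(d)
        return np.where(d <= self.radius_mm, 1.0, outside)


def _lesion_distance(grid, lesion):
    x, y, z = grid.world_coords()
    cx, cy, cz = lesion.center_mm
    return np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)


def lesion_mask(grid, lesion):
    """Ground-truth voxel set of a lesion: voxels with k(d) >= 0.5.

    This covers the full-reduction core plus the inner half of the smooth
    edge, which is the support where at least half of the nominal
    reduction is applied.
    """
    d = _lesion_distance(grid, lesion)
    return lesion.profile(d) >= 0.5


def insert_lesion(volume, lesion):
    """Apply a multiplicative lesion; never increases any voxel value."""
    grid = volume.grid
    vox = grid.world_to_voxel(lesion.center_mm)
    if np.any(vox < 0) or np.any(vox > np.asarray(grid.shape) - 1):
        raise ValueError(f"lesion centre {lesion.center_mm} lies outside the grid")
    d = _lesion_distance(grid, lesion)
    factor = 1.0 - lesion.reduction * lesion.profile(d)
    return volume.with_data(volume.data * factor)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineJitter:
    max_translation_mm: float = 5.0
    max_rotation_deg: float = 3.0
    scale_range: tuple = (0.97, 1.03)

    @classmethod
    def none(cls):
        return cls(0.0, 0.0, (1.0, 1.0))


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for one synthetic cohort.

    The defaults describe an elderly healthy-control cohort of the size
    used to build the normal database (37 subjects), with modest pose
    jitter, smooth anatomic shape variation, a +/-15 % global metabolic
    factor, and additive noise at a few percent of cortical uptake.
    """

    n_subjects: int = 37
    seed: int = 0
    affine_jitter: AffineJitter = field(default_factory=AffineJitter)
    warp_amplitude_mm: float = 2.0
    global_scale_range: tuple = (0.85, 1.15)
    noise_sd: float = 4.0
    lesions: tuple = ()

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.global_scale_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"invalid global_scale_range {self.global_scale_range}")
        if self.warp_amplitude_mm < 0 or self.noise_sd < 0:
            raise ValueError("warp amplitude and noise SD must be nonnegative")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    @classmethod
    def normalized_controls(cls, n_subjects=37, seed=0, noise_sd=10.0,
                            warp_amplitude_mm=0.25, lesions=()):
        """A cohort representing scans *after* spatial normalization.

        Pose jitter is zero; only residual shape variability (0.25 mm RMS,
        the registration error left by a successful nonlinear
        normalization), the global metabolic factor and noise remain.
        """
        return cls(n_subjects=n_subjects, seed=seed,
                   affine_jitter=AffineJitter.none(),
                   warp_amplitude_mm=warp_amplitude_mm,
                   noise_sd=noise_sd, lesions=lesions)


@dataclass
class GroundTruthRecord:
    subject_index: int
    affine: AffineParams
    global_scale: float
    warp_amplitude_mm: float
    lesions: tuple
    lesion_masks: list           # one boolean array per lesion
    displacement: Optional[np.ndarray] = None   # (3, *shape) field in mm

    def to_dict(self):
        return {
            "subject_index": self.subject_index,
            "affine": {"translation_mm": self.affine.translation_mm,
                       "rotation_deg": self.affine.rotation_deg,
                       "scale": self.affine.scale,
                       "shear": self.affine.shear},
            "global_scale": self.global_scale,
            "warp_amplitude_mm": self.warp_amplitude_mm,
            "lesions": [{"center_mm": l.center_mm, "radius_mm": l.radius_mm,
                         "reduction": l.reduction,
                         "edge_sigma_mm": l.edge_sigma_mm, "label": l.label}
                        for l in self.lesions],
            "lesion_voxels": [np.argwhere(m).tolist() for m in self.lesion_masks],
        }


WARP_SMOOTHING_FWHM_MM = 20.0   # fixed smoothing of the white-noise field


def _random_displacement(grid, rng, rms_mm, smoothing_fwhm_mm=None):
    """Smooth random displacement field with the requested RMS magnitude."""
    if smoothing_fwhm_mm is None:
        smoothing_fwhm_mm = WARP_SMOOTHING_FWHM_MM
    noise = rng.standard_normal((3,) + tuple(grid.shape))
    sigma = smoothing_fwhm_mm / (np.sqrt(8 * np.log(2))
                                 * np.asarray(grid.voxel_size_mm))
    field_ = np.stack([ndimage.gaussian_filter(noise[d], sigma, mode="wrap")
                       for d in range(3)])
    rms = np.sqrt(np.mean(np.sum(field_ ** 2, axis=0)))
    if rms > 0:
        field_ *= rms_mm / rms
    return field_


def _subject_rng(spec, subject_index):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=abs(int(spec.seed)),
                               spawn_key=(int(subject_index),)))


def sample_subject(template, spec, subject_index, keep_displacement=False):
    """Draw one synthetic subject; deterministic in (spec.seed, index).

    Returns ``(volume, ground_truth)``.  The draw order (pose, warp,
    global factor, noise) is fixed so that cohorts are bit-reproducible.
    """
    rng = _subject_rng(spec, subject_index)
    grid = template.grid
    j = spec.affine_jitter
    t = rng.uniform(-j.max_translation_mm, j.max_translation_mm, 3)
    r = rng.uniform(-j.max_rotation_deg, j.max_rotation_deg, 3)
    s = rng.uniform(j.scale_range[0], j.scale_range[1], 3)
    affine = AffineParams(tuple(t), tuple(r), tuple(s))

    disp = None
    if spec.warp_amplitude_mm > 0:
        disp = _random_displacement(grid, rng, spec.warp_amplitude_mm)

    g = float(rng.uniform(*spec.global_scale_range))

    if affine.is_identity and disp is None:
        vol = template.copy()
    else:
        tf = SpatialTransform(affine, grid, warp=disp)
        vol = apply_transform(template, tf, "trilinear")

    vol = vol.with_data(vol.data * g)

    masks = []
    for lesion in spec.lesions:
        vol = insert_lesion(vol, lesion)
        masks.append(lesion_mask(grid, lesion))

    if spec.noise_sd > 0:
        # Noise amplitude scales with the global activity factor, mirroring
        # count statistics: fewer detected counts mean proportionally lower
        # signal *and* lower absolute noise, so intensity normalization can
        # cancel the global factor.
        vol = vol.with_data(
            vol.data + rng.normal(0.0, g * spec.noise_sd, grid.shape))

    gt = GroundTruthRecord(subject_index, affine, g, spec.warp_amplitude_mm,
                           spec.lesions, masks,
                           displacement=disp if keep_displacement else None)
    return vol, gt


def make_cohort(template, spec, keep_displacement=False):
    """Generate ``spec.n_subjects`` subjects (see :func:`sample_subject`)."""
    return [sample_subject(template, spec, i, keep_displacement)
            for i in range(spec.n_subjects)]
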