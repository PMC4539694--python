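"""Volume geometry and container types.

Every image in the pipeline lives on a :class:`VolumeGrid`, which couples a
voxel lattice to world (scanner/atlas) millimetre coordinates through

    world_k = (voxel_k - origin_k) * voxel_size_k

i.e. a diagonal affine with the coordinate origin at ``origin_voxel``.
Two standard spaces are provided: an MNI-like grid (91x109x91 voxels of
2 mm) and a Talairach-like grid (128x128x60 voxels of 2.25 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

SPACES = ("MNI_LIKE", "TAL_LIKE", "NATIVE")


class GridError(ValueError):
    """Invalid grid geometry or a geometry mismatch between volumes."""


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis (each >= 8).
    voxel_size_mm : tuple of float
        Positive voxel edge lengths in mm.
    space : str
        One of ``MNI_LIKE``, ``TAL_LIKE``, ``NATIVE``.
    origin_voxel : tuple of float, optional
        Voxel index of the world-coordinate origin.  Defaults to the
        geometric centre ``(shape - 1) / 2``.
    """

    shape: tuple
    voxel_size_mm: tuple
    space: str = "NATIVE"
    origin_voxel: tuple = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(shape) != 3 or len(vs) != 3:
            raise GridError("grid shape and voxel size must be 3-vectors")
        if any(s < 8 for s in shape):
            raise GridError(f"all grid dimensions must be >= 8, got {shape}")
        if any(v <= 0 for v in vs):
            raise GridError(f"voxel sizes must be positive, got {vs}")
        if self.space not in SPACES:
            raise GridError(f"unknown space {self.space!r}; expected one of {SPACES}")
        origin = self.origin_voxel
        if origin is None:
            origin = tuple((s - 1) / 2.0 for s in shape)
        else:
            origin = tuple(float(o) for o in origin)
            if len(origin) != 3:
                raise GridError("origin_voxel must be a 3-vector")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vs)
        object.__setattr__(self, "origin_voxel", origin)

    # ---- standard spaces -------------------------------------------------
    @classmethod
    def mni_like(cls):
        """Default MNI-like grid: 91x109x91 voxels of 2 mm, origin (45,63,36)."""
        return cls((91, 109, 91), (2.0, 2.0, 2.0), "MNI_LIKE", (45.0, 63.0, 36.0))

    @classmethod
    def tal_like(cls):
        """Default Talairach-like grid: 128x128x60 voxels of 2.25 mm."""
        return cls((128, 128, 60), (2.25, 2.25, 2.25), "TAL_LIKE",
                   (63.5, 63.5, 29.5))

    @classmethod
    def centered(cls, shape, voxel_size_mm, space="NATIVE"):
        """Grid with the world origin at the geometric centre of the lattice."""
        return cls(tuple(shape), tuple(voxel_size_mm), space)

    # ---- coordinates -----------------------------------------------------
    @property
    def affine(self):
        """4x4 voxel-to-world affine (diagonal scaling + origin shift)."""
        A = np.diag(list(self.voxel_size_mm) + [1.0])
        A[:3, 3] = -np.asarray(self.origin_voxel) * np.asarray(self.voxel_size_mm)
        return A

    def voxel_to_world(self, idx):
        idx = np.asarray(idx, dtype=float)
        return (idx - np.asarray(self.origin_voxel)) * np.asarray(self.voxel_size_mm)

    def world_to_voxel(self, mm):
        mm = np.asarray(mm, dtype=float)
        return mm / np.asarray(self.voxel_size_mm) + np.asarray(self.origin_voxel)

    def world_axes(self):
        """World coordinate 1-D arrays along each axis."""
        return tuple(
            (np.arange(n) - o) * v
            for n, o, v in zip(self.shape, self.origin_voxel, self.voxel_size_mm)
        )

    def world_coords(self):
        """Broadcastable world-coordinate arrays (open meshgrid)."""
        ax = self.world_axes()
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    @property
    def n_voxels(self):
        return int(np.prod(self.shape))

    def with_space(self, space):
        return replace(self, space=space)


def _require_same_grid(a, b, what="volumes"):
    if a.grid != b.grid:
        raise GridError(f"{what} are on different grids: {a.grid} vs {b.grid}")


@dataclass
class BrainVolume:
    """A scalar 3-D intensity field on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.shape != tuple(self.grid.shape):
            raise GridError(
                f"data shape {data.shape} does not match grid shape {self.grid.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume data contains non-finite values")
        self.data = data

    def with_data(self, data):
        return BrainVolume(self.grid, data)

    def copy(self):
        return BrainVolume(self.grid, self.data.copy())

    # ---- I/O -------------------------------------------------------------
    def to_nifti(self, path, dtype="float32"):
        save_nifti(self, path, dtype=dtype)

    @classmethod
    def from_nifti(cls, path, space=None):
        return load_nifti(path, space=space)


@dataclass
class BrainMask:
    """Boolean voxel mask on a :class:`VolumeGrid` (must be nonempty)."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.dtype != bool:
            data = data.astype(bool)
        if data.shape != tuple(self.grid.shape):
            raise GridError(
                f"mask shape {data.shape} does not match grid shape {self.grid.shape}")
        if not data.any():
            raise ValueError("mask is empty")
        self.data = data

    @property
    def n_true(self):
        return int(self.data.sum())

    def to_nifti(self, path):
        save_nifti(BrainVolume(self.grid, self.data.astype(float)), path,
                   dtype="uint8")

    @classmethod
    def from_nifti(cls, path, space=None):
        vol = load_nifti(path, space=space)
        return cls(vol.grid, vol.data > 0.5)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O.  The space tag is stored in the header 'descrip' field; int16
# output uses a scale slope so that reload stays within quantisation error.
# ---------------------------------------------------------------------------

def save_nifti(volume, path, dtype="float32"):
    path = Path(path)
    data = volume.data
    img_dtype = np.dtype(dtype)
    hdr = nib.Nifti1Header()
    hdr["descrip"] = f"space={volume.grid.space}".encode()
    if img_dtype == np.int16:
        amax = float(np.abs(data).max())
        slope = amax / 32000.0 if amax > 0 else 1.0
        scaled = np.round(data / slope).astype(np.int16)
        img = nib.Nifti1Image(scaled, volume.grid.affine, header=hdr)
        img.header.set_data_dtype(np.int16)
        img.header["scl_slope"] = slope
        img.header["scl_inter"] = 0.0
    else:
        img = nib.Nifti1Image(data.astype(img_dtype), volume.grid.affine,
                              header=hdr)
        img.header.set_data_dtype(img_dtype)
    img.header["descrip"] = f"space={volume.grid.space}".encode()
    nib.save(img, str(path))


def load_nifti(path, space=None):
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise GridError(f"expected a 3-D volume, got shape {data.shape}")
    aff = img.affine
    vs = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    if space is None:
        descrip = bytes(img.header["descrip"]).decode(errors="ignore")
        space = "NATIVE"
        for tag in SPACES:
            if f"space={tag}" in descrip:
                space = tag
                break
    origin = tuple(float(o) for o in (-aff[:3, 3] / np.diag(aff)[:3]))
    grid = VolumeGrid(data.shape, vs, space, origin)
    return BrainVolume(grid, data)


def save_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path):
    return json.loads(Path(path).read_text())
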