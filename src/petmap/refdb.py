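"""The voxel-wise normal reference database (MEAN and STDDEV images).

The database is the sample mean and unbiased (n-1) standard deviation of
identically preprocessed control scans, together with the grey/white
matter mask and a descriptor of the preprocessing applied.  The standard
deviation is floored at a small fraction of the in-mask average SD so
that near-constant voxels (ventricular edges, background rims) cannot
produce arbitrarily large z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import (BrainMask, BrainVolume, GridError, load_json, load_nifti,
                   save_json, save_nifti)

DEFAULT_FLOOR_FRACTION = 0.01


@dataclass
class ReferenceDatabase:
    mean: BrainVolume
    stddev: BrainVolume
    n: int
    mask: BrainMask
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mean.grid != self.stddev.grid or self.mean.grid != self.mask.grid:
            raise GridError("mean, stddev and mask must share one grid")
        if self.n < 2:
            raise ValueError("a reference database needs at least 2 subjects")

    @property
    def grid(self):
        return self.mean.grid


def build_reference(volumes, mask, floor_fraction=DEFAULT_FLOOR_FRACTION,
                    meta=None):
    """Voxel-wise MEAN/STDDEV database from preprocessed control volumes.

    Parameters
    ----------
    volumes : list of BrainVolume
        >= 2 identically preprocessed scans on one grid.
    mask : BrainMask
        Grey/white matter mask on the same grid.
    floor_fraction : float
        The SD image is floored at ``floor_fraction`` times the average
        in-mask SD (variance floor against division blow-ups).
    meta : dict, optional
        Preprocessing descriptor (fwhm_mm, scaling, space, ...), recorded
        so that patients can be checked for identical preprocessing.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes to build a reference database")
    grid = volumes[0].grid
    for v in volumes[1:]:
        if v.grid != grid:
            raise GridError("all reference volumes must share one grid")
    if mask.grid != grid:
        raise GridError("mask grid does not match reference volumes")
    if floor_fraction < 0:
        raise ValueError("floor_fraction must be nonnegative")

    stack = np.stack([v.data for v in volumes])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    floor = floor_fraction * float(sd[mask.data].mean())
    floor = max(floor, np.finfo(float).tiny)
    sd = np.maximum(sd, floor)

    meta = dict(meta or {})
    meta.setdefault("space", grid.space)
    meta["n"] = len(volumes)
    meta["floor_fraction"] = float(floor_fraction)
    meta["sd_floor"] = float(floor)
    return ReferenceDatabase(BrainVolume(grid, mean), BrainVolume(grid, sd),
                             len(volumes), mask, meta)


def save_reference(db, path, dtype="float64"):
    """Write mean.nii.gz / stddev.nii.gz / mask.nii.gz / meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    save_nifti(db.mean, path / "mean.nii.gz", dtype=dtype)
    save_nifti(db.stddev, path / "stddev.nii.gz", dtype=dtype)
    db.mask.to_nifti(path / "mask.nii.gz")
    meta = dict(db.meta)
    meta["grid"] = {"shape": db.grid.shape,
                    "voxel_size_mm": db.grid.voxel_size_mm,
                    "space": db.grid.space,
                    "origin_voxel": db.grid.origin_voxel}
    save_json(meta, path / "meta.json")


def load_reference(path):
    path = Path(path)
    for fname in ("mean.nii.gz", "stddev.nii.gz", "mask.nii.gz", "meta.json"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"reference database is missing {fname}")
    meta = load_json(path / "meta.json")
    mean = load_nifti(path / "mean.nii.gz")
    sd = load_nifti(path / "stddev.nii.gz")
    mask = BrainMask(mean.grid, load_nifti(path / "mask.nii.gz").data > 0.5)
    g = meta.get("grid", {})
    if g and (tuple(g["shape"]) != mean.grid.shape
              or tuple(g["voxel_size_mm"]) != mean.grid.voxel_size_mm):
        raise GridError("meta.json grid does not match the stored volumes")
    meta.pop("grid", None)
    return ReferenceDatabase(mean, sd, int(meta["n"]), mask, meta)
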