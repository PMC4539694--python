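"""Voxel-wise statistics: z-maps, single-subject t-maps, group tests.

Sign convention: a *positive* statistic means hypometabolism, i.e. the
patient (or second group) lies *below* the reference, because the maps
are computed as (reference - patient) / spread.  Hypermetabolism maps
are the negation.

The z-score map is the direct database comparison

    z(v) = (mean(v) - patient(v)) / stddev(v),

optionally clipped at a display cap (the clinical default caps the peak
z-score at 7.9).  The single-subject t-map treats the patient as a
second "group" of size one against the n controls with only the control
variance contributing:

    t(v) = (mean(v) - patient(v)) / (sd(v) * sqrt(1 + 1/n)),  df = n - 1,

and t-maps are converted to z-maps by exact one-sided tail-probability
matching, Phi^{-1}(F_t(t; df)), evaluated in log-tail space so that very
large deviates stay finite instead of being truncated by a tail
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special, stats

from .grid import BrainMask, BrainVolume, GridError, VolumeGrid

DEFAULT_Z_CAP = 7.9


class MetaMismatchError(ValueError):
    """Patient preprocessing does not match the reference database."""


class DegenerateDataError(ValueError):
    """All-zero variance input where a variance is required."""


@dataclass
class StatMap:
    """A z- or t-valued statistical volume (positive = hypometabolism)."""

    values: np.ndarray
    kind: str                      # "z" or "t"
    grid: VolumeGrid
    mask: BrainMask
    df: Optional[int] = None
    sign_convention: str = "positive = hypometabolism"

    def __post_init__(self):
        if self.kind not in ("z", "t"):
            raise ValueError(f"kind must be 'z' or 't', got {self.kind!r}")
        if self.kind == "t" and (self.df is None or self.df < 1):
            raise ValueError("t-maps require df >= 1")
        if self.kind == "z" and self.df is not None:
            raise ValueError("z-maps carry no df")
        values = np.asarray(self.values, dtype=float)
        if values.shape != tuple(self.grid.shape):
            raise GridError("stat map shape does not match grid")
        if self.mask.grid != self.grid:
            raise GridError("stat map mask is on a different grid")
        inside = values[self.mask.data]
        if not np.all(np.isfinite(inside)):
            raise ValueError("non-finite statistic inside the mask")
        self.values = np.where(self.mask.data, values, 0.0)

    def volume(self):
        return BrainVolume(self.grid, self.values)

    def max_in_mask(self):
        return float(self.values[self.mask.data].max())

    def negated(self):
        """Flip the sign convention (hypometabolism <-> hypermetabolism)."""
        out = StatMap(-self.values, self.kind, self.grid, self.mask, self.df)
        out.sign_convention = "positive = hypermetabolism" \
            if self.sign_convention.endswith("hypometabolism") \
            else "positive = hypometabolism"
        return out


def _check_meta(db, patient_meta):
    if patient_meta is None:
        return
    relevant = ("fwhm_mm", "scaling", "space", "target_value")
    for key in relevant:
        if key in db.meta and key in patient_meta \
                and db.meta[key] != patient_meta[key]:
            raise MetaMismatchError(
                f"patient preprocessing {key}={patient_meta[key]!r} differs "
                f"from database {key}={db.meta[key]!r}")


def zscore_map(patient, db, cap=DEFAULT_Z_CAP, patient_meta=None):
    """Direct database z-score map of one patient.

    ``cap`` clips the map (in both directions) at the given magnitude;
    the default mirrors the clinical display cap of 7.9.  Pass
    ``cap=None`` for an uncapped map.
    """
    if patient.grid != db.grid:
        raise GridError("patient volume is not on the database grid")
    _check_meta(db, patient_meta)
    if cap is not None and cap <= 0:
        raise ValueError("cap must be positive")
    z = (db.mean.data - patient.data) / db.stddev.data
    if cap is not None:
        z = np.clip(z, -cap, cap)
    return StatMap(z, "z", db.grid, db.mask)


def single_subject_tmap(patient, cohort_volumes, mask, cohort_meta=None,
                        patient_meta=None):
    """Two-sample t model with a single patient against n controls.

    Only the control variance enters; ``df = n - 1``.
    """
    n = len(cohort_volumes)
    if n < 2:
        raise ValueError("need at least 2 control volumes")
    grid = cohort_volumes[0].grid
    for v in cohort_volumes[1:]:
        if v.grid != grid:
            raise GridError("control volumes are on different grids")
    if patient.grid != grid or mask.grid != grid:
        raise GridError("patient/mask grid does not match the controls")
    if cohort_meta is not None and patient_meta is not None:
        db_like = type("M", (), {"meta": cohort_meta})
        _check_meta(db_like, patient_meta)
    stack = np.stack([v.data for v in cohort_volumes])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    sd = np.maximum(sd, np.finfo(float).tiny)
    t = (mean - patient.data) / (sd * np.sqrt(1.0 + 1.0 / n))
    return StatMap(t, "t", grid, mask, df=n - 1)


def t_to_z(t, df):
    """Exact tail-matching t -> z transformation.

    Maps a t-deviate to the standard-normal deviate with the same
    one-sided tail probability, computed in log-tail space so that
    extreme deviates (|t| up to ~50, df up to ~100) stay finite.  Odd in
    t and strictly increasing.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    sign = np.sign(t)
    log_sf = stats.t.logsf(np.abs(t), df)      # log upper-tail probability
    z = -special.ndtri_exp(log_sf)             # z with same upper tail
    out = sign * z
    if out.ndim == 0:
        return float(out)
    return out


def tmap_to_zmap(tmap):
    """Element-wise exact t -> z conversion of a t-map."""
    if tmap.kind != "t":
        raise ValueError("tmap_to_zmap expects a t-map")
    z = np.zeros_like(tmap.values)
    m = tmap.mask.data
    z[m] = t_to_z(tmap.values[m], tmap.df)
    out = StatMap(z, "z", tmap.grid, tmap.mask)
    out.sign_convention = tmap.sign_convention
    return out


def _stacked(volumes):
    grid = volumes[0].grid
    for v in volumes[1:]:
        if v.grid != grid:
            raise GridError("volumes are on different grids")
    return grid, np.stack([v.data for v in volumes])


def paired_ttest_map(volumes_a, volumes_b, mask, floor_fraction=1e-6):
    """Voxel-wise paired t-test on per-subject differences (df = n - 1).

    The within-pair SD is floored at ``floor_fraction`` of its in-mask
    average; if the differences have zero variance *everywhere* the input
    is degenerate and an error is raised.
    """
    if len(volumes_a) != len(volumes_b):
        raise ValueError("paired lists must have equal length")
    n = len(volumes_a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    grid, a = _stacked(volumes_a)
    grid_b, b = _stacked(volumes_b)
    if grid_b != grid or mask.grid != grid:
        raise GridError("paired volumes/mask are on different grids")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    in_mask_sd = float(sd[mask.data].mean())
    if in_mask_sd == 0:
        raise DegenerateDataError("zero within-pair variance everywhere")
    sd = np.maximum(sd, floor_fraction * in_mask_sd)
    t = mean / (sd / np.sqrt(n))
    return StatMap(t, "t", grid, mask, df=n - 1)


def group_two_sample_tmap(group_a, group_b, mask, floor_fraction=1e-6):
    """Pooled-variance two-sample t-map, positive where group B is lower.

    ``df = n_a + n_b - 2``.  Group A is the reference/control group and
    group B the patients, so hypometabolism in B is positive.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 subjects")
    grid, a = _stacked(group_a)
    grid_b, b = _stacked(group_b)
    if grid_b != grid or mask.grid != grid:
        raise GridError("groups/mask are on different grids")
    na, nb = len(group_a), len(group_b)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    in_mask_sp = float(sp[mask.data].mean())
    if in_mask_sp == 0:
        raise DegenerateDataError("zero pooled variance everywhere")
    sp = np.maximum(sp, floor_fraction * in_mask_sp)
    t = (a.mean(axis=0) - b.mean(axis=0)) / (sp * np.sqrt(1.0 / na + 1.0 / nb))
    return StatMap(t, "t", grid, mask, df=na + nb - 2)


def stat_threshold(kind, df, alpha, correction, n_comparisons):
    """One-sided critical value for the requested correction."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    alpha_eff = alpha / n_comparisons if correction == "bonferroni" else alpha
    if kind == "z":
        return float(stats.norm.isf(alpha_eff))
    return float(stats.t.isf(alpha_eff, df))


def threshold_map(statmap, alpha, correction="none"):
    """Mask of voxels with one-sided p < alpha (optionally Bonferroni).

    Bonferroni divides alpha by the number of in-mask voxels.  The
    returned object carries ``data`` (possibly empty) on the map's grid;
    it is a plain boolean array wrapper rather than a BrainMask because a
    thresholded map may legitimately be empty.
    """
    crit = stat_threshold(statmap.kind, statmap.df, alpha, correction,
                          statmap.mask.n_true)
    sel = (statmap.values > crit) & statmap.mask.data
    return ThresholdResult(statmap.grid, sel, crit, alpha, correction)


@dataclass
class ThresholdResult:
    grid: VolumeGrid
    data: np.ndarray
    critical_value: float
    alpha: float
    correction: str

    @property
    def n_voxels(self):
        return int(self.data.sum())
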