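"""Cluster extraction, peak localization, classification and concordance.

A statistical map is reduced to the quantities used for evaluation:
connected suprathreshold components (strict ``value > threshold``) under
6-, 18- or 26-connectivity, their sizes, the global peak value and its
world position, a positive/negative scan classification (any cluster
larger than a size cutoff at the z > 3 threshold), Dice/overlap
concordance between thresholded maps, and Wilcoxon signed-rank
comparison of per-subject cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .grid import GridError, VolumeGrid

DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_SIZE_THRESHOLD = 250
DEFAULT_CONNECTIVITY = 26

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Cluster:
    voxel_indices: np.ndarray     # (k, 3) integer indices, lexicographically sorted
    size_voxels: int
    peak_value: float
    peak_voxel: tuple
    peak_mm: tuple
    region_label: Optional[str] = None


@dataclass
class ClusterReport:
    clusters: list                # sorted by size descending
    threshold: float
    connectivity: int
    grid: VolumeGrid

    @property
    def total_size(self):
        return int(sum(c.size_voxels for c in self.clusters))

    @property
    def n_clusters(self):
        return len(self.clusters)

    @property
    def max_cluster_size(self):
        return max((c.size_voxels for c in self.clusters), default=0)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "size_voxels": c.size_voxels,
            "peak_value": c.peak_value,
            "peak_x_mm": c.peak_mm[0],
            "peak_y_mm": c.peak_mm[1],
            "peak_z_mm": c.peak_mm[2],
            "region": c.region_label,
        } for c in self.clusters])


def extract_clusters(statmap, threshold=DEFAULT_Z_THRESHOLD,
                     connectivity=DEFAULT_CONNECTIVITY):
    """Connected components of {v : value(v) > threshold} (strict).

    Peaks within each cluster break ties by the lexicographically
    smallest voxel index, so reports are deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    supra = statmap.values > threshold
    labeled, n = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)   # argwhere is lexicographically sorted
        vals = statmap.values[tuple(idx.T)]
        peak_val = float(vals.max())
        peak_voxel = tuple(int(i) for i in idx[np.argmax(vals)])
        peak_mm = tuple(float(v) for v in statmap.grid.voxel_to_world(peak_voxel))
        clusters.append(Cluster(idx, int(idx.shape[0]), peak_val,
                                peak_voxel, peak_mm))
    clusters.sort(key=lambda c: (-c.size_voxels, c.peak_voxel))
    return ClusterReport(clusters, float(threshold), connectivity, statmap.grid)


def peak_info(report):
    """Global peak (max value, world mm position) over all clusters."""
    if not report.clusters:
        raise ValueError("report has no clusters")
    best = None
    for c in report.clusters:
        if best is None or c.peak_value > best.peak_value or (
                c.peak_value == best.peak_value
                and c.peak_voxel < best.peak_voxel):
            best = c
    return best.peak_value, best.peak_mm


def classify_scan(report, z_threshold=DEFAULT_Z_THRESHOLD,
                  size_threshold=DEFAULT_SIZE_THRESHOLD):
    """'positive' iff any single cluster exceeds ``size_threshold`` voxels.

    Both cutoffs are strict (z > 3, size > 250 by default).  The report
    must have been extracted at the same z threshold.
    """
    if report.threshold != z_threshold:
        raise ValueError(
            f"report was thresholded at {report.threshold}, not {z_threshold}")
    positive = any(c.size_voxels > size_threshold for c in report.clusters)
    return "positive" if positive else "negative"


def overlap_stats(*masks, grid=None):
    """Common-cluster size and per-mask overlap fractions (plus Dice).

    Accepts two or more boolean arrays (or objects with ``.data``).
    ``fraction_k = |intersection| / |mask_k|``; Dice is reported for the
    two-mask case.
    """
    if len(masks) < 2:
        raise ValueError("need at least two masks")
    arrays = []
    for m in masks:
        a = getattr(m, "data", m)
        arrays.append(np.asarray(a, dtype=bool))
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise GridError("masks have different shapes")
    common = arrays[0].copy()
    for a in arrays[1:]:
        common &= a
    n_common = int(common.sum())
    sizes = [int(a.sum()) for a in arrays]
    fractions = [n_common / s if s > 0 else 0.0 for s in sizes]
    out = {"common_size": n_common,
           "sizes": sizes,
           "fractions": fractions}
    if len(arrays) == 2:
        denom = sizes[0] + sizes[1]
        out["dice"] = 2.0 * n_common / denom if denom > 0 else 0.0
    return out


def compare_cluster_sizes(sizes_a, sizes_b, paired=True):
    """Two-sided Wilcoxon signed-rank test between paired cluster sizes.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 nonzero pairs.  All-zero differences are degenerate.
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if not paired:
        raise ValueError("only the paired comparison is supported")
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    nonzero = np.count_nonzero(d)
    if nonzero == 0:
        raise ValueError("all differences are zero; Wilcoxon test is degenerate")
    method = "exact" if nonzero <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.statistic), float(res.pvalue)


def label_peak(peak_mm, atlas, labels=None):
    """Region name containing a world point, or 'outside'.

    ``atlas`` is an integer-valued label volume; ``labels`` maps label
    values to names (defaults to the phantom atlas names).
    """
    if labels is None:
        from .phantom import ATLAS_LABELS
        labels = ATLAS_LABELS
    vox = np.round(atlas.grid.world_to_voxel(peak_mm)).astype(int)
    if np.any(vox < 0) or np.any(vox >= np.asarray(atlas.grid.shape)):
        return "outside"
    value = int(round(atlas.data[tuple(vox)]))
    return labels.get(value, "outside")
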