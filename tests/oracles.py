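"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain Python loops and set
arithmetic (no vectorized shortcuts shared with the package), so that
agreement with the package is meaningful.
"""

import math
from itertools import product

import numpy as np
from scipy import integrate, stats


# ---------------------------------------------------------------------------
# Voxel-wise statistics
# ---------------------------------------------------------------------------

def zscore_loop(mean, sd, patient, mask, cap=None):
    """Per-voxel (mean - patient) / sd with optional symmetric cap."""
    out = np.zeros(mean.shape)
    for i in range(mean.shape[0]):
        for j in range(mean.shape[1]):
            for k in range(mean.shape[2]):
                if not mask[i, j, k]:
                    continue
                z = (mean[i, j, k] - patient[i, j, k]) / sd[i, j, k]
                if cap is not None:
                    z = max(-cap, min(cap, z))
                out[i, j, k] = z
    return out


def single_subject_t_loop(patient, controls, mask):
    """t = (mean - patient) / (sd * sqrt(1 + 1/n)), df = n - 1."""
    n = len(controls)
    out = np.zeros(patient.shape)
    for i in range(patient.shape[0]):
        for j in range(patient.shape[1]):
            for k in range(patient.shape[2]):
                if not mask[i, j, k]:
                    continue
                vals = [c[i, j, k] for c in controls]
                m = sum(vals) / n
                var = sum((v - m) ** 2 for v in vals) / (n - 1)
                sd = max(math.sqrt(var), np.finfo(float).tiny)
                out[i, j, k] = (m - patient[i, j, k]) / (sd * math.sqrt(1 + 1 / n))
    return out


def paired_t_loop(group_a, group_b, mask, floor_fraction=1e-6):
    """Paired t on per-subject differences with the in-mask SD floor."""
    n = len(group_a)
    shape = group_a[0].shape
    sd_img = np.zeros(shape)
    mean_img = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                d = [a[i, j, k] - b[i, j, k] for a, b in zip(group_a, group_b)]
                m = sum(d) / n
                var = sum((v - m) ** 2 for v in d) / (n - 1)
                mean_img[i, j, k] = m
                sd_img[i, j, k] = math.sqrt(var)
    in_mask = [sd_img[i, j, k]
               for i, j, k in product(*map(range, shape)) if mask[i, j, k]]
    floor = floor_fraction * (sum(in_mask) / len(in_mask))
    out = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not mask[i, j, k]:
                    continue
                sd = max(sd_img[i, j, k], floor)
                out[i, j, k] = mean_img[i, j, k] / (sd / math.sqrt(n))
    return out


def two_sample_t_loop(group_a, group_b, mask, floor_fraction=1e-6):
    """Pooled-variance two-sample t (positive where B is lower)."""
    na, nb = len(group_a), len(group_b)
    shape = group_a[0].shape
    sp_img = np.zeros(shape)
    num_img = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                va = [a[i, j, k] for a in group_a]
                vb = [b[i, j, k] for b in group_b]
                ma = sum(va) / na
                mb = sum(vb) / nb
                sa = sum((v - ma) ** 2 for v in va) / (na - 1)
                sb = sum((v - mb) ** 2 for v in vb) / (nb - 1)
                sp_img[i, j, k] = math.sqrt(
                    ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2))
                num_img[i, j, k] = ma - mb
    in_mask = [sp_img[i, j, k]
               for i, j, k in product(*map(range, shape)) if mask[i, j, k]]
    floor = floor_fraction * (sum(in_mask) / len(in_mask))
    out = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not mask[i, j, k]:
                    continue
                sp = max(sp_img[i, j, k], floor)
                out[i, j, k] = num_img[i, j, k] / (sp * math.sqrt(1 / na + 1 / nb))
    return out


def t_to_z_quadrature(t, df):
    """Tail-matching t -> z via numeric integration of the t density."""
    if t == 0:
        return 0.0
    sign = 1.0 if t > 0 else -1.0
    p, _err = integrate.quad(lambda x: stats.t.pdf(x, df), abs(t), np.inf,
                             limit=200)
    return float(sign * stats.norm.isf(p))


# ---------------------------------------------------------------------------
# Clusters / overlap
# ---------------------------------------------------------------------------

_NEIGHBOURS = {
    6: [(di, dj, dk) for di, dj, dk in product((-1, 0, 1), repeat=3)
        if abs(di) + abs(dj) + abs(dk) == 1],
    18: [(di, dj, dk) for di, dj, dk in product((-1, 0, 1), repeat=3)
         if 0 < abs(di) + abs(dj) + abs(dk) <= 2],
    26: [(di, dj, dk) for di, dj, dk in product((-1, 0, 1), repeat=3)
         if (di, dj, dk) != (0, 0, 0)],
}


def flood_fill_clusters(binary, connectivity):
    """Connected components of a boolean array as a list of frozensets."""
    binary = np.asarray(binary, dtype=bool)
    remaining = {tuple(idx) for idx in np.argwhere(binary)}
    offsets = _NEIGHBOURS[connectivity]
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(frozenset(comp))
    return components


def overlap_sets(*masks):
    """Set-arithmetic version of overlap_stats."""
    sets = [{tuple(idx) for idx in np.argwhere(np.asarray(m, dtype=bool))}
            for m in masks]
    common = set.intersection(*sets)
    sizes = [len(s) for s in sets]
    fractions = [len(common) / s if s else 0.0 for s in sizes]
    out = {"common_size": len(common), "sizes": sizes, "fractions": fractions}
    if len(sets) == 2:
        denom = sizes[0] + sizes[1]
        out["dice"] = 2 * len(common) / denom if denom else 0.0
    return out


def wilcoxon_exact_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    ``diffs`` must be nonzero and tie-free in absolute value.
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = {}
    for r, x in enumerate(sorted(d, key=abs), start=1):
        ranks[abs(x)] = r
    w_plus = sum(ranks[abs(x)] for x in d if x > 0)
    total = n * (n + 1) // 2
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in product((0, 1), repeat=n):
        wp = sum(ranks[abs(d[i])] for i in range(n) if signs[i])
        if min(wp, total - wp) <= w_obs:
            count += 1
    return count / 2 ** n
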