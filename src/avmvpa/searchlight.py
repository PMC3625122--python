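"""Whole-volume searchlight decoding and permutation cluster inference.

A sphere of integer voxel offsets is centred on every grey-matter voxel;
the local patterns are decoded with the same mean-correct + one-against-one
jackknife procedure as the ROI analysis and the fold-mean accuracy is
written back to the seed voxel.  Group inference on accuracy-contrast maps
uses a one-sample t map thresholded at an uncorrected cluster-forming p,
with family-wise error controlled by a max-cluster-size sign-flipping
permutation distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import mvpa

#: Searchlight radius in voxels.
DEFAULT_RADIUS = 4
#: Cluster-forming threshold (uncorrected, one-sample t).
CLUSTER_FORMING_P = 0.001


def sphere_offsets(radius: float) -> np.ndarray:
    """All integer (dx, dy, dz) with dx^2 + dy^2 + dz^2 <= radius^2.

    Includes the origin; closed under sign flips and axis permutations.
    Rows are sorted lexicographically for determinism.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    axis = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    keep = dx ** 2 + dy ** 2 + dz ** 2 <= radius ** 2
    offsets = np.column_stack([dx[keep], dy[keep], dz[keep]])
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0]))
    return offsets[order]


def searchlight_accuracy_maps(
    trial_maps,
    grey_mask: np.ndarray,
    offsets: np.ndarray | None = None,
    conditions=None,
    min_voxels: int = 2,
) -> dict[str, np.ndarray]:
    """Per-condition 3-D maps of local four-way decoding accuracy.

    Spheres are truncated at the mask border; seeds whose sphere holds
    fewer than ``min_voxels`` in-mask voxels stay NaN.  The result does
    not depend on the seed iteration order.
    """
    grey_mask = np.asarray(grey_mask, dtype=bool)
    if offsets is None:
        offsets = sphere_offsets(DEFAULT_RADIUS)
    patterns = mvpa.extract_patterns(trial_maps, grey_mask)
    conditions = conditions or patterns.condition_names

    shape = grey_mask.shape
    # map voxel coordinates -> column index of the grey pattern matrix
    col_index = np.full(shape, -1, dtype=int)
    coords = np.argwhere(grey_mask.transpose(2, 1, 0))[:, ::-1]  # x-fastest order
    col_index[tuple(coords.T)] = np.arange(len(coords))

    maps = {c: np.full(shape, np.nan) for c in conditions}
    for seed_xyz in coords:
        neigh = seed_xyz + offsets
        ok = np.all((neigh >= 0) & (neigh < shape), axis=1)
        cols = col_index[tuple(neigh[ok].T)]
        cols = cols[cols >= 0]
        if len(cols) < min_voxels:
            continue
        local = replace(patterns, vectors=patterns.vectors[:, cols])
        local = mvpa.mean_correct(local)
        for cond in conditions:
            acc, _ = mvpa.jackknife_accuracy(local, cond)
            maps[cond][tuple(seed_xyz)] = acc
    return maps


def accuracy_contrast(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Voxelwise A - B on voxels defined in both maps."""
    a, b = np.asarray(maps_a, float), np.asarray(maps_b, float)
    if a.shape != b.shape:
        raise ValueError("accuracy maps live on different grids")
    return a - b


def _connectivity_structure(connectivity: int) -> np.ndarray:
    table = {6: 1, 18: 2, 26: 3}
    if connectivity not in table:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, table[connectivity])


def _t_map(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def cluster_inference(
    subject_maps,
    cluster_forming_p: float = CLUSTER_FORMING_P,
    n_permutations: int = 1000,
    seed: int = 0,
    connectivity: int = 6,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sign-flip permutation cluster test on subject contrast maps.

    ``subject_maps``: (n_subjects, nx, ny, nz) array (or list of volumes).
    The observed one-sample t map is thresholded at
    t(p=cluster_forming_p, df=n-1); suprathreshold voxels are grouped into
    clusters (6-connected by default) and each cluster's FWE p is the
    proportion of sign-flip permutations whose maximum cluster size
    reaches the observed size.

    Returns a table with cluster id, size (voxels), 0-based peak
    coordinate, peak t and FWE p.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    shape = maps.shape[1:]
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: FWE p resolution is coarse")
    if mask is None:
        mask = np.all(np.isfinite(maps), axis=0)
    flat = maps[:, mask]                                 # (n, V)
    # canonical subject order: sort rows by content so the result is
    # invariant to the order subjects are passed in
    order = np.lexsort(flat.T[::-1])
    flat = flat[order]

    df = n - 1
    t_crit = stats.t.isf(cluster_forming_p, df)
    structure = _connectivity_structure(connectivity)

    def clusters_of(t_flat):
        vol = np.zeros(shape)
        vol[mask] = t_flat
        lab, n_lab = ndimage.label(vol > t_crit, structure=structure)
        return vol, lab, n_lab

    t_obs = _t_map(flat)
    vol_obs, lab_obs, n_obs = clusters_of(t_obs)
    sizes = ndimage.sum_labels(np.ones(shape), lab_obs, range(1, n_obs + 1))

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    # E[x], E[x^2] under sign flips: squares are invariant, so the
    # permuted variance comes from the permuted mean alone
    mean_sq = (flat ** 2).mean(axis=0)
    max_sizes = np.empty(n_permutations)
    for p in range(n_permutations):
        m = signs[p] @ flat / n
        var = (mean_sq - m ** 2) * n / df
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = m / np.sqrt(var / n)
        t_perm = np.where(var > 0, t_perm, 0.0)
        _, lab, n_lab = clusters_of(t_perm)
        if n_lab:
            max_sizes[p] = ndimage.sum_labels(np.ones(shape), lab, range(1, n_lab + 1)).max()
        else:
            max_sizes[p] = 0

    rows = []
    for k in range(n_obs):
        in_cluster = lab_obs == k + 1
        peak_flat = np.argmax(np.where(in_cluster, vol_obs, -np.inf))
        peak = np.unravel_index(peak_flat, shape)
        p_fwe = (1 + np.sum(max_sizes >= sizes[k])) / (n_permutations + 1)
        rows.append(
            {
                "cluster_id": k + 1,
                "size_voxels": int(sizes[k]),
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "peak_t": float(vol_obs[peak]),
                "p_fwe": float(p_fwe),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "size_voxels", "peak_x", "peak_y", "peak_z", "peak_t", "p_fwe"],
    )
    return table.sort_values("size_voxels", ascending=False, ignore_index=True)
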