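"""Pattern reliability, inter-stimulus similarity, amplitudes, and the
16 x 16 trial-type correlation matrix.

Reliability is the odd/even split-half correlation of a stimulus's mean
pattern (an inverse index of trial-to-trial pattern noise); similarity is
the correlation between mean patterns of different stimuli (an index of
class-centroid separation).  Correlations are Fisher z-transformed before
averaging so a condition's value is the mean z over stimuli (reliability)
or over the six stimulus pairs (similarity).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np

from .mvpa import PatternSet

#: Correlations are clipped to +/- (1 - CLIP_EPS) before atanh so that
#: noiseless (r = 1) inputs map to a large finite z instead of infinity.
CLIP_EPS = 1e-12


def fisher_z(r):
    """atanh transform of a correlation, clipped just inside +/-1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("correlation outside [-1, 1]")
    return np.arctanh(np.clip(r, -(1 - CLIP_EPS), 1 - CLIP_EPS))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return np.nan
    return float(np.clip(a @ b / denom, -1.0, 1.0))


def _odd_even_split(runs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # 1-based acquisition order defines parity, so run index 0 is "run 1",
    # i.e. odd
    uniq = np.unique(runs)
    odd = uniq[::2]
    even = uniq[1::2]
    return odd, even


def _stim_mean(patterns: PatternSet, condition, stimulus, runs=None) -> np.ndarray:
    keep = (patterns.conditions == condition) & (patterns.labels == stimulus)
    if runs is not None:
        keep &= np.isin(patterns.runs, runs)
    return patterns.vectors[keep].mean(axis=0)


def pattern_reliability(patterns: PatternSet, conditions=None) -> dict[str, float]:
    """Split-half pattern reliability (Fisher z) per condition.

    For each (condition, stimulus): average the patterns over odd and over
    even runs (1-based acquisition order), correlate the two means, Fisher
    z-transform; the condition value is the mean z over stimuli.  A
    stimulus with a zero-variance mean pattern is skipped with a warning.
    """
    odd, even = _odd_even_split(patterns.runs)
    if not len(odd) or not len(even):
        raise ValueError("need at least one odd and one even run")
    conditions = conditions or patterns.condition_names
    out = {}
    for cond in conditions:
        zs = []
        for stim in patterns.stimulus_ids:
            r = _pearson(
                _stim_mean(patterns, cond, stim, odd),
                _stim_mean(patterns, cond, stim, even),
            )
            if np.isnan(r):
                warnings.warn(
                    f"zero-variance mean pattern for condition {cond}, "
                    f"stimulus {stim}; skipped"
                )
                continue
            zs.append(fisher_z(r))
        out[cond] = float(np.mean(zs)) if zs else np.nan
    return out


def pattern_similarity(patterns: PatternSet, conditions=None) -> dict[str, float]:
    """Mean Fisher z over the six pairwise inter-stimulus correlations.

    Stimulus means are taken over all runs.  After mean correction across
    stimuli the pairwise correlations are negative in expectation (the
    four centred class means sum to zero).
    """
    stims = patterns.stimulus_ids
    if len(stims) < 2:
        raise ValueError("similarity needs at least two stimuli")
    conditions = conditions or patterns.condition_names
    out = {}
    for cond in conditions:
        means = {s: _stim_mean(patterns, cond, s) for s in stims}
        zs = []
        for a, b in combinations(stims, 2):
            r = _pearson(means[a], means[b])
            if np.isnan(r):
                warnings.warn(
                    f"zero-variance mean pattern in condition {cond}; pair "
                    f"({a},{b}) skipped"
                )
                continue
            zs.append(fisher_z(r))
        out[cond] = float(np.mean(zs)) if zs else np.nan
    return out


def full_correlation_matrix(
    patterns: PatternSet, conditions=None
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """16 x 16 correlation matrix over (stimulus x condition) trial types.

    Row/column order is stimulus-major, then condition.  Off-diagonal
    entries correlate the all-run mean patterns of two types (symmetric);
    diagonal entries are the odd/even split-half correlation within a
    type.
    """
    conditions = conditions or patterns.condition_names
    stims = patterns.stimulus_ids
    types = [(int(s), c) for s in stims for c in conditions]
    for stim, cond in types:
        if not np.any((patterns.conditions == cond) & (patterns.labels == stim)):
            raise ValueError(f"missing trial type (stimulus {stim}, {cond})")
    odd, even = _odd_even_split(patterns.runs)
    means = {tc: _stim_mean(patterns, tc[1], tc[0]) for tc in types}
    n = len(types)
    mat = np.empty((n, n))
    for i, ti in enumerate(types):
        for j, tj in enumerate(types):
            if i == j:
                mat[i, j] = _pearson(
                    _stim_mean(patterns, ti[1], ti[0], odd),
                    _stim_mean(patterns, ti[1], ti[0], even),
                )
            else:
                mat[i, j] = _pearson(means[ti], means[tj])
    return mat, types


def roi_mean_amplitude(trial_maps, roi_mask: np.ndarray, conditions=None) -> dict[str, float]:
    """Mean (non-mean-corrected) beta per condition within an ROI.

    Averages beta values over voxels, stimuli and runs, giving one scalar
    per condition — the univariate amplitude the multivariate effects are
    dissociated from.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    acc: dict[str, list] = {}
    for maps in trial_maps:
        for k, (stim, cond) in enumerate(maps.types):
            acc.setdefault(cond, []).append(maps.betas[k][roi_mask])
    conditions = conditions or list(acc)
    return {c: float(np.mean(acc[c])) for c in conditions}


def pattern_mean_amplitude(patterns: PatternSet, conditions=None) -> dict[str, float]:
    """Mean over voxels, stimuli and runs of raw (uncorrected) patterns."""
    conditions = conditions or patterns.condition_names
    return {
        c: float(patterns.vectors[patterns.conditions == c].mean())
        for c in conditions
    }


def matrix_to_text(mat: np.ndarray, types, path) -> None:
    """Write the correlation matrix as a diffable plain-text grid."""
    header = "\t".join(f"s{s}_{c}" for s, c in types)
    np.savetxt(path, mat, fmt="%.6f", delimiter="\t", header=header)
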