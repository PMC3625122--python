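"""Condition-specific four-way stimulus decoding from ROI patterns.

The four-way classifier is built from six pairwise linear support vector
machines (one per unordered stimulus pair) combined by one-against-one
voting, evaluated with a leave-one-run-out jackknife.  Patterns are mean
corrected across the four stimuli within each (run, condition) cell before
decoding, which centres each cell on zero without changing the geometry of
the class distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

#: SVM cost parameter; fixed, no kernel, no per-feature scaling.
SVM_C = 1.0


@dataclass
class PatternSet:
    """Trial-wise voxel vectors with stimulus / run / condition labels."""

    vectors: np.ndarray       # (n_trials, n_voxels)
    labels: np.ndarray        # stimulus index per row
    runs: np.ndarray          # run index per row
    conditions: np.ndarray    # condition label per row
    roi: str = ""

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels)
        self.runs = np.asarray(self.runs)
        self.conditions = np.asarray(self.conditions, dtype=object)
        n = len(self.vectors)
        if not (len(self.labels) == len(self.runs) == len(self.conditions) == n):
            raise ValueError("label/run/condition lengths must match vectors")

    @property
    def n_trials(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.vectors.shape[1]

    @property
    def run_ids(self) -> np.ndarray:
        return np.unique(self.runs)

    @property
    def condition_names(self) -> list[str]:
        seen = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def stimulus_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def select(self, condition=None, run=None) -> "PatternSet":
        keep = np.ones(self.n_trials, dtype=bool)
        if condition is not None:
            keep &= self.conditions == condition
        if run is not None:
            keep &= self.runs == run
        return replace(
            self,
            vectors=self.vectors[keep],
            labels=self.labels[keep],
            runs=self.runs[keep],
            conditions=self.conditions[keep],
        )

    def trial_vector(self, run, condition, stimulus) -> np.ndarray:
        """The single pattern for a (run, condition, stimulus) cell entry."""
        keep = (self.runs == run) & (self.conditions == condition) & (self.labels == stimulus)
        idx = np.flatnonzero(keep)
        if len(idx) != 1:
            raise KeyError(f"expected one trial for ({run}, {condition}, {stimulus})")
        return self.vectors[idx[0]]


def _flat_f(volume: np.ndarray) -> np.ndarray:
    """Flatten a 3-D volume in mask scan order (x varies fastest)."""
    return np.asarray(volume).ravel(order="F")


def extract_patterns(trial_maps, roi_mask: np.ndarray, use: str = "t") -> PatternSet:
    """Vectorise per-trial maps within an ROI mask.

    ``trial_maps`` is a sequence of per-run :class:`~avmvpa.glm.TrialMaps`.
    Rows are ordered run-major, then by the map order within a run
    (condition-major, stimulus within condition); columns follow the mask
    scan order with x varying fastest.  ``use`` picks ``"t"`` statistics
    (decoding, correlations) or ``"beta"`` maps (univariate amplitudes).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    mask_flat = _flat_f(roi_mask)
    rows, labels, runs, conds = [], [], [], []
    for maps in trial_maps:
        volumes = maps.tstats if use == "t" else maps.betas
        for k, (stim, cond) in enumerate(maps.types):
            rows.append(_flat_f(volumes[k])[mask_flat])
            labels.append(stim)
            runs.append(maps.run)
            conds.append(cond)
    return PatternSet(
        vectors=np.asarray(rows),
        labels=np.asarray(labels),
        runs=np.asarray(runs),
        conditions=np.asarray(conds, dtype=object),
    )


def mean_correct(patterns: PatternSet, pooled: bool = False) -> PatternSet:
    """Subtract the voxelwise mean across stimuli within each condition.

    With ``pooled=False`` (default) the mean is taken within each
    (run, condition) cell, so each cell's four stimulus rows sum to zero
    per voxel.  ``pooled=True`` instead centres across all runs of a
    condition at once.  Pairwise distances within a cell are unchanged
    (pure translation), so classification is unaffected.
    """
    vec = patterns.vectors.copy()
    if pooled:
        groups = [(None, c) for c in patterns.condition_names]
    else:
        groups = [
            (r, c) for r in patterns.run_ids for c in patterns.condition_names
        ]
    n_stim = len(patterns.stimulus_ids)
    for run, cond in groups:
        keep = patterns.conditions == cond
        if run is not None:
            keep &= patterns.runs == run
            if keep.sum() != n_stim or len(set(patterns.labels[keep])) != n_stim:
                raise ValueError(
                    f"incomplete (run={run}, condition={cond}) cell: "
                    f"expected one trial per stimulus"
                )
        vec[keep] -= vec[keep].mean(axis=0)
    return replace(patterns, vectors=vec)


def _fit_pair(train_x, train_y, i, j, test_x):
    """Signed decision values for one stimulus pair; positive favours j."""
    keep = (train_y == i) | (train_y == j)
    x, y = train_x[keep], train_y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError(f"training data missing stimulus {i} or {j}")
    clf = SVC(kernel="linear", C=SVM_C)
    try:
        clf.fit(x, y)
        d = np.atleast_1d(clf.decision_function(test_x))
        # sklearn orders classes ascending, so positive margins favour j
        if clf.classes_[1] == i:  # pragma: no cover - classes_ is sorted
            d = -d
    except ValueError:
        # degenerate training (e.g. identical rows across classes) - the
        # contract is to still return labels, never crash
        d = np.zeros(len(test_x))
    return d


def ovo_classify(train: PatternSet, test) -> np.ndarray:
    """Predict stimulus labels by one-against-one voting over six lSVMs.

    Each pairwise SVM casts one vote per test pattern; the prediction is
    the stimulus with most votes.  Ties are broken by the largest sum of
    signed decision values among the tied classes, then by the lowest
    stimulus index.
    """
    test_x = test.vectors if isinstance(test, PatternSet) else np.asarray(test)
    classes = np.unique(train.labels)
    if train.vectors.shape[1] != test_x.shape[1]:
        raise ValueError("train/test voxel counts differ")
    n = len(test_x)
    votes = np.zeros((n, len(classes)))
    dsum = np.zeros((n, len(classes)))
    index = {c: k for k, c in enumerate(classes)}
    for i, j in combinations(classes, 2):
        d = _fit_pair(train.vectors, train.labels, i, j, test_x)
        ki, kj = index[i], index[j]
        votes[d > 0, kj] += 1
        votes[d <= 0, ki] += 1
        dsum[:, ki] -= d
        dsum[:, kj] += d
    pred = np.empty(n, dtype=classes.dtype)
    for row in range(n):
        best = votes[row] == votes[row].max()
        if best.sum() > 1:
            tied_scores = np.where(best, dsum[row], -np.inf)
            best = tied_scores == tied_scores.max()
        pred[row] = classes[np.flatnonzero(best)[0]]
    return pred


def jackknife_accuracy(patterns: PatternSet, condition: str) -> tuple[float, np.ndarray]:
    """Leave-one-run-out decoding accuracy for one condition.

    Each fold trains the four-way classifier on the condition's patterns
    from all runs but one and tests on the held-out run's four patterns.
    Returns the unweighted fold-mean accuracy and the per-fold accuracies.
    """
    sub = patterns.select(condition=condition)
    run_ids = sub.run_ids
    if len(run_ids) < 2:
        raise ValueError("jackknife needs at least two runs")
    fold_acc = np.empty(len(run_ids))
    for k, held in enumerate(run_ids):
        train = sub.select(run=None)
        keep = sub.runs != held
        train = replace(
            sub,
            vectors=sub.vectors[keep],
            labels=sub.labels[keep],
            runs=sub.runs[keep],
            conditions=sub.conditions[keep],
        )
        test = sub.select(run=held)
        pred = ovo_classify(train, test)
        fold_acc[k] = float(np.mean(pred == test.labels))
    return float(fold_acc.mean()), fold_acc


def decode_all(patterns: PatternSet, conditions=None, mean_corrected: bool = False):
    """Fold-mean accuracy per condition (mean-correcting first by default)."""
    pats = patterns if mean_corrected else mean_correct(patterns)
    conditions = conditions or pats.condition_names
    return {c: jackknife_accuracy(pats, c)[0] for c in conditions}
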