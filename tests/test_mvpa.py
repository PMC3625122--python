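"""Decoding contracts: pattern extraction order, mean correction,
one-against-one voting (with an exhaustive vote-table oracle), jackknife
folds, permutation null, and agreement with an independent SVM stack."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.svm import SVC

from avmvpa import glm, mvpa, synth
from conftest import make_subject_patterns


def _toy_maps(volumes_by_run, types):
    """Fabricate TrialMaps from explicit (n_types, x, y, z) arrays."""
    out = []
    for run, vols in enumerate(volumes_by_run):
        vols = np.asarray(vols, dtype=float)
        out.append(
            glm.TrialMaps(
                betas=vols, tstats=vols.copy(), types=list(types),
                resid_var=np.ones(vols.shape[1:]), df=1, run=run,
            )
        )
    return out


class TestExtractPatterns:
    def test_shape_counting(self):
        """10-voxel mask, 18 runs, one condition -> 72 x 10 matrix."""
        rng = np.random.default_rng(0)
        types = [(s, "V") for s in range(4)]
        maps = _toy_maps([rng.standard_normal((4, 5, 2, 1)) for _ in range(18)], types)
        mask = np.ones((5, 2, 1), dtype=bool)
        pats = mvpa.extract_patterns(maps, mask)
        assert pats.vectors.shape == (72, 10)
        assert list(pats.runs[:4]) == [0, 0, 0, 0]

    def test_single_voxel_mask_is_identity(self):
        rng = np.random.default_rng(1)
        vols = rng.standard_normal((4, 3, 3, 2))
        maps = _toy_maps([vols], [(s, "V") for s in range(4)])
        mask = np.zeros((3, 3, 2), dtype=bool)
        mask[2, 1, 0] = True
        pats = mvpa.extract_patterns(maps, mask)
        np.testing.assert_array_equal(pats.vectors[:, 0], vols[:, 2, 1, 0])

    def test_voxel_order_x_fastest(self):
        """Columns follow mask scan order with x varying fastest."""
        shape = (3, 2, 2)
        vol = np.zeros(shape)
        for x in range(3):
            for y in range(2):
                for z in range(2):
                    vol[x, y, z] = x + 10 * y + 100 * z
        maps = _toy_maps([vol[None]], [(0, "V")])
        pats = mvpa.extract_patterns(maps, np.ones(shape, dtype=bool))
        expected = [x + 10 * y + 100 * z
                    for z in range(2) for y in range(2) for x in range(3)]
        np.testing.assert_array_equal(pats.vectors[0], expected)

    def test_empty_mask_rejected(self):
        maps = _toy_maps([np.zeros((1, 2, 2, 2))], [(0, "V")])
        with pytest.raises(ValueError, match="empty"):
            mvpa.extract_patterns(maps, np.zeros((2, 2, 2), dtype=bool))


class TestMeanCorrect:
    def test_identical_rows_become_zero(self):
        vec = np.tile(np.arange(5.0), (4, 1))
        pats = mvpa.PatternSet(vec, np.arange(4), np.zeros(4, int), ["V"] * 4)
        out = mvpa.mean_correct(pats)
        np.testing.assert_allclose(out.vectors, 0.0)

    def test_cellwise_column_sums_zero(self, patterns):
        out = mvpa.mean_correct(patterns["V1"])
        for run in out.run_ids[:3]:
            for cond in synth.CONDITIONS:
                keep = (out.runs == run) & (out.conditions == cond)
                np.testing.assert_allclose(
                    out.vectors[keep].sum(axis=0), 0.0, atol=1e-12
                )

    def test_pairwise_distances_preserved(self, patterns):
        """Translation invariance: classification geometry unchanged."""
        raw = patterns["V2"]
        out = mvpa.mean_correct(raw)
        for run in (0, 5):
            keep = (raw.runs == run) & (raw.conditions == "V")
            a, b = raw.vectors[keep], out.vectors[keep]
            da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
            db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
            np.testing.assert_allclose(da, db, atol=1e-9)

    def test_incomplete_cell_rejected(self, patterns):
        broken = patterns["V1"].select(condition="V")
        broken = mvpa.PatternSet(
            broken.vectors[1:], broken.labels[1:], broken.runs[1:],
            broken.conditions[1:],
        )
        with pytest.raises(ValueError, match="incomplete"):
            mvpa.mean_correct(broken)


def _gaussian_clusters(rng, n_per_class, spread=0.3):
    centers = np.array([[4, 0], [0, 4], [-4, 0], [0, -4]], dtype=float)
    x = np.concatenate(
        [c + spread * rng.standard_normal((n_per_class, 2)) for c in centers]
    )
    y = np.repeat(np.arange(4), n_per_class)
    return x, y


class TestOvoClassify:
    def test_separable_clusters_perfect(self):
        rng = np.random.default_rng(3)
        xtr, ytr = _gaussian_clusters(rng, 20)
        xte, yte = _gaussian_clusters(rng, 5)
        train = mvpa.PatternSet(xtr, ytr, np.zeros(len(ytr), int), ["V"] * len(ytr))
        pred = mvpa.ovo_classify(train, xte)
        assert np.mean(pred == yte) == 1.0

    def test_pure_noise_accuracy_near_chance(self):
        rng = np.random.default_rng(4)
        hits, total = 0, 0
        for _ in range(150):
            xtr = rng.standard_normal((40, 10))
            ytr = np.repeat(np.arange(4), 10)
            xte = rng.standard_normal((8, 10))
            yte = np.repeat(np.arange(4), 2)
            train = mvpa.PatternSet(xtr, ytr, np.zeros(40, int), ["V"] * 40)
            hits += np.sum(mvpa.ovo_classify(train, xte) == yte)
            total += 8
        p = hits / total
        assert abs(p - 0.25) < 3 * np.sqrt(0.25 * 0.75 / total)

    def test_vote_table_matches_exhaustive_oracle(self):
        """Predictions equal an independent enumeration of all six pairwise
        outcomes with the documented tie-break (votes -> summed decision
        values -> lowest index), on a grid dense enough to include ties."""
        rng = np.random.default_rng(5)
        # rock-paper-scissors geometry among classes 0-2, class 3 remote
        xtr = np.concatenate([
            [[2.0, 0.1]] * 5, [[-1.0, 1.9]] * 5, [[-1.0, -1.7]] * 5, [[8.0, 8.0]] * 5,
        ]) + 0.05 * rng.standard_normal((20, 2))
        ytr = np.repeat(np.arange(4), 5)
        grid = np.array([[x, y] for x in np.linspace(-2, 3, 21)
                         for y in np.linspace(-2, 3, 21)])
        # the three pairwise boundaries among classes 0-2 bound the classic
        # one-vs-one ambiguity triangle; its centroid is a guaranteed vote
        # tie, which the oracle must resolve by summed decision values
        lines = {}
        for i, j in combinations(range(3), 2):
            keep = (ytr == i) | (ytr == j)
            clf = SVC(kernel="linear", C=1.0).fit(xtr[keep], ytr[keep])
            lines[(i, j)] = (clf.coef_[0], clf.intercept_[0])
        corners = []
        for (la, lb) in combinations(lines.values(), 2):
            a = np.vstack([la[0], lb[0]])
            b = -np.array([la[1], lb[1]])
            corners.append(np.linalg.solve(a, b))
        grid = np.vstack([grid, np.mean(corners, axis=0)])

        votes = np.zeros((len(grid), 4))
        dsum = np.zeros((len(grid), 4))
        for i, j in combinations(range(4), 2):
            keep = (ytr == i) | (ytr == j)
            clf = SVC(kernel="linear", C=1.0).fit(xtr[keep], ytr[keep])
            d = clf.decision_function(grid)
            votes[d > 0, j] += 1
            votes[d <= 0, i] += 1
            dsum[:, i] -= d
            dsum[:, j] += d
        expected = np.empty(len(grid), dtype=int)
        n_ties = 0
        for k in range(len(grid)):
            best = np.flatnonzero(votes[k] == votes[k].max())
            if len(best) > 1:
                n_ties += 1
                scores = dsum[k][best]
                best = best[scores == scores.max()]
            expected[k] = best[0]

        train = mvpa.PatternSet(xtr, ytr, np.zeros(20, int), ["V"] * 20)
        pred = mvpa.ovo_classify(train, grid)
        np.testing.assert_array_equal(pred, expected)
        assert n_ties > 0  # the grid really exercises the tie-break

    def test_degenerate_training_still_returns_labels(self):
        xtr = np.ones((8, 3))
        ytr = np.repeat(np.arange(4), 2)
        train = mvpa.PatternSet(xtr, ytr, np.zeros(8, int), ["V"] * 8)
        pred = mvpa.ovo_classify(train, np.ones((2, 3)))
        assert pred.shape == (2,)
        assert set(pred) <= {0, 1, 2, 3}

    def test_instantiates_exactly_six_binary_svms(self, monkeypatch):
        fits = []
        orig = SVC.fit

        def counting_fit(self, X, y, **kw):
            fits.append(np.unique(y))
            return orig(self, X, y, **kw)

        monkeypatch.setattr(SVC, "fit", counting_fit)
        rng = np.random.default_rng(6)
        xtr, ytr = _gaussian_clusters(rng, 5)
        train = mvpa.PatternSet(xtr, ytr, np.zeros(len(ytr), int), ["V"] * len(ytr))
        mvpa.ovo_classify(train, xtr[:3])
        assert len(fits) == 6
        assert sorted(tuple(f) for f in fits) == [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)
        ]


class TestJackknife:
    def test_fold_arithmetic_18_runs(self):
        pats = make_subject_patterns(seed=10, roi_voxels=40, n_runs=18)
        corr = mvpa.mean_correct(pats)
        acc, folds = mvpa.jackknife_accuracy(corr, "V")
        assert len(folds) == 18
        assert acc == pytest.approx(folds.mean())
        # each fold tests 4 patterns, so fold accuracies are quarters
        assert np.all(np.isin(np.round(folds * 4), np.arange(5)))

    def test_noiseless_templates_decode_perfectly(self, small_geometry, design):
        truth = synth.default_ground_truth(
            small_geometry, 7, sigma=0.0, sigma_incongruent=0.0
        )
        pats = synth.generate_trial_patterns(truth, design, 8)["V1"]
        corr = mvpa.mean_correct(pats)
        acc, _ = mvpa.jackknife_accuracy(corr, "AV_congruent")
        assert acc == 1.0

    def test_fewer_than_two_runs_rejected(self):
        pats = make_subject_patterns(seed=11, roi_voxels=20, n_runs=18)
        one_run = pats.select(run=0)
        with pytest.raises(ValueError, match="two runs"):
            mvpa.jackknife_accuracy(one_run, "V")

    def test_label_permutation_null_centred_on_chance(self):
        """Shuffling stimulus labels within cells gives chance accuracy."""
        pats = make_subject_patterns(seed=12, roi_voxels=30, n_runs=18)
        sub = mvpa.mean_correct(pats).select(condition="V")
        rng = np.random.default_rng(13)
        accs = []
        for _ in range(60):
            labels = sub.labels.copy()
            for run in sub.run_ids:
                idx = np.flatnonzero(sub.runs == run)
                labels[idx] = labels[rng.permutation(idx)]
            shuffled = mvpa.PatternSet(sub.vectors, labels, sub.runs, sub.conditions)
            accs.append(mvpa.jackknife_accuracy(shuffled, "V")[0])
        n_trials = 60 * 18 * 4
        assert abs(np.mean(accs) - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n_trials) * 2

    def test_accuracy_monotone_in_pattern_noise(self):
        """Group-mean accuracy decreases over an increasing noise-SD grid."""
        sigmas = [0.3, 0.8, 1.6, 3.2]
        geom = synth.default_geometry(roi_voxels=60)
        means = []
        for s_i, sigma in enumerate(sigmas):
            accs = []
            for subj in range(12):
                pats = make_subject_patterns(
                    seed=500 + subj, sigma=sigma, sigma_incongruent=sigma,
                    geometry=geom, roi_voxels=60,
                )
                corr = mvpa.mean_correct(pats)
                accs.append(mvpa.jackknife_accuracy(corr, "V")[0])
            means.append(np.mean(accs))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_agreement_with_independent_svm_implementation(self):
        """Our six-SVM voting matches sklearn's built-in one-vs-one multiclass
        SVC to within 0.01 accuracy on the same split."""
        rng = np.random.default_rng(14)
        centers = rng.standard_normal((4, 30))
        def draw(n):
            y = np.repeat(np.arange(4), n)
            x = centers[y] + 1.5 * rng.standard_normal((4 * n, 30))
            return x, y
        xtr, ytr = draw(30)
        xte, yte = draw(125)
        train = mvpa.PatternSet(xtr, ytr, np.zeros(len(ytr), int), ["V"] * len(ytr))
        acc_ours = np.mean(mvpa.ovo_classify(train, xte) == yte)
        ref = SVC(kernel="linear", C=1.0, decision_function_shape="ovo").fit(xtr, ytr)
        acc_ref = np.mean(ref.predict(xte) == yte)
        assert abs(acc_ours - acc_ref) <= 0.01
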