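"""Identity model fitting, grouped CV tuning, voting, accuracy."""

import collections

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainprint import classify
from brainprint.classify import VotingScheme
from brainprint.features import BandScheme, FeatureSet, SegmentationScheme


def _toy_features(X, subjects, weeks=None, tasks=None, segments=None):
    n = len(subjects)
    meta = pd.DataFrame(
        {
            "subject": subjects,
            "pair": [(s + 1) // 2 for s in subjects],
            "week": weeks if weeks is not None else [1] * n,
            "task": tasks if tasks is not None else ["rce"] * n,
            "block": [1] * n,
            "segment": segments if segments is not None else list(range(n)),
        }
    )
    X = np.asarray(X, dtype=np.float32)
    return FeatureSet(
        X=X,
        meta=meta,
        mode="concatenated",
        bands=BandScheme(),
        channel_names=("FP1",),
        feature_channels=np.array(["FP1"] * X.shape[1]),
        feature_freqs=np.arange(X.shape[1], dtype=float),
        segmentation=SegmentationScheme(),
    )


def _separable_features(n_per=40, n_subjects=2, n_groups=20, seed=0):
    """Each subject occupies a disjoint region of feature space; samples
    come in recording-like groups (task label varies per group)."""
    rng = np.random.default_rng(seed)
    rows, subjects, tasks, segments = [], [], [], []
    for s in range(1, n_subjects + 1):
        center = np.zeros(4)
        center[(s - 1) % 4] = 10.0 * (1 if s <= 4 else -1)
        for g in range(n_groups):
            for seg in range(n_per // n_groups):
                rows.append(center + 0.1 * rng.standard_normal(4))
                subjects.append(s)
                tasks.append(f"t{g}")
                segments.append(seg)
    return _toy_features(rows, subjects, tasks=tasks, segments=segments)


class TestTuneC:
    def test_single_value_grid(self):
        fs = _separable_features()
        assert classify.tune_C(fs, grid=[1.0], n_folds=5) == 1.0

    def test_separable_data_prefers_smallest_C(self):
        fs = _separable_features()
        best, scores = classify.tune_C(
            fs, grid=[0.01, 1.0, 100.0], n_folds=5, return_scores=True
        )
        assert all(v == 1.0 for v in scores.values())
        assert best == 0.01

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            classify.tune_C(_separable_features(), grid=[])

    def test_too_few_groups_rejected(self):
        fs = _separable_features(n_groups=4)
        with pytest.raises(ValueError, match="folds"):
            classify.tune_C(fs, grid=[1.0], n_folds=10)

    def test_groups_assigned_whole_to_folds(self):
        groups = np.repeat(np.arange(37), 13)
        fold = classify.assign_group_folds(groups, n_folds=10, seed=3)
        table = pd.DataFrame({"g": groups, "f": fold})
        assert (table.groupby("g")["f"].nunique() == 1).all()
        assert set(fold) == set(range(10))


class TestFit:
    def test_disjoint_supports_give_opposite_weights(self):
        X = [[1.0, 0.0]] * 20 + [[0.0, 1.0]] * 20
        fs = _toy_features(X, [1] * 20 + [2] * 20)
        model = classify.fit(fs, C=1.0)
        # feature 0 is evidence for subject 1, against subject 2
        assert model.coef[0, 0] > 0 > model.coef[1, 0]
        assert model.coef[0, 1] < 0 < model.coef[1, 1]

    def test_duplicated_training_set_gives_same_model(self):
        fs = _separable_features(seed=5)
        doubled = _toy_features(
            np.vstack([fs.X, fs.X]),
            list(fs.meta["subject"]) * 2,
        )
        m1 = classify.fit(fs, C=1e6)  # near-unregularized: loss scaling immaterial
        m2 = classify.fit(doubled, C=1e6)
        assert np.allclose(m1.coef, m2.coef, atol=1e-2, rtol=1e-2)

    def test_ridge_limit_shrinks_weights(self):
        fs = _separable_features(seed=2)
        norms = [
            np.linalg.norm(classify.fit(fs, C=C).coef)
            for C in (10.0, 0.1, 1e-3, 1e-5)
        ]
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] < 0.01 * norms[0]

    def test_single_class_rejected(self):
        fs = _toy_features([[1.0]] * 5, [1] * 5)
        with pytest.raises(ValueError, match="two subjects"):
            classify.fit(fs)

    def test_determinism(self):
        fs = _separable_features(seed=8)
        m1 = classify.fit(fs, C=1.0)
        m2 = classify.fit(fs, C=1.0)
        assert np.allclose(m1.coef, m2.coef, atol=1e-8)

    def test_save_load_round_trip(self, tmp_path):
        model = classify.fit(_separable_features(), C=0.5)
        model.save(tmp_path / "m.json")
        back = classify.IdentityModel.load(tmp_path / "m.json")
        assert np.allclose(back.coef, model.coef)
        assert back.C == 0.5
        assert list(back.labels) == list(model.labels)


class TestPredict:
    def test_training_accuracy_on_separable_problem(self):
        fs = _separable_features()
        model = classify.fit(fs, C=1.0)
        raw = classify.predict_raw(model, fs)
        assert classify.accuracy(raw) == 100.0

    def test_empty_test_set(self):
        fs = _separable_features()
        model = classify.fit(fs, C=1.0)
        empty = fs.subset(subjects=[99])
        raw = classify.predict_raw(model, empty)
        assert len(raw) == 0
        with pytest.raises(ValueError, match="predictions"):
            classify.accuracy(raw)

    def test_feature_dimension_mismatch(self):
        model = classify.fit(_separable_features(), C=1.0)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((3, 7)))


def _raw_predictions(pred_labels, true=1):
    n = len(pred_labels)
    frame = pd.DataFrame(
        {
            "subject": [true] * n,
            "pair": [(true + 1) // 2] * n,
            "week": [4] * n,
            "task": ["rce"] * n,
            "block": [1] * n,
            "segment": list(range(n)),
            "true": [true] * n,
            "predicted": pred_labels,
        }
    )
    return classify.PredictionSet(frame, "raw", ("subject", "week", "task", "block"))


def _brute_force_vote(labels, window):
    out = []
    for i in range(len(labels) - window + 1):
        counts = collections.Counter(labels[i: i + window])
        top = max(counts.values())
        out.append(min(k for k, v in counts.items() if v == top))
    return out


class TestVote:
    def test_64_raws_yield_50_finals(self):
        raw = _raw_predictions([1] * 64)
        final = classify.vote(raw, VotingScheme(window=15))
        assert len(final) == 50

    def test_unanimous_votes_pass_through(self):
        final = classify.vote(_raw_predictions([7] * 20, true=7))
        assert (final.frame["predicted"] == 7).all()

    def test_strict_majority_wins(self):
        window = [2] * 8 + [3] * 7
        final = classify.vote(_raw_predictions(window), VotingScheme(window=15))
        assert final.frame["predicted"].tolist() == [2]

    def test_tie_goes_to_lowest_label(self):
        final = classify.vote(_raw_predictions([5, 2, 5, 2]), VotingScheme(window=4))
        assert final.frame["predicted"].tolist() == [2]

    def test_group_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            classify.vote(_raw_predictions([1] * 10), VotingScheme(window=15))

    def test_voting_never_crosses_groups(self):
        a = _raw_predictions([1] * 30).frame
        b = _raw_predictions([2] * 30, true=2).frame.assign(task="roe", true=1)
        raw = classify.PredictionSet(
            pd.concat([a, b], ignore_index=True), "raw",
            ("subject", "week", "task", "block"),
        )
        final = classify.vote(raw, VotingScheme(window=15))
        assert len(final) == 2 * (30 - 15 + 1)
        assert set(final.frame["predicted"]) == {1, 2}

    @settings(max_examples=1000, deadline=None)
    @given(
        labels=st.lists(st.integers(1, 5), min_size=1, max_size=40),
        window=st.integers(1, 20),
    )
    def test_matches_brute_force_mode(self, labels, window):
        """Sliding majority vote equals explicit per-window mode computation
        (ties to the lowest label) on arbitrary label sequences."""
        if window > len(labels):
            return
        raw = _raw_predictions(labels)
        final = classify.vote(raw, VotingScheme(window=window))
        assert final.frame["predicted"].tolist() == _brute_force_vote(labels, window)


class TestAccuracy:
    def test_all_correct(self):
        assert classify.accuracy(_raw_predictions([1, 1, 1])) == 100.0

    def test_fraction_scale(self):
        assert classify.accuracy(_raw_predictions([1, 2, 1, 2])) == 50.0

    def test_confusion_rows_normalized(self):
        frame = _raw_predictions([1, 1, 2, 3]).frame
        pred = classify.PredictionSet(frame, "raw", ("subject",))
        conf = classify.confusion(pred, labels=np.array([1, 2, 3]))
        assert conf.loc[1].sum() == pytest.approx(1.0)
        assert conf.loc[1, 1] == pytest.approx(0.5)
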