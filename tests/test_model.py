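"""Classifier, holdout split, CV folds, grid search and leakage audit."""

import numpy as np
import pandas as pd
import pytest

from rcmstrata import (
    PipelineParams,
    SyntheticStackSpec,
    generate_cohort,
    train_pipeline,
)
from rcmstrata.model import (
    GridSearchPlan,
    LeakageError,
    MissingClassError,
    ModelError,
    PartitionError,
    StrataClassifier,
    assert_no_leakage,
    grid_search,
    holdout_split,
    make_participant_folds,
    predict,
    select_best,
    train_classifier,
)
from rcmstrata.stack_io import Stratum


def _separable_encodings(n_per_class=20, noise=0.02, seed=0, k=16):
    """Four tight clusters of unit-L2 histograms, one per stratum."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c, s in enumerate(Stratum):
        base = np.zeros(k)
        base[c * 4 : c * 4 + 4] = 0.5
        pts = np.abs(base + noise * rng.standard_normal((n_per_class, k)))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        X.append(pts)
        y.extend([s] * n_per_class)
    return np.vstack(X), y


class TestTrainClassifier:
    def test_separable_data_reaches_training_accuracy_one(self):
        X, y = _separable_encodings()
        clf = train_classifier(X, y, C=100.0)
        labels, probs = predict(clf, X)
        assert labels == y
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)

    def test_confident_probability_for_clear_class_member(self):
        X, y = _separable_encodings()
        clf = train_classifier(X, y, C=100.0)
        _, probs = predict(clf, X[:1])
        assert probs[0, int(Stratum.SC)] > 0.9

    def test_missing_class_raises(self):
        X, y = _separable_encodings()
        keep = [i for i, s in enumerate(y) if s != Stratum.PD]
        with pytest.raises(MissingClassError):
            train_classifier(X[keep], [y[i] for i in keep], C=1.0)

    def test_weights_vanish_as_C_goes_to_zero(self):
        X, y = _separable_encodings()
        clf = train_classifier(X, y, C=1e-6)
        assert np.abs(clf.weights).max() == 0.0
        # predictions then collapse to the same prior-driven vector everywhere
        _, probs = predict(clf, X)
        assert np.ptp(probs, axis=0).max() < 1e-12

    def test_l1_sparsity_decreases_with_larger_C(self):
        """L1 at moderate C zeroes more coefficients than at very large C."""
        rng = np.random.default_rng(1)
        X = np.abs(rng.standard_normal((200, 100)))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        # labels depend on a handful of features; the rest are irrelevant
        score = X[:, 0] - X[:, 1] + 0.5 * X[:, 2]
        q = np.quantile(score, [0.25, 0.5, 0.75])
        y = [Stratum(int(np.searchsorted(q, v))) for v in score]
        frac_zero = {}
        for C in (100.0, 1e5):
            clf = train_classifier(X, y, C=C)
            frac_zero[C] = float(np.mean(clf.weights == 0.0))
        assert frac_zero[100.0] > frac_zero[1e5]

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ModelError):
            train_classifier(np.zeros((3, 4)), [Stratum.SC] * 2)


class TestPredict:
    def test_probabilities_sum_to_one(self):
        X, y = _separable_encodings(seed=3)
        clf = train_classifier(X, y, C=10.0)
        _, probs = predict(clf, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)
        assert (probs >= 0).all()

    def test_argmax_tie_broken_by_anatomical_order(self):
        clf = StrataClassifier(weights=np.zeros((4, 5)), intercepts=np.zeros(4), C=1.0)
        labels, probs = predict(clf, np.ones((1, 5)))
        np.testing.assert_allclose(probs, 0.25)
        assert labels[0] == Stratum.SC  # shallowest wins the 4-way tie

    def test_feature_count_mismatch_raises(self):
        clf = StrataClassifier(weights=np.zeros((4, 5)), intercepts=np.zeros(4), C=1.0)
        with pytest.raises(ModelError):
            predict(clf, np.ones((1, 7)))

    def test_serialisation_round_trip(self, tmp_path):
        X, y = _separable_encodings(seed=4)
        clf = train_classifier(X, y, C=10.0)
        clf.save(tmp_path / "clf.npz")
        back = StrataClassifier.load(tmp_path / "clf.npz")
        labels_a, probs_a = predict(clf, X)
        labels_b, probs_b = predict(back, X)
        assert labels_a == labels_b
        np.testing.assert_array_equal(probs_a, probs_b)


class TestHoldoutSplit:
    def _participants(self):
        rows = [{"participant_id": f"y{i:02d}", "age_group": "20-30"} for i in range(25)]
        rows += [{"participant_id": f"o{i:02d}", "age_group": "50-70"} for i in range(29)]
        return pd.DataFrame(rows)

    def test_stratified_counts(self):
        train, test = holdout_split(
            self._participants(), {"20-30": 8, "50-70": 10}, rng_seed=0
        )
        assert len(test) == 18
        assert sum(t.startswith("y") for t in test) == 8
        assert sum(t.startswith("o") for t in test) == 10
        assert len(train) == 54 - 18

    def test_disjoint_and_exhaustive(self):
        train, test = holdout_split(self._participants(), 0.25, rng_seed=1)
        assert not set(train) & set(test)
        assert set(train) | set(test) == set(self._participants()["participant_id"])

    def test_seed_reproducibility(self):
        a = holdout_split(self._participants(), {"20-30": 8, "50-70": 10}, rng_seed=7)
        b = holdout_split(self._participants(), {"20-30": 8, "50-70": 10}, rng_seed=7)
        assert a == b

    def test_excessive_request_raises(self):
        with pytest.raises(ModelError):
            holdout_split(self._participants(), {"20-30": 26}, rng_seed=0)


class TestParticipantFolds:
    def test_folds_partition_participants(self):
        ids = [f"p{i}" for i in range(23)]
        folds = make_participant_folds(ids, 10, rng_seed=0)
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(ids)
        assert len(folds) == 10

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(12)]
        assert make_participant_folds(ids, 10, 3) == make_participant_folds(ids, 10, 3)

    def test_too_few_participants_raise(self):
        with pytest.raises(PartitionError):
            make_participant_folds(["a", "b"], 10, 0)


class TestSelectBest:
    def _table(self, rows):
        return pd.DataFrame(
            [{"fold": 0, "n_levels": l, "n_splits": s, "C": c, "accuracy": a}
             for l, s, c, a in rows]
        )

    def test_maximum_mean_accuracy_wins(self):
        table = self._table([(1, 4, 1.0, 0.8), (2, 4, 1.0, 0.9), (1, 8, 1.0, 0.85)])
        assert select_best(table) == (2, 4, 1.0)

    def test_tie_goes_to_first_grid_point_in_order(self):
        table = self._table(
            [(2, 8, 100.0, 1.0), (1, 6, 10.0, 1.0), (1, 4, 1.0, 1.0), (1, 4, 100.0, 1.0)]
        )
        assert select_best(table) == (1, 4, 1.0)


@pytest.fixture(scope="module")
def tiny_cohort():
    """10 participants, short small-section stacks, for CV/leakage tests."""
    base = SyntheticStackSpec(width_px=64, height_px=64)
    return generate_cohort(
        10,
        1,
        spec_ranges={
            "sc_thickness": (1, 2), "ve_thickness": (2, 3),
            "dej_thickness": (2, 2), "pd_thickness": (2, 3),
        },
        rng_seed=42,
        base_spec=base,
    )


TINY_PARAMS = dict(downsample_factor=1, stride=2, n_random_patches=60)


class TestGridSearchAndLeakage:
    def test_grid_search_table_and_determinism(self, tiny_cohort):
        plan = GridSearchPlan(
            levels_grid=(1,), splits_grid=(4,), C_grid=(1.0, 100.0), n_folds=10,
            base_params=PipelineParams(**TINY_PARAMS),
        )
        best, table = grid_search(tiny_cohort.stacks, tiny_cohort.labels, plan, rng_seed=0)
        assert len(table) == 10 * 2
        assert best[0] == 1 and best[1] == 4 and best[2] in (1.0, 100.0)
        best2, table2 = grid_search(tiny_cohort.stacks, tiny_cohort.labels, plan, rng_seed=0)
        assert best2 == best
        pd.testing.assert_frame_equal(table, table2)

    def test_pipeline_records_fit_participants(self, tiny_cohort):
        stacks = tiny_cohort.stacks[:4]
        pipe = train_pipeline(
            stacks, tiny_cohort.labels, PipelineParams(n_levels=1, n_splits=4, **TINY_PARAMS), 0
        )
        ids = {s.participant_id for s in stacks}
        for stage in ("whitening", "dictionary", "classifier"):
            assert pipe.fit_participants[stage] == frozenset(ids)

    def test_leakage_audit_raises_on_overlap(self, tiny_cohort):
        stacks = tiny_cohort.stacks[:4]
        pipe = train_pipeline(
            stacks, tiny_cohort.labels, PipelineParams(n_levels=1, n_splits=4, **TINY_PARAMS), 0
        )
        held_out = {s.participant_id for s in tiny_cohort.stacks[4:]}
        assert_no_leakage(pipe, held_out)  # disjoint: passes
        with pytest.raises(LeakageError):
            assert_no_leakage(pipe, {stacks[0].participant_id})
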