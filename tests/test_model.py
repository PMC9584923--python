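import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ppv.evaluation import roc_auc
from ppv.features import FEATURE_NAMES
from ppv.model import (
    ModelBundle,
    classify_score_tier,
    combine_tissue_scores,
    rank_predictions,
    score_peptides,
    train_nested_cv,
)


def synthetic_design(rng, n_rows=400, n_positives=40, shift=5.0):
    """A separable toy design: positives shifted on the boundary features."""
    X = rng.normal(size=(n_rows, len(FEATURE_NAMES)))
    labels = np.zeros(n_rows, dtype=int)
    pos = rng.choice(n_rows, size=n_positives, replace=False)
    labels[pos] = 1
    X[pos, 0] += shift  # intensity_start
    X[pos, 1] += shift  # intensity_stop
    frame = pd.DataFrame(X, columns=FEATURE_NAMES)
    frame["label"] = labels
    frame["group_key"] = [f"G{i % 40}" for i in range(n_rows)]
    frame["protein_accession"] = frame["group_key"]
    frame["start"] = np.arange(n_rows)
    frame["stop"] = np.arange(n_rows) + 10
    frame["total_abundance"] = 10 ** rng.uniform(3, 8, size=n_rows)
    return frame


class TestNestedCV:
    def test_twenty_inner_models_and_fold_partition(self, rng):
        design = synthetic_design(rng)
        bundle = train_nested_cv(design, seed=3)
        assert len(bundle.inner_models) == 5 * 4
        assert set(bundle.outer_fold) == set(range(5))
        # group-aware: every protein lives in exactly one outer fold
        folds_per_group = (
            pd.DataFrame({"g": design["group_key"], "f": bundle.outer_fold})
            .groupby("g")["f"].nunique()
        )
        assert (folds_per_group == 1).all()
        assert np.isfinite(bundle.oof_scores).all()

    def test_standardization_fit_on_training_rows_only(self, rng):
        design = synthetic_design(rng)
        bundle = train_nested_cv(design, seed=3)
        X = design[FEATURE_NAMES].to_numpy()
        for outer in bundle.outer_models:
            train = X[bundle.outer_fold != outer.outer_fold]
            np.testing.assert_allclose(outer.mean, train.mean(axis=0), atol=1e-12)
            np.testing.assert_allclose(outer.sd, train.std(axis=0), atol=1e-12)

    def test_bit_identical_rerun_under_fixed_seed(self, rng):
        design = synthetic_design(rng)
        a = train_nested_cv(design, seed=7)
        b = train_nested_cv(design, seed=7)
        assert np.array_equal(a.oof_scores, b.oof_scores)
        assert np.array_equal(a.outer_fold, b.outer_fold)
        assert np.array_equal(a.final_coef, b.final_coef)
        assert a.selected_C == b.selected_C

    def test_separable_design_scores_near_perfectly(self, rng):
        design = synthetic_design(rng)
        bundle = train_nested_cv(design, seed=1)
        assert roc_auc(design["label"], bundle.oof_scores) >= 0.99

    def test_degenerate_inputs_rejected(self, rng):
        design = synthetic_design(rng)
        all_neg = design.copy()
        all_neg["label"] = 0
        with pytest.raises(ValueError):
            train_nested_cv(all_neg, seed=1)
        with pytest.raises(ValueError):
            train_nested_cv(design, n_outer=1, seed=1)

    def test_upsampling_changes_fit_but_keeps_contract(self, rng):
        design = synthetic_design(rng)
        bundle = train_nested_cv(design, upsample_ratio=0.1, seed=1)
        assert len(bundle.inner_models) == 20
        assert roc_auc(design["label"], bundle.oof_scores) >= 0.95

    def test_bundle_json_roundtrip(self, rng, tmp_path):
        design = synthetic_design(rng)
        bundle = train_nested_cv(design, seed=5)
        path = tmp_path / "bundle.json"
        bundle.to_json(path)
        back = ModelBundle.from_json(path)
        np.testing.assert_array_equal(back.oof_scores, bundle.oof_scores)
        np.testing.assert_array_equal(back.final_coef, bundle.final_coef)
        scores_a = score_peptides(bundle, design)
        scores_b = score_peptides(back, design)
        np.testing.assert_array_equal(scores_a, scores_b)


class TestScoring:
    def _hand_bundle(self, coef, intercept, mean=None, sd=None):
        k = len(FEATURE_NAMES)
        return ModelBundle(
            feature_names=list(FEATURE_NAMES),
            inner_models=[],
            outer_fold=np.array([]),
            selected_C={},
            final_coef=np.asarray(coef, dtype=float),
            final_intercept=float(intercept),
            final_mean=np.zeros(k) if mean is None else np.asarray(mean),
            final_sd=np.ones(k) if sd is None else np.asarray(sd),
            oof_scores=np.array([]),
            seed=0,
        )

    def test_all_zero_features_give_sigmoid_intercept(self):
        bundle = self._hand_bundle(np.zeros(len(FEATURE_NAMES)), -1.2)
        frame = pd.DataFrame(np.zeros((3, len(FEATURE_NAMES))), columns=FEATURE_NAMES)
        np.testing.assert_allclose(
            score_peptides(bundle, frame), 1 / (1 + np.exp(1.2))
        )

    def test_hand_set_weight_reaches_half_at_balancing_zscore(self):
        # weight 1 on the abundance feature, intercept -3, z-score 3 => 0.5
        coef = np.zeros(len(FEATURE_NAMES))
        coef[FEATURE_NAMES.index("log_abundance")] = 1.0
        bundle = self._hand_bundle(coef, -3.0)
        frame = pd.DataFrame(np.zeros((1, len(FEATURE_NAMES))), columns=FEATURE_NAMES)
        frame.loc[0, "log_abundance"] = 3.0
        assert score_peptides(bundle, frame)[0] == pytest.approx(0.5)

    def test_monotone_in_positively_weighted_feature(self):
        coef = np.zeros(len(FEATURE_NAMES))
        coef[0] = 0.8
        bundle = self._hand_bundle(coef, 0.1)
        frame = pd.DataFrame(np.zeros((5, len(FEATURE_NAMES))), columns=FEATURE_NAMES)
        frame[FEATURE_NAMES[0]] = [0.0, 0.5, 1.0, 2.0, 5.0]
        scores = score_peptides(bundle, frame)
        assert np.all(np.diff(scores) > 0)

    def test_schema_mismatch_rejected(self):
        bundle = self._hand_bundle(np.zeros(len(FEATURE_NAMES)), 0.0)
        with pytest.raises(ValueError, match="missing"):
            score_peptides(bundle, pd.DataFrame({"x": [1.0]}))


class TestTiers:
    @pytest.mark.parametrize(
        "p, tier",
        [
            (0.273, "very_high"),  # a top-ranked brain neuropeptide score
            (0.017, "high"),
            (0.05, "high"),  # boundary falls to the lower tier
            (0.01, "low"),
            (0.0, "low"),
            (1.0, "very_high"),
        ],
    )
    def test_tier_thresholds(self, p, tier):
        assert classify_score_tier(p) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_score_tier(1.5)
        with pytest.raises(ValueError):
            classify_score_tier(-0.1)


class TestCombineTissues:
    def test_single_tissue_identity(self):
        assert combine_tissue_scores({"brain": 0.42}) == pytest.approx(0.42)

    def test_two_halves(self):
        assert combine_tissue_scores({"a": 0.5, "b": 0.5}) == pytest.approx(0.75)

    def test_absorbing_one(self):
        assert combine_tissue_scores({"a": 1.0, "b": 0.3}) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_tissue_scores({})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    def test_symmetric_and_bounded(self, ps):
        forward = combine_tissue_scores({f"t{i}": p for i, p in enumerate(ps)})
        backward = combine_tissue_scores(
            {f"t{i}": p for i, p in enumerate(reversed(ps))}
        )
        assert forward == pytest.approx(backward)
        assert 0.0 <= forward <= 1.0
        assert forward >= max(ps) - 1e-12  # never below the best single tissue


def test_rank_predictions_tie_break_deterministic():
    frame = pd.DataFrame(
        {
            "ppv_score": [0.5, 0.5, 0.5, 0.9],
            "total_abundance": [10.0, 30.0, 30.0, 1.0],
            "protein_accession": ["B", "A", "A", "C"],
            "start": [5, 9, 2, 1],
        }
    )
    ranked = rank_predictions(frame)
    assert ranked["rank"].tolist() == [1, 2, 3, 4]
    assert ranked["protein_accession"].tolist() == ["C", "A", "A", "B"]
    assert ranked["start"].tolist() == [1, 2, 9, 5]
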