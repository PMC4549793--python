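"""Packaged classifiers, POLE flagging, tree induction, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from msikit.classifier import (
    LABELS,
    ClassifierBundle,
    PoleFlagRule,
    TreeNode,
    classify,
    cross_validate,
    default_exome_classifier,
    default_genome_classifier,
    deserialize,
    serialize,
    stratified_folds,
    stump,
    train,
)
from msikit.mutations import MSI_HIGH, NON_MSI_HIGH


def features_frame(s_ind, t_sns=None, **extra):
    n = len(s_ind)
    data = {"S.ind": list(s_ind), "T.sns": list(t_sns) if t_sns is not None else [1.0] * n}
    data.update(extra)
    return pd.DataFrame(data, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))


class TestDefaultClassifiers:
    def test_exome_stump(self):
        bundle = default_exome_classifier()
        assert bundle.regime == "exome"
        assert bundle.tree.feature == "S.ind"
        assert bundle.tree.threshold == 0.395
        assert bundle.tree.right.label == MSI_HIGH
        assert bundle.tree.left.label == NON_MSI_HIGH

    def test_genome_stump(self):
        bundle = default_genome_classifier()
        assert bundle.regime == "genome"
        assert bundle.tree.feature == "S.ind"
        assert bundle.tree.threshold == 0.909

    @pytest.mark.parametrize(
        "s_ind, expected",
        [
            (2.61, MSI_HIGH),  # well above the exome cutoff
            (0.27, NON_MSI_HIGH),
            (0.395, NON_MSI_HIGH),  # strict inequality at the boundary
            (0.3951, MSI_HIGH),
        ],
    )
    def test_exome_calls(self, s_ind, expected):
        feats = features_frame([s_ind])
        result = classify(feats, default_exome_classifier())
        assert result.loc["S0", "predicted_status"] == expected

    @pytest.mark.parametrize(
        "s_ind, expected",
        [(1.0, MSI_HIGH), (0.909, NON_MSI_HIGH), (0.5, NON_MSI_HIGH)],
    )
    def test_genome_calls(self, s_ind, expected):
        feats = features_frame([s_ind])
        result = classify(feats, default_genome_classifier())
        assert result.loc["S0", "predicted_status"] == expected


class TestPoleFlag:
    @pytest.mark.parametrize(
        "t_sns, s_ind, flagged",
        [
            (70, 0.045, True),  # ultramutated, few repeat indels
            (70, 0.25, False),  # repeat-indel rate too high for the flag
            (50, 0.045, False),  # burden below the cutoff
            (60, 0.045, False),  # both inequalities strict
            (70, 0.18, False),
        ],
    )
    def test_rule(self, t_sns, s_ind, flagged):
        assert PoleFlagRule().applies(t_sns, s_ind) is flagged

    def test_flag_reported_alongside_status(self):
        feats = features_frame([2.61, 0.045], t_sns=[70, 70])
        result = classify(feats, default_exome_classifier())
        assert list(result["predicted_status"]) == [MSI_HIGH, NON_MSI_HIGH]
        assert list(result["pole_flag"]) == [False, True]

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            PoleFlagRule(t_sns_cutoff=-1)


class TestClassifyErrors:
    def test_missing_feature_names_sample_and_feature(self):
        feats = features_frame([np.nan])
        with pytest.raises(ValueError, match=r"S0.*S\.ind"):
            classify(feats, default_exome_classifier())


class TestTraining:
    def test_separable_data_yields_midpoint_stump(self):
        feats = features_frame([0.1, 0.2, 0.6, 0.7])
        labels = [NON_MSI_HIGH, NON_MSI_HIGH, MSI_HIGH, MSI_HIGH]
        bundle = train(feats, labels)
        tree = bundle.tree
        assert tree.kind == "numeric" and tree.feature == "S.ind"
        assert tree.threshold == pytest.approx(0.4)
        assert tree.left.label == NON_MSI_HIGH and tree.right.label == MSI_HIGH

    def test_single_class_returns_leaf_with_warning(self):
        feats = features_frame([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="single class"):
            bundle = train(feats, [NON_MSI_HIGH] * 3)
        assert bundle.tree.kind == "leaf"
        assert bundle.tree.label == NON_MSI_HIGH

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train(features_frame([]), [])

    def test_perfectly_separating_feature_wins(self, rng):
        # S.ind separates perfectly; T.sns is noise: induction must
        # reduce to a stump on S.ind
        n = 60
        labels = np.array([MSI_HIGH] * (n // 2) + [NON_MSI_HIGH] * (n // 2))
        s_ind = np.where(labels == MSI_HIGH, 1.0, 0.1) + rng.normal(0, 0.01, n)
        feats = features_frame(s_ind, t_sns=rng.normal(10, 5, n))
        bundle = train(feats, labels)
        assert bundle.tree.kind == "numeric"
        assert bundle.tree.feature == "S.ind"
        assert bundle.tree.left.kind == "leaf" and bundle.tree.right.kind == "leaf"

    def test_cancer_type_one_vs_rest_split_usable(self):
        # labels depend only on the categorical column
        feats = features_frame(
            [0.1] * 8,
            cancer_type=["colon"] * 4 + ["rectal"] * 4,
        )
        labels = [MSI_HIGH] * 4 + [NON_MSI_HIGH] * 4
        bundle = train(feats, labels)
        assert bundle.tree.kind == "categorical"
        assert bundle.tree.feature == "cancer_type"

    def test_monotonicity_of_threshold_calls(self, rng):
        # scaling every S.ind up by a constant > 1 never flips MSI-H to
        # Non-MSI-H under a fixed positive threshold
        bundle = default_exome_classifier()
        s_ind = rng.uniform(0, 1, 50)
        before = classify(features_frame(s_ind), bundle)["predicted_status"]
        after = classify(features_frame(s_ind * 3.7), bundle)["predicted_status"]
        flipped = (before == MSI_HIGH) & (after == NON_MSI_HIGH)
        assert not flipped.any()

    def test_planted_boundary_recovered(self, rng):
        # quick version of the recovery simulation (more seeds in the
        # acceptance suite): boundary at S.ind = 0.4
        for seed in (1, 2, 3):
            local = np.random.default_rng(seed)
            n = 400
            labels = np.array(
                [MSI_HIGH] * (n // 4) + [NON_MSI_HIGH] * (3 * n // 4)
            )
            s_ind = np.where(
                labels == MSI_HIGH,
                local.uniform(0.45, 2.5, n),
                local.uniform(0.0, 0.35, n),
            )
            feats = features_frame(s_ind, t_sns=local.uniform(1, 40, n))
            bundle = train(feats, labels)
            assert bundle.tree.kind == "numeric"
            assert bundle.tree.feature == "S.ind"
            assert abs(bundle.tree.threshold - 0.4) <= 0.05


class TestCrossValidation:
    def _separable(self, n=60):
        labels = np.array([MSI_HIGH, NON_MSI_HIGH] * (n // 2))
        s_ind = np.where(labels == MSI_HIGH, 1.5, 0.05)
        return features_frame(s_ind), labels

    def test_perfectly_separable_is_fully_concordant(self):
        feats, labels = self._separable()
        result = cross_validate(feats, labels, k=5, seed=11)
        assert result.concordance == 100.0

    def test_same_seed_reproduces_folds_and_score(self):
        feats, labels = self._separable()
        r1 = cross_validate(feats, labels, k=5, seed=3)
        r2 = cross_validate(feats, labels, k=5, seed=3)
        assert np.array_equal(r1.fold_assignment, r2.fold_assignment)
        assert r1.concordance == r2.concordance
        assert r1.fold_concordance == r2.fold_concordance

    def test_fold_assignment_partitions_samples(self):
        feats, labels = self._separable(100)
        result = cross_validate(feats, labels, k=5, seed=0)
        assert result.fold_assignment.shape == (100,)
        counts = np.bincount(result.fold_assignment, minlength=5)
        assert counts.sum() == 100 and (counts == 20).all()

    def test_stratification_balances_classes(self):
        labels = [MSI_HIGH] * 20 + [NON_MSI_HIGH] * 80
        folds = stratified_folds(labels, k=5, seed=2)
        for fold in range(5):
            test = folds == fold
            assert sum(test[:20]) == 4  # 4 MSI-H per fold
            assert sum(test[20:]) == 16

    def test_small_class_degrades_with_warning(self):
        labels = [MSI_HIGH] * 3 + [NON_MSI_HIGH] * 17
        with pytest.warns(UserWarning, match="stratification"):
            stratified_folds(labels, k=5, seed=0)

    def test_permuted_labels_score_near_chance(self):
        # balanced data with labels shuffled independently of the feature:
        # concordance should sit near 50% (binomial noise at n = 400)
        local = np.random.default_rng(99)
        n = 400
        s_ind = local.uniform(0, 1, n)
        labels = np.array([MSI_HIGH, NON_MSI_HIGH] * (n // 2))
        local.shuffle(labels)
        feats = features_frame(s_ind, t_sns=local.uniform(0, 1, n))
        result = cross_validate(feats, labels, k=5, seed=0)
        # 50% +/- 5 sigma of binomial(400, .5) in percentage points
        assert abs(result.concordance - 50.0) < 5 * 100 * 0.5 / np.sqrt(n)


class TestSerialization:
    def test_default_bundle_round_trips(self):
        bundle = default_exome_classifier()
        restored = deserialize(serialize(bundle))
        assert restored.regime == bundle.regime
        assert restored.provenance == bundle.provenance
        assert restored.tree.to_dict() == bundle.tree.to_dict()

    def test_two_level_tree_round_trips(self):
        tree = TreeNode(
            kind="numeric",
            feature="S.ind",
            threshold=0.4,
            left=TreeNode(
                kind="categorical",
                feature="cancer_type",
                category="colon",
                left=TreeNode(kind="leaf", label=MSI_HIGH),
                right=TreeNode(kind="leaf", label=NON_MSI_HIGH),
            ),
            right=TreeNode(kind="leaf", label=MSI_HIGH),
        )
        bundle = ClassifierBundle(tree=tree, regime="custom", provenance="hand-built")
        restored = deserialize(serialize(bundle))
        assert restored.tree.to_dict() == tree.to_dict()

    def test_predictions_survive_round_trip(self, rng):
        feats = features_frame(rng.uniform(0, 1, 30))
        bundle = default_exome_classifier()
        restored = deserialize(serialize(bundle))
        pd.testing.assert_frame_equal(
            classify(feats, bundle), classify(feats, restored)
        )

    def test_truncated_document_rejected(self):
        text = serialize(default_exome_classifier())
        with pytest.raises(ValueError):
            deserialize(text[: len(text) // 2])

    def test_missing_field_named(self):
        with pytest.raises(ValueError, match="regime"):
            deserialize('{"tree": {"kind": "leaf", "label": "MSI-H"}, "version": "1", "provenance": ""}')
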