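"""Feature assembly, embedding, random forest, AUC/DeLong, confusion metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score, silhouette_score

import formantmod as fm
from formantmod.classify import FEATURE_COLUMNS, delong_auc_variance


def fake_summaries(n_per_day=4, days=range(1, 55), rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for day in days:
        for v in range(n_per_day):
            for vt in ("BL", "CD"):
                row = {
                    "voc_id": f"{vt}{day}_{v}",
                    "vocal_type": vt,
                    "session_id": f"s{day}",
                    "day": day,
                }
                for col in FEATURE_COLUMNS:
                    row[col] = rng.normal()
                rows.append(row)
    return pd.DataFrame(rows)


class TestBuildFeatures:
    def test_eighteen_columns(self):
        fmx = fm.build_features(fake_summaries())
        assert fmx.X.shape[1] == 18

    def test_incomplete_rows_excluded(self):
        df = fake_summaries()
        n_before = len(fm.build_features(df).voc_ids)
        df.loc[0, "se_q3_F1"] = np.nan  # a start-epoch row
        assert len(fm.build_features(df).voc_ids) == n_before - 1

    def test_day_quartile_epochs(self):
        """For days 1..54: day 10 is in the start epoch, day 50 in the end,
        day 30 in neither."""
        fmx = fm.build_features(fake_summaries())
        days = {vid: int(vid.split("_")[0][2:]) for vid in fmx.voc_ids}
        for vid, ep in zip(fmx.voc_ids, fmx.epoch):
            d = days[vid]
            assert ep == ("start" if d <= 14.25 else "end")
            assert not (15 <= d <= 40)
        epoch_days = {days[v] for v in fmx.voc_ids}
        assert 10 in epoch_days and 50 in epoch_days and 30 not in epoch_days

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fm.build_features(fake_summaries(n_per_day=1, days=[1, 54]))


class TestEmbed:
    def test_seed_determinism(self):
        X = np.random.default_rng(1).normal(size=(40, 18))
        assert np.array_equal(fm.embed(X, seed=5), fm.embed(X, seed=5))

    def test_duplicated_rows_land_together(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 18))
        X[15:] = X[:15]  # duplicate block
        coords = fm.embed(X, seed=1, n_neighbors=5)
        d = np.linalg.norm(coords[:15] - coords[15:], axis=1)
        spread = np.linalg.norm(coords - coords.mean(0), axis=1).mean()
        assert np.median(d) < 0.25 * spread

    def test_separable_clusters_stay_separable(self):
        rng = np.random.default_rng(3)
        X = np.r_[rng.normal(0, 0.3, (25, 18)), rng.normal(4, 0.3, (25, 18))]
        coords = fm.embed(X, seed=2)
        labels = np.r_[np.zeros(25), np.ones(25)]
        assert silhouette_score(coords, labels) > 0.5


class TestRandomForest:
    def test_separable_coords_perfect(self):
        rng = np.random.default_rng(4)
        coords = np.r_[rng.normal(0, 0.2, (30, 2)), rng.normal(5, 0.2, (30, 2))]
        labels = np.array(["BL"] * 30 + ["CD"] * 30)
        rep = fm.rf_train_test(coords, labels, seed=1)
        assert rep.auc == 1.0
        assert rep.oob_error <= 0.05

    def test_shuffled_labels_chance_auc(self):
        """Label permutation null: mean AUC over seeds ~ 0.5."""
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(60, 2))
        aucs = []
        for seed in range(30):
            labels = rng.permutation(np.array(["BL", "CD"] * 30))
            rep = fm.rf_train_test(coords, labels, n_trees=200, seed=seed)
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.07

    def test_auc_equals_rank_statistic(self):
        """Forest AUC equals the brute-force pairwise Mann-Whitney statistic
        and sklearn's trapezoidal ROC area on the same scores."""
        rng = np.random.default_rng(6)
        coords = np.r_[rng.normal(0, 1.2, (40, 2)), rng.normal(1.0, 1.2, (40, 2))]
        labels = np.array(["BL"] * 40 + ["CD"] * 40)
        rep = fm.rf_train_test(coords, labels, seed=3)
        brute = np.mean(
            [
                (a > b) + 0.5 * (a == b)
                for a, b in itertools.product(
                    rep.test_scores[rep.test_labels == "BL"],
                    rep.test_scores[rep.test_labels == "CD"],
                )
            ]
        )
        assert rep.auc == pytest.approx(brute)
        assert rep.auc == pytest.approx(
            roc_auc_score(rep.test_labels == "BL", rep.test_scores)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fm.rf_train_test(np.zeros((10, 2)), np.array(["BL"] * 10))


class TestDeLong:
    def test_identical_score_sets_null(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        labels = np.array(["BL", "CD", "BL", "BL", "CD", "CD"])
        out = fm.delong_test(scores, labels, scores, labels)
        assert out["D"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_three_vs_three_exhaustive_auc(self):
        """AUC from placement values matches enumeration of all 9 pairs."""
        scores = np.array([0.9, 0.6, 0.3, 0.8, 0.2, 0.1])
        labels = np.array(["BL", "BL", "BL", "CD", "CD", "CD"])
        auc, _ = delong_auc_variance(scores, labels)
        pairs = [
            (a > b) + 0.5 * (a == b)
            for a in scores[:3]
            for b in scores[3:]
        ]
        assert auc == pytest.approx(np.mean(pairs))

    def test_variance_matches_bootstrap(self):
        """DeLong AUC variance agrees with a 10k-resample bootstrap."""
        rng = np.random.default_rng(7)
        scores = np.r_[rng.normal(1, 1, 25), rng.normal(0, 1, 25)]
        labels = np.array(["BL"] * 25 + ["CD"] * 25)
        _, var = delong_auc_variance(scores, labels)
        boots = []
        for _ in range(10000):
            ip = rng.integers(0, 25, 25)
            ineg = 25 + rng.integers(0, 25, 25)
            boots.append(fm.auc_mann_whitney(
                np.r_[scores[ip], scores[ineg]],
                np.r_[labels[ip], labels[ineg]],
            ))
        assert var == pytest.approx(np.var(boots), rel=0.25)

    def test_degenerate_scores_rejected(self):
        labels = np.array(["BL", "CD"] * 5)
        with pytest.raises(ValueError):
            delong_auc_variance(np.full(10, 0.5), labels)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        labels = np.array(["BL", "CD"] * 10)
        m = fm.confusion_metrics(labels, labels)
        assert m == {"sensitivity": 1.0, "specificity": 1.0, "balanced_accuracy": 1.0}

    def test_hand_confusion_matrix(self):
        """BL: 8 right / 2 wrong; CD: 7 right / 3 wrong -> 0.8 / 0.7 / 0.75."""
        labels = np.array(["BL"] * 10 + ["CD"] * 10)
        preds = np.array(["BL"] * 8 + ["CD"] * 2 + ["BL"] * 3 + ["CD"] * 7)
        m = fm.confusion_metrics(preds, labels)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.7)
        assert m["balanced_accuracy"] == pytest.approx(0.75)

    def test_constant_predictor_balanced_half(self):
        labels = np.array(["BL"] * 10 + ["CD"] * 10)
        m = fm.confusion_metrics(np.array(["BL"] * 20), labels)
        assert m["balanced_accuracy"] == pytest.approx(0.5)

    def test_balanced_accuracy_identity(self):
        rng = np.random.default_rng(8)
        labels = rng.choice(["BL", "CD"], 50)
        preds = rng.choice(["BL", "CD"], 50)
        m = fm.confusion_metrics(preds, labels)
        assert m["balanced_accuracy"] == pytest.approx(
            (m["sensitivity"] + m["specificity"]) / 2
        )
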