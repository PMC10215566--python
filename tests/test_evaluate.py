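"""ROC, bootstrap CIs, PLS-DA/VIP, and MCCV panel evaluation."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from csfmark.evaluate import (
    _auc_mann_whitney,
    bootstrap_auc,
    correlate_discovery_validation,
    mccv_panel_evaluation,
    plsda_fit,
    roc_auc,
)
from csfmark.simulate import simulate_biomarker_panel


def pair_count_auc(pos, neg):
    """Exhaustive pair-counting oracle."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def labelled(pos, neg):
    scores = np.concatenate([pos, neg])
    labels = np.array(["ALS"] * len(pos) + ["HC"] * len(neg))
    return scores, labels


class TestRocAuc:
    def test_identical_distributions_give_half(self):
        scores, labels = labelled([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert roc_auc(scores, labels).auc == 0.5

    def test_perfect_separation(self):
        scores, labels = labelled([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        res = roc_auc(scores, labels)
        assert res.auc == 1.0
        assert res.orientation == 1

    def test_small_example_with_tie_free_overlap(self):
        scores, labels = labelled([2.5, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert roc_auc(scores, labels).auc == pytest.approx(8.0 / 9.0)

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n1 = int(rng.integers(2, 26))
            n2 = int(rng.integers(2, 26))
            pos = rng.integers(0, 8, n1).astype(float)  # forces ties
            neg = rng.integers(0, 8, n2).astype(float)
            assert _auc_mann_whitney(pos, neg) == pytest.approx(
                pair_count_auc(pos, neg), abs=1e-12
            )

    def test_negation_complements_auc(self):
        rng = np.random.default_rng(4)
        pos, neg = rng.normal(1, 1, 15), rng.normal(0, 1, 12)
        assert _auc_mann_whitney(-pos, -neg) == pytest.approx(
            1.0 - _auc_mann_whitney(pos, neg)
        )

    def test_auto_orientation_recorded(self):
        scores, labels = labelled([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        res = roc_auc(scores, labels)
        assert res.auc == 1.0
        assert res.orientation == -1

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(9)
        scores, labels = labelled(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        res = roc_auc(scores, labels)
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], ["ALS", "ALS"])

    def test_gaussian_shift_limit(self):
        """Two Normal groups separated by d=1: AUC -> Phi(1/sqrt(2)) ~ 0.760."""
        rng = np.random.default_rng(123)
        scores, labels = labelled(rng.normal(1, 1, 2000), rng.normal(0, 1, 2000))
        assert roc_auc(scores, labels).auc == pytest.approx(
            norm.cdf(1 / np.sqrt(2)), abs=0.01
        )


class TestBootstrapAuc:
    def test_perfect_separation_degenerate_ci(self):
        scores, labels = labelled([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        res = bootstrap_auc(scores, labels, n_boot=200, seed=1)
        assert res.auc == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(6)
        scores, labels = labelled(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        a = bootstrap_auc(scores, labels, seed=42)
        b = bootstrap_auc(scores, labels, seed=42)
        assert (a.auc, a.ci_low, a.ci_high) == (b.auc, b.ci_low, b.ci_high)

    def test_bootstrap_mean_near_gaussian_truth(self):
        rng = np.random.default_rng(15)
        scores, labels = labelled(rng.normal(1, 1, 100), rng.normal(0, 1, 100))
        res = bootstrap_auc(scores, labels, seed=3)
        truth = norm.cdf(1 / np.sqrt(2))
        assert res.ci_low <= truth <= res.ci_high
        assert res.auc == pytest.approx(truth, abs=0.08)

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (20, 80, 320):
            rng = np.random.default_rng(1000 + n)
            scores, labels = labelled(rng.normal(1, 1, n), rng.normal(0, 1, n))
            res = bootstrap_auc(scores, labels, seed=5)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_tiny_class_rejected(self):
        scores, labels = labelled([1.0, 2.0], [0.0, 0.5, 0.6])
        with pytest.raises(ValueError, match=">= 3"):
            bootstrap_auc(scores, labels)


class TestCorrelation:
    def test_identical_vectors(self):
        s = pd.Series([0.5, 1.0, 2.0], index=list("abc"))
        r, _ = correlate_discovery_validation(s, s)
        assert r == pytest.approx(1.0)

    def test_negated_vector(self):
        s = pd.Series([0.5, 1.0, 2.0], index=list("abc"))
        r, _ = correlate_discovery_validation(s, -s)
        assert r == pytest.approx(-1.0)

    def test_small_example_value(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        y = pd.Series([2.0, 4.0, 7.0], index=list("abc"))
        r, pairs = correlate_discovery_validation(x, y)
        assert r == pytest.approx(0.9933992677987828, rel=1e-9)
        assert len(pairs) == 3

    def test_disjoint_indices_rejected(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("xyz"))
        with pytest.raises(ValueError, match="shared"):
            correlate_discovery_validation(x, y)


class TestPlsda:
    def test_mean_squared_vip_is_one(self, rng):
        for _ in range(5):
            X = rng.normal(size=(25, 12))
            y = rng.choice(["ALS", "HC"], 25)
            if len(set(y)) < 2:
                continue
            model = plsda_fit(X, y)
            assert np.mean(model.vip**2) == pytest.approx(1.0, rel=1e-10)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.array(["ALS"] * 15 + ["HC"] * 15)
        model = plsda_fit(X, y)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_informative_feature_gets_top_vip(self, rng):
        y = np.array(["ALS"] * 15 + ["HC"] * 15)
        X = rng.normal(size=(30, 10))
        X[:, 4] += 5.0 * (y == "ALS")
        model = plsda_fit(X, y, positive="ALS")
        assert int(np.argmax(model.vip)) == 4

    def test_scores_match_reference_pls_implementation(self):
        """Component scores agree with scikit-learn's PLS regression to
        1e-6 (up to per-component sign) on random 20x10 inputs."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 10))
            y = np.array(["HC"] * 10 + ["ALS"] * 10)
            model = plsda_fit(X, y, positive="ALS")
            ref = sklearn_pls.PLSRegression(n_components=2, scale=True)
            ref.fit(X, (y == "ALS").astype(float))
            for a in range(2):
                ours, theirs = model.scores[:, a], ref.x_scores_[:, a]
                sign = np.sign(ours @ theirs)
                assert np.abs(ours - sign * theirs).max() < 1e-6

    def test_constant_feature_dropped_with_warning(self, rng):
        X = rng.normal(size=(20, 5))
        X[:, 2] = 3.0
        y = np.array(["ALS"] * 10 + ["HC"] * 10)
        with pytest.warns(UserWarning, match="constant"):
            model = plsda_fit(X, y, feature_names=list("abcde"))
        assert model.dropped_features == ["c"]
        assert model.feature_names == ["a", "b", "d", "e"]

    def test_predictions_separate_clean_classes(self, rng):
        y = np.array(["ALS"] * 12 + ["HC"] * 12)
        X = rng.normal(size=(24, 6))
        X[:, 0] += 6.0 * (y == "ALS")
        model = plsda_fit(X, y, positive="ALS")
        assert (model.predict(X) == y).all()


class TestMccv:
    def test_pure_noise_panel_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 12))
        labels = np.array(["ALS"] * 30 + ["HC"] * 30)
        res = mccv_panel_evaluation(
            X, labels, panel_sizes=(3, 12), n_repeats=60, seed=8
        )
        for k in (3, 12):
            assert abs(res.auc_mean[k] - 0.5) < 0.12
            assert abs(res.accuracy[k] - 0.5) < 0.12
            lo, hi = res.auc_ci[k]
            assert lo <= 0.5 <= hi

    def test_same_seed_identical(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 8))
        labels = np.array(["ALS"] * 20 + ["HC"] * 20)
        a = mccv_panel_evaluation(X, labels, panel_sizes=(3, 8), n_repeats=20, seed=5)
        b = mccv_panel_evaluation(X, labels, panel_sizes=(3, 8), n_repeats=20, seed=5)
        assert a.auc_mean == b.auc_mean
        assert a.accuracy == b.accuracy
        assert a.importance.equals(b.importance)

    def test_oversized_panel_rejected(self):
        X = np.zeros((10, 4)) + np.arange(4)
        labels = np.array(["ALS"] * 5 + ["HC"] * 5)
        with pytest.raises(ValueError, match="panel sizes"):
            mccv_panel_evaluation(X, labels, panel_sizes=(6,))

    def test_ranking_is_computed_on_training_split_only(self):
        """Permuting held-out structure cannot help: with labels shuffled
        the held-out AUC collapses to chance even though individual
        features are strong under their original labels."""
        rng = np.random.default_rng(13)
        labels = np.array(["ALS"] * 30 + ["HC"] * 31)
        X = rng.normal(size=(61, 10))
        X[:, 0] += 3.0 * (labels == "ALS")
        # a single shuffle is conditionally biased on a finite sample, so
        # average over independent shuffles
        means = {3: [], 10: []}
        for rep in range(5):
            shuffled = rng.permutation(labels)
            res = mccv_panel_evaluation(
                X, shuffled, panel_sizes=(3, 10), n_repeats=30, seed=21 + rep
            )
            for k in (3, 10):
                means[k].append(res.auc_mean[k])
        for k in (3, 10):
            assert abs(np.mean(means[k]) - 0.5) < 0.1

    def test_informative_panel_beats_best_univariate(self):
        """A 15-feature panel with discovery-calibrated effect sizes: the
        full-panel held-out AUC exceeds the best single-feature AUC."""
        from csfmark.fixtures import load_paper_fixtures

        table2 = load_paper_fixtures().table2
        confirmed = [
            "APOB", "APP", "CAMK2A", "CHI3L1", "CHIT1", "CLSTN3", "ERAP2",
            "FSTL4", "GPNMB", "JCHAIN", "L1CAM", "NPTX2", "SERPINA1",
            "SERPINA3", "UCHL1",
        ]
        validated = table2[table2["gene_symbol"].isin(confirmed)].drop_duplicates(
            "gene_symbol"
        )
        assert len(validated) == 15
        X, labels = simulate_biomarker_panel(validated, seed=31)
        best_univariate = max(
            roc_auc(X[g].to_numpy(), labels.to_numpy()).auc for g in X.columns
        )
        res = mccv_panel_evaluation(
            X.to_numpy(),
            labels.to_numpy(),
            panel_sizes=(len(X.columns),),
            n_repeats=60,
            seed=31,
            feature_names=list(X.columns),
        )
        assert res.auc_mean[len(X.columns)] > best_univariate
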