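import warnings

import numpy as np
import pytest

import _oracles as oracle
from conftest import make_epochs
from errpkit import errors
from errpkit.dcpm import (
    FEATURE_NAMES,
    ClassTemplates,
    balanced_accuracy,
    canonical_correlations,
    extract_features,
    feature_matrix,
    fit_dcpm,
    fit_dsp,
    fit_feature_classifier,
    fit_templates,
    load_model,
    predict,
    save_model,
    scatter_matrices,
)
from errpkit.io import split_epochs
from errpkit.search import evaluate


def random_epochs(rng, n=40, c=4, s=50, n_err=15):
    labels = ["error"] * n_err + ["correct"] * (n - n_err)
    return make_epochs(rng.standard_normal((n, c, s)), labels)


class TestDsp:
    def residual(self, epochs, dsp):
        s_b, s_w = scatter_matrices(epochs)
        c = s_b.shape[0]
        reg = s_w + dsp.shrinkage * (np.trace(s_w) / c) * np.eye(c)
        res = s_b @ dsp.W - reg @ dsp.W @ np.diag(dsp.eigenvalues)
        return np.linalg.norm(res, axis=0), np.linalg.norm(s_b @ dsp.W, axis=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_generalized_eigen_residual(self, seed):
        rng = np.random.default_rng(seed)
        epochs = random_epochs(rng)
        dsp = fit_dsp(epochs, d=3, shrinkage=0.05)
        res, scale = self.residual(epochs, dsp)
        assert np.all(res <= 1e-6 * np.maximum(scale, 1e-12))
        assert np.all(np.diff(dsp.eigenvalues) <= 1e-12)  # descending

    def test_single_channel_class_difference_dominates_first_filter(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            data = rng.standard_normal((60, 4, 50))
            labels = ["error"] * 20 + ["correct"] * 40
            data[:20, 2] += 1.5
            epochs = make_epochs(data, labels)
            dsp = fit_dsp(epochs, d=1)
            hits += int(np.abs(dsp.W[:, 0]).argmax() == 2)
        assert hits == 10

    def test_identical_class_means_give_zero_eigenvalues(self, rng):
        x = rng.standard_normal((10, 3, 20))
        data = np.concatenate([x, x])
        epochs = make_epochs(data, ["error"] * 10 + ["correct"] * 10)
        dsp = fit_dsp(epochs, d=3)
        assert np.all(dsp.eigenvalues < 1e-10)

    def test_full_dimension_and_errors(self, rng):
        epochs = random_epochs(rng)
        dsp = fit_dsp(epochs, d=4, shrinkage=0.0)
        assert np.linalg.matrix_rank(dsp.W) == 4
        with pytest.raises(errors.DimensionError):
            fit_dsp(epochs, d=5)
        with pytest.raises(errors.EmptyClassError):
            fit_dsp(make_epochs(rng.standard_normal((4, 3, 10)), ["error"] * 4), d=2)


class TestFeatures:
    def build(self, rng, c=5, s=60, d=2):
        epochs = random_epochs(rng, n=30, c=c, s=s, n_err=12)
        dsp = fit_dsp(epochs, d=d)
        templates = fit_templates(epochs)
        return epochs, dsp, templates

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_definitions(self, seed):
        rng = np.random.default_rng(seed)
        epochs, dsp, templates = self.build(rng)
        trial = rng.standard_normal((5, 60))
        got = extract_features(trial, dsp, templates)
        want = oracle.dcpm_features(trial, dsp.W, templates.template_error, templates.template_correct)
        for k in FEATURE_NAMES:
            assert got[k] == pytest.approx(want[k], abs=1e-8)

    def test_batch_matches_single_trial_path(self, rng):
        epochs, dsp, templates = self.build(rng)
        batch = feature_matrix(epochs.data[:5], dsp, templates, FEATURE_NAMES)
        for i in range(5):
            single = extract_features(epochs.data[i], dsp, templates)
            assert np.allclose(batch[i], [single[k] for k in FEATURE_NAMES], atol=1e-10)

    def test_self_match_favours_own_template(self, rng):
        _, dsp, templates = self.build(rng)
        got = extract_features(templates.template_error, dsp, templates)
        assert got["corr"] > 0 and got["dist"] > 0 and got["cca"] >= 0

    def test_midpoint_of_mirror_templates_is_equidistant(self, rng):
        _, dsp, _ = self.build(rng)
        t = np.random.default_rng(5).standard_normal((5, 60))
        templates = ClassTemplates(template_error=t, template_correct=-t)
        got = extract_features((templates.template_error + templates.template_correct) / 2, dsp, templates, ["dist"])
        assert got["dist"] == pytest.approx(0.0, abs=1e-8)

    def test_invariant_to_common_positive_rescaling(self, rng):
        epochs, dsp, templates = self.build(rng)
        trial = rng.standard_normal((5, 60))
        a = extract_features(trial, dsp, templates)
        scaled = ClassTemplates(3.7 * templates.template_error, 3.7 * templates.template_correct)
        b = extract_features(3.7 * trial, dsp, scaled)
        for k in FEATURE_NAMES:
            assert a[k] == pytest.approx(b[k], abs=1e-10)

    def test_feature_ranges(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            epochs, dsp, templates = self.build(r)
            got = extract_features(r.standard_normal((5, 60)), dsp, templates)
            assert -2.0 <= got["corr"] <= 2.0
            assert -1.0 <= got["cca"] <= 1.0

    def test_label_swap_negates_features(self, rng):
        epochs, dsp, templates = self.build(rng)
        swapped = ClassTemplates(templates.template_correct, templates.template_error)
        trial = rng.standard_normal((5, 60))
        a = extract_features(trial, dsp, templates)
        b = extract_features(trial, dsp, swapped)
        for k in FEATURE_NAMES:
            assert a[k] == pytest.approx(-b[k], abs=0.0)  # exact antisymmetry

    def test_cca_matches_covariance_whitening_oracle(self, rng):
        y = rng.standard_normal((3, 80))
        t = rng.standard_normal((3, 80))
        assert np.allclose(sorted(canonical_correlations(y, t)), sorted(oracle.canonical_correlations(y, t)), atol=1e-8)


class TestFeatureClassifier:
    def test_perfectly_separated_feature(self):
        f = np.array([[2.0], [3.0], [2.5], [-2.0], [-3.0], [-2.5]])
        labels = np.array(["error"] * 3 + ["correct"] * 3, dtype=object)
        clf = fit_feature_classifier(f, labels, ["corr"])
        pred = np.where(clf.score(f[:, :1]) > 0, "error", "correct")
        assert oracle.balanced_accuracy(labels, pred) == 1.0

    def test_shuffled_labels_give_chance(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal((2000, 2))
        labels = np.array(["error"] * 1000 + ["correct"] * 1000, dtype=object)
        rng.shuffle(labels)
        clf = fit_feature_classifier(f, labels, ["corr", "dist"])
        pred = np.where(clf.score(f) > 0, "error", "correct")
        assert abs(oracle.balanced_accuracy(labels, pred) - 0.5) < 0.1

    def test_recovers_closed_form_gaussian_direction(self):
        rng = np.random.default_rng(8)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        chol = np.linalg.cholesky(cov)
        mu = np.array([0.8, -0.4])
        pos = rng.standard_normal((2000, 2)) @ chol.T + mu
        neg = rng.standard_normal((2000, 2)) @ chol.T
        f = np.vstack([pos, neg])
        labels = np.array(["error"] * 2000 + ["correct"] * 2000, dtype=object)
        mean, scale = f.mean(axis=0), f.std(axis=0)
        clf = fit_feature_classifier(f, labels, ["corr", "dist"])
        # undo standardisation to compare with the raw-space direction
        w_raw = clf.weights / scale
        expect = np.linalg.solve(cov, mu)
        w_raw /= np.linalg.norm(w_raw)
        expect /= np.linalg.norm(expect)
        assert np.allclose(w_raw, expect, rtol=0.05, atol=0.02)

    def test_zero_variance_feature_dropped(self):
        f = np.column_stack([np.ones(6), [2.0, 3, 2.5, -2, -3, -2.5]])
        labels = np.array(["error"] * 3 + ["correct"] * 3, dtype=object)
        with pytest.warns(UserWarning):
            clf = fit_feature_classifier(f, labels, ["corr", "dist"])
        assert clf.feature_names == ["dist"]

    def test_all_degenerate_rejected(self):
        f = np.ones((6, 2))
        labels = np.array(["error"] * 3 + ["correct"] * 3, dtype=object)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(errors.DegenerateFeaturesError):
                fit_feature_classifier(f, labels, ["corr", "dist"])


class TestBalancedAccuracy:
    def test_all_correct(self):
        assert balanced_accuracy(["error", "correct"], ["error", "correct"]) == 1.0

    def test_hand_case(self):
        true = ["a"] * 5 + ["b"] * 5
        pred = ["a"] * 3 + ["b"] * 2 + ["b"] * 4 + ["a"]
        assert balanced_accuracy(true, pred) == pytest.approx(0.7)

    def test_balanced_classes_equal_plain_accuracy(self, rng):
        true = np.array(["error"] * 50 + ["correct"] * 50, dtype=object)
        pred = np.array(rng.choice(["error", "correct"], 100), dtype=object)
        assert balanced_accuracy(true, pred) == pytest.approx(np.mean(true == pred))

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            true = rng.choice(["error", "correct"], 30)
            pred = rng.choice(["error", "correct"], 30)
            if len(set(true)) < 2:
                continue
            assert balanced_accuracy(true, pred) == pytest.approx(oracle.balanced_accuracy(true, pred))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([], [])


class TestModel:
    def test_templates_replicated_are_recognised(self, two_class_epochs):
        model = fit_dcpm(two_class_epochs, d=2)
        reps = np.stack([model.templates.template_error] * 3 + [model.templates.template_correct] * 3)
        eps = make_epochs(reps, ["error"] * 3 + ["correct"] * 3, channel_names=two_class_epochs.channel_names)
        labels, _ = predict(model, eps)
        assert list(labels) == ["error"] * 3 + ["correct"] * 3

    def test_prediction_is_deterministic(self, two_class_epochs):
        model = fit_dcpm(two_class_epochs, d=2)
        l1, s1 = predict(model, two_class_epochs)
        l2, s2 = predict(model, two_class_epochs)
        assert np.array_equal(l1, l2) and np.array_equal(s1, s2)

    def test_missing_channel_named_in_error(self, two_class_epochs):
        model = fit_dcpm(two_class_epochs, d=2)
        reduced = two_class_epochs.select_channels(["ch0", "ch1", "ch2", "ch3"])
        with pytest.raises(errors.ChannelMismatchError, match="ch4"):
            predict(model, reduced)

    def test_save_load_round_trip_preserves_predictions(self, tmp_path, two_class_epochs):
        model = fit_dcpm(two_class_epochs, d=2)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        l1, s1 = predict(model, two_class_epochs)
        l2, s2 = predict(back, two_class_epochs)
        assert np.array_equal(l1, l2)
        assert np.allclose(s1, s2)

    def test_high_snr_synthetic_subject_classified(self, conditioned_subject):
        train, test = split_epochs(conditioned_subject, 0.4, seed=0)
        model = fit_dcpm(train, d=3)
        report = evaluate(model, test)
        assert report["balanced_accuracy"] >= 0.85
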