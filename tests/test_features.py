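import numpy as np
import pytest

from ocuclean.core_io import Segment
from ocuclean.features import (
    FeatureVector,
    _lz_complexity,
    classify_segments,
    extract_features,
    mrmr_select,
    nonlinear_features,
    psd_features,
    time_features,
    train_classifier,
    load_classifier,
    save_classifier,
)
from ocuclean.synth import gen_labeled_corpus

from conftest import make_segment


class TestTimeFeatures:
    def test_symmetric_sequence_zero_skewness(self):
        fv = time_features(make_segment([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert dict(zip(fv.names, fv.values))["skewness"] == pytest.approx(0.0)

    def test_white_noise_activity_is_variance(self):
        x = np.random.default_rng(0).standard_normal(4000)
        fv = dict(zip(*[(f.names, f.values) for f in [time_features(make_segment(x))]][0]))
        assert fv["hjorth_activity"] == pytest.approx(1.0, abs=0.1)

    def test_sine_mobility_analytic(self, fs):
        t = np.arange(2000) / fs
        fv = time_features(make_segment(np.sin(2 * np.pi * 5 * t)))
        got = dict(zip(fv.names, fv.values))["hjorth_mobility"]
        assert got == pytest.approx(2 * np.sin(np.pi * 5 / fs), rel=1e-2)

    def test_constant_conventions(self):
        fv = time_features(make_segment(np.full(100, 2.0)))
        d = dict(zip(fv.names, fv.values))
        assert d["skewness"] == 0.0 and d["kurtosis"] == 0.0
        assert d["hjorth_activity"] == 0.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            time_features(make_segment([1.0, 2.0]))


class TestPSDFeatures:
    def test_pure_alpha_tone(self, fs):
        t = np.arange(2000) / fs
        fv = psd_features(make_segment(np.sin(2 * np.pi * 10 * t)))
        d = dict(zip(fv.names, fv.values))
        assert d["psd_alpha_rel"] > 0.9

    def test_zero_signal_all_zero(self):
        fv = psd_features(make_segment(np.zeros(2000)))
        assert np.all(fv.values == 0.0)

    def test_delta_tone_dominates(self, fs):
        t = np.arange(2000) / fs
        fv = psd_features(make_segment(np.sin(2 * np.pi * 2 * t)))
        d = dict(zip(fv.names, fv.values))
        assert d["psd_delta_rel"] > 0.8
        assert d["psd_beta_rel"] < 0.01

    def test_relative_powers_sum_below_one(self, white_noise):
        fv = psd_features(make_segment(white_noise))
        d = dict(zip(fv.names, fv.values))
        rel = sum(v for k, v in d.items() if k.endswith("_rel"))
        assert 0.0 < rel <= 1.0

    def test_band_above_nyquist_raises(self, white_noise):
        with pytest.raises(ValueError, match="Nyquist"):
            psd_features(make_segment(white_noise), bands={"hf": (90.0, 150.0)})


class TestNonlinearFeatures:
    def test_constant_signal_conventions(self):
        fv = nonlinear_features(make_segment(np.full(2000, 1.5)))
        d = dict(zip(fv.names, fv.values))
        assert d["shannon_entropy"] == pytest.approx(0.0)
        assert d["katz_fd"] == pytest.approx(1.0)
        assert d["hurst"] == 0.5

    def test_white_noise_hurst_near_half(self):
        x = np.random.default_rng(1).standard_normal(2000)
        d = dict(zip(*[(fv.names, fv.values) for fv in [nonlinear_features(make_segment(x))]][0]))
        assert d["hurst"] == pytest.approx(0.5, abs=0.12)

    def test_lz_periodic_below_random(self):
        rng = np.random.default_rng(2)
        periodic = np.tile([0.0, 1.0, 1.0, 0.0], 500)
        random = rng.random(2000)
        assert _lz_complexity(periodic) < _lz_complexity(random)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            nonlinear_features(make_segment(np.zeros(50)))

    def test_extraction_deterministic(self, white_noise):
        a = extract_features(make_segment(white_noise))
        b = extract_features(make_segment(white_noise))
        np.testing.assert_array_equal(a.values, b.values)
        assert a.names == b.names


class TestFeatureVector:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureVector(["a", "a"], [1.0, 2.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureVector(["a"], [np.inf])

    def test_concatenation(self):
        fv = FeatureVector(["a"], [1.0]) + FeatureVector(["b"], [2.0])
        assert fv.names == ["a", "b"]


class TestMRMR:
    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(3)
        y = (rng.random(300) < 0.5).astype(int)
        X = rng.standard_normal((300, 6))
        X[:, 4] = y
        assert mrmr_select(X, y, 3)[0] == 4

    def test_redundant_duplicate_penalized(self):
        """With a strong feature duplicated, its copy ranks below an
        independent weaker feature (oracle: direct MI computation)."""
        rng = np.random.default_rng(4)
        n = 600
        y = (rng.random(n) < 0.5).astype(int)
        strong = y + 0.2 * rng.standard_normal(n)
        weak = np.where(rng.random(n) < 0.75, y, 1 - y) + 0.2 * rng.standard_normal(n)
        X = np.column_stack([strong, strong.copy(), weak, rng.standard_normal(n)])
        order = mrmr_select(X, y, 4)
        assert order[0] in (0, 1)
        dup = 1 if order[0] == 0 else 0
        assert order.index(2) < order.index(dup)

    def test_full_selection_is_permutation(self):
        rng = np.random.default_rng(5)
        y = (rng.random(100) < 0.5).astype(int)
        X = rng.standard_normal((100, 5))
        assert sorted(mrmr_select(X, y, 5)) == [0, 1, 2, 3, 4]

    def test_permutation_invariance_of_ranking(self):
        rng = np.random.default_rng(6)
        y = (rng.random(400) < 0.5).astype(int)
        X = rng.standard_normal((400, 5))
        X[:, 2] = y + 0.3 * rng.standard_normal(400)
        perm = [3, 0, 2, 4, 1]
        sel_a = mrmr_select(X, y, 5)
        sel_b = mrmr_select(X[:, perm], y, 5)
        assert [perm[j] for j in sel_b] == sel_a

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mrmr_select(np.zeros((20, 3)), np.zeros(20), 2)

    def test_n_keep_too_large_raises(self):
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError):
            mrmr_select(np.zeros((20, 3)), y, 4)


def _gaussian_cloud_segments(n, seed, shift):
    """Segments whose feature clouds are linearly separable by amplitude."""
    rng = np.random.default_rng(seed)
    segs = []
    for _ in range(n):
        segs.append(make_segment(shift * rng.standard_normal(2000)))
    return segs


class TestClassifier:
    def test_separable_clouds_high_holdout_accuracy(self):
        a = _gaussian_cloud_segments(30, 7, 1.0)
        b = _gaussian_cloud_segments(30, 8, 6.0)
        train = a[:20] + b[:20]
        test = a[20:] + b[20:]
        clf = train_classifier(train, [0] * 20 + [1] * 20, n_keep=5)
        pred = classify_segments(clf, test)
        acc = (pred == np.array([0] * 10 + [1] * 10)).mean()
        assert acc >= 0.95

    def test_training_set_accuracy_perfect_on_separable(self):
        a = _gaussian_cloud_segments(12, 9, 1.0)
        b = _gaussian_cloud_segments(12, 10, 6.0)
        labels = [0] * 12 + [1] * 12
        clf = train_classifier(a + b, labels, n_keep=5)
        assert (classify_segments(clf, a + b) == labels).all()

    def test_single_class_raises(self):
        segs = _gaussian_cloud_segments(20, 11, 1.0)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(segs, [0] * 20)

    def test_too_few_per_class_raises(self):
        segs = _gaussian_cloud_segments(12, 12, 1.0)
        with pytest.raises(ValueError, match="at least 10"):
            train_classifier(segs, [0] * 5 + [1] * 7)

    def test_empty_segment_list_predicts_empty(self):
        a = _gaussian_cloud_segments(10, 13, 1.0)
        b = _gaussian_cloud_segments(10, 14, 6.0)
        clf = train_classifier(a + b, [0] * 10 + [1] * 10, n_keep=3)
        assert classify_segments(clf, []).size == 0

    def test_untrained_type_raises(self):
        with pytest.raises(TypeError):
            classify_segments(object(), [])

    def test_short_segment_error_propagates(self):
        a = _gaussian_cloud_segments(10, 15, 1.0)
        b = _gaussian_cloud_segments(10, 16, 6.0)
        clf = train_classifier(a + b, [0] * 10 + [1] * 10, n_keep=3)
        with pytest.raises(ValueError):
            classify_segments(clf, [make_segment(np.zeros(10))])

    def test_decision_invariant_to_affine_feature_scaling(self):
        """Rescaling the raw signal amplitude of the whole corpus is
        absorbed by standardization: predictions are unchanged."""
        rng = np.random.default_rng(17)
        corpus = list(gen_labeled_corpus(15, duration_s=5, seed=18))
        segs = [make_segment(c[0]) for c in corpus]
        labels = [c[1] for c in corpus]
        scaled = [make_segment(250.0 * c[0]) for c in corpus]
        clf1 = train_classifier(segs, labels, n_keep=8)
        clf2 = train_classifier(scaled, labels, n_keep=8)
        p1 = classify_segments(clf1, segs)
        p2 = classify_segments(clf2, scaled)
        np.testing.assert_array_equal(p1, p2)

    def test_save_load_roundtrip(self, tmp_path):
        a = _gaussian_cloud_segments(10, 19, 1.0)
        b = _gaussian_cloud_segments(10, 20, 6.0)
        clf = train_classifier(a + b, [0] * 10 + [1] * 10, n_keep=3)
        p = tmp_path / "model.joblib"
        save_classifier(clf, p)
        back = load_classifier(p)
        np.testing.assert_array_equal(
            classify_segments(back, a[:3]), classify_segments(clf, a[:3])
        )
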