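import numpy as np
import pytest

from vemseg.classifier import (GaussianClassifierModel, ProbabilityMap,
                               argmax_labeling, fit_pca, load_model,
                               predict_proba, save_model, train)
from vemseg.errors import TrainingError
from vemseg.features import FeatureStack, ScaleSet
from vemseg.volumes import LabelVolume


def feature_stack(values: np.ndarray) -> FeatureStack:
    """Wrap a (X, Y, Z, 4) array as a single-scale F2D feature stack."""
    return FeatureStack(np.asarray(values, dtype=np.float64), ScaleSet(1.0, 1), "f2d")


def axis_cloud(variance_shares) -> np.ndarray:
    """A tiny dataset whose per-axis variance shares are exact: for each
    axis i it contains +-sqrt(share_i) * e_i."""
    shares = np.asarray(variance_shares, dtype=np.float64)
    k = shares.size
    rows = []
    for i, s in enumerate(shares):
        e = np.zeros(k)
        e[i] = np.sqrt(s)
        rows += [e, -e]
    return np.asarray(rows)


class TestFitPCA:
    def test_single_informative_axis(self):
        basis = fit_pca(axis_cloud([1.0, 0.0]), 0.99)
        assert basis.n_components == 1

    def test_cumulative_variance_rule(self):
        # shares (0.90, 0.095, 0.005): two axes reach 0.995 >= 0.99
        basis = fit_pca(axis_cloud([0.90, 0.095, 0.005]), 0.99)
        assert basis.n_components == 2

    def test_isotropic_cloud_keeps_all_axes(self):
        basis = fit_pca(axis_cloud([1 / 3, 1 / 3, 1 / 3]), 0.99)
        assert basis.n_components == 3

    def test_zero_variance_degenerates_to_constant(self):
        basis = fit_pca(np.full((10, 3), 2.5), 0.99)
        assert basis.n_components == 1
        proj = basis.project(np.full((4, 3), 2.5))
        np.testing.assert_allclose(proj, 0.0, atol=1e-12)

    def test_basis_orthonormal(self):
        rng = np.random.default_rng(0)
        basis = fit_pca(rng.random((200, 5)), 0.99)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(basis.n_components), atol=1e-10)


def two_class_volume(n0, n1, rng, mu0=0.0, mu1=10.0):
    """1D informative channel: class 1 ~ N(mu0, 1), class 2 ~ N(mu1, 1)."""
    n = n0 + n1
    x = np.zeros((n, 1, 1, 4))
    x[:n0, 0, 0, 0] = rng.normal(mu0, 1.0, n0)
    x[n0:, 0, 0, 0] = rng.normal(mu1, 1.0, n1)
    labels = np.concatenate([np.full(n0, 1), np.full(n1, 2)]).reshape(n, 1, 1)
    table = {0: "unlabeled", 1: "background", 2: "synapse"}
    return feature_stack(x), LabelVolume(labels.astype(np.int64), table)


class TestTrain:
    def test_priors_are_label_frequencies(self):
        rng = np.random.default_rng(1)
        feats, labels = two_class_volume(30, 10, rng)
        model = train(feats, labels)
        assert model.priors[1] == pytest.approx(0.75)
        assert model.priors[2] == pytest.approx(0.25)

    def test_unlabeled_voxels_ignored(self):
        rng = np.random.default_rng(2)
        feats, labels = two_class_volume(20, 20, rng)
        masked = labels.labels.copy()
        masked[:10] = 0
        model = train(feats, LabelVolume(masked, labels.label_table))
        assert model.priors[1] == pytest.approx(10 / 30)

    def test_degenerate_class_gets_floor_covariance(self):
        x = np.zeros((20, 1, 1, 4))
        x[:, 0, 0, 0] = np.where(np.arange(20) < 10, 1.0, 5.0)
        labels = np.where(np.arange(20) < 10, 1, 2).reshape(20, 1, 1)
        model = train(
            feature_stack(x),
            LabelVolume(labels.astype(np.int64), {0: "u", 1: "a", 2: "b"}),
        )
        for lab in (1, 2):
            cov = model.covariances[lab]
            assert np.all(np.linalg.eigvalsh(cov) > 0)
            np.testing.assert_allclose(cov, np.diag(np.diag(cov)), atol=1e-12)

    def test_too_few_samples_raises_naming_label(self):
        x = np.zeros((5, 1, 1, 4))
        labels = np.array([1, 1, 1, 1, 2]).reshape(5, 1, 1)
        with pytest.raises(TrainingError, match="2"):
            train(feature_stack(x), LabelVolume(labels, {0: "u", 1: "a", 2: "b"}))

    def test_parameter_recovery_on_synthetic_gaussians(self):
        rng = np.random.default_rng(3)
        feats, labels = two_class_volume(10_000, 10_000, rng)
        model = train(feats, labels)
        # map the projected class means back into feature space
        for lab, target in ((1, 0.0), (2, 10.0)):
            recovered = model.pca.mean + model.means[lab] @ model.pca.components
            assert recovered[0] == pytest.approx(target, abs=0.1)
            # unit generating variance recovered within 5 %
            var = model.covariances[lab][0, 0]
            assert var == pytest.approx(1.0, rel=0.05)
        assert model.priors[1] == pytest.approx(0.5, abs=1e-12)


class TestPredict:
    def test_posteriors_normalized(self):
        rng = np.random.default_rng(4)
        feats, labels = two_class_volume(500, 500, rng)
        model = train(feats, labels)
        probmap = predict_proba(model, feats)
        np.testing.assert_allclose(probmap.probs.sum(axis=-1), 1.0, atol=1e-12)

    def test_identical_classes_return_priors(self):
        basis_x = np.zeros((10, 1, 1, 4))
        model = GaussianClassifierModel(
            pca=fit_pca(np.random.default_rng(5).random((50, 4))),
            labels=[1, 2],
            means={1: None, 2: None},
            covariances={1: None, 2: None},
            priors={1: 0.9, 2: 0.1},
            label_table={1: "a", 2: "b"},
            n_features=4,
        )
        k = model.pca.n_components
        for lab in (1, 2):
            model.means[lab] = np.zeros(k)
            model.covariances[lab] = np.eye(k)
        probmap = predict_proba(model, feature_stack(basis_x))
        np.testing.assert_allclose(probmap.probs[..., 0], 0.9, atol=1e-12)
        np.testing.assert_allclose(probmap.probs[..., 1], 0.1, atol=1e-12)

    def test_equidistant_point_splits_evenly(self):
        rng = np.random.default_rng(6)
        feats, labels = two_class_volume(50_000, 50_000, rng)
        model = train(feats, labels)
        # force the exact generating parameters to probe the Bayes rule
        mu0 = model.pca.project(np.array([[0.0, 0, 0, 0]]))[0]
        mu1 = model.pca.project(np.array([[10.0, 0, 0, 0]]))[0]
        model.means[1], model.means[2] = mu0, mu1
        k = model.pca.n_components
        model.covariances[1] = model.covariances[2] = np.eye(k)
        model.priors = {1: 0.5, 2: 0.5}
        model._chol.clear()
        x5 = np.zeros((1, 1, 1, 4))
        x5[0, 0, 0, 0] = 5.0
        probmap = predict_proba(model, feature_stack(x5))
        np.testing.assert_allclose(probmap.probs[0, 0, 0], [0.5, 0.5], atol=1e-9)

    def test_extreme_features_stay_finite_and_normalized(self):
        rng = np.random.default_rng(7)
        feats, labels = two_class_volume(100, 100, rng)
        model = train(feats, labels)
        far = np.zeros((3, 1, 1, 4))
        far[:, 0, 0, 0] = [1e3, -1e3, 2e3]  # hundreds of sigma away
        probmap = predict_proba(model, feature_stack(far))
        assert np.isfinite(probmap.probs).all()
        np.testing.assert_allclose(probmap.probs.sum(axis=-1), 1.0, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        feats, labels = two_class_volume(50, 50, rng)
        model = train(feats, labels)
        wrong = FeatureStack(np.zeros((2, 2, 2, 8)), ScaleSet(1.0, 2), "f2d")
        with pytest.raises(ValueError, match="channels"):
            predict_proba(model, wrong)


class TestArgmax:
    def _probmap(self, probs):
        probs = np.asarray(probs, dtype=np.float64)
        ids = tuple(range(1, probs.shape[-1] + 1))
        return ProbabilityMap(probs, ids, {i: f"l{i}" for i in ids})

    def test_picks_maximal_posterior(self):
        pm = self._probmap([[[[0.2, 0.7, 0.1]]]])
        assert argmax_labeling(pm).labels[0, 0, 0] == 2

    def test_exact_tie_goes_to_lowest_id(self):
        pm = self._probmap([[[[0.5, 0.5]]]])
        assert argmax_labeling(pm).labels[0, 0, 0] == 1

    def test_matches_per_voxel_oracle(self):
        rng = np.random.default_rng(9)
        raw = rng.dirichlet(np.ones(3), size=(8, 8, 2))
        pm = self._probmap(raw)
        out = argmax_labeling(pm).labels
        for x in range(8):
            for y in range(8):
                for z in range(2):
                    assert out[x, y, z] == 1 + int(np.argmax(raw[x, y, z]))


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(10)
        feats, labels = two_class_volume(500, 500, rng)
        model = train(feats, labels)
        save_model(tmp_path / "model.npz", model)
        back = load_model(tmp_path / "model.npz")
        a = predict_proba(model, feats).probs
        b = predict_proba(back, feats).probs
        np.testing.assert_array_equal(a, b)
        assert back.label_table == dict(model.label_table)
        assert back.scale_set == model.scale_set
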