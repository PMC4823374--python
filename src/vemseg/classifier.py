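"""PCA-reduced Gaussian Bayes voxel classifier.

The class-conditional density of the (PCA-projected) feature vector is
modeled as a multivariate Gaussian per label, with the label prior taken
from labeled-voxel frequencies.  The posterior

    P(y | f) ~ N(f; mu_y, Sigma_y) * P(y)

is evaluated in log space with a cached Cholesky factor per label and
normalized with log-sum-exp, so densities hundreds of sigma from the
mean still produce finite, normalized posteriors.

PCA is fitted on the cloud of all feature vectors of the training stack
(uniformly subsampled to at most ``max_pca_samples`` with a fixed seed)
and keeps the smallest number of leading axes whose cumulative explained
variance reaches ``variance_to_retain`` (default 99 %).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.decomposition import PCA

from .errors import TrainingError
from .features import FeatureStack, ScaleSet
from .volumes import LabelVolume

_COV_EPS = 1e-6  # relative covariance regularization floor


@dataclass(frozen=True)
class PCABasis:
    """Centering vector plus orthonormal projection basis (k' x k)."""

    mean: np.ndarray
    components: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean) @ self.components.T


@dataclass
class GaussianClassifierModel:
    """Fitted PCA basis and per-label Gaussian parameters."""

    pca: PCABasis
    labels: list[int]
    means: dict[int, np.ndarray]
    covariances: dict[int, np.ndarray]
    priors: dict[int, float]
    label_table: Mapping[int, str]
    n_features: int
    extractor_tag: str = "f2d"
    scale_set: ScaleSet | None = None
    _chol: dict[int, tuple] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.priors.values())
        if not np.isclose(total, 1.0):
            raise TrainingError(f"label priors must sum to 1, got {total}")

    def _cholesky(self, label: int):
        if label not in self._chol:
            self._chol[label] = cho_factor(self.covariances[label], lower=True)
        return self._chol[label]

    def log_density(self, label: int, projected: np.ndarray) -> np.ndarray:
        """Gaussian log-density of already-projected features, (N,) output."""
        c, lower = self._cholesky(label)
        diff = projected - self.means[label]
        solved = cho_solve((c, lower), diff.T)
        maha = np.einsum("ij,ji->i", diff, solved)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        k = self.pca.n_components
        return -0.5 * (maha + logdet + k * np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel posterior over labels, shape (X, Y, Z, L); sums to 1."""

    probs: np.ndarray
    label_ids: tuple[int, ...]
    label_table: Mapping[int, str]

    def __post_init__(self) -> None:
        if self.probs.shape[-1] != len(self.label_ids):
            raise ValueError("probability channels do not match label ids")
        if list(self.label_ids) != sorted(self.label_ids):
            raise ValueError("label ids must be sorted ascending")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[:3]


def fit_pca(
    features: np.ndarray,
    variance_to_retain: float = 0.99,
) -> PCABasis:
    """Fit PCA keeping the smallest k' with cumulative variance >= target.

    Zero-variance (constant) data degenerates to k' = 1 with a constant
    projection.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("features must be a (n_samples, k) matrix")
    if x.shape[0] < 2:
        raise TrainingError("PCA needs at least 2 samples")
    if not 0 < variance_to_retain <= 1:
        raise ValueError(f"variance_to_retain must be in (0, 1], got {variance_to_retain}")
    total_var = float(np.var(x, axis=0).sum())
    if total_var <= 0:
        return PCABasis(mean=x.mean(axis=0), components=np.eye(1, x.shape[1]))
    pca = PCA(n_components=min(x.shape))
    pca.fit(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_to_retain - 1e-12) + 1)
    k = min(k, pca.components_.shape[0])
    return PCABasis(mean=pca.mean_, components=pca.components_[:k])


def _regularized_covariance(samples: np.ndarray) -> np.ndarray:
    k = samples.shape[1]
    if samples.shape[0] > 1:
        cov = np.cov(samples, rowvar=False).reshape(k, k)
    else:
        cov = np.zeros((k, k))
    tr = float(np.trace(cov))
    floor = _COV_EPS * (tr / k if tr > 0 else 1.0)
    return cov + floor * np.eye(k)


def train(
    features: FeatureStack,
    training_labels: LabelVolume,
    variance_to_retain: float = 0.99,
    max_pca_samples: int = 1_000_000,
    seed: int = 0,
) -> GaussianClassifierModel:
    """Estimate the PCA basis, per-label Gaussians and priors from scribbles.

    Voxels with label id 0 are ignored.  Every remaining label needs at
    least 2 labeled voxels for a covariance estimate.
    """
    if features.values.shape[:3] != training_labels.shape:
        raise TrainingError(
            f"feature grid {features.values.shape[:3]} does not match "
            f"label grid {training_labels.shape}"
        )
    x = features.matrix()
    y = training_labels.labels.ravel()

    pool = x
    if pool.shape[0] > max_pca_samples:
        rng = np.random.default_rng(seed)
        pick = rng.choice(pool.shape[0], size=max_pca_samples, replace=False)
        pool = pool[pick]
    pca = fit_pca(pool, variance_to_retain)

    labels = sorted(int(v) for v in np.unique(y) if v != 0)
    if not labels:
        raise TrainingError("no labeled voxels in training volume")
    means, covs, counts = {}, {}, {}
    for lab in labels:
        mask = y == lab
        n = int(mask.sum())
        if n < 2:
            raise TrainingError(
                f"label {lab} ({training_labels.label_table.get(lab, '?')}) has {n} "
                "labeled voxel(s); at least 2 are required"
            )
        proj = pca.project(x[mask])
        means[lab] = proj.mean(axis=0)
        covs[lab] = _regularized_covariance(proj)
        counts[lab] = n
    total = sum(counts.values())
    priors = {lab: counts[lab] / total for lab in labels}
    return GaussianClassifierModel(
        pca=pca,
        labels=labels,
        means=means,
        covariances=covs,
        priors=priors,
        label_table=dict(training_labels.label_table),
        n_features=x.shape[1],
        extractor_tag=features.extractor_tag,
        scale_set=features.scale_set,
    )


def predict_proba(model: GaussianClassifierModel, features: FeatureStack) -> ProbabilityMap:
    """Voxel-wise posterior over the model's labels (normalized to 1)."""
    if features.values.shape[-1] != model.n_features:
        raise ValueError(
            f"model was trained on {model.n_features} channels but features "
            f"have {features.values.shape[-1]}"
        )
    shape = features.values.shape[:3]
    proj = model.pca.project(features.matrix())
    logpost = np.empty((proj.shape[0], len(model.labels)))
    for j, lab in enumerate(model.labels):
        logpost[:, j] = model.log_density(lab, proj) + np.log(model.priors[lab])
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    probs = np.exp(logpost).reshape(shape + (len(model.labels),))
    return ProbabilityMap(
        probs=probs,
        label_ids=tuple(model.labels),
        label_table=dict(model.label_table),
    )


def argmax_labeling(probmap: ProbabilityMap) -> LabelVolume:
    """Per-voxel label with maximal posterior; ties go to the lowest id."""
    idx = np.argmax(probmap.probs, axis=-1)  # first max = lowest id (ids sorted)
    ids = np.asarray(probmap.label_ids)
    table = {0: "unlabeled", **{int(i): probmap.label_table.get(int(i), f"label_{int(i)}")
                                for i in probmap.label_ids}}
    return LabelVolume(labels=ids[idx], label_table=table)


# ---------------------------------------------------------------------------
# Serialization: one portable .npz holding PCA, Gaussians, priors and metadata
# ---------------------------------------------------------------------------

def save_model(path: str | Path, model: GaussianClassifierModel) -> None:
    meta = {
        "labels": model.labels,
        "priors": {str(k): v for k, v in model.priors.items()},
        "label_table": {str(k): v for k, v in model.label_table.items()},
        "n_features": model.n_features,
        "extractor_tag": model.extractor_tag,
        "scale_set": (
            {"sigma0": model.scale_set.sigma0, "n": model.scale_set.n}
            if model.scale_set is not None
            else None
        ),
    }
    arrays = {
        "pca_mean": model.pca.mean,
        "pca_components": model.pca.components,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    for lab in model.labels:
        arrays[f"mu_{lab}"] = model.means[lab]
        arrays[f"sigma_{lab}"] = model.covariances[lab]
    np.savez(Path(path), **arrays)


def load_model(path: str | Path) -> GaussianClassifierModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        labels = [int(v) for v in meta["labels"]]
        scale_set = (
            ScaleSet(**meta["scale_set"]) if meta.get("scale_set") is not None else None
        )
        return GaussianClassifierModel(
            pca=PCABasis(mean=data["pca_mean"], components=data["pca_components"]),
            labels=labels,
            means={lab: data[f"mu_{lab}"] for lab in labels},
            covariances={lab: data[f"sigma_{lab}"] for lab in labels},
            priors={int(k): float(v) for k, v in meta["priors"].items()},
            label_table={int(k): v for k, v in meta["label_table"].items()},
            n_features=int(meta["n_features"]),
            extractor_tag=meta["extractor_tag"],
            scale_set=scale_set,
        )
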