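"""PCA feature extraction and Mahalanobis-rule LDA classification.

PCA is always fit on training data only (the caller — the cross-validation
driver — enforces this per fold).  The LDA rule with uniform priors assigns
the class whose mean feature vector is nearest in Mahalanobis distance
under the pooled within-class covariance; ties go to the negative class.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "PCABasis",
    "LDAModel",
    "BinaryTask",
    "TASKS",
    "SingularCovarianceError",
    "pca_fit",
    "pca_project",
    "pca_inverse",
    "lda_fit",
    "lda_predict",
    "make_task",
]


class SingularCovarianceError(ValueError):
    pass


@dataclass
class PCABasis:
    """Training-set mean, orthonormal components (rows), eigenvalues."""

    mean_spectrum: np.ndarray
    components: np.ndarray  # (k, p), rows orthonormal
    eigenvalues: np.ndarray  # (k,), non-increasing

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def pca_fit(spectra: np.ndarray) -> PCABasis:
    """Eigendecomposition of the sample covariance of mean-centered rows.

    Computed via thin SVD of the centered data matrix (identical to the
    covariance eigendecomposition with divisor n-1, but stable for p >> n).
    Sign convention: the largest-magnitude element of each component is
    made positive.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 spectra")
    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = (s**2) / (n - 1)
    components = Vt
    # deterministic sign: force the largest-|.| element of each row positive
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    components = components * signs[:, None]
    return PCABasis(mean, components, eigenvalues)


def pca_project(basis: PCABasis, spectra: np.ndarray, n_pcs: int) -> np.ndarray:
    """Project spectra (vector or matrix) onto the first n_pcs components."""
    if not 1 <= n_pcs <= basis.n_components:
        raise ValueError(
            f"n_pcs={n_pcs} out of range 1..{basis.n_components}"
        )
    X = np.asarray(spectra, dtype=float)
    return (X - basis.mean_spectrum) @ basis.components[:n_pcs].T


def pca_inverse(basis: PCABasis, coefficients: np.ndarray) -> np.ndarray:
    """Reconstruct spectra from projection coefficients."""
    C = np.asarray(coefficients, dtype=float)
    n = C.shape[-1]
    return basis.mean_spectrum + C @ basis.components[:n]


@dataclass
class LDAModel:
    """Two-class LDA: per-class means, pooled covariance, uniform priors."""

    class_labels: tuple  # (negative, positive)
    class_means: np.ndarray  # (2, d)
    pooled_covariance: np.ndarray  # (d, d), includes the ridge term
    priors: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    regularization: float = 0.0
    _cho: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def _factor(self):
        if self._cho is None:
            self._cho = linalg.cho_factor(self.pooled_covariance, lower=True)
        return self._cho


def lda_fit(features: np.ndarray, labels, regularization: float | None = None,
            class_labels: tuple = (0, 1)) -> LDAModel:
    """Fit the shared-covariance Gaussian model.

    ``labels`` must take exactly the two values in ``class_labels``
    (negative first).  Pooled within-class scatter uses divisor n-2; a
    ridge ``regularization`` (default 1e-8 * trace/dim) is added to the
    diagonal to guard near-singular high-PC fits.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if F.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    neg, pos = class_labels
    masks = [y == neg, y == pos]
    counts = [int(m.sum()) for m in masks]
    if min(counts) < 2:
        raise ValueError(
            f"both classes need >= 2 members (got {counts[0]} negative, "
            f"{counts[1]} positive)"
        )
    if counts[0] + counts[1] != y.size:
        raise ValueError("labels contain values outside class_labels")
    n, d = F.shape
    means = np.stack([F[m].mean(axis=0) for m in masks])
    scatter = np.zeros((d, d))
    for m, mu in zip(masks, means):
        R = F[m] - mu
        scatter += R.T @ R
    pooled = scatter / (n - 2)
    if regularization is None:
        regularization = 1e-8 * np.trace(pooled) / d
    cov = pooled + regularization * np.eye(d)
    try:
        linalg.cho_factor(cov, lower=True)
    except linalg.LinAlgError:
        raise SingularCovarianceError(
            f"pooled covariance singular at d={d}, n={n}; increase the "
            "ridge regularization or use fewer PCs"
        ) from None
    return LDAModel(
        class_labels=tuple(class_labels),
        class_means=means,
        pooled_covariance=cov,
        priors=np.array([0.5, 0.5]),
        regularization=float(regularization),
    )


def lda_predict(model: LDAModel, features: np.ndarray):
    """Classify by minimum squared Mahalanobis distance (tie -> negative).

    Returns ``(labels, distances)`` where distances has one column per
    class (negative, positive) of squared Mahalanobis distances.  A single
    feature vector returns a scalar label and a length-2 distance array.
    """
    F = np.asarray(features, dtype=float)
    single = F.ndim == 1
    F = np.atleast_2d(F)
    if F.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {F.shape[1]} != model dimension "
            f"{model.n_features}"
        )
    cho = model._factor()
    d2 = np.empty((F.shape[0], 2))
    for k, mu in enumerate(model.class_means):
        diff = F - mu
        z = linalg.cho_solve(cho, diff.T)
        d2[:, k] = np.einsum("ij,ji->i", diff, z)
    neg, pos = model.class_labels
    labels = np.where(d2[:, 1] < d2[:, 0], pos, neg)  # tie -> negative
    if single:
        return labels[0], d2[0]
    return labels, d2


@dataclass(frozen=True)
class BinaryTask:
    """A binary classification task with the positive-class convention."""

    task_id: str
    negative_classes: tuple
    positive_classes: tuple

    @property
    def positive_class(self) -> str:
        return "+".join(self.positive_classes)

    def membership(self, raw_label: str) -> int | None:
        """0 (negative), 1 (positive), or None (excluded from the task)."""
        if raw_label in self.positive_classes:
            return 1
        if raw_label in self.negative_classes:
            return 0
        return None


# positive-class conventions: abnormal is positive in normal-vs-abnormal,
# MBM-T is positive whenever present as a pure class, NIH/3T3 vs NFC takes
# NIH/3T3 positive.
TASKS = {
    "normal-vs-abnormal": BinaryTask(
        "normal-vs-abnormal", ("NFC",), ("NIH/3T3", "MBM-T")
    ),
    "NIH/3T3-vs-MBM-T": BinaryTask("NIH/3T3-vs-MBM-T", ("NIH/3T3",), ("MBM-T",)),
    "NFC-vs-NIH/3T3": BinaryTask("NFC-vs-NIH/3T3", ("NFC",), ("NIH/3T3",)),
    "NFC-vs-MBM-T": BinaryTask("NFC-vs-MBM-T", ("NFC",), ("MBM-T",)),
}


def make_task(task_id: str) -> BinaryTask:
    """Look up a binary task by id."""
    if task_id not in TASKS:
        raise ValueError(
            f"unknown task {task_id!r}; expected one of {sorted(TASKS)}"
        )
    return TASKS[task_id]


def save_model(model: LDAModel, basis: PCABasis, path, extra: dict | None = None):
    """Serialize an LDA model + PCA basis to a JSON container."""
    payload = {
        "format": "ramandx-model-v1",
        "class_labels": list(model.class_labels),
        "class_means": model.class_means.tolist(),
        "pooled_covariance": model.pooled_covariance.tolist(),
        "priors": model.priors.tolist(),
        "regularization": model.regularization,
        "pca_mean": basis.mean_spectrum.tolist(),
        "pca_components": basis.components.tolist(),
        "pca_eigenvalues": basis.eigenvalues.tolist(),
    }
    if extra:
        payload["extra"] = extra
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "ramandx-model-v1":
        raise ValueError(f"{path}: not a ramandx model container")
    model = LDAModel(
        class_labels=tuple(payload["class_labels"]),
        class_means=np.asarray(payload["class_means"], float),
        pooled_covariance=np.asarray(payload["pooled_covariance"], float),
        priors=np.asarray(payload["priors"], float),
        regularization=float(payload["regularization"]),
    )
    basis = PCABasis(
        np.asarray(payload["pca_mean"], float),
        np.asarray(payload["pca_components"], float),
        np.asarray(payload["pca_eigenvalues"], float),
    )
    return model, basis
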