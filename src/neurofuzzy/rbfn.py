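"""Radial basis function network with Gaussian receptive fields.

Hidden unit ``i`` responds to an input ``x`` with

    w_i = exp(-||x - u_i||^2 / (2 sigma_i^2))

and the per-class score is either the weighted sum  sum_i c_i w_i  or the
normalised weighted average  sum_i c_i w_i / sum_i w_i.  In the weighted-
average mode the network is functionally identical to a zero-order Sugeno
fuzzy system whose rule memberships are the same Gaussian fields and whose
rule outputs are the constants c_i.

Training is the standard two-stage scheme: receptive-field centers by
k-means on the training features, widths from the distance to the nearest
other center, and output weights by linear least squares against one-hot
class targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import ConfigurationError, DegenerateInputError, NeuroFuzzyError
from .membership import WIDTH_FLOOR


def rbf_activation(x, center, sigma: float):
    """Gaussian field response exp(-||x - u||^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise NeuroFuzzyError(f"RBF width must be > 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    d2 = np.sum((x - center) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * sigma * sigma))


@dataclass
class RBFNModel:
    """Centers, widths, output weights and the aggregation mode."""

    centers: np.ndarray   # (H, k)
    widths: np.ndarray    # (H,)
    weights: np.ndarray   # (H, n_classes)
    mode: str = "weighted_average"

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.asarray(self.widths, dtype=float)
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.mode not in ("weighted_sum", "weighted_average"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not (len(self.centers) == len(self.widths) == len(self.weights)):
            raise ConfigurationError("centers, widths and weights must align")
        if np.any(self.widths <= 0):
            raise ConfigurationError("all widths must be > 0")

    @property
    def n_fields(self) -> int:
        return len(self.centers)


def _activations(model: RBFNModel, X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.stack([rbf_activation(X, model.centers[i], float(model.widths[i]))
                     for i in range(model.n_fields)], axis=1)  # (n, H)


def rbfn_output(model: RBFNModel, x):
    """Per-class scores for one input vector (or a batch, row-wise)."""
    single = np.asarray(x).ndim == 1
    W = _activations(model, x)                        # (n, H)
    scores = W @ model.weights                        # (n, n_classes)
    if model.mode == "weighted_average":
        totals = W.sum(axis=1)
        if np.any(totals <= 0) or not np.all(np.isfinite(totals)):
            raise DegenerateInputError(
                "all receptive-field activations vanished; cannot average")
        scores = scores / totals[:, None]
    return scores[0] if single else scores


def train_rbfn(X, y, H: int, seed=None, mode: str = "weighted_average",
               retries: int = 3) -> RBFNModel:
    """Two-stage RBFN training.

    Centers come from seeded k-means with ``H`` clusters; each width is the
    distance from a center to its nearest other center (the feature-matrix
    standard deviation when H = 1), floored at a small positive value; the
    output weights solve the least-squares problem against one-hot targets
    in the configured mode.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if H > X.shape[0]:
        raise ConfigurationError(f"H={H} receptive fields but only {X.shape[0]} samples")
    classes, y_enc = np.unique(y, return_inverse=True)
    T = np.eye(len(classes))[y_enc]
    rng = np.random.default_rng(seed)
    centers = None
    for _ in range(retries):
        km = KMeans(n_clusters=H, n_init=1, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == H:
            centers = km.cluster_centers_
            break
    if centers is None:
        raise ConfigurationError(
            f"k-means produced an empty cluster in {retries} attempts; reduce H")
    if H == 1:
        widths = np.array([max(float(X.std()), WIDTH_FLOOR)])
    else:
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        widths = np.maximum(d.min(axis=1), WIDTH_FLOOR)
    model = RBFNModel(centers=centers, widths=widths,
                      weights=np.zeros((H, len(classes))), mode=mode)
    A = _activations(model, X)
    if mode == "weighted_average":
        totals = A.sum(axis=1)
        if np.any(totals <= 0):
            raise DegenerateInputError("zero total activation during training")
        A = A / totals[:, None]
    model.weights, *_ = np.linalg.lstsq(A, T, rcond=None)
    return model


def rbfn_classify(model: RBFNModel, x):
    """Predicted class: argmax of the per-class scores, ties to lowest index."""
    scores = rbfn_output(model, x)
    if scores.ndim == 1:
        return int(np.argmax(scores))
    return np.argmax(scores, axis=1)


class RBFNClassifier(ClassifierMixin, BaseEstimator):
    """k-means + least-squares radial basis function network classifier.

    Parameters
    ----------
    n_centers : int, default 10
        Number of Gaussian receptive fields H.
    mode : {"weighted_average", "weighted_sum"}, default "weighted_average"
        Output aggregation; the normalised average is the form equivalent
        to a zero-order Sugeno fuzzy system.
    random_state : int or None
        Seeds the k-means center selection.
    """

    def __init__(self, n_centers=10, mode="weighted_average", random_state=None):
        self.n_centers = n_centers
        self.mode = mode
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self.model_ = train_rbfn(X, y, H=self.n_centers, seed=self.random_state,
                                 mode=self.mode)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return rbfn_output(self.model_, X)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
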