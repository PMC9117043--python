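"""Hybrid neuro-fuzzy classifier.

The classifier runs in three stages:

1. *Fuzzification* — each training pattern is mapped to membership degrees
   in per-class generalized bell fuzzy sets fitted from class-conditional
   feature statistics (see :mod:`neurofuzzy.membership`).
2. *Learning* — the membership matrix feeds a one-hidden-layer perceptron
   trained by backpropagation with momentum; the hidden-layer width defaults
   to round((n_features + n_classes) * 2/3).
3. *Defuzzification* — a test pattern is fuzzified with the fitted sets and
   assigned to the class whose output activation is highest.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import membership, mlp


class HNFClassifier(ClassifierMixin, BaseEstimator):
    """Fuzzification + MLP-backpropagation hybrid classifier.

    Parameters
    ----------
    layout : {"flattened", "aggregated"}, default "flattened"
        Shape of the fuzzified input fed to the network.  ``flattened``
        keeps one column per (class, feature) membership degree;
        ``aggregated`` collapses features with the configured t-norm first.
    aggregation : {"product", "mean"}, default "product"
        Feature aggregation used by the ``aggregated`` layout.
    q_shape : float, default 2.0
        Shape exponent of every fitted bell function.
    hidden_size : int or None, default None
        Hidden-unit count; None selects round((k + M) * 2/3) from the raw
        feature count k and class count M.
    learning_rate : float, default 0.01
    momentum : float, default 0.9
    epochs : int, default 500
        Epoch budget; training also stops when the epoch loss change falls
        below ``tol``.
    tol : float, default 1e-6
    activation_hidden, activation_output : {"tanh", "logistic"}
        Transfer functions of the two layers (default tanh then logistic).
    random_state : int or None
        Seeds weight initialisation and the per-epoch pattern order.

    Attributes
    ----------
    classes_ : ndarray of the original class labels.
    membership_model_ : fitted :class:`~neurofuzzy.membership.ClassMembershipModel`.
    mlp_ : trained :class:`~neurofuzzy.mlp.MLPModel`.
    loss_curve_ : list of per-epoch sum-of-squared-errors values.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.r_[np.random.default_rng(0).normal(0, 1, (50, 1)),
    ...           np.random.default_rng(1).normal(10, 1, (50, 1))]
    >>> y = np.r_[np.zeros(50, int), np.ones(50, int)]
    >>> clf = HNFClassifier(epochs=50, random_state=0).fit(X, y)
    >>> (clf.predict(X) == y).mean()
    1.0
    """

    def __init__(self, layout="flattened", aggregation="product", q_shape=2.0,
                 hidden_size=None, learning_rate=0.01, momentum=0.9,
                 epochs=500, tol=1e-6, activation_hidden="tanh",
                 activation_output="logistic", random_state=None):
        self.layout = layout
        self.aggregation = aggregation
        self.q_shape = q_shape
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.tol = tol
        self.activation_hidden = activation_hidden
        self.activation_output = activation_output
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.n_features_in_ = X.shape[1]
        self.membership_model_ = membership.fit_bell_params(
            X, y_enc, q_default=self.q_shape, aggregation=self.aggregation)
        fz = membership.fuzzify(X, self.membership_model_, layout=self.layout)
        targets = np.eye(n_classes)[y_enc]
        hidden = self.hidden_size
        if hidden is None:
            hidden = mlp.hidden_layer_size(self.n_features_in_, n_classes)
        rng = np.random.default_rng(self.random_state)
        model = mlp.init_mlp(
            fz.values.shape[1], hidden, n_classes, rng,
            activation_hidden=self.activation_hidden,
            activation_output=self.activation_output,
            learning_rate=self.learning_rate, momentum=self.momentum)
        self.mlp_, trace = mlp.train_mlp(model, fz.values, targets,
                                         epochs=self.epochs, seed=rng, tol=self.tol)
        self.loss_curve_ = list(trace.sse)
        return self

    def decision_function(self, X):
        """Output-layer activations, one column per class."""
        check_is_fitted(self, "mlp_")
        X = check_array(X)
        fz = membership.fuzzify(X, self.membership_model_, layout=self.layout)
        return mlp.forward(self.mlp_, fz.values)

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.array([mlp.defuzzify_predict(row) for row in scores])]


def hnfc_fit(X, y, **params) -> HNFClassifier:
    """Convenience wrapper: ``HNFClassifier(**params).fit(X, y)``."""
    return HNFClassifier(**params).fit(X, y)


def hnfc_predict(fitted: HNFClassifier, X):
    return fitted.predict(X)
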