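"""Generalized bell membership functions and pattern fuzzification.

The fuzzification stage maps each crisp feature value onto a membership
degree in every class's fuzzy set.  Class ``n``'s set for feature ``j`` is a
generalized bell function

    mf(y; p, q, r) = 1 / (1 + ((y - r) / p)^(2q))

with center ``r`` (the value of full membership), half-width ``p`` (the
distance from ``r`` at which membership falls to 0.5) and shape exponent
``q`` (larger ``q`` -> steeper shoulders).  A pattern's per-feature degrees
are combined across features either by product (the standard fuzzy AND,
``aggregated`` layout, one column per class) or kept separate (``flattened``
layout, one column per (class, feature) pair) so a downstream network can
learn its own aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, NeuroFuzzyError

#: floor applied to fitted widths so zero-variance features keep a valid bell
WIDTH_FLOOR = 1e-6


@dataclass(frozen=True)
class BellParams:
    """Parameters of one generalized bell membership function.

    Attributes
    ----------
    p : float
        Half-width at membership 0.5, in the feature's units; must be > 0.
    q : float
        Dimensionless shape exponent; must be > 0.
    r : float
        Center, in the feature's units; membership equals 1 exactly at r.
    """

    p: float
    q: float
    r: float

    def __post_init__(self):
        if not (np.isfinite(self.p) and self.p > 0):
            raise NeuroFuzzyError(f"bell width p must be finite and > 0, got {self.p!r}")
        if not (np.isfinite(self.q) and self.q > 0):
            raise NeuroFuzzyError(f"bell shape q must be finite and > 0, got {self.q!r}")
        if not np.isfinite(self.r):
            raise NeuroFuzzyError(f"bell center r must be finite, got {self.r!r}")


def bell_membership(y, params: BellParams):
    """Evaluate the generalized bell function at ``y``.

    Accepts a scalar or an ndarray; returns degrees in (0, 1], symmetric
    about ``params.r`` and equal to 1 only at the center.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise NeuroFuzzyError("bell_membership requires finite input values")
    u = ((y - params.r) / params.p) ** 2
    out = 1.0 / (1.0 + u ** params.q)
    return float(out) if out.ndim == 0 else out


@dataclass
class ClassMembershipModel:
    """One fitted bell function per (class, feature) pair.

    ``params[n][j]`` is the bell for class ``n``, feature ``j``.
    """

    params: list  # list (over classes) of lists (over features) of BellParams
    aggregation: str = "product"  # {"product", "mean"}
    feature_names: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.params)

    @property
    def n_features(self) -> int:
        return len(self.params[0]) if self.params else 0

    def __post_init__(self):
        if self.aggregation not in ("product", "mean"):
            raise ConfigurationError(
                f"aggregation must be 'product' or 'mean', got {self.aggregation!r}"
            )
        lengths = {len(row) for row in self.params}
        if len(lengths) > 1:
            raise ConfigurationError("every class needs a bell per feature")


@dataclass
class FuzzificationMatrix:
    """Membership degrees of J patterns, rows = patterns.

    ``aggregated`` layout: J x I, one column per class.
    ``flattened`` layout: J x (I*k), column (n*k + j) holds the degree of
    feature j in class n's set; aggregation is deferred to the consumer.
    """

    values: np.ndarray
    layout: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.layout not in ("aggregated", "flattened"):
            raise ConfigurationError(f"unknown layout {self.layout!r}")


def fit_bell_params(X, y, q_default: float = 2.0, aggregation: str = "product",
                    feature_names=None) -> ClassMembershipModel:
    """Fit one bell per (class, feature) from class-conditional statistics.

    Centers are class-conditional means, widths are class-conditional sample
    (n-1) standard deviations floored at ``WIDTH_FLOOR`` (a class with a
    single sample, or a constant feature, gets the floor), and the shape
    exponent is ``q_default`` everywhere.

    ``y`` must contain labels 0..n_classes-1 with at least one sample each.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise NeuroFuzzyError("X must be 2-dimensional")
    n_classes = int(np.max(y)) + 1 if y.size else 0
    params = []
    for n in range(n_classes):
        rows = X[y == n]
        if rows.shape[0] == 0:
            raise ConfigurationError(f"class {n} has no training samples")
        centers = rows.mean(axis=0)
        if rows.shape[0] > 1:
            widths = rows.std(axis=0, ddof=1)
        else:
            widths = np.zeros(X.shape[1])
        widths = np.maximum(widths, WIDTH_FLOOR)
        params.append([BellParams(float(p), float(q_default), float(r))
                       for p, r in zip(widths, centers)])
    return ClassMembershipModel(params=params, aggregation=aggregation,
                                feature_names=list(feature_names or []))


def fuzzify(X, model: ClassMembershipModel, layout: str = "aggregated") -> FuzzificationMatrix:
    """Build the J x I (or J x I*k) fuzzification matrix for patterns ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise NeuroFuzzyError(
            f"pattern has {X.shape[1]} features but model expects {model.n_features}"
        )
    J, k = X.shape
    I = model.n_classes
    per_feature = np.empty((J, I, k))
    for n in range(I):
        for j in range(k):
            per_feature[:, n, j] = bell_membership(X[:, j], model.params[n][j])
    if layout == "flattened":
        return FuzzificationMatrix(per_feature.reshape(J, I * k), "flattened")
    if layout == "aggregated":
        if model.aggregation == "product":
            vals = per_feature.prod(axis=2)
        else:
            vals = per_feature.mean(axis=2)
        return FuzzificationMatrix(vals, "aggregated")
    raise ConfigurationError(f"unknown layout {layout!r}")


def membership_model_to_dict(model: ClassMembershipModel) -> dict:
    return {
        "aggregation": model.aggregation,
        "feature_names": list(model.feature_names),
        "params": [[{"p": b.p, "q": b.q, "r": b.r} for b in row] for row in model.params],
    }


def membership_model_from_dict(d: dict) -> ClassMembershipModel:
    params = [[BellParams(b["p"], b["q"], b["r"]) for b in row] for row in d["params"]]
    return ClassMembershipModel(params=params, aggregation=d["aggregation"],
                                feature_names=list(d.get("feature_names", [])))
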