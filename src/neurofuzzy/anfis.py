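"""Adaptive-network fuzzy inference system (first-order Sugeno).

The network evaluates a rule base in five layers: (1) per-feature
membership degrees, (2) rule firing strengths as the product of the rule's
memberships, (3) normalisation of the strengths to sum to one, (4) rule
consequents f_i(x) = a_i . x + b_i weighted by the normalised strengths and
(5) summation, so

    output = sum_i w_i f_i(x) / sum_i w_i .

Training is hybrid: with premises (membership parameters) held fixed the
consequent coefficients enter the output linearly and are solved exactly by
least squares each epoch; the premises then take one gradient-descent step
against the sum-of-squared-errors loss.

Classification uses one Sugeno output head per class trained against one-hot
targets; the predicted class is the argmax over heads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product as iterproduct

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError, NeuroFuzzyError
from .membership import WIDTH_FLOOR

_TINY = 1e-300


@dataclass
class MF:
    """A one-dimensional membership function.

    kind "bell": params (p, q, r) -> 1 / (1 + ((y-r)/p)^(2q))
    kind "gaussian": params (c, sigma) -> exp(-(y-c)^2 / (2 sigma^2))
    """

    kind: str
    params: np.ndarray

    def __post_init__(self):
        if self.kind not in ("bell", "gaussian"):
            raise ConfigurationError(f"unknown membership family {self.kind!r}")
        self.params = np.asarray(self.params, dtype=float)

    def value(self, y):
        y = np.asarray(y, dtype=float)
        if self.kind == "bell":
            p, q, r = self.params
            return 1.0 / (1.0 + (((y - r) / p) ** 2) ** q)
        c, s = self.params
        return np.exp(-((y - c) ** 2) / (2.0 * s * s))

    def grads(self, y):
        """d mu / d params, stacked along the last axis."""
        y = np.asarray(y, dtype=float)
        if self.kind == "bell":
            p, q, r = self.params
            u = ((y - r) / p) ** 2
            z = u ** q
            mu = 1.0 / (1.0 + z)
            dp = 2.0 * q * z * mu * mu / p
            with np.errstate(divide="ignore", invalid="ignore"):
                dq = np.where(u > 0, -mu * mu * z * np.log(np.maximum(u, _TINY)), 0.0)
                dr = np.where(u > 0, 2.0 * q * z * (y - r) * mu * mu / (p * p * np.maximum(u, _TINY)), 0.0)
            return np.stack([dp, dq, dr], axis=-1)
        c, s = self.params
        mu = np.exp(-((y - c) ** 2) / (2.0 * s * s))
        dc = mu * (y - c) / (s * s)
        ds = mu * (y - c) ** 2 / (s ** 3)
        return np.stack([dc, ds], axis=-1)


@dataclass
class ANFISModel:
    """Rule base, premise membership functions and Sugeno consequents.

    ``mfs[j]`` lists the membership functions of feature ``j``;
    ``rule_index[i, j]`` says which of them rule ``i`` uses, so rules may
    share premises (grid partitioning) or own them privately.
    ``consequents[i, h]`` holds rule ``i``'s linear coefficients for output
    head ``h``: one weight per feature plus an intercept.
    """

    mfs: list                # per feature: list of MF
    rule_index: np.ndarray   # (n_rules, n_features) int
    consequents: np.ndarray  # (n_rules, n_heads, n_features + 1)

    def __post_init__(self):
        self.rule_index = np.asarray(self.rule_index, dtype=int)
        self.consequents = np.asarray(self.consequents, dtype=float)
        if self.rule_index.ndim != 2 or self.rule_index.shape[0] < 1:
            raise ConfigurationError("need at least one rule")
        if self.consequents.shape[0] != self.n_rules or \
                self.consequents.shape[2] != self.n_features + 1:
            raise ConfigurationError("consequent shape inconsistent with rule base")

    @property
    def n_rules(self) -> int:
        return self.rule_index.shape[0]

    @property
    def n_features(self) -> int:
        return self.rule_index.shape[1]

    @property
    def n_heads(self) -> int:
        return self.consequents.shape[1]


def build_rule_base(n_features: int, mfs_per_feature: int, X,
                    n_heads: int = 1, mf_family: str = "bell",
                    q_shape: float = 2.0, rule_cap: int = 256) -> ANFISModel:
    """Grid-partitioned rule base over the observed feature ranges.

    Each feature gets ``mfs_per_feature`` membership functions with centers
    evenly spaced from its minimum to its maximum; widths are half the
    center spacing (half the range for a single function).  Rules are the
    full Cartesian product of the per-feature functions; consequents start
    at zero.
    """
    if mfs_per_feature < 1:
        raise ConfigurationError("mfs_per_feature must be >= 1")
    n_rules = mfs_per_feature ** n_features
    if n_rules > rule_cap:
        raise ConfigurationError(
            f"grid of {mfs_per_feature}^{n_features} = {n_rules} rules exceeds the "
            f"cap of {rule_cap}; reduce mfs_per_feature or raise rule_cap")
    X = np.asarray(X, dtype=float)
    if X.shape[1] != n_features:
        raise NeuroFuzzyError("X feature count does not match n_features")
    mfs = []
    for j in range(n_features):
        lo, hi = float(X[:, j].min()), float(X[:, j].max())
        if mfs_per_feature == 1:
            centers = [0.5 * (lo + hi)]
            width = max((hi - lo) / 2.0, WIDTH_FLOOR)
        else:
            centers = np.linspace(lo, hi, mfs_per_feature)
            width = max((hi - lo) / (2.0 * (mfs_per_feature - 1)), WIDTH_FLOOR)
        if mf_family == "bell":
            mfs.append([MF("bell", (width, q_shape, c)) for c in centers])
        else:
            mfs.append([MF("gaussian", (c, width)) for c in centers])
    rule_index = np.array(list(iterproduct(range(mfs_per_feature), repeat=n_features)),
                          dtype=int)
    consequents = np.zeros((n_rules, n_heads, n_features + 1))
    return ANFISModel(mfs=mfs, rule_index=rule_index, consequents=consequents)


def _membership_tensor(model: ANFISModel, X):
    """Per-(sample, rule, feature) membership degrees, shape (n, R, k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if k != model.n_features:
        raise NeuroFuzzyError(
            f"input has {k} features, model expects {model.n_features}")
    # evaluate each distinct MF once, then gather by rule index
    per_feature = [np.stack([mf.value(X[:, j]) for mf in model.mfs[j]], axis=1)
                   for j in range(k)]          # each (n, n_mfs_j)
    out = np.empty((n, model.n_rules, k))
    for j in range(k):
        out[:, :, j] = per_feature[j][:, model.rule_index[:, j]]
    return out


def firing_strengths(model: ANFISModel, x):
    """Rule strengths w_i = prod_j mu_ij(x_j) and their normalisation.

    Returns ``(w, w_bar)`` for a single input vector; ``w_bar`` sums to 1.
    """
    mu = _membership_tensor(model, np.atleast_2d(x))[0]  # (R, k)
    w = mu.prod(axis=1)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateInputError(
            "all rule firing strengths vanished; cannot normalise")
    return w, w / total


def _consequent_values(model: ANFISModel, X):
    """f_i,h(x) for every sample: shape (n, R, H)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X1 = np.hstack([X, np.ones((X.shape[0], 1))])      # (n, k+1)
    return np.einsum("nd,rhd->nrh", X1, model.consequents)


def anfis_forward(model: ANFISModel, x):
    """Network output per head: sum_i w_bar_i f_i(x).

    Accepts one vector (returns shape (H,)) or a batch (returns (n, H)).
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    mu = _membership_tensor(model, X)
    w = mu.prod(axis=2)                                # (n, R)
    totals = w.sum(axis=1)
    if np.any(totals <= 0) or not np.all(np.isfinite(totals)):
        raise DegenerateInputError(
            "all rule firing strengths vanished; cannot normalise")
    wbar = w / totals[:, None]
    out = np.einsum("nr,nrh->nh", wbar, _consequent_values(model, X))
    return out[0] if np.asarray(x).ndim == 1 else out


def _solve_consequents(model: ANFISModel, X, T, ridge: float = 1e-8):
    """Least-squares consequents given fixed premises.

    The design matrix stacks, per rule, the normalised strength times
    [x, 1]; ill-determined systems fall back to a ridge-regularised solve.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    n, k = X.shape
    R, H = model.n_rules, model.n_heads
    mu = _membership_tensor(model, X)
    w = mu.prod(axis=2)
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateInputError("zero total firing strength during training")
    wbar = w / totals[:, None]
    X1 = np.hstack([X, np.ones((n, 1))])
    phi = (wbar[:, :, None] * X1[:, None, :]).reshape(n, R * (k + 1))
    n_params = R * (k + 1)
    if n >= n_params:
        coef, _, rank, _ = np.linalg.lstsq(phi, T, rcond=None)
        if rank < n_params:
            warnings.warn("singular consequent system; using ridge-regularised solve",
                          RuntimeWarning, stacklevel=2)
            coef = np.linalg.solve(phi.T @ phi + ridge * np.eye(n_params), phi.T @ T)
    else:
        warnings.warn("fewer samples than consequent parameters; "
                      "using ridge-regularised solve", RuntimeWarning, stacklevel=2)
        coef = np.linalg.solve(phi.T @ phi + ridge * np.eye(n_params), phi.T @ T)
    model.consequents = coef.reshape(R, k + 1, H).transpose(0, 2, 1)
    return model


def premise_gradients(model: ANFISModel, X, T):
    """Analytic gradient of E = 1/2 sum (output - target)^2 w.r.t. premises.

    Returns a list matching ``model.mfs``: per feature, an array of shape
    (n_mfs_j, n_mf_params) of summed gradients over all samples and heads.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    n, k = X.shape
    mu = _membership_tensor(model, X)                  # (n, R, k)
    w = mu.prod(axis=2)                                # (n, R)
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateInputError("zero total firing strength in gradient pass")
    wbar = w / totals[:, None]
    f = _consequent_values(model, X)                   # (n, R, H)
    out = np.einsum("nr,nrh->nh", wbar, f)
    err = out - T                                      # (n, H)
    # dE/dw_i = sum_h err_h (f_ih - out_h) / total
    dE_dw = np.einsum("nh,nrh->nr", err, f - out[:, None, :]) / totals[:, None]
    grads = []
    for j in range(k):
        # product of memberships excluding feature j, per (sample, rule)
        with np.errstate(divide="ignore", invalid="ignore"):
            w_excl = np.where(mu[:, :, j] > 0, w / np.maximum(mu[:, :, j], _TINY), 0.0)
        zero_mask = mu[:, :, j] <= 0
        if np.any(zero_mask):
            others = np.delete(mu, j, axis=2).prod(axis=2)
            w_excl = np.where(zero_mask, others, w_excl)
        g_feature = np.zeros((len(model.mfs[j]), model.mfs[j][0].params.size))
        for a, mf in enumerate(model.mfs[j]):
            used = model.rule_index[:, j] == a         # rules using this MF
            if not np.any(used):
                continue
            dmu = mf.grads(X[:, j])                    # (n, n_params)
            # dw_i/dtheta = w_excl_i * dmu  for rules i using (j, a)
            coeff = (dE_dw[:, used] * w_excl[:, used]).sum(axis=1)  # (n,)
            g_feature[a] = coeff @ dmu
        grads.append(g_feature)
    return grads


def anfis_loss(model: ANFISModel, X, T) -> float:
    out = np.atleast_2d(anfis_forward(model, np.atleast_2d(X)))
    return 0.5 * float(np.sum((out - np.atleast_2d(T)) ** 2))


def train_anfis(model: ANFISModel, X, T, epochs: int = 10,
                premise_learning_rate: float = 0.01, ridge: float = 1e-8):
    """Hybrid training: exact consequent least squares + premise gradient steps.

    Each epoch solves the consequents by least squares with premises fixed,
    records the loss, then (except after the last epoch, so the returned
    consequents remain optimal for the returned premises) takes one gradient
    step of size ``premise_learning_rate`` on every premise parameter.
    Returns ``(model, loss_trace)``; the model is updated in place.
    """
    if epochs < 1:
        raise NeuroFuzzyError("epochs must be >= 1")
    trace = []
    for epoch in range(epochs):
        _solve_consequents(model, X, T, ridge=ridge)
        trace.append(anfis_loss(model, X, T))
        if epoch == epochs - 1 or premise_learning_rate == 0:
            continue
        grads = premise_gradients(model, X, T)
        for j, g_feature in enumerate(grads):
            for a, mf in enumerate(model.mfs[j]):
                new = mf.params - premise_learning_rate * g_feature[a]
                # keep widths/shapes positive so the MF stays valid
                if mf.kind == "bell":
                    new[0] = max(new[0], WIDTH_FLOOR)
                    new[1] = max(new[1], WIDTH_FLOOR)
                else:
                    new[1] = max(new[1], WIDTH_FLOOR)
                mf.params = new
    return model, trace


def anfis_classify(model: ANFISModel, x) -> int:
    """Predicted class: argmax over heads, ties to the lowest index."""
    out = anfis_forward(model, x)
    if out.ndim == 1:
        return int(np.argmax(out))
    return np.argmax(out, axis=1)


# ---------------------------------------------------------------------------
# sklearn-style estimator

from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class ANFISClassifier(ClassifierMixin, BaseEstimator):
    """Grid-partitioned Sugeno fuzzy classifier with hybrid training.

    One Sugeno output head per class is trained against one-hot targets;
    prediction takes the argmax over heads.

    Parameters
    ----------
    mfs_per_feature : int, default 2
        Membership functions per feature; the rule base is their full
        Cartesian grid, capped at ``rule_cap`` rules.
    mf_family : {"bell", "gaussian"}, default "bell"
    epochs : int, default 10
    premise_learning_rate : float, default 0.01
    rule_cap : int, default 256
    ridge : float, default 1e-8
        Regularisation used when the consequent system is ill-determined.
    random_state : int or None
        Accepted for API uniformity; the algorithm is deterministic.
    """

    def __init__(self, mfs_per_feature=2, mf_family="bell", epochs=10,
                 premise_learning_rate=0.01, rule_cap=256, ridge=1e-8,
                 q_shape=2.0, random_state=None):
        self.mfs_per_feature = mfs_per_feature
        self.mf_family = mf_family
        self.epochs = epochs
        self.premise_learning_rate = premise_learning_rate
        self.rule_cap = rule_cap
        self.ridge = ridge
        self.q_shape = q_shape
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        targets = np.eye(len(self.classes_))[y_enc]
        model = build_rule_base(X.shape[1], self.mfs_per_feature, X,
                                n_heads=len(self.classes_),
                                mf_family=self.mf_family, q_shape=self.q_shape,
                                rule_cap=self.rule_cap)
        self.model_, self.loss_curve_ = train_anfis(
            model, X, targets, epochs=self.epochs,
            premise_learning_rate=self.premise_learning_rate, ridge=self.ridge)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return anfis_forward(self.model_, X)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
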