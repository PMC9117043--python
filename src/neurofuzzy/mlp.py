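"""One-hidden-layer perceptron trained by backpropagation with momentum.

The network minimises the half sum-of-squared-errors loss

    E = 1/2 * sum_n (Target_n - Output_n)^2

by stochastic gradient descent: one update per training pattern, patterns
visited in a seeded shuffled order each epoch, with a momentum term adding a
fraction of the previous update to the current one.  Hidden and output
activations are independently selectable between tanh and the logistic
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DivergenceError, NeuroFuzzyError

ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a ** 2),
    "logistic": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
}


def hidden_layer_size(n_features: int, n_classes: int) -> int:
    """Hidden-unit count L = round((n_features + n_classes) * 2/3).

    Rounding is half-away-from-zero, and the result is floored at 1.
    """
    if n_features < 1 or n_classes < 2:
        raise NeuroFuzzyError("need n_features >= 1 and n_classes >= 2")
    raw = (n_features + n_classes) * 2.0 / 3.0
    return max(1, int(np.floor(raw + 0.5)))


def defuzzify_predict(activations) -> int:
    """Index of the maximum activation; ties go to the lowest class index."""
    activations = np.asarray(activations, dtype=float)
    if activations.size == 0:
        raise NeuroFuzzyError("empty activation vector")
    return int(np.argmax(activations))


@dataclass
class MLPModel:
    """Weights and hyper-parameters of the one-hidden-layer network."""

    W_ih: np.ndarray  # (n_inputs, L)
    b_h: np.ndarray   # (L,)
    W_ho: np.ndarray  # (L, n_outputs)
    b_o: np.ndarray   # (n_outputs,)
    activation_hidden: str = "tanh"
    activation_output: str = "logistic"
    learning_rate: float = 0.01
    momentum: float = 0.9

    def __post_init__(self):
        if self.learning_rate < 0:
            raise NeuroFuzzyError("learning rate must be >= 0")
        if not (0 <= self.momentum < 1):
            raise NeuroFuzzyError("momentum must lie in [0, 1)")
        for name in (self.activation_hidden, self.activation_output):
            if name not in ACTIVATIONS:
                raise NeuroFuzzyError(f"unknown activation {name!r}")

    def copy(self) -> "MLPModel":
        return MLPModel(self.W_ih.copy(), self.b_h.copy(), self.W_ho.copy(),
                        self.b_o.copy(), self.activation_hidden,
                        self.activation_output, self.learning_rate, self.momentum)


@dataclass
class TrainTrace:
    """Per-epoch sum-of-squared-errors values."""

    sse: list = field(default_factory=list)

    @property
    def epochs(self) -> int:
        return len(self.sse)


def init_mlp(n_inputs: int, hidden: int, n_outputs: int, rng,
             activation_hidden="tanh", activation_output="logistic",
             learning_rate=0.01, momentum=0.9, init_scale=0.5) -> MLPModel:
    """Seeded uniform initialisation in [-init_scale, init_scale]."""
    rng = np.random.default_rng(rng)
    return MLPModel(
        W_ih=rng.uniform(-init_scale, init_scale, (n_inputs, hidden)),
        b_h=rng.uniform(-init_scale, init_scale, hidden),
        W_ho=rng.uniform(-init_scale, init_scale, (hidden, n_outputs)),
        b_o=rng.uniform(-init_scale, init_scale, n_outputs),
        activation_hidden=activation_hidden,
        activation_output=activation_output,
        learning_rate=learning_rate,
        momentum=momentum,
    )


def forward(model: MLPModel, x):
    """Output activations for one pattern (or a batch, row-wise)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.W_ih.shape[0]:
        raise NeuroFuzzyError(
            f"input has {x.shape[-1]} features, network expects {model.W_ih.shape[0]}"
        )
    f_h = ACTIVATIONS[model.activation_hidden][0]
    f_o = ACTIVATIONS[model.activation_output][0]
    h = f_h(x @ model.W_ih + model.b_h)
    return f_o(h @ model.W_ho + model.b_o)


def sample_loss(model: MLPModel, x, target) -> float:
    out = forward(model, x)
    return 0.5 * float(np.sum((np.asarray(target) - out) ** 2))


def sample_gradients(model: MLPModel, x, target):
    """Analytic gradients of the half-SSE loss for one pattern.

    Returns (dW_ih, db_h, dW_ho, db_o).  Used both by training and by the
    finite-difference oracle tests.
    """
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    f_h, df_h = ACTIVATIONS[model.activation_hidden]
    f_o, df_o = ACTIVATIONS[model.activation_output]
    h = f_h(x @ model.W_ih + model.b_h)
    out = f_o(h @ model.W_ho + model.b_o)
    delta_o = (out - target) * df_o(out)          # (n_outputs,)
    delta_h = (model.W_ho @ delta_o) * df_h(h)    # (L,)
    return (np.outer(x, delta_h), delta_h, np.outer(h, delta_o), delta_o)


def train_mlp(model: MLPModel, inputs, targets, epochs: int = 500,
              seed=None, tol: float = 1e-6):
    """Train by per-pattern backpropagation with momentum.

    Stops after ``epochs`` epochs or once the epoch-to-epoch change in the
    summed loss falls below ``tol``.  Returns ``(trained copy, TrainTrace)``;
    the input model is not modified.
    """
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if inputs.shape[0] != targets.shape[0]:
        raise NeuroFuzzyError("inputs and targets must have equal row counts")
    if epochs < 1:
        raise NeuroFuzzyError("epochs must be >= 1")
    model = model.copy()
    rng = np.random.default_rng(seed)
    eta, mu = model.learning_rate, model.momentum
    vW_ih = np.zeros_like(model.W_ih)
    vb_h = np.zeros_like(model.b_h)
    vW_ho = np.zeros_like(model.W_ho)
    vb_o = np.zeros_like(model.b_o)
    trace = TrainTrace()
    n = inputs.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        sse = 0.0
        for i in order:
            x, t = inputs[i], targets[i]
            gW_ih, gb_h, gW_ho, gb_o = sample_gradients(model, x, t)
            vW_ih = mu * vW_ih - eta * gW_ih
            vb_h = mu * vb_h - eta * gb_h
            vW_ho = mu * vW_ho - eta * gW_ho
            vb_o = mu * vb_o - eta * gb_o
            model.W_ih += vW_ih
            model.b_h += vb_h
            model.W_ho += vW_ho
            model.b_o += vb_o
            sse += sample_loss(model, x, t)
        if not np.isfinite(sse):
            raise DivergenceError(
                f"training loss became non-finite; try a smaller learning rate "
                f"(current eta={eta})"
            )
        trace.sse.append(sse)
        if len(trace.sse) >= 2 and abs(trace.sse[-2] - trace.sse[-1]) < tol:
            break
    return model, trace


def mlp_to_dict(model: MLPModel) -> dict:
    return {
        "W_ih": model.W_ih.tolist(), "b_h": model.b_h.tolist(),
        "W_ho": model.W_ho.tolist(), "b_o": model.b_o.tolist(),
        "activation_hidden": model.activation_hidden,
        "activation_output": model.activation_output,
        "learning_rate": model.learning_rate, "momentum": model.momentum,
    }


def mlp_from_dict(d: dict) -> MLPModel:
    return MLPModel(
        W_ih=np.asarray(d["W_ih"], dtype=float), b_h=np.asarray(d["b_h"], dtype=float),
        W_ho=np.asarray(d["W_ho"], dtype=float), b_o=np.asarray(d["b_o"], dtype=float),
        activation_hidden=d["activation_hidden"], activation_output=d["activation_output"],
        learning_rate=d["learning_rate"], momentum=d["momentum"],
    )
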