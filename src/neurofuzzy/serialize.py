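"""JSON serialization of fitted classifiers (versioned schema)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import anfis as _anfis
from . import membership as _membership
from . import mlp as _mlp
from .anfis import ANFISClassifier, ANFISModel, MF
from .exceptions import NeuroFuzzyError
from .hnfc import HNFClassifier
from .rbfn import RBFNClassifier, RBFNModel

SCHEMA = "neurofuzzy-model"
SCHEMA_VERSION = 1


def _state(est) -> dict:
    if isinstance(est, HNFClassifier):
        return {
            "membership_model": _membership.membership_model_to_dict(est.membership_model_),
            "mlp": _mlp.mlp_to_dict(est.mlp_),
            "loss_curve": list(est.loss_curve_),
        }
    if isinstance(est, ANFISClassifier):
        m = est.model_
        return {
            "mfs": [[{"kind": mf.kind, "params": mf.params.tolist()} for mf in row]
                    for row in m.mfs],
            "rule_index": m.rule_index.tolist(),
            "consequents": m.consequents.tolist(),
            "loss_curve": list(est.loss_curve_),
        }
    if isinstance(est, RBFNClassifier):
        m = est.model_
        return {"centers": m.centers.tolist(), "widths": m.widths.tolist(),
                "weights": m.weights.tolist(), "mode": m.mode}
    raise NeuroFuzzyError(f"cannot serialize {type(est).__name__}")


KINDS = {"hnfc": HNFClassifier, "anfis": ANFISClassifier, "rbfn": RBFNClassifier}


def save_model(est, path):
    """Write a fitted estimator to a JSON model file."""
    kind = {HNFClassifier: "hnfc", ANFISClassifier: "anfis",
            RBFNClassifier: "rbfn"}.get(type(est))
    if kind is None:
        raise NeuroFuzzyError(f"cannot serialize {type(est).__name__}")
    doc = {
        "schema": SCHEMA, "version": SCHEMA_VERSION, "kind": kind,
        "params": est.get_params(),
        "classes": np.asarray(est.classes_).tolist(),
        "n_features_in": int(est.n_features_in_),
        "state": _state(est),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_model(path):
    """Rebuild a fitted estimator from a model file."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != SCHEMA:
        raise NeuroFuzzyError("not a neurofuzzy model file")
    if doc.get("version") != SCHEMA_VERSION:
        raise NeuroFuzzyError(f"unsupported model schema version {doc.get('version')}")
    est = KINDS[doc["kind"]](**doc["params"])
    est.classes_ = np.asarray(doc["classes"])
    est.n_features_in_ = doc["n_features_in"]
    state = doc["state"]
    if doc["kind"] == "hnfc":
        est.membership_model_ = _membership.membership_model_from_dict(
            state["membership_model"])
        est.mlp_ = _mlp.mlp_from_dict(state["mlp"])
        est.loss_curve_ = list(state["loss_curve"])
    elif doc["kind"] == "anfis":
        mfs = [[MF(d["kind"], d["params"]) for d in row] for row in state["mfs"]]
        est.model_ = ANFISModel(mfs=mfs,
                                rule_index=np.asarray(state["rule_index"]),
                                consequents=np.asarray(state["consequents"]))
        est.loss_curve_ = list(state["loss_curve"])
    else:
        est.model_ = RBFNModel(centers=np.asarray(state["centers"]),
                               widths=np.asarray(state["widths"]),
                               weights=np.asarray(state["weights"]),
                               mode=state["mode"])
    return est
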