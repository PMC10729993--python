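"""Model checkpoint archive: RBM + optional classifier in one .npz file.

The archive carries the parameter arrays, the alphabet, the training config
and a schema version, so a checkpoint written by one run can be reloaded for
scoring or sampling later.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .rbm_core import RBMParams, TrainConfig
from .ssl_head import ClassifierParams

SCHEMA_VERSION = 1


def save_checkpoint(path, rbm: RBMParams, cls: ClassifierParams | None = None,
                    train_config: TrainConfig | None = None) -> None:
    meta = {
        "schema_version": SCHEMA_VERSION,
        "alphabet": rbm.alphabet,
        "train_config": asdict(train_config) if train_config else None,
        "has_classifier": cls is not None,
        "classifier": None if cls is None else {
            "gamma": cls.gamma,
            "bn_momentum": cls.bn_momentum,
            "n_positions": cls.n_positions,
        },
    }
    arrays = {"g": rbm.g, "W": rbm.W,
              "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if cls is not None:
        arrays.update(cls_dense_w=cls.dense_w, cls_dense_b=cls.dense_b,
                      cls_bn_mean=cls.bn_mean, cls_bn_var=cls.bn_var)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[RBMParams, ClassifierParams | None, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta["schema_version"] != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported checkpoint schema {meta['schema_version']}")
        rbm = RBMParams(g=data["g"], W=data["W"], alphabet=meta["alphabet"])
        cls = None
        if meta["has_classifier"]:
            c = meta["classifier"]
            cls = ClassifierParams(
                dense_w=data["cls_dense_w"], dense_b=data["cls_dense_b"],
                bn_mean=data["cls_bn_mean"], bn_var=data["cls_bn_var"],
                gamma=c["gamma"], bn_momentum=c["bn_momentum"],
                n_positions=c["n_positions"])
    return rbm, cls, meta
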