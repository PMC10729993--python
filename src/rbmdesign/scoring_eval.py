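"""Scores and evaluation procedures for designed and natural variants.

Covers the experimental activity scale (normalized repression and its
categories), per-unit PAM classification AUC, activity-detection AUROC,
per-position precision maps for inactive-variant detection, and assembly of
the per-sequence score table (RBM energy, classifier motif score, Hamming
distance to a reference, external structural scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import rbm_core, ssl_head
from .msa_io import PamLabel, encode_pam_motif, hamming_distance
from .rbm_core import RBMParams


def normalized_repression(f: float, f0: float, f1: float) -> float:
    """nr(f) = log(f/f0) / log(f1/f0).

    1 corresponds to the wild-type fold f1 and 0 to the negative-control fold
    f0 (log midpoint sqrt(f0 f1) maps to 0.5).
    """
    if f <= 0 or f0 <= 0 or f1 <= 0:
        raise ValueError("fold changes must be positive")
    if f1 == f0:
        raise ValueError("f1 must differ from f0")
    return float(np.log(f / f0) / np.log(f1 / f0))


class ActivityCategory(Enum):
    VERY_FUNCTIONAL = "very_functional"    # nr >= 0.8
    FUNCTIONAL = "functional"              # 0.5 <= nr < 0.8
    MARGINAL = "marginal"                  # 0.2 <= nr < 0.5
    NOT_FUNCTIONAL = "not_functional"      # nr < 0.2


#: strictly decreasing category bounds; boundary values go to the higher class
ACTIVITY_BOUNDS = (0.8, 0.5, 0.2)


def activity_category(nr: float) -> ActivityCategory:
    if nr >= ACTIVITY_BOUNDS[0]:
        return ActivityCategory.VERY_FUNCTIONAL
    if nr >= ACTIVITY_BOUNDS[1]:
        return ActivityCategory.FUNCTIONAL
    if nr >= ACTIVITY_BOUNDS[2]:
        return ActivityCategory.MARGINAL
    return ActivityCategory.NOT_FUNCTIONAL


def mean_pam_auc(predictions: np.ndarray, labels: list[PamLabel]
                 ) -> tuple[np.ndarray, float]:
    """Per-unit ROC AUC plus their mean over evaluable units.

    predictions is (n, K) per-unit probabilities aligned with ``labels``.
    A unit is evaluable if its unmasked labels contain both classes; other
    units are NaN in the per-unit array and excluded from the mean.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    y, mask = ssl_head._stack_labels(labels)
    if predictions.shape != y.shape:
        raise ValueError("predictions and labels disagree in shape")
    K = y.shape[1]
    per_unit = np.full(K, np.nan)
    for k in range(K):
        obs = mask[:, k] > 0
        yk = y[obs, k]
        if obs.sum() == 0 or yk.min() == yk.max():
            continue
        per_unit[k] = roc_auc_score(yk, predictions[obs, k])
    finite = np.isfinite(per_unit)
    if not finite.any():
        raise ValueError("no unit has both classes among unmasked labels")
    return per_unit, float(per_unit[finite].mean())


def auroc_active(scores: np.ndarray, activities: np.ndarray,
                 threshold: float = 0.5, orientation: str = "high") -> float:
    """AUROC for detecting activity (nr > threshold) from a score.

    ``orientation`` states whether high or low scores indicate activity.
    """
    scores = np.asarray(scores, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if orientation not in ("high", "low"):
        raise ValueError("orientation must be 'high' or 'low'")
    y = (activities > threshold).astype(int)
    if y.min() == y.max():
        raise ValueError("both active and inactive samples are required")
    s = scores if orientation == "high" else -scores
    return float(roc_auc_score(y, s))


def per_position_precision(rows: np.ndarray, activities: np.ndarray,
                           score_calls: dict[str, np.ndarray],
                           ref: np.ndarray, min_support: int = 5,
                           inactive_threshold: float = 0.2) -> pd.DataFrame:
    """Per-column precision of each scorer at flagging inactive variants.

    For every alignment column, the inactive variants (nr < threshold)
    mutated at that column are collected; a scorer's precision is the
    fraction of them it called inactive (``score_calls[name]`` is a boolean
    predicted-inactive vector per variant).  Columns with fewer than
    ``min_support`` qualifying variants are emitted as NaN.
    """
    rows = np.atleast_2d(np.asarray(rows))
    activities = np.asarray(activities, dtype=float)
    ref = np.asarray(ref)
    L = rows.shape[1]
    inactive = activities < inactive_threshold
    mutated = rows != ref  # (n, L)
    out = {"position": np.arange(1, L + 1)}  # 1-based in reports
    support = (mutated & inactive[:, None]).sum(axis=0)
    out["support"] = support
    for name, calls in score_calls.items():
        calls = np.asarray(calls, dtype=bool)
        prec = np.full(L, np.nan)
        for i in range(L):
            if support[i] >= min_support:
                sel = mutated[:, i] & inactive
                prec[i] = calls[sel].mean()
        out[name] = prec
    return pd.DataFrame(out)


def classifier_motif_score(probs: np.ndarray, motif_query: str,
                           n_positions: int, method: str = "product"
                           ) -> np.ndarray:
    """Score of a query motif under per-unit acceptance probabilities.

    Default: the joint (product) probability over the units the query
    requires accepted, restricted to observed query positions.  Alternative
    ``mean_log``: the mean log-probability of those units.
    """
    query = encode_pam_motif(motif_query, n_positions)
    need = (query.flat() > 0) & (query.mask.ravel() > 0)
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    sel = probs[:, need]
    if method == "product":
        return np.prod(sel, axis=1)
    if method == "mean_log":
        return np.mean(np.log(sel + 1e-12), axis=1)
    raise ValueError("method must be 'product' or 'mean_log'")


SCORE_TABLE_COLUMNS = ("seq_id", "rbm_energy", "classifier_score",
                       "hamming_to_ref")


def score_sequences(ids: list[str], rows: np.ndarray, rbm: RBMParams,
                    cls: ssl_head.ClassifierParams | None,
                    ref: np.ndarray, motif_query: str = "NGG",
                    external: pd.DataFrame | None = None,
                    method: str = "product") -> pd.DataFrame:
    """Assemble the per-sequence score table.

    Columns: seq_id, rbm_energy (normalised F/L), classifier_score
    (probability assigned to ``motif_query``; NaN if no classifier),
    hamming_to_ref, then any external columns joined on seq_id (missing
    entries stay null, never 0).  Duplicate ids on the join raise.
    """
    rows = np.atleast_2d(np.asarray(rows))
    if len(ids) != rows.shape[0]:
        raise ValueError("ids and rows disagree in length")
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    df = pd.DataFrame({
        "seq_id": ids,
        "rbm_energy": rbm_core.energy_score(rows, rbm),
        "hamming_to_ref": hamming_distance(rows, ref),
    })
    if cls is not None:
        probs = ssl_head.predict_pam_probs(rows, rbm, cls)
        df["classifier_score"] = classifier_motif_score(
            probs, motif_query, cls.n_positions, method)
    else:
        df["classifier_score"] = np.nan
    df = df[list(SCORE_TABLE_COLUMNS)]
    if external is not None:
        if external["seq_id"].duplicated().any():
            raise ValueError("duplicate seq_id in the external score table")
        df = df.merge(external, on="seq_id", how="left", validate="1:1")
    return df
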