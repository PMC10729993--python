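"""Semi-supervised head: a one-layer PAM classifier on the RBM representation.

The classifier receives the hidden representation (a stochastic draw
h ~ N(I(x), Id) during training, the deterministic mean I(x) at prediction
time), batch-normalises it, applies a dense layer and an independent sigmoid
per output unit.  Each unit predicts whether one nucleotide is accepted at
one PAM position (n_positions x 4 units, 20 by default).  The supervised loss
is a masked per-unit binary cross-entropy; the joint loss is

    L = L_RBM + gamma * L_C,

where the classifier term also back-propagates into the RBM couplings W
through the sampled representation, so the latent space is shaped by the
labels.  At gamma = 0 the update is bit-for-bit the unsupervised one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rbm_core
from .msa_io import Alignment, PamLabel, SplitSpec, pam_matrix_to_motif, \
    split_train_validation
from .optim import AdamW
from .rbm_core import RBMParams, TrainConfig, _flat_index, input_current

BN_EPS = 1e-5


@dataclass
class ClassifierParams:
    """Dense weights/bias plus batch-norm running statistics.

    The batch-norm layer carries no learned affine terms: any scale/shift is
    absorbed by the dense layer that immediately follows it.
    """

    dense_w: np.ndarray  # (M, K)
    dense_b: np.ndarray  # (K,)
    bn_mean: np.ndarray  # (M,)
    bn_var: np.ndarray   # (M,)
    gamma: float = 1.0
    bn_momentum: float = 0.1
    n_positions: int = 5

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.dense_w.shape[1] != self.dense_b.shape[0]:
            raise ValueError("dense weight / bias shape mismatch")
        if self.K != 4 * self.n_positions:
            raise ValueError("K must equal n_positions * 4")

    @property
    def M(self) -> int:
        return self.dense_w.shape[0]

    @property
    def K(self) -> int:
        return self.dense_w.shape[1]


def init_classifier(M: int, gamma: float, rng: np.random.Generator,
                    n_positions: int = 5) -> ClassifierParams:
    K = 4 * n_positions
    return ClassifierParams(
        dense_w=rng.normal(0.0, 0.1 / np.sqrt(M), size=(M, K)),
        dense_b=np.zeros(K),
        bn_mean=np.zeros(M),
        bn_var=np.ones(M),
        gamma=gamma,
        n_positions=n_positions,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def classifier_forward(h: np.ndarray, cls: ClassifierParams,
                       mode: str = "predict",
                       update_running: bool = True) -> np.ndarray:
    """Per-unit acceptance probabilities, shape (..., K), in (0, 1).

    ``train`` mode normalises with batch statistics (and updates the running
    ones); ``predict`` mode uses the running statistics, so the output is a
    deterministic function of h.
    """
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if mode == "train":
        mu = h.mean(axis=0)
        var = h.var(axis=0)
        if update_running:
            m = cls.bn_momentum
            cls.bn_mean *= 1.0 - m
            cls.bn_mean += m * mu
            cls.bn_var *= 1.0 - m
            cls.bn_var += m * var
    elif mode == "predict":
        mu, var = cls.bn_mean, cls.bn_var
    else:
        raise ValueError(f"unknown mode {mode!r}")
    hn = (h - mu) / np.sqrt(var + BN_EPS)
    return _sigmoid(hn @ cls.dense_w + cls.dense_b)


def _stack_labels(labels: list[PamLabel]) -> tuple[np.ndarray, np.ndarray]:
    y = np.stack([lab.flat() for lab in labels]).astype(float)
    m = np.stack([lab.mask.ravel() for lab in labels]).astype(float)
    return y, m


def classifier_loss(labels: list[PamLabel], h: np.ndarray,
                    cls: ClassifierParams, mode: str = "train") -> float:
    """Masked per-unit BCE averaged over observed units (no grads)."""
    loss, _ = _classifier_loss_grads(labels, h, cls, mode=mode,
                                     update_running=False)
    return loss


def _classifier_loss_grads(labels: list[PamLabel], h: np.ndarray,
                           cls: ClassifierParams, mode: str = "train",
                           update_running: bool = True
                           ) -> tuple[float, dict[str, np.ndarray]]:
    """Loss plus gradients w.r.t. dense_w, dense_b and the input h.

    The batch-norm backward pass treats the batch statistics as functions of
    h (full gradient), so the coupling gradient the RBM receives is exact.
    """
    y, mask = _stack_labels(labels)
    n_obs = mask.sum()
    if n_obs == 0:
        raise ValueError("all label units are masked; nothing to fit")
    h = np.atleast_2d(np.asarray(h, dtype=float))
    B = h.shape[0]
    if mode == "train":
        mu = h.mean(axis=0)
        var = h.var(axis=0)
        if update_running:
            m = cls.bn_momentum
            cls.bn_mean *= 1.0 - m
            cls.bn_mean += m * mu
            cls.bn_var *= 1.0 - m
            cls.bn_var += m * var
    else:
        mu, var = cls.bn_mean, cls.bn_var
    inv = 1.0 / np.sqrt(var + BN_EPS)
    hn = (h - mu) * inv
    z = hn @ cls.dense_w + cls.dense_b
    p = _sigmoid(z)
    eps = 1e-12
    bce = -(y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps))
    loss = float(np.sum(mask * bce) / n_obs)
    dz = mask * (p - y) / n_obs  # (B, K)
    grads = {
        "dense_w": hn.T @ dz,
        "dense_b": dz.sum(axis=0),
    }
    dhn = dz @ cls.dense_w.T  # (B, M)
    if mode == "train" and B > 1:
        dh = inv * (dhn - dhn.mean(axis=0)
                    - hn * np.mean(dhn * hn, axis=0))
    else:
        dh = dhn * inv
    grads["h"] = dh
    return loss, grads


def coupling_gradient_from_classifier(rows: np.ndarray, dh: np.ndarray,
                                      rbm: RBMParams) -> np.ndarray:
    """Back-propagate d(loss)/dh through h = I(x) + noise into W.

    dW[i, a, mu] = sum_b 1(x_{b,i} = a) dh[b, mu].
    """
    L, q, M = rbm.L, rbm.q, rbm.M
    gW = np.zeros((L * q, M))
    idx = _flat_index(rows, q)
    np.add.at(gW, idx.ravel(), np.repeat(dh, L, axis=0))
    return gW.reshape(L, q, M)


@dataclass
class SSLBatch:
    """Weighted unlabeled sequences plus labeled (sequence, PamLabel) pairs."""

    rows: np.ndarray
    weights: np.ndarray
    labeled_rows: np.ndarray
    labels: list[PamLabel]


def ssl_train_step(batch: SSLBatch, rbm: RBMParams, cls: ClassifierParams,
                   chains: np.ndarray, opt_rbm: AdamW, opt_cls: AdamW,
                   gibbs_steps: int, rng: np.random.Generator,
                   n_label_draws: int = 1,
                   freeze_coupling_path: bool = False
                   ) -> tuple[np.ndarray, dict[str, float]]:
    """One optimizer update on (g, W, classifier) for the joint loss.

    The classifier path is skipped entirely at gamma = 0 (no extra RNG use),
    so the update reduces exactly to the unsupervised PCD step.
    ``freeze_coupling_path`` stops the classifier gradient from flowing into
    W (ablation flag).
    """
    grads, chains = rbm_core.pcd_gradient(
        batch.rows, batch.weights, chains, rbm, gibbs_steps, rng)
    info: dict[str, float] = {}
    cls_grads = None
    if cls.gamma > 0 and len(batch.labels) > 0:
        gW_cls = np.zeros_like(rbm.W)
        acc_w = np.zeros_like(cls.dense_w)
        acc_b = np.zeros_like(cls.dense_b)
        loss = 0.0
        for _ in range(n_label_draws):
            h = rbm_core.sample_h_given_x(batch.labeled_rows, rbm, rng)
            li, cg = _classifier_loss_grads(batch.labels, h, cls, mode="train")
            loss += li
            acc_w += cg["dense_w"]
            acc_b += cg["dense_b"]
            if not freeze_coupling_path:
                gW_cls += coupling_gradient_from_classifier(
                    batch.labeled_rows, cg["h"], rbm)
        scale = cls.gamma / n_label_draws
        grads["W"] = grads["W"] + scale * gW_cls
        cls_grads = {"dense_w": scale * acc_w, "dense_b": scale * acc_b}
        info["classifier_loss"] = loss / n_label_draws
    opt_rbm.step({"g": rbm.g, "W": rbm.W}, grads)
    if cls_grads is not None:
        opt_cls.step({"dense_w": cls.dense_w, "dense_b": cls.dense_b},
                     cls_grads)
    return chains, info


def train_ssl_rbm(aln: Alignment, labels: list[PamLabel], config: TrainConfig,
                  gamma: float, n_positions: int = 5,
                  freeze_coupling_path: bool = False
                  ) -> tuple[RBMParams, ClassifierParams, list[dict]]:
    """Joint PCD + classifier training; delegates the loop to rbm_core.

    Labeled pairs are re-presented in full at every update (the labeled set is
    small by construction).  Deterministic given config.seed.
    """
    label_ids = {lab.seq_id for lab in labels}
    id_to_row = {sid: i for i, sid in enumerate(aln.ids)}
    keep = [lab for lab in labels if lab.seq_id in id_to_row]
    labeled_rows = np.array(
        [aln.rows[id_to_row[lab.seq_id]] for lab in keep], dtype=np.int64
    ).reshape(len(keep), aln.L)
    del label_ids
    cls_rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed & 0x7FFFFFFF, 0x5513]))
    cls = init_classifier(config.hidden_units, gamma, cls_rng, n_positions)
    opt_cls = AdamW(lr=config.learning_rate, weight_decay=config.weight_decay)

    if gamma > 0 and len(keep) > 0:
        def hook(params: RBMParams, rng: np.random.Generator):
            h = rbm_core.sample_h_given_x(labeled_rows, params, rng)
            loss, cg = _classifier_loss_grads(keep, h, cls, mode="train")
            opt_cls.step({"dense_w": cls.dense_w, "dense_b": cls.dense_b},
                         {"dense_w": gamma * cg["dense_w"],
                          "dense_b": gamma * cg["dense_b"]})
            if freeze_coupling_path:
                return None
            return gamma * coupling_gradient_from_classifier(
                labeled_rows, cg["h"], params)
    else:
        hook = None
    rbm, log = rbm_core.train_rbm(aln, config, grad_hook=hook)
    return rbm, cls, log


def predict_pam(x: np.ndarray, rbm: RBMParams, cls: ClassifierParams
                ) -> tuple[np.ndarray, str]:
    """Per-unit probabilities (predict mode, deterministic) + IUPAC motif.

    The motif string maps the per-position sets of units with probability
    > 0.5 back to IUPAC codes.
    """
    h = input_current(np.atleast_2d(x), rbm)
    probs = classifier_forward(h, cls, mode="predict")[0]
    accepted = (probs > 0.5).astype(np.int8).reshape(cls.n_positions, 4)
    return probs, pam_matrix_to_motif(accepted)


def predict_pam_probs(rows: np.ndarray, rbm: RBMParams,
                      cls: ClassifierParams) -> np.ndarray:
    """Batched predict-mode probabilities, shape (n, K)."""
    h = input_current(np.atleast_2d(rows), rbm)
    return classifier_forward(h, cls, mode="predict")


def gamma_sweep(aln: Alignment, labels: list[PamLabel], gammas,
                config: TrainConfig, validation_fraction: float = 0.10,
                n_positions: int = 5) -> pd.DataFrame:
    """Train one SSL-RBM per gamma and score it on a cluster-disjoint split.

    Returns a table with one row per gamma: (gamma, seed, mean_auc,
    n_units_evaluated, per_unit_auc).  The split and the per-unit AUC follow
    the evaluation procedure in scoring_eval.
    """
    from .scoring_eval import mean_pam_auc

    train_aln, val_aln = split_train_validation(
        aln, SplitSpec(validation_fraction=validation_fraction,
                       seed=config.seed))
    train_ids = set(train_aln.ids)
    val_ids = {sid: i for i, sid in enumerate(val_aln.ids)}
    train_labels = [lab for lab in labels if lab.seq_id in train_ids]
    val_labels = [lab for lab in labels if lab.seq_id in val_ids]
    if not val_labels:
        raise ValueError("no labeled sequences fall in the validation split")
    val_rows = np.stack([val_aln.rows[val_ids[lab.seq_id]]
                         for lab in val_labels])
    records = []
    for gamma in gammas:
        rbm, cls, _ = train_ssl_rbm(train_aln, train_labels, config,
                                    gamma=float(gamma),
                                    n_positions=n_positions)
        probs = predict_pam_probs(val_rows, rbm, cls)
        per_unit, mean_auc = mean_pam_auc(probs, val_labels)
        records.append({
            "gamma": float(gamma),
            "seed": config.seed,
            "mean_auc": mean_auc,
            "n_units_evaluated": int(np.sum(np.isfinite(per_unit))),
            "per_unit_auc": ",".join(
                "" if not np.isfinite(a) else f"{a:.4f}" for a in per_unit),
        })
    return pd.DataFrame.from_records(records)
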