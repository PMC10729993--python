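"""Planted RBM families, latent-derived labels and stand-in structural scores.

The generator plants an RBM with known parameters and draws an aligned family
from it by Gibbs sampling, so that every other module can be exercised and
validated against a ground truth without any external data.  Fields are drawn
per column with realistic conservation (most columns carry one or a few
dominant residues); hidden units are sparse and compositional — each unit is
strongly coupled to a small subset of columns — which is the weight structure
reported for RBMs trained on natural protein families, and it gives the
family the collective covariation the navigation method relies on.

Labels emulate scarce functional annotations: per-unit acceptance
probabilities are a logistic function of a linear readout of the mean hidden
representation, corrupted by label-flip noise, attached to a small fraction
of sequences.  The synthetic structural scorer is the planted free energy
plus a fixed random quadratic perturbation: correlated with, but not
identical to, the model's own score, standing in for an external
stability-style score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rbm_core
from .msa_io import PROTEIN_ALPHABET, Alignment, PamLabel
from .rbm_core import RBMParams, input_current


@dataclass
class PlantedModel:
    """Ground-truth RBM plus the latent label map and scorer perturbation."""

    rbm: RBMParams
    label_units: np.ndarray     # hidden indices the labels depend on
    label_w: np.ndarray         # (n_label_units, K)
    label_b: np.ndarray         # (K,)
    label_scale: float
    scorer_b: np.ndarray        # (L, q) quadratic-perturbation loadings
    scorer_scale: float
    seed: int

    @property
    def n_label_units(self) -> int:
        return len(self.label_units)


def make_planted_model(L: int = 300, q: int = 21, M: int = 50,
                       coupling_scale: float = 1.0, seed: int = 0,
                       field_scale: float = 2.5,
                       units_per_column: float = 2.5,
                       n_label_units: int = 10, label_scale: float = 1.0,
                       scorer_scale: float = 0.8) -> PlantedModel:
    """Plant an RBM family model, deterministic by seed.

    Couplings are sparse: each hidden unit touches ~L * units_per_column / M
    columns with entries of standard deviation ``coupling_scale``; with
    coupling_scale = 0 the model is independent-site.  Fields are i.i.d.
    normal with standard deviation ``field_scale``, giving columns a realistic
    spread of conservation.
    """
    if L < 2 or q < 2 or M < 1:
        raise ValueError("need L >= 2, q >= 2, M >= 1")
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, field_scale, size=(L, q))
    W = np.zeros((L, q, M))
    if coupling_scale > 0:
        n_cols = max(2, int(round(L * units_per_column / M)))
        for mu in range(M):
            cols = rng.choice(L, size=min(n_cols, L), replace=False)
            W[cols, :, mu] = rng.normal(
                0.0, coupling_scale, size=(len(cols), q))
            # zero-sum over states per column: pure covariation, no field leak
            W[cols, :, mu] -= W[cols, :, mu].mean(axis=1, keepdims=True)
    alphabet = PROTEIN_ALPHABET if q == len(PROTEIN_ALPHABET) \
        else PROTEIN_ALPHABET[:q]
    rbm = RBMParams(g=g, W=W, alphabet=alphabet)
    units = rng.choice(M, size=min(n_label_units, M), replace=False)
    K = 20
    label_w = rng.normal(0.0, 1.0 / np.sqrt(len(units)), size=(len(units), K))
    label_b = rng.normal(0.0, 0.3, size=K)
    scorer_b = rng.normal(0.0, 1.0, size=(L, q)) / np.sqrt(L)
    return PlantedModel(rbm=rbm, label_units=units, label_w=label_w,
                        label_b=label_b, label_scale=label_scale,
                        scorer_b=scorer_b, scorer_scale=scorer_scale,
                        seed=seed)


def sample_family(model: PlantedModel, n_sequences: int, burn_in: int = 300,
                  thinning: int = 10, seed: int = 0,
                  max_chains: int = 512) -> Alignment:
    """Gibbs-sample an aligned family from the planted model.

    Up to ``max_chains`` parallel chains are initialised uniformly at random
    and equilibrated for ``burn_in`` full sweeps; samples are then taken every
    ``thinning`` sweeps per chain until ``n_sequences`` are collected.
    Weights are uniform; ids are synth_0000...  Deterministic by seed.
    """
    if n_sequences <= 0 or burn_in < 0 or thinning <= 0:
        raise ValueError("positive counts required")
    rbm = model.rbm
    rng = np.random.default_rng(seed)
    n_chains = min(n_sequences, max_chains)
    x = rng.integers(0, rbm.q, size=(n_chains, rbm.L))
    x = rbm_core.gibbs_sweep(x, rbm, rng, burn_in)
    out = [x.copy()]
    collected = n_chains
    while collected < n_sequences:
        x = rbm_core.gibbs_sweep(x, rbm, rng, thinning)
        out.append(x.copy())
        collected += n_chains
    rows = np.concatenate(out, axis=0)[:n_sequences]
    ids = [f"synth_{i:04d}" for i in range(n_sequences)]
    return Alignment(ids=ids, rows=rows, alphabet=rbm.alphabet)


def label_probabilities(model: PlantedModel, rows: np.ndarray) -> np.ndarray:
    """Ground-truth per-unit acceptance probabilities for given sequences."""
    h = input_current(np.atleast_2d(rows), model.rbm)
    z = model.label_scale * (h[:, model.label_units] @ model.label_w) \
        + model.label_b
    return 1.0 / (1.0 + np.exp(-z))


def assign_labels(model: PlantedModel, aln: Alignment,
                  labeled_fraction: float = 0.15, noise: float = 0.1,
                  seed: int = 0) -> list[PamLabel]:
    """Draw noisy latent-derived PAM labels for a subset of sequences.

    Per-unit labels are Bernoulli draws from the planted logistic map, then
    flipped independently with probability ``noise``.  The labeled subset is
    cluster-respecting when clusters are available (whole clusters are
    labeled), otherwise uniform.  The default fraction 0.15 mirrors the
    scarce-label regime the method is meant for.
    """
    if not (0.0 < labeled_fraction <= 1.0):
        raise ValueError("labeled_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    target = max(1, int(round(labeled_fraction * aln.n)))
    if aln.cluster_id is not None:
        cids = rng.permutation(np.unique(aln.cluster_id))
        chosen: list[int] = []
        count = 0
        for c in cids:
            if count >= target:
                break
            members = np.flatnonzero(aln.cluster_id == c)
            chosen.extend(members.tolist())
            count += len(members)
        idx = np.array(chosen[:max(target, 1)])
    else:
        idx = rng.choice(aln.n, size=target, replace=False)
    probs = label_probabilities(model, aln.rows[idx])
    y = (rng.random(probs.shape) < probs).astype(np.int8)
    flips = rng.random(probs.shape) < noise
    y = np.where(flips, 1 - y, y)
    labels = []
    for j, s in enumerate(idx):
        labels.append(PamLabel(seq_id=aln.ids[s],
                               accepted=y[j].reshape(5, 4),
                               mask=np.ones((5, 4), dtype=np.int8)))
    return labels


def synthetic_scorer(model: PlantedModel):
    """A deterministic stand-in for an external structural score.

    scorer(x) = F_true(x)/L + scale * (sum_i b_i(x_i))^2: correlated with the
    planted energy but carrying its own quadratic signal, emulating the
    complementarity between a physics-style score and the sequence model.
    Accepts a batch (n, L) or a single sequence and returns float values.
    """
    b_flat = model.scorer_b.ravel()
    q = model.rbm.q
    L = model.rbm.L

    def scorer(rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows))
        base = rbm_core.energy_score(rows, model.rbm)
        idx = np.arange(L) * q + rows
        v = b_flat[idx].sum(axis=-1)
        return base + model.scorer_scale * v * v

    return scorer


def make_tiny_fixture(seed: int = 20240 % (2 ** 31), n_sequences: int = 60
                      ) -> tuple[PlantedModel, Alignment, list[PamLabel]]:
    """Canonical enumerable fixture: L=5, q=3, M=2 (q**L = 243 states).

    Used by every exact-oracle test; the partition function enumerates in
    well under a second.
    """
    model = make_planted_model(L=5, q=3, M=2, coupling_scale=0.8,
                               field_scale=0.7, units_per_column=1.2,
                               n_label_units=2, seed=seed)
    aln = sample_family(model, n_sequences, burn_in=100, thinning=5,
                        seed=seed + 1)
    labels = assign_labels(model, aln, labeled_fraction=0.5, noise=0.05,
                           seed=seed + 2)
    return model, aln, labels
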