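"""Categorical-visible / Gaussian-hidden Restricted Boltzmann Machine.

The joint law over an encoded sequence x (L categorical units, q states) and
a latent vector h (M Gaussian units) is

    P(x, h) = exp[ sum_i g_i(x_i) - sum_mu h_mu^2 / 2
                   + sum_{i,mu} h_mu W_{i mu}(x_i) ] / Z,

with trainable visible fields g and couplings W and a fixed quadratic hidden
potential.  Integrating out h gives the sequence free energy

    F(x) = - sum_i g_i(x_i) - 1/2 sum_mu I_mu(x)^2,
    I_mu(x) = sum_i W_{i mu}(x_i),

so P(x) = exp(-F(x)) / Z.  The conditionals are h|x ~ N(I(x), Id) and,
per position, x_i|h ~ softmax[g_i(.) + sum_mu h_mu W_{i mu}(.)].

Training maximises the (cluster-weighted) likelihood by persistent
contrastive divergence: the data term is an empirical moment, the model term
is estimated from persistent Gibbs fantasy chains.  An exact-enumeration
oracle (partition function, likelihood, analytic gradient) is provided for
tiny models and is the reference every stochastic estimate is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .msa_io import PROTEIN_ALPHABET, Alignment
from .optim import AdamW

MAX_ENUMERABLE = 10 ** 6


class ModelTooLargeError(ValueError):
    """Raised when exact enumeration is requested for q**L beyond the cap."""


class TrainingDivergedError(RuntimeError):
    """Raised when training produces a non-finite loss or gradient."""


@dataclass
class RBMParams:
    """Trainable RBM parameters: fields g (L x q) and couplings W (L x q x M)."""

    g: np.ndarray
    W: np.ndarray
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.g.ndim != 2 or self.W.ndim != 3 or self.g.shape != self.W.shape[:2]:
            raise ValueError("g must be (L, q) and W must be (L, q, M)")

    @property
    def L(self) -> int:
        return self.g.shape[0]

    @property
    def q(self) -> int:
        return self.g.shape[1]

    @property
    def M(self) -> int:
        return self.W.shape[2]

    def copy(self) -> "RBMParams":
        return RBMParams(self.g.copy(), self.W.copy(), self.alphabet)


def init_params(L: int, q: int, M: int, rng: np.random.Generator,
                alphabet: str | None = None) -> RBMParams:
    """Xavier-style initialisation: W ~ U(-1/sqrt(qL), 1/sqrt(qL)), g = 0."""
    bound = 1.0 / np.sqrt(q * L)
    W = rng.uniform(-bound, bound, size=(L, q, M))
    if alphabet is None:
        alphabet = PROTEIN_ALPHABET if q == len(PROTEIN_ALPHABET) else \
            PROTEIN_ALPHABET[:q]
    return RBMParams(g=np.zeros((L, q)), W=W, alphabet=alphabet)


def _flat_index(x: np.ndarray, q: int) -> np.ndarray:
    """(..., L) codes -> (..., L) flat indices into an (L*q, ...) table."""
    L = x.shape[-1]
    return np.arange(L) * q + x


def input_current(x: np.ndarray, params: RBMParams) -> np.ndarray:
    """I_mu(x) = sum_i W_{i mu}(x_i); x is (..., L), result (..., M)."""
    x = np.asarray(x)
    Wf = params.W.reshape(params.L * params.q, params.M)
    return Wf[_flat_index(x, params.q)].sum(axis=-2)


def sample_h_given_x(x: np.ndarray, params: RBMParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw h ~ N(I(x), Id)."""
    mean = input_current(x, params)
    return mean + rng.standard_normal(mean.shape)


def logits_x_given_h(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """Per-position softmax logits g_i(a) + sum_mu h_mu W_{i mu}(a); (..., L, q)."""
    h = np.asarray(h)
    Wf = params.W.reshape(params.L * params.q, params.M)
    lin = h @ Wf.T  # (..., L*q)
    return params.g + lin.reshape(h.shape[:-1] + (params.L, params.q))


def sample_x_given_h(h: np.ndarray, params: RBMParams,
                     rng: np.random.Generator,
                     n_samples: int | None = None) -> np.ndarray:
    """Draw each position independently from its conditional softmax law.

    With ``n_samples`` set and a single h of shape (M,), returns
    (n_samples, L) draws sharing that representation.
    """
    logits = logits_x_given_h(h, params)
    if n_samples is not None:
        if logits.ndim != 2:
            raise ValueError("n_samples requires a single representation h")
        # shared-representation fast path: one softmax, many draws
        c = np.cumsum(softmax(logits, axis=-1), axis=-1)
        u = rng.random(size=(n_samples, logits.shape[0], 1))
        codes = (c[None, :, :] < u).sum(axis=-1)
        return np.minimum(codes, params.q - 1)
    p = softmax(logits, axis=-1)
    c = np.cumsum(p, axis=-1)
    u = rng.random(size=logits.shape[:-1] + (1,))
    codes = (c < u).sum(axis=-1)
    return np.minimum(codes, params.q - 1)


def argmax_x_given_h(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """Per-position modal decoding of p(x|h)."""
    return np.argmax(logits_x_given_h(h, params), axis=-1)


def gibbs_sweep(x: np.ndarray, params: RBMParams, rng: np.random.Generator,
                n_sweeps: int = 1) -> np.ndarray:
    """Alternate h|x then x|h for ``n_sweeps`` full sweeps."""
    for _ in range(n_sweeps):
        h = sample_h_given_x(x, params, rng)
        x = sample_x_given_h(h, params, rng)
    return x


def free_energy(x: np.ndarray, params: RBMParams) -> np.ndarray:
    """F(x) = -sum_i g_i(x_i) - 1/2 ||I(x)||^2 (additive constant dropped)."""
    x = np.asarray(x)
    gf = params.g.ravel()[_flat_index(x, params.q)].sum(axis=-1)
    I = input_current(x, params)
    return -gf - 0.5 * np.sum(I * I, axis=-1)


def energy_score(x: np.ndarray, params: RBMParams) -> np.ndarray:
    """Length-normalised RBM energy F(x)/L used for reporting and intervals."""
    return free_energy(x, params) / params.L


# ---------------------------------------------------------------------------
# Exact enumeration oracle (tiny models)
# ---------------------------------------------------------------------------

def enumerate_states(L: int, q: int) -> np.ndarray:
    if q ** L > MAX_ENUMERABLE:
        raise ModelTooLargeError(f"q**L = {q}**{L} exceeds {MAX_ENUMERABLE}")
    return np.indices((q,) * L).reshape(L, -1).T.copy()


def exact_log_partition(params: RBMParams) -> float:
    states = enumerate_states(params.L, params.q)
    return float(logsumexp(-free_energy(states, params)))


def exact_distribution(params: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    """All q**L states and their exact probabilities."""
    states = enumerate_states(params.L, params.q)
    logp = -free_energy(states, params)
    logp -= logsumexp(logp)
    return states, np.exp(logp)


def exact_nll(aln: Alignment | np.ndarray, params: RBMParams,
              weights: np.ndarray | None = None) -> float:
    """Weighted mean negative log-likelihood, with Z by enumeration."""
    rows, w = _rows_weights(aln, weights)
    w = w / w.sum()
    logZ = exact_log_partition(params)
    return float(np.sum(w * (free_energy(rows, params) + logZ)))


def _rows_weights(aln, weights):
    if isinstance(aln, Alignment):
        return aln.rows, (aln.weights if weights is None else weights)
    rows = np.asarray(aln)
    if weights is None:
        weights = np.ones(rows.shape[0])
    return rows, np.asarray(weights, dtype=float)


def _moments(rows: np.ndarray, probs: np.ndarray,
             params: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    """Expectations of the energy sufficient statistics under given weights.

    Returns (E[onehot] of shape (L, q), E[onehot_i(a) * I_mu] of shape
    (L, q, M)); ``probs`` must sum to 1.
    """
    L, q, M = params.L, params.q, params.M
    I = input_current(rows, params)  # (n, M)
    idx = _flat_index(rows, q)  # (n, L)
    mg = np.zeros(L * q)
    np.add.at(mg, idx.ravel(), np.repeat(probs, L))
    mW = np.zeros((L * q, M))
    contrib = probs[:, None] * I  # (n, M)
    np.add.at(mW, idx.ravel(), np.repeat(contrib, L, axis=0))
    return mg.reshape(L, q), mW.reshape(L, q, M)


def exact_model_moments(params: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    states, p = exact_distribution(params)
    return _moments(states, p, params)


def exact_nll_grad(aln: Alignment | np.ndarray, params: RBMParams,
                   weights: np.ndarray | None = None
                   ) -> dict[str, np.ndarray]:
    """Analytic gradient of :func:`exact_nll` w.r.t. g and W (tiny models)."""
    rows, w = _rows_weights(aln, weights)
    w = w / w.sum()
    data_g, data_W = _moments(rows, w, params)
    model_g, model_W = exact_model_moments(params)
    return {"g": model_g - data_g, "W": model_W - data_W}


# ---------------------------------------------------------------------------
# Persistent contrastive divergence
# ---------------------------------------------------------------------------

def pcd_gradient(rows: np.ndarray, weights: np.ndarray, chains: np.ndarray,
                 params: RBMParams, gibbs_steps: int,
                 rng: np.random.Generator
                 ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """One PCD estimate of the NLL gradient, plus the advanced chains.

    The data term uses the batch weights renormalised to sum 1 (minibatch
    renormalisation); the model term averages over the persistent chains
    after ``gibbs_steps`` full Gibbs sweeps.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    chains = gibbs_sweep(chains, params, rng, gibbs_steps)
    data_g, data_W = _moments(rows, w, params)
    n_chains = chains.shape[0]
    model_g, model_W = _moments(
        chains, np.full(n_chains, 1.0 / n_chains), params)
    return {"g": model_g - data_g, "W": model_W - data_W}, chains


@dataclass
class TrainConfig:
    """PCD training configuration."""

    n_chains: int = 100
    gibbs_steps: int = 10
    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    batch_size: int = 128
    epochs: int = 100
    seed: int = 0
    hidden_units: int = 200
    init_fields_from_data: bool = True

    def __post_init__(self) -> None:
        for name in ("n_chains", "gibbs_steps", "batch_size", "epochs",
                     "hidden_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0, weight_decay >= 0")


def train_rbm(aln: Alignment, config: TrainConfig,
              params: RBMParams | None = None,
              grad_hook=None) -> tuple[RBMParams, list[dict]]:
    """Fit the RBM to a weighted alignment by PCD with AdamW.

    ``grad_hook(params, rng) -> extra W gradient or None`` lets the
    semi-supervised head inject its coupling gradient per update while the
    core loop (and its RNG stream) stays identical; with no hook this is the
    plain unsupervised trainer.  Returns the fitted parameters and a per-epoch
    log (weighted data free energy as the pseudo-NLL proxy, chain free energy
    and gradient norms).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(aln.L, aln.q, config.hidden_units, rng,
                             alphabet=aln.alphabet)
        if config.init_fields_from_data:
            w = aln.weights / aln.weights.sum()
            freq = np.zeros((aln.L, aln.q))
            np.add.at(freq.reshape(-1), _flat_index(aln.rows, aln.q).ravel(),
                      np.repeat(w, aln.L))
            params.g[:] = np.log(freq + 1e-3)
            params.g -= params.g.mean(axis=1, keepdims=True)
    else:
        params = params.copy()
    opt = AdamW(lr=config.learning_rate, weight_decay=config.weight_decay)
    chains = aln.rows[rng.choice(aln.n, size=config.n_chains, replace=True)].copy()
    log: list[dict] = []
    pdict = {"g": params.g, "W": params.W}
    for epoch in range(config.epochs):
        order = rng.permutation(aln.n)
        gnorm = 0.0
        n_batches = 0
        for start in range(0, aln.n, config.batch_size):
            idx = order[start:start + config.batch_size]
            grads, chains = pcd_gradient(
                aln.rows[idx], aln.weights[idx], chains, params,
                config.gibbs_steps, rng)
            if grad_hook is not None:
                extra = grad_hook(params, rng)
                if extra is not None:
                    grads["W"] = grads["W"] + extra
            opt.step(pdict, grads)
            gnorm += float(np.linalg.norm(grads["W"]))
            n_batches += 1
        w = aln.weights / aln.weights.sum()
        data_f = float(np.sum(w * free_energy(aln.rows, params)))
        chain_f = float(np.mean(free_energy(chains, params)))
        if not (np.isfinite(data_f) and np.isfinite(chain_f)):
            raise TrainingDivergedError(
                f"non-finite free energy at epoch {epoch}: "
                f"data {data_f}, chains {chain_f}")
        log.append({"epoch": epoch, "data_free_energy": data_f,
                    "chain_free_energy": chain_f,
                    "grad_norm": gnorm / max(n_batches, 1)})
    return params, log
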