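"""Constrained Langevin dynamics in the RBM representation space.

Any function f over sequence space is embedded into the latent space as its
conditional expectation phi[f](h) = E_{x|h}[f(x)].  Both the value and the
gradient have simple Monte-Carlo estimators from draws x ~ p(x|h):

    phi[f](h)      ~ mean of f(x),
    grad phi[f](h) = E[f(x) Wx] - E[f(x)] E[Wx]   (Wx = input current I(x)),

i.e. the sample covariance between f and the coupling image of x.  The walk
ascends the embedded objective with Brownian noise and a norm regulariser
lambda that keeps h in the region populated by data representations:

    C = grad phi[f](h) + eps N(0, I) - lambda h.

Each constraint g (to be held at phi[g] = 0) adds a projection term b_t
grad phi[g](h); imposing phi[g](h_{t+1}) = 0 at first order gives

    b_t = -[phi[g](h_t)/alpha + grad phi[g] . C] / ||grad phi[g]||^2,

solved jointly as a k x k linear system when several constraints are active.
Interval criteria (RBM energy, similarity/distance to a reference) measure
the distance outside a time-scheduled interval that ramps linearly over a
horizon of T steps, so a walk can be steered from the reference sequence out
to a target Hamming-distance window while staying on the model's manifold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import rbm_core
from .msa_io import hamming_distance
from .rbm_core import RBMParams, input_current

logger = logging.getLogger(__name__)

CRITERION_KINDS = ("similarity", "rbm_energy_interval", "external_threshold",
                   "scheduled_similarity")


class ExternalScorerError(RuntimeError):
    """External scoring executable failed, timed out or returned bad output."""


def command_scorer(command: list[str], alphabet: str, timeout: float = 600.0):
    """Adapter for an external scoring executable.

    The executable is invoked as ``command <in.fasta> <out.tsv>``; it must
    read sequences from the FASTA file and write ``seq_id<TAB>score`` rows.
    Returns a callable mapping encoded sequence batches to float scores, the
    same contract as a Python scorer, raising :class:`ExternalScorerError` on
    nonzero exit, timeout or missing/unparsable scores.  Stability-predictor
    pipelines (mutate/optimise/score) fit this contract; none is bundled.
    """
    import subprocess
    import tempfile
    from pathlib import Path

    from .msa_io import Alignment, write_alignment

    def scorer(rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows))
        ids = [f"q{i}" for i in range(rows.shape[0])]
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "in.fasta"
            table = Path(tmp) / "out.tsv"
            write_alignment(Alignment(ids=ids, rows=rows, alphabet=alphabet),
                            fasta)
            try:
                proc = subprocess.run(
                    [*command, str(fasta), str(table)],
                    capture_output=True, text=True, timeout=timeout)
            except subprocess.TimeoutExpired as exc:
                raise ExternalScorerError(
                    f"scorer timed out after {timeout}s") from exc
            if proc.returncode != 0:
                raise ExternalScorerError(
                    f"scorer exited {proc.returncode}: {proc.stderr[-500:]}")
            try:
                scores = dict(
                    line.split("\t") for line in
                    table.read_text().splitlines() if line.strip())
                return np.array([float(scores[i]) for i in ids])
            except (OSError, KeyError, ValueError) as exc:
                raise ExternalScorerError(
                    f"unparsable scorer output: {exc}") from exc

    return scorer


@dataclass
class Criterion:
    """An objective or constraint function over sequence space.

    kind:
      similarity           -- count of positions matching (or differing from)
                              the reference, per ``statistic``.
      rbm_energy_interval  -- distance of the normalised RBM energy F(x)/L
                              outside the scheduled interval
                              [t/T * lo, t/T * lo + (hi - lo)].
      external_threshold   -- hinge (f_a(x) - c)_+ on an external scorer.
      scheduled_similarity -- distance of the similarity/distance statistic
                              outside the same scheduled interval form.
    """

    kind: str
    role: str = "constraint"
    x0: np.ndarray | None = None
    statistic: str | None = None  # "similarity" | "distance"
    bounds: tuple[float, float] | None = None
    threshold: float | None = None
    scorer: object | None = None
    horizon: int = 100

    def __post_init__(self) -> None:
        if self.kind not in CRITERION_KINDS:
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.kind in ("similarity", "scheduled_similarity"):
            if self.x0 is None:
                raise ValueError(f"{self.kind} requires a reference sequence")
            self.x0 = np.asarray(self.x0)
            if self.statistic not in ("similarity", "distance"):
                raise ValueError(
                    "similarity criteria must state statistic="
                    "'similarity' or 'distance' explicitly")
        if self.kind in ("rbm_energy_interval", "scheduled_similarity"):
            if self.bounds is None or self.bounds[0] > self.bounds[1]:
                raise ValueError(f"{self.kind} requires ordered bounds")
        if self.kind == "external_threshold":
            if self.scorer is None or self.threshold is None:
                raise ValueError(
                    "external_threshold requires a scorer and a threshold")
        if self.horizon <= 0:
            raise ValueError("schedule horizon must be positive")


def _match_statistic(crit: Criterion, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.shape[-1] != crit.x0.shape[-1]:
        raise ValueError("sequence length does not match the reference")
    sim = np.sum(x == crit.x0, axis=-1).astype(float)
    return sim if crit.statistic == "similarity" else x.shape[-1] - sim


def _interval_excess(value: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.maximum(lo - value, 0.0) + np.maximum(value - hi, 0.0)


def _scheduled_interval(bounds: tuple[float, float], t: float,
                        horizon: int) -> tuple[float, float]:
    frac = min(max(float(t), 0.0), float(horizon)) / float(horizon)
    lo = frac * bounds[0]
    return lo, lo + (bounds[1] - bounds[0])


def criterion_value(crit: Criterion, x: np.ndarray, t: float = 0,
                    rbm: RBMParams | None = None) -> np.ndarray:
    """Evaluate a criterion on encoded sequences x (batched over leading axes)."""
    if crit.kind == "similarity":
        return _match_statistic(crit, x)
    if crit.kind == "scheduled_similarity":
        lo, hi = _scheduled_interval(crit.bounds, t, crit.horizon)
        return _interval_excess(_match_statistic(crit, x), lo, hi)
    if crit.kind == "rbm_energy_interval":
        if rbm is None:
            raise ValueError("rbm_energy_interval requires RBM parameters")
        lo, hi = _scheduled_interval(crit.bounds, t, crit.horizon)
        return _interval_excess(rbm_core.energy_score(x, rbm), lo, hi)
    if crit.kind == "external_threshold":
        vals = np.asarray(crit.scorer(np.atleast_2d(x)), dtype=float)
        if np.asarray(x).ndim == 1:
            vals = vals[0]
        return np.maximum(vals - crit.threshold, 0.0)
    raise AssertionError("unreachable")


def embed_phi(f, h: np.ndarray, rbm: RBMParams, n_samples: int,
              rng: np.random.Generator,
              samples: np.ndarray | None = None
              ) -> tuple[float, np.ndarray]:
    """Monte-Carlo estimate of phi[f](h) and its latent gradient.

    ``f`` maps a batch of encoded sequences (n, L) to n values.  A shared
    sample batch may be passed in so several criteria are estimated on the
    same draws.  The gradient is the centred covariance estimator
    mean[(f - mean f) (Wx - mean Wx)]; for constant f it is exactly zero.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (covariance undefined)")
    if samples is None:
        samples = rbm_core.sample_x_given_h(h, rbm, rng, n_samples=n_samples)
    vals = np.asarray(f(samples), dtype=float)
    wx = input_current(samples, rbm)  # (n, M)
    value = float(vals.mean())
    grad = ((vals - value)[:, None] * wx).mean(axis=0)
    return value, grad


@dataclass
class CLDConfig:
    """Step size alpha, noise scale eps, norm regulariser lam, and budgets."""

    alpha: float = 1e-2
    eps: float = 0.1
    lam: float = 1e-2
    n_samples: int = 200
    n_steps: int = 200
    n_chains: int = 1
    seed: int = 0
    decode: str = "sample"  # or "argmax"
    checkpoint_every: int = 0  # 0 = final step only
    grad_norm_floor: float = 1e-8
    max_correction: float = 2.0  # trust region on the projection move
    final_estimate_factor: int = 4  # extra samples for the final phi-hat

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.eps < 0 or self.lam < 0:
            raise ValueError("alpha > 0, eps >= 0, lam >= 0 required")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_steps <= 0 or self.n_chains <= 0:
            raise ValueError("n_steps and n_chains must be positive")
        if self.decode not in ("sample", "argmax"):
            raise ValueError("decode must be 'sample' or 'argmax'")


ILL_CONDITIONED = 1e8


def _solve_projection(G: np.ndarray, vals: np.ndarray, C: np.ndarray,
                      alpha: float, floor: float) -> np.ndarray:
    """Projection coefficients b for constraints with gradients G (k, M)."""
    k = G.shape[0]
    norms2 = np.sum(G * G, axis=1)
    if k == 1:
        if norms2[0] < floor ** 2:
            logger.warning("constraint gradient ~0; projection skipped")
            return np.zeros(1)
        return np.array([-(vals[0] / alpha + G[0] @ C) / norms2[0]])
    A = G @ G.T
    rhs = -(vals / alpha + G @ C)
    live = norms2 >= floor ** 2
    if not live.all():
        logger.warning("degenerate constraint gradients; projection skipped "
                       "for %d constraint(s)", int((~live).sum()))
    b = np.zeros(k)
    if live.any():
        A_live = A[np.ix_(live, live)]
        if np.linalg.cond(A_live) > ILL_CONDITIONED:
            # sequential single-constraint fallback
            delta = C.copy()
            for j in np.flatnonzero(live):
                bj = -(vals[j] / alpha + G[j] @ delta) / norms2[j]
                b[j] = bj
                delta = delta + bj * G[j]
        else:
            b[live] = np.linalg.lstsq(A_live, rhs[live], rcond=None)[0]
    return b


def cld_step(h: np.ndarray, objective: Criterion | None,
             constraints: list[Criterion], rbm: RBMParams, cfg: CLDConfig,
             t: int, rng: np.random.Generator
             ) -> tuple[np.ndarray, dict]:
    """One constrained Langevin update h -> h + alpha (C + sum_j b_j grad_j).

    All criteria are estimated on one shared batch of n_samples draws from
    p(x|h).  Raises on a non-finite state with step diagnostics.
    """
    samples = rbm_core.sample_x_given_h(h, rbm, rng, n_samples=cfg.n_samples)
    info: dict = {"t": t}
    if objective is not None:
        obj_val, obj_grad = embed_phi(
            lambda s: criterion_value(objective, s, t, rbm), h, rbm,
            cfg.n_samples, rng, samples=samples)
        sign = 1.0
        info["objective"] = obj_val
    else:
        obj_grad = np.zeros_like(h)
        sign = 0.0
    C = sign * obj_grad + cfg.eps * rng.standard_normal(h.shape) - cfg.lam * h
    b = np.zeros(len(constraints))
    if constraints:
        vals = np.empty(len(constraints))
        G = np.empty((len(constraints), h.shape[-1]))
        for j, crit in enumerate(constraints):
            vals[j], G[j] = embed_phi(
                lambda s, c=crit: criterion_value(c, s, t, rbm), h, rbm,
                cfg.n_samples, rng, samples=samples)
        b = _solve_projection(G, vals, C, cfg.alpha, cfg.grad_norm_floor)
        corr = b @ G
        # The projection coefficient is first-order; far outside a
        # constraint's feasible set it prescribes a step beyond the linear
        # regime, so the correction is capped to a trust region and the
        # constraint is closed over several steps instead.
        corr_norm = cfg.alpha * float(np.linalg.norm(corr))
        if corr_norm > cfg.max_correction:
            corr = corr * (cfg.max_correction / corr_norm)
        C = C + corr
        info["constraints"] = vals
    h_next = h + cfg.alpha * C
    if not np.all(np.isfinite(h_next)):
        raise FloatingPointError(
            f"non-finite representation at step {t}: |h|="
            f"{np.linalg.norm(h)}, b={b}")
    info["b"] = b
    return h_next, info


@dataclass
class ChainResult:
    """Per-chain record of a constrained walk."""

    h_norm: np.ndarray                 # (n_steps,)
    objective: np.ndarray              # (n_steps,) or empty
    constraint_values: np.ndarray      # (n_steps, k)
    b: np.ndarray                      # (n_steps, k)
    checkpoints: list[tuple[int, np.ndarray]]
    final_h: np.ndarray
    final_x: np.ndarray
    final_constraints: np.ndarray      # fresh phi-hat estimates at final h


@dataclass
class Trajectory:
    """A multi-chain CLD run with decoded sequences and summary scores."""

    config: CLDConfig
    x0: np.ndarray
    chains: list[ChainResult]

    @property
    def final_sequences(self) -> np.ndarray:
        return np.stack([c.final_x for c in self.chains])

    def final_distances(self) -> np.ndarray:
        return hamming_distance(self.final_sequences, self.x0)

    def qualifying(self, tolerance: float) -> np.ndarray:
        """Chains whose final constraint estimates are all within tolerance."""
        if not self.chains or self.chains[0].final_constraints.size == 0:
            return np.ones(len(self.chains), dtype=bool)
        return np.array([
            np.all(np.abs(c.final_constraints) <= tolerance)
            for c in self.chains
        ])


def _decode(h: np.ndarray, rbm: RBMParams, cfg: CLDConfig,
            rng: np.random.Generator) -> np.ndarray:
    if cfg.decode == "argmax":
        return rbm_core.argmax_x_given_h(h, rbm)
    return rbm_core.sample_x_given_h(h, rbm, rng, n_samples=1)[0]


def run_cld(x0: np.ndarray, objective: Criterion | None,
            constraints: list[Criterion], rbm: RBMParams,
            cfg: CLDConfig) -> Trajectory:
    """Run n_chains constrained walks from h0 = W x0.

    Chains share parameters and differ only by their RNG stream.  Criterion
    estimates, projection coefficients and the norm of h are recorded per
    step; sequences are decoded at checkpoints and at the final step, where a
    fresh estimate of every constraint is also stored.
    """
    x0 = np.asarray(x0)
    h0 = input_current(x0, rbm)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    k = len(constraints)
    chains: list[ChainResult] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        h = h0.copy()
        h_norm = np.empty(cfg.n_steps)
        obj = np.full(cfg.n_steps, np.nan)
        cvals = np.empty((cfg.n_steps, k))
        bs = np.empty((cfg.n_steps, k))
        checkpoints: list[tuple[int, np.ndarray]] = []
        for t in range(cfg.n_steps):
            h, info = cld_step(h, objective, constraints, rbm, cfg, t, rng)
            h_norm[t] = np.linalg.norm(h)
            if objective is not None:
                obj[t] = info["objective"]
            if k:
                cvals[t] = info["constraints"]
            bs[t] = info["b"]
            if cfg.checkpoint_every and (t + 1) % cfg.checkpoint_every == 0:
                checkpoints.append((t, _decode(h, rbm, cfg, rng)))
        final_x = _decode(h, rbm, cfg, rng)
        t_final = cfg.n_steps
        n_final = cfg.n_samples * cfg.final_estimate_factor
        final_c = np.array([
            embed_phi(lambda s, c=crit: criterion_value(c, s, t_final, rbm),
                      h, rbm, n_final, rng)[0]
            for crit in constraints
        ])
        chains.append(ChainResult(
            h_norm=h_norm, objective=obj, constraint_values=cvals, b=bs,
            checkpoints=checkpoints, final_h=h, final_x=final_x,
            final_constraints=final_c))
    return Trajectory(config=cfg, x0=x0, chains=chains)


def design_batch(rbm: RBMParams, objective: Criterion | None,
                 constraints: list[Criterion], cfg: CLDConfig,
                 post_filters: list[tuple[str, object, float]] | None = None,
                 x0: np.ndarray | None = None):
    """Generate a scored, deduplicated design set.

    External scorers may act inside the dynamics (as external_threshold
    constraints; method 1) or as post-hoc filters (``post_filters`` of
    (name, scorer, threshold) tuples; method 2).  Scorer failures flag the
    sequence instead of dropping it.  Returns (DataFrame, unique sequences).
    """
    import pandas as pd

    if x0 is None:
        for crit in ([objective] if objective else []) + list(constraints):
            if crit is not None and crit.x0 is not None:
                x0 = crit.x0
                break
    if x0 is None:
        raise ValueError("no starting sequence: pass x0 or a similarity "
                         "criterion carrying one")
    traj = run_cld(x0, objective, constraints, rbm, cfg)
    seqs = [x for c in traj.chains for _, x in c.checkpoints]
    seqs += [c.final_x for c in traj.chains]
    uniq = np.unique(np.stack(seqs), axis=0)
    table = {
        "seq_id": [f"design_{i:04d}" for i in range(len(uniq))],
        "rbm_energy": rbm_core.energy_score(uniq, rbm),
        "hamming_to_ref": hamming_distance(uniq, x0),
    }
    keep = np.ones(len(uniq), dtype=bool)
    for name, scorer, threshold in (post_filters or []):
        scores = np.full(len(uniq), np.nan)
        failed = np.zeros(len(uniq), dtype=bool)
        try:
            scores = np.asarray(scorer(uniq), dtype=float)
        except Exception:
            # retry row-wise so one failure does not void the batch
            for i, row in enumerate(uniq):
                try:
                    scores[i] = float(np.asarray(
                        scorer(row[None, :]), dtype=float)[0])
                except Exception:
                    failed[i] = True
        table[name] = scores
        table[f"{name}_failed"] = failed
        keep &= failed | ~(scores > threshold)
    df = pd.DataFrame(table)
    df["passes_filters"] = keep
    return df, uniq
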