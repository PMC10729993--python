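# Methods

## The model

`rbmdesign` models an aligned protein family with a Restricted Boltzmann
Machine whose visible layer is the sequence — L categorical units over q = 21
states (20 amino acids and the gap, which is treated as an ordinary symbol
throughout, including in Hamming distances) — and whose hidden layer is a
vector h of M Gaussian units with the fixed quadratic potential U(h) = h²/2.
The joint law is

    P(x, h) ∝ exp[ Σᵢ gᵢ(xᵢ) − ½‖h‖² + Σᵢ,µ hµ Wᵢµ(xᵢ) ],

with trainable fields g and couplings W.  Because the hidden potential is
quadratic, the hidden layer integrates out in closed form and the sequence
marginal is P(x) ∝ exp(−F(x)) with the free energy

    F(x) = −Σᵢ gᵢ(xᵢ) − ½ Σµ Iµ(x)²,     Iµ(x) = Σᵢ Wᵢµ(xᵢ).

The conditionals are exactly h|x ~ N(I(x), Id) and, independently per column,
x_i|h ~ softmax[gᵢ(·) + Σµ hµ Wᵢµ(·)], which is what makes both Gibbs
sampling and the latent-space machinery below cheap.

**Reported energies.** The literature plots "RBM energy" values of order
−0.3 without stating a normalisation.  This package defines the reported
score as F(x)/L (per-column free energy) and exposes raw F(x) alongside it;
all interval criteria on the RBM energy operate on the normalised score.

## Training

Maximum likelihood by persistent contrastive divergence (PCD): the data term
of the gradient is a weighted empirical moment, the model term is estimated
from persistent fantasy chains advanced a few full Gibbs sweeps per update.
Sequences are weighted 1/|cluster| after greedy clustering at 90% fractional
identity (an external MMseqs2 cluster file can be supplied instead); batch
weights are renormalised within each minibatch.  Parameters are updated with
an adaptive-moment optimizer with decoupled weight decay, implemented here in
NumPy.  Couplings are initialised uniformly in ±1/√(qL); fields are
initialised to the (weighted) log column frequencies, a standard warm start
that removes the trivial part of the learning problem.

Defaults: 100 persistent chains, 10 Gibbs sweeps per update, learning rate
5·10⁻⁴, weight decay 10⁻⁴, batch 128.  The desk-scale studies below use a
slightly more aggressive setting (lr 10⁻³, weight decay 10⁻³, 200 chains)
because the planted families are small and strongly coupled; with few chains
and a low decay the coupling norm grows faster than the fantasy chains can
mix, which shows up as steadily rising gradient norms.

An exact-enumeration oracle (partition function, likelihood and its analytic
gradient) is implemented for models with q^L ≤ 10⁶ and is the reference for
every stochastic estimate: the analytic gradient is verified against central
finite differences to relative error < 10⁻⁵, and PCD moment estimates against
enumerated moments within Monte-Carlo error.

## Semi-supervision

A one-layer classifier reads the hidden representation — a stochastic draw
h ~ N(I(x), Id) during training (cheap data augmentation), the mean I(x) at
prediction time — through a batch-normalisation layer (batch statistics in
training, running statistics at prediction; no learned affine, which the
following dense layer absorbs) and a dense map to K = n_positions × 4 = 20
sigmoid units, one per (PAM position, nucleotide).

The supervised loss is a masked per-unit binary cross-entropy averaged over
observed units.  The label vector is multi-hot (a motif like NGGNN accepts
several nucleotides per position), so independent per-unit Bernoulli
likelihoods are the coherent reading, and they match the per-unit ROC
evaluation used throughout.  Unobserved units (motifs shorter than
n_positions, or unknown positions) are masked, never imputed; fully masked
units receive exactly zero gradient.

The joint loss is L = L_RBM + γ·L_C, and the classifier term back-propagates
into W through the sampled representation (one draw per update by default),
so the latent space itself is shaped by the labels; a flag freezes that path
for ablation.  Both classifier-head and coupling contributions are scaled by
γ, hence γ = 0 reproduces the unsupervised update bit-for-bit and leaves the
head untrained (its sweep point sits at chance AUC by construction).

On-disk label format: `seq_id<TAB>motif` with IUPAC nucleotide codes in
column order (A, T, C, G) per position, plus '-' for an observed position
that accepts nothing (the empty set has no IUPAC code); this makes every
binary acceptance matrix round-trip through its motif string.

## Latent navigation

Any function f over sequences embeds into the latent space as
φ[f](h) = E[f(x) | h].  With n draws from p(x|h), the value is the sample
mean and the gradient is the centred covariance estimator

    ∂φ[f](h) ≈ mean[(f(x) − f̄)(I(x) − Ī)],

exact for constant f and unbiased up to the covariance estimator's
finite-sample bias.  Both are validated against enumeration and central
finite differences on the tiny fixture (relative error < 5% at 10⁵ samples;
error decaying as 1/√n).

The walk starts at h₀ = I(x₀) (the mode of p(h|x₀) for a quadratic
potential) and updates

    h ← h + α ( ∂φ[f](h) + ε N(0, Id) − λ h + Σⱼ bⱼ ∂φ[gⱼ](h) ),

where α is the step size (named α to avoid the collision with the loss
weight γ), ε scales the Brownian noise, and λ regularises ‖h‖, whose
unchecked growth would otherwise carry the walk outside the region populated
by data representations.  Each constraint gⱼ is held near zero by the
first-order projection coefficient; for one constraint

    b = −[ φ̂[g]/α + ∂φ[g]·C ] / ‖∂φ[g]‖²,

the sign being fixed by requiring φ[g](h_{t+1}) = 0 in the Taylor expansion
(a corrective, not amplifying, term).  Several constraints are solved as the
corresponding k×k linear system by least squares, with a sequential
single-constraint fallback when the system is ill-conditioned (condition
number > 10⁸).  Two numerical guards matter in practice:

* constraint gradients below 10⁻⁸ in norm zero their coefficient (with a
  warning) rather than dividing by ~0;
* the projection move is capped to a trust region (default 2.0 in latent
  units per step).  The coefficient is first-order: far outside a
  constraint's feasible set it prescribes a correction well beyond the
  linear regime, which in early experiments drove ‖h‖ to ~10³–10⁴ where the
  conditionals saturate, the constraint gradient vanishes, and the walk
  freezes.  With the cap, the constraint closes over a number of steps and
  the walk stays on scale.

### Criteria

* **similarity / distance to a reference** — Σᵢ 1(xᵢ = x⁰ᵢ), or L minus it.
  Which of the two a run maximises must be stated explicitly in the
  configuration; the two differ only in sign but naming them removes a
  recurring source of confusion about whether "difference to reference" is
  being maximised or minimised.
* **scheduled interval criteria** (RBM energy, similarity/distance) — the
  distance outside a moving interval [lo(t), lo(t) + (c_max − c_min)] with
  lo(t) = (t/T)·c_min, t clamped to the horizon T (default 100).  The value
  is zero on the interval and grows linearly outside, so "hold at zero" is
  attainable; the ramp carries a walk smoothly from its start to the target
  window.
* **external threshold** — the hinge (f_a(x) − c)₊ on an adapter-provided
  scorer (an executable or callable mapping sequences to scores; stability
  predictors fit this contract), used either inside the dynamics or as a
  post-hoc filter on decoded sequences.  Scorer failures flag the sequence
  rather than dropping it.

Decoding at checkpoints draws one sample from p(x|h) (argmax per position is
available as a configuration).  Chains of a multi-chain run differ only in
their RNG streams.  A chain's final constraint values are re-estimated with
4× the per-step sample count; a chain *qualifies* when all of them are within
a tolerance whose default, for sequence-distance constraints, is one amino
acid of average excess outside the window.

## Synthetic data

The generator plants an RBM with known parameters and produces families,
labels and an external-style score from it, so that every pipeline stage is
testable against ground truth without downloads.

* **Fields**: i.i.d. N(0, 2.5²) per (column, state), giving a realistic
  spread of column conservation (dominant-residue frequency around 0.5 in
  sampled families).
* **Couplings**: sparse and compositional — each hidden unit touches a small
  random subset of columns (≈ L·2.5/M of them) with N(0, 1) entries,
  zero-summed over states so they carry pure covariation.  This is the weight
  structure reported for RBMs trained on natural families, and it gives the
  planted family collective modes: moving along a latent direction flips a
  specific set of columns decisively, which is the structure the constrained
  walk exploits.
* **Sampling**: one Gibbs chain per output sequence (up to 512 parallel
  chains), 300 burn-in sweeps, thinning 10 if chains are reused.  For a
  bipartite model this equilibrates quickly; fidelity is verified against the
  enumerated distribution of the tiny fixture by chi-square test rather than
  assumed from sweep counts.
* **Labels**: per-unit acceptance probabilities are a logistic readout of a
  linear map of the mean hidden representation of a random subset of hidden
  units, Bernoulli-sampled, then flipped with probability `noise`; labels
  attach to a cluster-respecting 15% of sequences, mirroring the scarce-label
  regime (~14% coverage) the method targets.  Because the readout is linear
  in the one-hot sequence, a purely supervised classifier *can* represent
  it — the benefit of semi-supervision here is statistical, not
  representational, and it only shows when labels are scarce and noisy
  enough that the unlabeled family structure regularises the fit.  The
  benefit study therefore uses flip noise 0.25.
* **Synthetic scorer**: planted free energy per column plus a fixed random
  quadratic perturbation (scale 0.8), rank-correlated with the true energy
  (ρ ∈ (0.3, 0.95) across desk-scale settings) but not identical — a
  stand-in for the complementarity between a physics-style score and the
  sequence model.
* **Tiny fixture**: L = 5, q = 3, M = 2 (3⁵ = 243 states), enumerable in
  well under a second; every oracle test runs on it.

## Desk-scale studies

Two end-to-end studies live in `rbmdesign.experiments` and are executed both
by the test suite and by `scripts/acceptance.py`:

* **Constrained-walk study** — planted family with L = 300, n = 500, M = 50;
  PCD training for 200 epochs; 10 chains steered from one training sequence
  by a scheduled distance constraint ramping to the window [50, 55] over 100
  steps and held for 200 more (α = 10⁻², ε = 0.02, λ = 10⁻², 600 samples per
  estimate).  Success is ≥ 80% of chains decoding a final sequence inside the
  closed window.  The problem size keeps the full study under ~10 minutes on
  one CPU while leaving the window (width 5 at L = 300) a genuinely tight
  target.
* **Gamma-sweep study** — planted families with L = 100, n = 700, M = 40,
  15% labeled, flip noise 0.25; one SSL-RBM per γ ∈ {0, 0.5, 5, 100} per
  seed, 100 epochs each; mean validation AUC per γ on a cluster-disjoint
  15% split.  The expected shape — an interior maximum strictly above both
  the unsupervised endpoint and the classifier-dominated endpoint — is
  required in at least 2 of 3 seeds, reflecting the stochasticity of a small
  study.

What these studies show: that the implemented machinery (training,
embedding, projection, scheduling, evaluation) does on a planted family what
the method is designed to do.  What they do not show: performance on real
protein families, whose phylogenetic correlations, alignment artefacts,
length variation and non-RBM-like higher-order structure the generator does
not emulate; nor anything about wet-lab activity of designed sequences,
which requires experiments.  Published real-data results additionally depend
on an experimental score table and external structure tools, so they are
reachable only through the optional `scripts/validate_real_data.py` entry
point with user-supplied inputs.

## Degenerate inputs and edge conventions

* '.' and lowercase in alignments normalise to gap/uppercase; ambiguous
  residues (X, B, Z, J, U, O) map to gap with a warning (configurable to
  error).  The source family is reported with both 1071 and 1102 sequences
  and both ~10% and ~15% validation fractions in different places; both are
  plain configuration here (validation fraction default 0.10).
* Activity categories put boundary values (0.2, 0.5, 0.8) in the higher
  category; the published category definitions use strict inequalities on
  both sides and leave the boundaries undefined.
* AUC units with a single class among unmasked labels are excluded from the
  mean and reported; columns with < 5 qualifying variants in the
  per-position precision map are null, never zero.
* The classifier score of a query motif is the product of the predicted
  probabilities of the units the query requires accepted (a joint
  probability), with mean-log-probability available behind a flag.
* Splits assign whole clusters; if the requested validation fraction is
  unreachable, the smallest overshooting cluster is added with a warning.
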