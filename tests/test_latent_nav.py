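"""Function embedding, criteria and constrained Langevin dynamics."""

import numpy as np
import pytest
from scipy.special import softmax

from rbmdesign import latent_nav, rbm_core
from rbmdesign.latent_nav import (
    CLDConfig, Criterion, cld_step, criterion_value, design_batch, embed_phi,
    run_cld,
)
from rbmdesign.msa_io import hamming_distance
from rbmdesign.rbm_core import enumerate_states, input_current, \
    logits_x_given_h


def exact_phi(f, h, rbm):
    """Enumerated conditional expectation E[f(x) | h] (oracle)."""
    states = enumerate_states(rbm.L, rbm.q)
    p = softmax(logits_x_given_h(h, rbm), axis=-1)
    px = np.prod(p[np.arange(rbm.L)[None, :], states], axis=1)
    return float(np.sum(px * np.asarray(f(states), dtype=float)))


class TestCriteria:
    def test_similarity_self_match_is_length(self, tiny_aln):
        x0 = tiny_aln.rows[0]
        crit = Criterion(kind="similarity", statistic="similarity", x0=x0)
        assert criterion_value(crit, x0) == tiny_aln.L
        dist = Criterion(kind="similarity", statistic="distance", x0=x0)
        assert criterion_value(dist, x0) == 0

    def test_statistic_must_be_explicit(self, tiny_aln):
        with pytest.raises(ValueError, match="statistic"):
            Criterion(kind="similarity", x0=tiny_aln.rows[0])

    def test_length_mismatch_rejected(self, tiny_aln):
        crit = Criterion(kind="similarity", statistic="similarity",
                         x0=tiny_aln.rows[0])
        with pytest.raises(ValueError, match="length"):
            criterion_value(crit, np.zeros(3, dtype=int))

    def test_external_threshold_hinge(self):
        crit = Criterion(kind="external_threshold", threshold=2.0,
                         scorer=lambda rows: rows.sum(axis=-1).astype(float))
        assert criterion_value(crit, np.array([1, 1, 0])) == 0.0
        assert criterion_value(crit, np.array([2, 2, 0])) == 2.0

    def test_scheduled_interval_at_horizon(self, tiny_aln):
        x0 = tiny_aln.rows[0]
        crit = Criterion(kind="scheduled_similarity", statistic="distance",
                         x0=x0, bounds=(2.0, 4.0), horizon=100)
        inside = x0.copy()
        inside[:3] = (inside[:3] + 1) % tiny_aln.q  # distance 3
        assert criterion_value(crit, inside, t=100) == 0.0
        outside = x0.copy()
        outside[:] = (outside + 1) % tiny_aln.q  # distance 5, excess 1
        assert criterion_value(crit, outside, t=100) == pytest.approx(1.0)

    def test_schedule_clamps_beyond_horizon(self, tiny_aln):
        x0 = tiny_aln.rows[0]
        crit = Criterion(kind="scheduled_similarity", statistic="distance",
                         x0=x0, bounds=(2.0, 4.0), horizon=100)
        x = x0.copy()
        x[0] = (x[0] + 1) % tiny_aln.q  # distance 1
        assert criterion_value(crit, x, t=100) == \
            criterion_value(crit, x, t=10_000)

    def test_energy_interval_schedule(self, tiny_model):
        rbm = tiny_model.rbm
        crit = Criterion(kind="rbm_energy_interval", bounds=(-2.0, -1.0),
                         horizon=100)
        x = np.zeros(rbm.L, dtype=int)
        e = rbm_core.energy_score(x, rbm)
        # at t=0 the interval is [0, width]; at t=T it is [e_min, e_max]
        v0 = criterion_value(crit, x, t=0, rbm=rbm)
        assert v0 == pytest.approx(max(0 - e, 0) + max(e - 1.0, 0))
        vT = criterion_value(crit, x, t=100, rbm=rbm)
        assert vT == pytest.approx(max(-2.0 - e, 0) + max(e + 1.0, 0))


class TestEmbedPhi:
    def test_constant_function(self, tiny_model, rng):
        value, grad = embed_phi(lambda s: np.full(len(s), 3.0),
                                np.zeros(tiny_model.rbm.M), tiny_model.rbm,
                                100, rng)
        assert value == pytest.approx(3.0)
        np.testing.assert_array_equal(grad, 0.0)

    def test_requires_two_samples(self, tiny_model, rng):
        with pytest.raises(ValueError):
            embed_phi(lambda s: np.zeros(len(s)), np.zeros(tiny_model.rbm.M),
                      tiny_model.rbm, 1, rng)

    def test_value_converges_to_enumeration(self, tiny, rng):
        model, aln, _ = tiny
        rbm = model.rbm
        h = rng.normal(size=rbm.M)
        f = lambda s: np.sum(s == aln.rows[0], axis=-1).astype(float)
        exact = exact_phi(f, h, rbm)
        errs = []
        for n in (100, 1000, 10_000):
            reps = [abs(embed_phi(f, h, rbm, n,
                                  np.random.default_rng(100 + r))[0] - exact)
                    for r in range(8)]
            errs.append(np.mean(reps))
        # error shrinks roughly like 1/sqrt(n): one decade in n per sqrt(10)
        assert errs[2] < errs[0] / 3
        assert errs[1] < errs[0]

    def test_gradient_matches_finite_differences(self, tiny, rng):
        model, aln, _ = tiny
        rbm = model.rbm
        h = rng.normal(size=rbm.M) * 0.5
        f = lambda s: np.sum(s == aln.rows[0], axis=-1).astype(float)
        eps = 1e-4
        fd = np.zeros(rbm.M)
        for mu in range(rbm.M):
            e = np.zeros(rbm.M)
            e[mu] = eps
            fd[mu] = (exact_phi(f, h + e, rbm) - exact_phi(f, h - e, rbm)) \
                / (2 * eps)
        _, grad = embed_phi(f, h, rbm, 100_000, np.random.default_rng(7))
        assert np.linalg.norm(grad - fd) / np.linalg.norm(fd) < 0.05


class TestCldStep:
    def test_unconstrained_step_is_estimated_ascent(self, tiny, tiny_model):
        _, aln, _ = tiny
        rbm = tiny_model.rbm
        obj = Criterion(kind="similarity", statistic="similarity",
                        x0=aln.rows[0], role="objective")
        cfg = CLDConfig(alpha=0.05, eps=0.0, lam=0.0, n_samples=200, seed=0)
        h = np.zeros(rbm.M)
        rng_a = np.random.default_rng(42)
        h_next, info = cld_step(h, obj, [], rbm, cfg, 0, rng_a)
        # replay the same RNG stream manually
        rng_b = np.random.default_rng(42)
        samples = rbm_core.sample_x_given_h(h, rbm, rng_b, n_samples=200)
        _, grad = embed_phi(lambda s: criterion_value(obj, s), h, rbm, 200,
                            rng_b, samples=samples)
        rng_b.standard_normal(h.shape)  # the (zero-scaled) noise draw
        np.testing.assert_allclose(h_next, h + 0.05 * grad, rtol=1e-12)

    def test_single_constraint_contraction(self, tiny, tiny_model):
        """First-order projection reduces |phi[g]| when it starts sizable."""
        _, aln, _ = tiny
        rbm = tiny_model.rbm
        x0 = aln.rows[0]
        g_crit = Criterion(kind="scheduled_similarity", statistic="distance",
                           x0=x0, bounds=(1.0, 2.0), horizon=1)
        g_exact = lambda h: exact_phi(
            lambda s: criterion_value(g_crit, s, t=1), h, rbm)
        cfg = CLDConfig(alpha=0.05, eps=0.0, lam=0.0, n_samples=2000, seed=0,
                        max_correction=10.0)
        rng = np.random.default_rng(3)
        improved = total = 0
        for _ in range(100):
            h = rng.normal(size=rbm.M) * 2.0
            before = g_exact(h)
            if before < 0.5:
                continue
            h_next, _ = cld_step(h, None, [g_crit], rbm, cfg, 1, rng)
            total += 1
            if g_exact(h_next) < before:
                improved += 1
        assert total >= 30
        assert improved / total >= 0.9

    def test_degenerate_gradient_guard(self, tiny_model, rng, caplog):
        rbm = tiny_model.rbm
        # a constraint that is identically zero has zero gradient
        crit = Criterion(kind="external_threshold", threshold=10.0,
                         scorer=lambda rows: np.zeros(len(rows)))
        cfg = CLDConfig(alpha=0.01, eps=0.0, lam=0.0, n_samples=50, seed=0)
        h = rng.normal(size=rbm.M)
        with caplog.at_level("WARNING", logger="rbmdesign.latent_nav"):
            h_next, info = cld_step(h, None, [crit], rbm, cfg, 0, rng)
        assert np.all(info["b"] == 0.0)
        assert np.all(np.isfinite(h_next))
        assert any("projection skipped" in r.message for r in caplog.records)


class TestRunCld:
    def test_same_seed_identical_trajectory(self, tiny, tiny_model):
        _, aln, _ = tiny
        crit = Criterion(kind="scheduled_similarity", statistic="distance",
                         x0=aln.rows[0], bounds=(1.0, 3.0), horizon=10)
        cfg = CLDConfig(alpha=0.02, eps=0.1, lam=0.01, n_samples=50,
                        n_steps=15, n_chains=2, seed=5)
        a = run_cld(aln.rows[0], None, [crit], tiny_model.rbm, cfg)
        b = run_cld(aln.rows[0], None, [crit], tiny_model.rbm, cfg)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.final_x, cb.final_x)
            np.testing.assert_array_equal(ca.constraint_values,
                                          cb.constraint_values)

    def test_regularised_walk_stays_bounded(self, tiny, tiny_model):
        """With no objective and no constraints the walk is an
        Ornstein-Uhlenbeck process: the norm of h must not blow up."""
        _, aln, _ = tiny
        rbm = tiny_model.rbm
        lam = 0.05
        cfg = CLDConfig(alpha=0.05, eps=0.5, lam=lam, n_samples=2,
                        n_steps=1000, n_chains=1, seed=8)
        traj = run_cld(aln.rows[0], None, [], rbm, cfg)
        bound = np.linalg.norm(input_current(aln.rows[0], rbm)) \
            + 10 * np.sqrt(rbm.M / (2 * lam))
        assert np.isfinite(traj.chains[0].h_norm).all()
        assert traj.chains[0].h_norm.max() < bound

    def test_distance_window_reached_on_tiny_model(self, tiny, tiny_model):
        """Scaled-down analogue of the full walk study: the scheduled
        distance constraint should place most final sequences in its
        window."""
        _, aln, _ = tiny
        rbm = tiny_model.rbm
        x0 = aln.rows[0]
        crit = Criterion(kind="scheduled_similarity", statistic="distance",
                         x0=x0, bounds=(2.0, 4.0), horizon=30)
        cfg = CLDConfig(alpha=0.02, eps=0.05, lam=0.01, n_samples=400,
                        n_steps=60, n_chains=10, seed=9)
        traj = run_cld(x0, None, [crit], rbm, cfg)
        d = traj.final_distances()
        assert np.mean((d >= 2) & (d <= 4)) >= 0.8


class TestDesignBatch:
    def test_infinite_threshold_removes_nothing(self, tiny, tiny_model):
        _, aln, _ = tiny
        crit = Criterion(kind="scheduled_similarity", statistic="distance",
                         x0=aln.rows[0], bounds=(1.0, 3.0), horizon=10)
        cfg = CLDConfig(alpha=0.02, eps=0.1, lam=0.01, n_samples=50,
                        n_steps=12, n_chains=4, checkpoint_every=4, seed=6)
        scorer = lambda rows: rbm_core.energy_score(rows, tiny_model.rbm)
        df, uniq = design_batch(tiny_model.rbm, None, [crit], cfg,
                                post_filters=[("e", scorer, np.inf)])
        assert df["passes_filters"].all()
        assert len(uniq) <= 4 * (3 + 1)  # chains x (checkpoints + final)
        assert df["seq_id"].is_unique

    def test_scorer_failure_flags_sequence(self, tiny, tiny_model):
        _, aln, _ = tiny
        crit = Criterion(kind="scheduled_similarity", statistic="distance",
                         x0=aln.rows[0], bounds=(1.0, 3.0), horizon=10)
        cfg = CLDConfig(alpha=0.02, eps=0.1, lam=0.01, n_samples=50,
                        n_steps=10, n_chains=3, seed=7)

        calls = {"n": 0}

        def flaky(rows):
            rows = np.atleast_2d(rows)
            if len(rows) > 1:
                raise RuntimeError("batch failure")
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("boom")
            return np.zeros(1)

        df, _ = design_batch(tiny_model.rbm, None, [crit], cfg,
                             post_filters=[("flaky", flaky, 0.5)])
        assert df["flaky_failed"].any()
        assert len(df) == df["seq_id"].nunique()

    def test_command_scorer_adapter_roundtrip(self, tiny, tiny_model,
                                              tmp_path):
        """An external executable following the FASTA -> TSV contract is
        usable exactly like a Python scorer; failures raise with context."""
        import sys
        _, aln, _ = tiny
        script = tmp_path / "scorer.py"
        script.write_text(
            "import sys\n"
            "from Bio import SeqIO\n"
            "with open(sys.argv[2], 'w') as out:\n"
            "    for rec in SeqIO.parse(sys.argv[1], 'fasta'):\n"
            "        out.write(f'{rec.id}\\t{len(set(rec.seq))}\\n')\n")
        scorer = latent_nav.command_scorer([sys.executable, str(script)],
                                           alphabet=aln.alphabet)
        vals = scorer(aln.rows[:5])
        expected = [len(set(aln.sequence(i))) for i in range(5)]
        np.testing.assert_array_equal(vals, expected)
        bad = latent_nav.command_scorer([sys.executable, "-c", "exit(3)"],
                                        alphabet=aln.alphabet)
        with pytest.raises(latent_nav.ExternalScorerError, match="exited 3"):
            bad(aln.rows[:2])

    def test_external_scorer_inside_dynamics(self, tiny, tiny_model):
        """Method 1: an external-score hinge used as a constraint is close
        to zero at the final step for most chains."""
        _, aln, _ = tiny
        rbm = tiny_model.rbm
        scorer = lambda rows: rbm_core.energy_score(rows, rbm)
        c = float(np.median(scorer(aln.rows)))
        crit = Criterion(kind="external_threshold", threshold=c,
                         scorer=scorer)
        cfg = CLDConfig(alpha=0.02, eps=0.05, lam=0.01, n_samples=300,
                        n_steps=40, n_chains=10, seed=11)
        traj = run_cld(aln.rows[0], None, [crit], rbm, cfg)
        final = np.array([ch.final_constraints[0] for ch in traj.chains])
        assert np.mean(final < 0.25) >= 0.8
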