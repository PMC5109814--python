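"""Dynamic-logic engine: associations, similarity, updates, annealing,
structural adaptation, and the full loop."""

import numpy as np
import pytest

from dynlogic.engine import (
    EngineConfig,
    EngineError,
    adapt_structure,
    anneal,
    associations,
    emotion_trace,
    log_similarity,
    run_dl,
    update_weights,
    vague_init,
)
from dynlogic.families import ComponentState, MixtureState, bernoulli_likelihood
from dynlogic.observations import Domain, ObservationSet
from dynlogic.scenes import SceneSpec, simulate_scene


def bernoulli_obs(x, w=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = len(x)
    return ObservationSet(
        ids=np.arange(n),
        weights=np.ones(n) if w is None else np.asarray(w, float),
        dialect="features",
        features=x,
    )


def bernoulli_mixture(ps, rs):
    comps = [
        ComponentState(m, "bernoulli", {"p": np.asarray(p, float)}, r=float(r))
        for m, (p, r) in enumerate(zip(ps, rs))
    ]
    return MixtureState(comps)


# ---------------------------------------------------------------------------
# Brute-force oracle: direct evaluation of the association, similarity and
# update formulas with plain Python loops (no shared code with the engine).


def oracle_f(ps, rs, x, eps=1e-6):
    M, N = len(ps), len(x)
    lik = np.zeros((M, N))
    for m in range(M):
        for n in range(N):
            val = 1.0
            for i in range(len(x[n])):
                p = min(max(ps[m][i], eps), 1 - eps)
                val *= p ** x[n][i] * (1 - p) ** (1 - x[n][i])
            lik[m, n] = val
    f = np.zeros((M, N))
    for n in range(N):
        denom = sum(rs[m] * lik[m, n] for m in range(M))
        for m in range(M):
            f[m, n] = rs[m] * lik[m, n] / denom
    return f, lik


def oracle_ll(ps, rs, x, w):
    _, lik = oracle_f(ps, rs, x)
    return sum(
        w[n] * np.log(sum(rs[m] * lik[m, n] for m in range(len(ps))))
        for n in range(len(x))
    )


def oracle_r(f, w):
    M, N = f.shape
    return np.array(
        [sum(w[n] * f[m, n] for n in range(N)) / sum(w) for m in range(M)]
    )


def oracle_p_update(f, x, w, eps=1e-6):
    M, N = f.shape
    K = x.shape[1]
    p = np.zeros((M, K))
    for m in range(M):
        denom = sum(w[n] * f[m, n] for n in range(N))
        for i in range(K):
            p[m, i] = sum(w[n] * f[m, n] * x[n, i] for n in range(N)) / denom
    # probabilities are clamped away from 0/1 to keep log-likelihoods finite
    return np.clip(p, eps, 1 - eps)


class TestAssociations:
    def test_single_component_is_one(self, feature_obs):
        mix = bernoulli_mixture([np.full(6, 0.4)], [1.0])
        f = associations(mix, feature_obs)
        np.testing.assert_allclose(f, 1.0, atol=1e-15)

    def test_identical_components_split_evenly(self, feature_obs):
        p = np.full(6, 0.3)
        mix = bernoulli_mixture([p, p], [0.5, 0.5])
        f = associations(mix, feature_obs)
        np.testing.assert_allclose(f, 0.5, atol=1e-12)

    def test_hand_value(self):
        # x=(1,0), p1=(0.9,0.1), p2=(0.5,0.5), r=(0.5,0.5)
        # f(1|n) = 0.81/(0.81+0.25)
        obs = bernoulli_obs([[1.0, 0.0]])
        mix = bernoulli_mixture([[0.9, 0.1], [0.5, 0.5]], [0.5, 0.5])
        f = associations(mix, obs)
        assert f[0, 0] == pytest.approx(0.81 / 1.06, abs=1e-10)

    def test_columns_sum_to_one(self, feature_obs):
        mix = bernoulli_mixture(
            [np.full(6, 0.2), np.full(6, 0.6), np.full(6, 0.9)],
            [0.2, 0.3, 0.5],
        )
        f = associations(mix, feature_obs)
        np.testing.assert_allclose(f.sum(axis=0), 1.0, atol=1e-12)


class TestLogSimilarity:
    def test_clutter_only_unit_domain_is_zero(self):
        obs = ObservationSet(
            ids=np.arange(5),
            weights=np.ones(5),
            dialect="points",
            positions=np.random.default_rng(0).uniform(0, 1, (5, 2)),
            domain=Domain(1.0, 1.0),
        )
        mix = MixtureState(
            [ComponentState(0, "clutter", {}, r=1.0)], domain=obs.domain
        )
        assert log_similarity(mix, obs) == pytest.approx(0.0, abs=1e-12)

    def test_empty_set_is_zero(self):
        obs = ObservationSet(
            ids=np.array([], dtype=int),
            weights=np.array([]),
            dialect="points",
            positions=np.empty((0, 2)),
            domain=Domain(1.0, 1.0),
        )
        mix = MixtureState(
            [ComponentState(0, "clutter", {}, r=1.0)], domain=obs.domain
        )
        assert log_similarity(mix, obs) == 0.0

    def test_hand_value_single_observation(self):
        obs = bernoulli_obs([[1.0, 0.0]])
        mix = bernoulli_mixture([[0.9, 0.1], [0.5, 0.5]], [0.5, 0.5])
        assert log_similarity(mix, obs) == pytest.approx(np.log(0.53), abs=1e-10)


class TestUpdateWeights:
    def test_single_component(self):
        assert update_weights(np.ones((1, 4)), np.ones(4)) == pytest.approx([1.0])

    def test_hand_value(self):
        f = np.array([[0.8, 0.6], [0.2, 0.4]])
        r = update_weights(f, np.ones(2))
        np.testing.assert_allclose(r, [0.7, 0.3], atol=1e-12)

    def test_normalization_identity(self):
        rng = np.random.default_rng(2)
        f = rng.dirichlet(np.ones(3), size=10).T
        r = update_weights(f, rng.uniform(0.1, 2.0, 10))
        assert r.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_weight_errors(self):
        with pytest.raises(EngineError):
            update_weights(np.ones((1, 3)), np.zeros(3))


class TestOracleEquivalence:
    """Engine vs independent brute-force evaluation on random instances."""

    @pytest.mark.parametrize("trial", range(50))
    def test_f_r_and_m_step_match_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        N = rng.integers(2, 11)
        M = rng.integers(1, 4)
        K = rng.integers(1, 5)
        x = (rng.uniform(size=(N, K)) < 0.5).astype(float)
        w = rng.uniform(0.2, 2.0, N)
        ps = rng.uniform(0.05, 0.95, size=(M, K))
        rs = rng.dirichlet(np.ones(M))
        obs = bernoulli_obs(x, w)
        mix = bernoulli_mixture(ps, rs)

        f = associations(mix, obs)
        f_want, _ = oracle_f(ps, rs, x)
        np.testing.assert_allclose(f, f_want, atol=1e-12)

        ll = log_similarity(mix, obs)
        assert ll == pytest.approx(oracle_ll(ps, rs, x, w), abs=1e-12 * max(1, abs(ll)))

        r = update_weights(f, w)
        np.testing.assert_allclose(r, oracle_r(f_want, w), atol=1e-12)

        from dynlogic.families import m_step

        p_want = oracle_p_update(f_want, x, w)
        for m, comp in enumerate(mix.components):
            new = m_step(comp, obs, f[m], dt=1.0)
            np.testing.assert_allclose(new.params["p"], p_want[m], atol=1e-12)

    def test_blob_m_step_matches_weighted_moments(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            N = rng.integers(3, 11)
            xy = rng.uniform(0, 10, size=(N, 2))
            w = rng.uniform(0.2, 2.0, N)
            f = rng.uniform(0.05, 1.0, N)
            obs = ObservationSet(
                ids=np.arange(N), weights=w, dialect="points",
                positions=xy, domain=Domain(10.0, 10.0),
            )
            comp = ComponentState(
                0, "blob", {"mean": [5.0, 5.0], "cov": np.eye(2)},
                r=1.0, vagueness=1e-9,
            )
            from dynlogic.families import m_step

            new = m_step(comp, obs, f, dt=1.0)
            wf = w * f
            mean_want = wf @ xy / wf.sum()
            d = xy - mean_want
            cov_want = (d * wf[:, None]).T @ d / wf.sum()
            np.testing.assert_allclose(new.params["mean"], mean_want, atol=1e-12)
            np.testing.assert_allclose(new.params["cov"], cov_want, atol=1e-10)


class TestVagueInit:
    def test_bernoulli_near_half(self, feature_obs):
        cfg = EngineConfig(seed=4)
        mix = vague_init(feature_obs, ["bernoulli", "bernoulli"], cfg)
        for comp in mix.components:
            assert np.all(np.abs(comp.params["p"] - 0.5) <= 0.01)
        # p(1-p) is maximized at 0.5: init sits within 0.01 of the maximizer
        assert np.all(
            comp.params["p"] * (1 - comp.params["p"]) > 0.25 - 1e-3
        )

    def test_equal_weights_and_clutter_for_scenes(self, point_obs):
        cfg = EngineConfig(seed=0)
        mix = vague_init(point_obs, ["blob"], cfg)
        assert any(c.family == "clutter" for c in mix.components)
        rs = [c.r for c in mix.components]
        np.testing.assert_allclose(rs, 1.0 / len(rs), atol=1e-12)

    def test_same_seed_identical(self, point_obs):
        cfg = EngineConfig(seed=8)
        a = vague_init(point_obs, ["blob"], cfg)
        b = vague_init(point_obs, ["blob"], cfg)
        for ca, cb in zip(a.components, b.components):
            if ca.family == "blob":
                np.testing.assert_array_equal(ca.params["mean"], cb.params["mean"])

    def test_dual_model_language_block_crisp(self):
        rng = np.random.default_rng(0)
        x = (rng.uniform(size=(20, 8)) < 0.5).astype(float)
        obs = ObservationSet(
            ids=np.arange(20), weights=np.ones(20), dialect="features",
            features=x,
            feature_blocks={"cognitive": range(0, 4), "language": range(4, 8)},
        )
        lexicon = np.array([[0.95, 0.05, 0.95, 0.05], [0.05, 0.95, 0.05, 0.95]])
        cfg = EngineConfig(seed=1)
        mix = vague_init(obs, ["bernoulli", "bernoulli"], cfg, lexicon=lexicon)
        for m, comp in enumerate(mix.components):
            np.testing.assert_allclose(
                comp.params["p"][4:], np.clip(lexicon[m], 1e-6, 1 - 1e-6)
            )
            assert np.all(np.abs(comp.params["p"][:4] - 0.5) <= 0.01)

    def test_nonpositive_vagueness_rejected(self):
        with pytest.raises(EngineError):
            EngineConfig(initial_vagueness=0.0)


class TestAnneal:
    def test_floor_sequence_monotone_and_clamped(self, point_obs):
        cfg = EngineConfig(anneal_factor=0.8, floor_min=1.0, seed=0)
        mix = vague_init(point_obs, ["blob"], cfg)
        blob = next(c for c in mix.components if c.family == "blob")
        floors = [blob.vagueness]
        for _ in range(60):
            anneal(mix, cfg)
            floors.append(blob.vagueness)
        diffs = np.diff(floors)
        assert np.all(diffs <= 1e-12)
        assert floors[-1] == pytest.approx(cfg.floor_min)

    def test_factor_one_disables(self, point_obs):
        cfg = EngineConfig(anneal_factor=1.0, seed=0)
        mix = vague_init(point_obs, ["blob"], cfg)
        blob = next(c for c in mix.components if c.family == "blob")
        before = blob.vagueness
        anneal(mix, cfg)
        assert blob.vagueness == before


class TestEMMonotonicity:
    @pytest.mark.parametrize("seed", range(100))
    def test_bernoulli_ll_nondecreasing(self, seed):
        """Fixed structure, fixed floors, dt=1: exact-EM similarity ascent."""
        rng = np.random.default_rng(seed)
        N, M, K = 30, 3, 5
        x = (rng.uniform(size=(N, K)) < rng.uniform(0.2, 0.8, K)).astype(float)
        obs = bernoulli_obs(x)
        ps = rng.uniform(0.2, 0.8, size=(M, K))
        rs = rng.dirichlet(np.ones(M))
        mix = bernoulli_mixture(ps, rs)
        for c in mix.components:
            c.vagueness = 0.0
        from dynlogic.engine import _em_sweep

        cfg = EngineConfig(dt=1.0, seed=seed)
        ll_prev = log_similarity(mix, obs)
        for _ in range(50):
            _em_sweep(mix, obs, cfg)
            ll = log_similarity(mix, obs)
            assert ll >= ll_prev - 1e-9
            ll_prev = ll


class TestStructuralAdaptation:
    def test_rejected_moves_leave_state_identical(self, feature_obs):
        cfg = EngineConfig(seed=0, structure_penalty=1e9, adapt=True)
        mix = vague_init(feature_obs, ["bernoulli"], cfg)
        before = [c.to_record() for c in mix.components]
        after, events = adapt_structure(mix, feature_obs, cfg)
        assert all(not e.accepted for e in events)
        assert [c.to_record() for c in after.components] == before

    def test_two_blob_split_accepted(self):
        rng = np.random.default_rng(1)
        a = rng.normal([3.0, 3.0], 0.4, size=(150, 2))
        b = rng.normal([9.0, 9.0], 0.4, size=(150, 2))
        xy = np.clip(np.vstack([a, b]), 0, 12)
        obs = ObservationSet(
            ids=np.arange(300), weights=np.ones(300), dialect="points",
            positions=xy, domain=Domain(12.0, 12.0),
        )
        cfg = EngineConfig(
            seed=0, floor_min=0.05, anneal_factor=0.8, settle_iterations=20,
            structure_penalty=None, adapt=True,
        )
        from dynlogic.engine import _em_sweep, penalized_ll

        mix = vague_init(obs, ["blob"], cfg)
        for _ in range(40):
            _em_sweep(mix, obs, cfg)
            anneal(mix, cfg)
        base = penalized_ll(mix, obs, cfg)
        after, events = adapt_structure(mix, obs, cfg)
        split_like = [e for e in events if e.accepted]
        assert split_like, "no structural move accepted on two-blob data"
        assert penalized_ll(after, obs, cfg) > base


class TestRunDL:
    def test_single_blob_recovery(self):
        rng = np.random.default_rng(0)
        truth = np.array([6.0, 4.0])
        pts = np.clip(rng.normal(truth, 0.5, size=(300, 2)), 0, 10)
        obs = ObservationSet(
            ids=np.arange(300), weights=np.ones(300), dialect="points",
            positions=pts, domain=Domain(10.0, 10.0),
        )
        cfg = EngineConfig(
            seed=1, floor_min=0.05, anneal_factor=0.85, max_iterations=120,
            convergence_tol=1e-7, adapt=False,
        )
        rep = run_dl(obs, cfg, families=["clutter", "blob"])
        blob = next(c for c in rep.mixture.components if c.family == "blob")
        se = 0.5 / np.sqrt(300)
        centroid = pts.mean(axis=0)  # closed-form weighted centroid oracle
        np.testing.assert_allclose(blob.params["mean"], centroid, atol=5 * se)
        np.testing.assert_allclose(blob.params["mean"], truth, atol=4 * se + 0.1)

    def test_determinism_identical_reports(self, feature_obs):
        cfg = EngineConfig(seed=3, max_iterations=40, adapt=False)
        a = run_dl(feature_obs, cfg, families=["bernoulli", "bernoulli"])
        b = run_dl(feature_obs, cfg, families=["bernoulli", "bernoulli"])
        assert a.to_json() == b.to_json()

    def test_normalization_invariants_along_run(self, feature_obs):
        cfg = EngineConfig(seed=5, max_iterations=30, adapt=False)
        rep = run_dl(feature_obs, cfg, families=["bernoulli", "bernoulli"])
        rs = [c.r for c in rep.mixture.components]
        assert sum(rs) == pytest.approx(1.0, abs=1e-12)
        f = associations(rep.mixture, feature_obs)
        np.testing.assert_allclose(f.sum(axis=0), 1.0, atol=1e-12)


class TestEmotionTrace:
    def _report(self, obs, **kw):
        cfg = EngineConfig(seed=2, max_iterations=60, adapt=False, **kw)
        return run_dl(obs, cfg, families=["bernoulli", "bernoulli"])

    def test_telescoping_sum(self, feature_obs):
        rep = self._report(feature_obs)
        d = emotion_trace(rep)
        assert d.sum() == pytest.approx(
            rep.final_ll() - rep.initial_ll, abs=1e-9
        )

    def test_exact_em_phase_nonnegative(self, feature_obs):
        rep = self._report(feature_obs, anneal_factor=1.0)
        # with annealing disabled and fixed structure every step is exact EM
        assert np.all(emotion_trace(rep)[1:] >= -1e-9)

    def test_short_run_empty(self, feature_obs):
        cfg = EngineConfig(seed=2, max_iterations=1, adapt=False)
        rep = run_dl(feature_obs, cfg, families=["bernoulli"])
        assert emotion_trace(rep).size == 0

    def test_converged_run_small_final_gain(self, feature_obs):
        rep = self._report(feature_obs, anneal_factor=1.0, convergence_tol=1e-8)
        if rep.convergence_reason == "similarity_stopped_increasing":
            d = emotion_trace(rep)
            assert abs(d[-1]) < 1e-8 * max(abs(rep.final_ll()), 1.0)
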