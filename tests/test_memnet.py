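"""Unit and property tests for the HC-PFC memory network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memflex as mf
from memflex.memnet import _k_wta, default_cue


# ---------------------------------------------------------------------------
# Configuration and construction
# ---------------------------------------------------------------------------

class TestConfig:
    @pytest.mark.parametrize("field,value", [
        ("k_hc", 0), ("k_hc", 43), ("k_pfc", 0), ("p_connect", 1.5),
        ("p_connect", -0.1), ("lambda_plus_assoc", -1.0),
        ("forgetting_ratio", -0.5), ("recall_threshold", 2.0),
        ("noise_range", (0.5, 0.0)),
    ])
    def test_invalid_fields_rejected_by_name(self, field, value):
        with pytest.raises(mf.ConfigError, match=field):
            mf.ModelConfig(**{field: value})

    def test_defaults_match_published_parameterisation(self):
        cfg = mf.ModelConfig()
        assert (cfg.n_hc, cfg.n_pfc, cfg.k_hc, cfg.k_pfc) == (42, 200, 7, 10)
        assert cfg.acquisition_rates() == {
            "hc<-hc": 0.4, "pfc<-hc": 0.4, "hc<-pfc": 0.4, "pfc<-pfc": 0.06}
        assert cfg.consolidation_rates()["pfc<-pfc"] == 0.0025


class TestBuildNetwork:
    def test_saturated_connectivity(self, small_config, rng):
        cfg = mf.ModelConfig(n_hc=10, n_pfc=20, k_hc=3, k_pfc=4,
                             p_connect=1.0)
        st_ = mf.build_network(cfg, rng)
        for block in ("hc<-hc", "pfc<-pfc"):
            m = st_.masks[block]
            assert m.sum() == m.size - m.shape[0]  # all but the diagonal
        assert st_.masks["pfc<-hc"].all()
        assert all(w.max() == 0 for w in st_.weights.values())

    def test_null_network_stays_null(self, rng):
        cfg = mf.ModelConfig(n_hc=10, n_pfc=20, k_hc=3, k_pfc=4,
                             p_connect=0.0)
        st_ = mf.build_network(cfg, rng)
        assert all(not m.any() for m in st_.masks.values())
        p = mf.sample_pattern(cfg, rng, 1)
        mf.acquire(st_, p, cfg)
        assert all((w == 0).all() for w in st_.weights.values())

    def test_connection_density_matches_bernoulli(self, config):
        # Monte Carlo against the binomial expectation at p = 0.5
        n_seeds, n_entries = 1000, config.n_pfc * config.n_hc
        fracs = np.empty(n_seeds)
        for s in range(n_seeds):
            st_ = mf.build_network(config, np.random.default_rng(s))
            fracs[s] = st_.masks["pfc<-hc"].mean()
        se = np.sqrt(0.25 / (n_seeds * n_entries))
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_activity_starts_silent(self, config, rng):
        st_ = mf.build_network(config, rng)
        assert st_.a_hc.sum() == 0 and st_.a_pfc.sum() == 0


# ---------------------------------------------------------------------------
# Pattern sampling
# ---------------------------------------------------------------------------

class TestPatterns:
    def test_pattern_sizes_default(self, config, rng):
        p = mf.sample_pattern(config, rng, 1)
        assert len(p.hc_nodes) == 7 and len(p.pfc_nodes) == 10

    def test_full_layer_pattern(self, rng):
        cfg = mf.ModelConfig(n_hc=5, n_pfc=6, k_hc=5, k_pfc=6)
        p = mf.sample_pattern(cfg, rng)
        assert p.hc_nodes == frozenset(range(5))
        assert p.pfc_nodes == frozenset(range(6))

    def test_overlap_pair_shares_exactly_half_pfc(self, config, rng):
        base = mf.sample_pattern(config, rng, 1)
        for i in range(20):
            pair = mf.sample_overlap_pair(config, base, rng, i)
            assert len(pair.pfc_nodes & base.pfc_nodes) == 5
            assert len(pair.pfc_nodes) == 10

    def test_overlap_pair_minimal(self, rng):
        cfg = mf.ModelConfig(n_hc=4, n_pfc=4, k_hc=2, k_pfc=2)
        base = mf.sample_pattern(cfg, rng, 1)
        pair = mf.sample_overlap_pair(cfg, base, rng, 2)
        assert len(pair.pfc_nodes & base.pfc_nodes) == 1

    def test_odd_k_pfc_warns(self, rng):
        cfg = mf.ModelConfig(n_hc=10, n_pfc=20, k_hc=3, k_pfc=5)
        base = mf.sample_pattern(cfg, rng, 1)
        with pytest.warns(UserWarning, match="odd"):
            pair = mf.sample_overlap_pair(cfg, base, rng, 2)
        assert len(pair.pfc_nodes & base.pfc_nodes) == 2

    def test_overlap_pair_nonshared_nodes_uniform(self, config, rng):
        # chi-square goodness of fit over the complement of the base set
        base = mf.sample_pattern(config, rng, 1)
        complement = sorted(set(range(config.n_pfc)) - base.pfc_nodes)
        counts = dict.fromkeys(complement, 0)
        n_draws = 1000
        for i in range(n_draws):
            pair = mf.sample_overlap_pair(config, base, rng, i)
            for node in pair.pfc_nodes - base.pfc_nodes:
                counts[node] += 1
        from scipy.stats import chisquare
        res = chisquare(list(counts.values()))
        assert res.pvalue > 0.01

    @pytest.mark.parametrize("k,n,expected", [
        (7, 42, 1 / 6), (10, 200, 1 / 20), (5, 5, 1.0)])
    def test_expected_overlap(self, k, n, expected):
        assert mf.expected_overlap(k, n) == pytest.approx(expected)

    @pytest.mark.parametrize("k,n", [(0, 5), (6, 5), (-1, 5)])
    def test_expected_overlap_domain(self, k, n):
        with pytest.raises(ValueError):
            mf.expected_overlap(k, n)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

class TestCycle:
    def test_noise_only_dynamics_pick_largest_noise(self, small_config):
        st_ = mf.build_network(small_config, 0)
        # duplicate the noise stream to predict the winners
        rng_a, rng_b = np.random.default_rng(9), np.random.default_rng(9)
        lo, hi = small_config.noise_range
        noise_hc = rng_b.uniform(lo, hi, small_config.n_hc)
        noise_pfc = rng_b.uniform(lo, hi, small_config.n_pfc)
        mf.cycle(st_, small_config, rng_a)
        expect_hc = np.sort(np.argsort(-noise_hc)[:small_config.k_hc])
        assert np.array_equal(np.flatnonzero(st_.a_hc), expect_hc)
        expect_pfc = np.sort(np.argsort(-noise_pfc)[:small_config.k_pfc])
        assert np.array_equal(np.flatnonzero(st_.a_pfc), expect_pfc)

    def test_argmax_winners(self):
        assert np.array_equal(
            _k_wta(np.array([0.9, 0.7, 0.5, 0.1]), 2, None),
            np.array([1, 1, 0, 0], dtype=np.uint8))

    def test_tie_break_lowest_index(self):
        assert np.array_equal(
            _k_wta(np.zeros(5), 2, None),
            np.array([1, 1, 0, 0, 0], dtype=np.uint8))

    def test_exactly_k_active_per_layer(self, config, rng):
        st_ = mf.build_network(config, rng)
        for _ in range(10):
            mf.cycle(st_, config, rng)
            assert st_.a_hc.sum() == config.k_hc
            assert st_.a_pfc.sum() == config.k_pfc

    def test_clamp_counts_toward_k_and_fills_rest(self):
        active = _k_wta(np.array([0.0, 0.1, 0.9, 0.2]), 2, clamp=[0])
        assert np.array_equal(active, np.array([1, 0, 1, 0], dtype=np.uint8))

    def test_oversized_clamp_rejected(self):
        with pytest.raises(ValueError, match="clamp"):
            _k_wta(np.zeros(5), 2, clamp=[0, 1, 2])

    def test_hc_evolves_independently_without_associative_coupling(self):
        # with zero between-layer weights the HC trajectory cannot depend
        # on anything happening in the PFC layer
        cfg = mf.ModelConfig(lambda_plus_assoc=0.0)
        st_a = mf.build_network(cfg, 3)
        st_b = mf.build_network(cfg, 3)
        st_b.weights["pfc<-pfc"][st_b.masks["pfc<-pfc"]] = 0.7
        rng_a, rng_b = np.random.default_rng(4), np.random.default_rng(4)
        for _ in range(15):
            mf.cycle(st_a, cfg, rng_a)
            mf.cycle(st_b, cfg, rng_b)
            assert np.array_equal(st_a.a_hc, st_b.a_hc)


# ---------------------------------------------------------------------------
# Learning
# ---------------------------------------------------------------------------

class TestLearning:
    @pytest.mark.parametrize("a_post,a_pre,lp,lm,expected", [
        (1, 1, 0.4, 0.3, 0.4),
        (0, 1, 0.4, 0.3, 0.0),
        (0, 0, 0.4, 0.3, 0.0),
        (1, 0, 0.4, 0.3, -0.3),
    ])
    def test_hebbian_delta(self, a_post, a_pre, lp, lm, expected):
        assert mf.hebbian_delta(a_post, a_pre, lp, lm) == pytest.approx(
            expected)

    def test_weights_clipped_at_one(self, small_config, rng):
        st_ = mf.build_network(
            mf.ModelConfig(n_hc=10, n_pfc=20, k_hc=3, k_pfc=4,
                           p_connect=1.0), rng)
        p = mf.sample_pattern(small_config, rng, 1)
        hc = sorted(p.hc_nodes)
        st_.weights["hc<-hc"][np.ix_(hc, hc)] = 0.9
        st_.set_activity(p)
        mf.apply_learning(st_, {"hc<-hc": 0.4}, small_config)
        block = st_.weights["hc<-hc"][np.ix_(hc, hc)]
        off_diag = block[~np.eye(len(hc), dtype=bool)]
        assert np.all(off_diag == 1.0)

    def test_weights_clipped_at_zero(self, small_config, rng):
        st_ = mf.build_network(
            mf.ModelConfig(n_hc=10, n_pfc=20, k_hc=3, k_pfc=4,
                           p_connect=1.0), rng)
        p = mf.sample_pattern(small_config, rng, 1)
        inactive = sorted(set(range(10)) - p.hc_nodes)
        st_.weights["hc<-hc"][np.ix_(sorted(p.hc_nodes), inactive)] = 0.1
        st_.set_activity(p)
        mf.apply_learning(st_, {"hc<-hc": 0.4}, small_config)
        # delta = -0.75*0.4 = -0.3 < -0.1: clipped to 0
        assert np.all(
            st_.weights["hc<-hc"][np.ix_(sorted(p.hc_nodes), inactive)] == 0)

    def test_zero_rate_block_untouched(self, small_config, rng):
        st_ = mf.build_network(small_config, rng)
        st_.weights["pfc<-hc"][st_.masks["pfc<-hc"]] = 0.5
        before = st_.weights["pfc<-hc"].copy()
        p = mf.sample_pattern(small_config, rng, 1)
        st_.set_activity(p)
        mf.apply_learning(st_, {"hc<-hc": 0.4}, small_config)
        assert np.array_equal(st_.weights["pfc<-hc"], before)

    def test_masked_absent_entries_never_learn(self, small_config, rng):
        st_ = mf.build_network(small_config, rng)
        p = mf.sample_pattern(small_config, rng, 1)
        mf.acquire(st_, p, small_config)
        for block in mf.BLOCKS:
            assert np.all(st_.weights[block][~st_.masks[block]] == 0)


class TestAcquire:
    def test_one_shot_encoding_rates(self, config, rng):
        st_ = mf.build_network(config, rng)
        p = mf.sample_pattern(config, rng, 1)
        mf.acquire(st_, p, config)
        hc, pfc = sorted(p.hc_nodes), sorted(p.pfc_nodes)
        # associative pathway: co-active present pairs at 0.4
        blk = st_.weights["pfc<-hc"][np.ix_(pfc, hc)]
        msk = st_.masks["pfc<-hc"][np.ix_(pfc, hc)]
        assert np.all(blk[msk] == 0.4)
        # intra-PFC co-active present pairs at 0.06
        blk = st_.weights["pfc<-pfc"][np.ix_(pfc, pfc)]
        msk = st_.masks["pfc<-pfc"][np.ix_(pfc, pfc)]
        assert np.all(blk[msk] == 0.06)
        # post active / pre inactive: stays at the lower clip
        inactive = sorted(set(range(config.n_pfc)) - p.pfc_nodes)
        assert np.all(st_.weights["pfc<-pfc"][np.ix_(pfc, inactive)] == 0)
        # activity left clamped at the pattern
        assert set(np.flatnonzero(st_.a_pfc)) == p.pfc_nodes


class TestConsolidate:
    def test_only_intra_pfc_weights_change(self, config, rng):
        st_ = mf.build_network(config, rng)
        p = mf.sample_pattern(config, rng, 1)
        mf.acquire(st_, p, config)
        before = {b: st_.weights[b].copy() for b in mf.BLOCKS}
        mf.consolidate(st_, [p], config, rng)
        for block in ("hc<-hc", "pfc<-hc", "hc<-pfc"):
            assert np.array_equal(st_.weights[block], before[block])
        assert not np.array_equal(st_.weights["pfc<-pfc"],
                                  before["pfc<-pfc"])

    def test_zero_repeats_is_identity(self, config, rng):
        cfg = mf.ModelConfig(consolidation_repeats=0)
        st_ = mf.build_network(cfg, rng)
        p = mf.sample_pattern(cfg, rng, 1)
        mf.acquire(st_, p, cfg)
        before = {b: st_.weights[b].copy() for b in mf.BLOCKS}
        a_before = (st_.a_hc.copy(), st_.a_pfc.copy())
        mf.consolidate(st_, [p], cfg, rng)
        for block in mf.BLOCKS:
            assert np.array_equal(st_.weights[block], before[block])
        assert np.array_equal(st_.a_hc, a_before[0])

    def test_empty_pattern_list_rejected(self, config, rng):
        st_ = mf.build_network(config, rng)
        with pytest.raises(ValueError, match="non-empty"):
            mf.consolidate(st_, [], config, rng)

    def test_repeated_reactivation_strengthens_pattern_weights(self, config,
                                                               rng):
        # fixed point of the clipped Hebbian update under reactivation:
        # a single stored pattern's intra-PFC weights climb toward 1
        st_ = mf.build_network(config, rng)
        p = mf.sample_pattern(config, rng, 1)
        mf.acquire(st_, p, config)
        pfc = sorted(p.pfc_nodes)
        sub = np.ix_(pfc, pfc)
        msk = st_.masks["pfc<-pfc"][sub]
        means = []
        for _ in range(25):
            mf.consolidate(st_, [p], config, rng)
            means.append(st_.weights["pfc<-pfc"][sub][msk].mean())
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]
        assert means[-1] > 0.5


# ---------------------------------------------------------------------------
# Lesioning
# ---------------------------------------------------------------------------

class TestLesion:
    def test_zero_fraction_identity(self, config, rng):
        st_ = mf.build_network(config, rng)
        before = st_.masks["pfc<-hc"].copy()
        mf.lesion_hc_to_pfc(st_, 0.0, rng)
        assert np.array_equal(st_.masks["pfc<-hc"], before)

    def test_full_lesion_empties_block(self, config, rng):
        st_ = mf.build_network(config, rng)
        mf.lesion_hc_to_pfc(st_, 1.0, rng)
        assert not st_.masks["pfc<-hc"].any()
        assert np.all(st_.weights["pfc<-hc"] == 0)

    def test_exact_count_removed(self, config, rng):
        st_ = mf.build_network(config, rng)
        m0 = int(st_.masks["pfc<-hc"].sum())
        mf.lesion_hc_to_pfc(st_, 0.2, rng)
        assert int(st_.masks["pfc<-hc"].sum()) == m0 - round(0.2 * m0)

    def test_other_blocks_untouched(self, config, rng):
        st_ = mf.build_network(config, rng)
        before = {b: st_.masks[b].copy() for b in mf.BLOCKS
                  if b != "pfc<-hc"}
        mf.lesion_hc_to_pfc(st_, 0.5, rng)
        for b, m in before.items():
            assert np.array_equal(st_.masks[b], m)

    def test_composing_lesions_never_resurrects(self, config, rng):
        st_ = mf.build_network(config, rng)
        removed = np.zeros_like(st_.masks["pfc<-hc"])
        for frac in (0.2, 0.2, 0.5):
            prev = st_.masks["pfc<-hc"].copy()
            mf.lesion_hc_to_pfc(st_, frac, rng)
            removed |= prev & ~st_.masks["pfc<-hc"]
            assert not (st_.masks["pfc<-hc"] & removed).any()

    @pytest.mark.parametrize("fraction", [-0.1, 1.1])
    def test_fraction_domain(self, config, rng, fraction):
        st_ = mf.build_network(config, rng)
        with pytest.raises(ValueError):
            mf.lesion_hc_to_pfc(st_, fraction, rng)


# ---------------------------------------------------------------------------
# Recall
# ---------------------------------------------------------------------------

class TestRecallScore:
    def test_direct_set_arithmetic(self):
        score = mf.recall_score(set(range(1, 11)), set(range(1, 6)),
                                {1, 2, 3, 4, 5, 6, 7, 8, 21, 22})
        assert score == pytest.approx(0.6)

    def test_superset_retrieval_is_perfect(self):
        assert mf.recall_score({1, 2, 3, 4}, {1, 2},
                               {1, 2, 3, 4, 5, 6}) == 1.0

    def test_disjoint_retrieval_is_zero(self):
        assert mf.recall_score({1, 2, 3, 4}, {1, 2}, {9, 10}) == 0.0

    def test_cue_equal_pattern_undefined(self):
        with pytest.raises(ValueError):
            mf.recall_score({1, 2}, {1, 2}, {1, 2})


class TestRecall:
    def test_perfect_attractor_completion(self, config, rng):
        # hand-built weights storing one pattern: cue completes it fully
        cfg = mf.ModelConfig(p_connect=1.0)
        st_ = mf.build_network(cfg, rng)
        p = mf.sample_pattern(cfg, rng, 1)
        pfc = sorted(p.pfc_nodes)
        st_.weights["pfc<-pfc"][np.ix_(pfc, pfc)] = \
            st_.masks["pfc<-pfc"][np.ix_(pfc, pfc)] * 1.0
        res = mf.recall(st_, p, cfg, rng)
        assert res.score == 1.0 and res.success

    def test_untrained_network_scores_at_chance(self, config, rng):
        st_ = mf.build_network(config, rng)
        p = mf.sample_pattern(config, rng, 1)
        scores = [mf.recall(st_, p, config, rng).score for _ in range(200)]
        # chance = expected overlap of k_pfc random winners with the 5
        # uncued pattern nodes ~ k/n; far below the success threshold
        assert np.mean(scores) < 0.15
        assert not any(s > 0.9 for s in scores)

    def test_recall_never_modifies_weights(self, config, rng):
        st_ = mf.build_network(config, rng)
        p = mf.sample_pattern(config, rng, 1)
        mf.acquire(st_, p, config)
        before = {b: st_.weights[b].copy() for b in mf.BLOCKS}
        mf.recall(st_, p, config, rng)
        for block in mf.BLOCKS:
            assert np.array_equal(st_.weights[block], before[block])

    def test_default_cue_is_deterministic_half(self, config, rng):
        p = mf.sample_pattern(config, rng, 1)
        cue = default_cue(p, config)
        assert cue == frozenset(sorted(p.pfc_nodes)[:5])
        assert default_cue(p, config) == cue


class TestChance:
    def test_stable_across_seeds(self, config):
        st_ = mf.build_network(config, 0)
        a = mf.chance_score(st_, config, 1, n_draws=1000)
        b = mf.chance_score(st_, config, 2, n_draws=1000)
        se = np.hypot(a.sem, b.sem)
        assert abs(a.mean - b.mean) < 3 * se

    def test_single_draw_in_unit_interval(self, config, rng):
        st_ = mf.build_network(config, rng)
        est = mf.chance_score(st_, config, rng, n_draws=1)
        assert 0.0 <= est.mean <= 1.0

    def test_drawn_probes_avoid_learned_patterns(self, rng):
        # layer so small that collisions with the learned set are certain
        cfg = mf.ModelConfig(n_hc=4, n_pfc=4, k_hc=2, k_pfc=2)
        st_ = mf.build_network(cfg, rng)
        learned = [mf.Pattern(1, frozenset({0, 1}), frozenset({a, b}))
                   for a, b in [(0, 1), (0, 2), (0, 3), (1, 2), (2, 3)]]
        est = mf.chance_score(st_, cfg, rng, n_draws=50, learned=learned)
        assert len(est.scores) == 50  # terminated despite 5/6 collisions


# ---------------------------------------------------------------------------
# Protocols and flexibility
# ---------------------------------------------------------------------------

class TestFlexibilityIndex:
    @pytest.mark.parametrize("n_new,n_old,expected", [
        (8, 0, 1.0), (5, 5, 0.0), (0, 5, -1.0), (3, 1, 0.5)])
    def test_endpoints_and_midpoints(self, n_new, n_old, expected):
        assert mf.flexibility_index(n_new, n_old) == pytest.approx(expected)

    def test_undefined_when_no_recalls(self):
        with pytest.raises(ValueError, match="undefined"):
            mf.flexibility_index(0, 0)

    @given(st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        f = mf.flexibility_index(a, b)
        assert -1.0 <= f <= 1.0
        assert f == pytest.approx(-mf.flexibility_index(b, a))


class TestLesionProtocol:
    def test_reproducible_bit_exact(self, config):
        r1 = mf.run_lesion_protocol(config, 0.4, np.random.default_rng(5),
                                    chance_draws=5)
        r2 = mf.run_lesion_protocol(config, 0.4, np.random.default_rng(5),
                                    chance_draws=5)
        assert np.array_equal(r1.final_scores, r2.final_scores)
        assert r1.trajectory.equals(r2.trajectory)
        for b in mf.BLOCKS:
            assert np.array_equal(r1.state.weights[b], r2.state.weights[b])

    def test_probe_trajectory_layout(self, config, rng):
        res = mf.run_lesion_protocol(config, 0.0, rng, chance_draws=2)
        t = res.trajectory
        # probe 1 tested at every step, probe 11 only from step 11
        assert set(t[t.probe_pattern == 1].step) == set(range(1, 21))
        assert set(t[t.probe_pattern == 11].step) == set(range(11, 21))
        assert len(res.final_scores) == 20
        assert ((t.score >= 0) & (t.score <= 1)).all()

    def test_weight_bounds_after_full_protocol(self, config, rng):
        res = mf.run_lesion_protocol(config, 0.6, rng, chance_draws=1)
        for b in mf.BLOCKS:
            w = res.state.weights[b]
            assert w.min() >= 0.0 and w.max() <= 1.0
            assert np.all(w[~res.state.masks[b]] == 0)


class TestConsolidationProportion:
    def test_all_consolidated_gives_half(self):
        assert mf.consolidation_proportion(np.ones(20)) == pytest.approx(0.5)

    def test_only_old_consolidated_gives_zero(self):
        scores = np.r_[np.ones(10), np.zeros(10)]
        assert mf.consolidation_proportion(scores) == 0.0

    def test_none_consolidated_is_nan(self):
        assert np.isnan(mf.consolidation_proportion(np.zeros(20)))


class TestFlexibilitySweep:
    def test_single_sim_single_block_shape(self, config):
        res = mf.run_flexibility_sweep(
            config, forgetting_ratios=[0.75], lesion_fractions=[0.0],
            blocks=1, sims_per_block=1, rng=np.random.default_rng(0))
        assert len(res.per_block) == 1
        assert len(res.summary) == 1
        row = res.summary.iloc[0]
        assert np.isnan(row.sem_flexibility)  # SEM undefined for one block

    def test_tie_policy_validated(self, config, rng):
        with pytest.raises(ValueError, match="tie_policy"):
            mf.run_flexibility_trial(config, 0.0, rng, tie_policy="bogus")

    def test_empty_grid_rejected(self, config):
        with pytest.raises(ValueError):
            mf.run_flexibility_sweep(config, forgetting_ratios=[],
                                     lesion_fractions=[0.0])


# ---------------------------------------------------------------------------
# Property test: weight bounds under random operation sequences
# ---------------------------------------------------------------------------

@given(st.lists(st.sampled_from(["acquire", "consolidate", "lesion",
                                 "recall", "cycle"]),
                min_size=1, max_size=12),
       st.integers(0, 2 ** 31 - 1))
@settings(max_examples=25, deadline=None)
def test_weights_bounded_under_random_operation_sequences(ops, seed):
    cfg = mf.ModelConfig(n_hc=10, n_pfc=20, k_hc=3, k_pfc=4)
    rng = np.random.default_rng(seed)
    state = mf.build_network(cfg, rng)
    learned = [mf.sample_pattern(cfg, rng, 0)]
    mf.acquire(state, learned[0], cfg)
    for op in ops:
        if op == "acquire":
            learned.append(mf.sample_pattern(cfg, rng, len(learned)))
            mf.acquire(state, learned[-1], cfg)
        elif op == "consolidate":
            mf.consolidate(state, learned, cfg, rng)
        elif op == "lesion":
            mf.lesion_hc_to_pfc(state, float(rng.uniform()), rng)
        elif op == "recall":
            mf.recall(state, learned[-1], cfg, rng)
        else:
            mf.cycle(state, cfg, rng)
        for b in mf.BLOCKS:
            w = state.weights[b]
            assert w.min() >= 0.0 and w.max() <= 1.0
            assert np.all(w[~state.masks[b]] == 0)
    assert state.a_hc.sum() in (0, cfg.k_hc)
    assert state.a_pfc.sum() in (0, cfg.k_pfc)
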