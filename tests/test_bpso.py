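"""BPSO mechanics: velocity/position updates, fitness, best bookkeeping."""

from itertools import product

import numpy as np
import pytest

from oralcad.bpso import (
    BpsoConfig,
    Particle,
    _HoldoutFitness,
    _repair_empty,
    bpso_select,
    bpso_select_runs,
    fitness,
    init_swarm,
    sigmoid_transfer,
    update_pbest_gbest,
    update_position,
    update_velocity,
)
from oralcad.datasets import FeatureDataset
from oralcad.synth import FeatureFixtureSpec, make_feature_fixture


def _cfg(**kw):
    defaults = dict(swarm_size=6, max_iter=10, seed=0)
    defaults.update(kw)
    return BpsoConfig(**defaults)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid_transfer(0.0) == pytest.approx(0.5)

    def test_monotone_and_saturating(self):
        v = np.linspace(-30, 30, 101)
        s = sigmoid_transfer(v)
        assert np.all(np.diff(s) > 0)
        assert s[-1] > 1 - 1e-12 and s[0] < 1e-12

    def test_symmetry_identity(self, rng):
        v = rng.normal(scale=5, size=50)
        assert np.allclose(sigmoid_transfer(v) + sigmoid_transfer(-v), 1.0)


class TestInitSwarm:
    def test_shapes_and_binary_positions(self):
        rng = np.random.default_rng(0)
        swarm = init_swarm(5, _cfg(swarm_size=4), rng)
        assert len(swarm) == 4
        for p in swarm:
            assert p.position.shape == (5,)
            assert set(np.unique(p.position)) <= {0, 1}
            assert np.abs(p.velocity).max() <= _cfg().v_max
            assert np.array_equal(p.pbest_position, p.position)

    def test_seeded_determinism(self):
        s1 = init_swarm(7, _cfg(), np.random.default_rng(3))
        s2 = init_swarm(7, _cfg(), np.random.default_rng(3))
        for a, b in zip(s1, s2):
            assert np.array_equal(a.position, b.position)
            assert np.array_equal(a.velocity, b.velocity)

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            init_swarm(0, _cfg(), np.random.default_rng(0))

    def test_empty_mask_repair_sets_one_coordinate(self):
        repaired = _repair_empty(np.zeros(6, dtype=np.int8), np.random.default_rng(1))
        assert repaired.sum() == 1


class TestVelocityUpdate:
    def test_fixed_point_when_all_positions_agree(self):
        x = np.array([1, 0, 1], dtype=np.int8)
        p = Particle(x, np.array([0.5, -1.0, 2.0]), x.copy(), 0.1)
        cfg = BpsoConfig(w_start=1.0, seed=0)
        v = update_velocity(p, x, cfg, np.random.default_rng(0), w=1.0)
        assert np.allclose(v, p.velocity)

    def test_pull_toward_differing_gbest_coordinate(self):
        x = np.zeros(4, dtype=np.int8)
        p = Particle(x, np.zeros(4), x.copy(), 0.1)
        gbest = np.array([0, 0, 1, 0], dtype=np.int8)
        v = update_velocity(p, gbest, _cfg(), np.random.default_rng(1), w=0.0)
        assert np.count_nonzero(v) <= 1
        assert v[2] >= 0  # attraction toward gbest=1

    def test_matches_scalar_transcription_oracle(self):
        rng_draws = np.random.default_rng(9)
        D = 6
        x = (rng_draws.random(D) < 0.5).astype(np.int8)
        vel = rng_draws.normal(size=D)
        pb = (rng_draws.random(D) < 0.5).astype(np.int8)
        gb = (rng_draws.random(D) < 0.5).astype(np.int8)
        p = Particle(x, vel, pb, 0.2)
        cfg = _cfg(c1=1.7, c2=2.3, v_max=4.0)

        got = update_velocity(p, gb, cfg, np.random.default_rng(77), w=0.6)
        # independent scalar loop with the same random draws
        oracle_rng = np.random.default_rng(77)
        r1 = oracle_rng.random(D)
        r2 = oracle_rng.random(D)
        for d in range(D):
            v = 0.6 * vel[d] + 1.7 * r1[d] * (pb[d] - x[d]) + 2.3 * r2[d] * (gb[d] - x[d])
            v = max(-4.0, min(4.0, v))
            assert got[d] == pytest.approx(v)

    def test_clamping_to_vmax(self):
        x = np.zeros(3, dtype=np.int8)
        p = Particle(x, np.full(3, 100.0), np.ones(3, dtype=np.int8), 0.0)
        v = update_velocity(p, np.ones(3, dtype=np.int8), _cfg(v_max=2.0),
                            np.random.default_rng(0), w=1.0)
        assert np.abs(v).max() <= 2.0

    def test_dimension_mismatch(self):
        p = Particle(np.zeros(3, dtype=np.int8), np.zeros(3), np.zeros(3, dtype=np.int8), 0.0)
        with pytest.raises(ValueError):
            update_velocity(p, np.zeros(4), _cfg(), np.random.default_rng(0))


class TestPositionUpdate:
    def test_saturated_velocity_gives_all_ones(self):
        p = Particle(np.zeros(20, dtype=np.int8), np.full(20, 20.0),
                     np.zeros(20, dtype=np.int8), 0.0)
        pos = update_position(p, np.random.default_rng(0))
        assert pos.sum() == 20

    def test_zero_velocity_gives_fair_coins(self):
        p = Particle(np.zeros(10_000, dtype=np.int8), np.zeros(10_000),
                     np.zeros(10_000, dtype=np.int8), 0.0)
        pos = update_position(p, np.random.default_rng(4))
        assert pos.mean() == pytest.approx(0.5, abs=0.02)

    def test_reproducible_with_fixed_stream(self):
        p = Particle(np.zeros(8, dtype=np.int8), np.linspace(-2, 2, 8),
                     np.zeros(8, dtype=np.int8), 0.0)
        a = update_position(p, np.random.default_rng(5))
        b = update_position(p, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestFitness:
    def test_separable_data_reaches_zero_error(self):
        X = np.vstack([np.zeros((20, 2)), np.full((20, 2), 10.0)])
        y = np.repeat([0, 1], 20)
        ds = FeatureDataset(X, y)
        f = fitness(np.array([1, 1]), ds, _cfg(knn_k=1))
        assert f == 0.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(0)
        ds = make_feature_fixture(FeatureFixtureSpec(n_samples=400, seed=2))
        y_perm = rng.permutation(ds.y)
        shuffled = FeatureDataset(ds.X, y_perm)
        f = fitness(np.ones(ds.n_features, dtype=int), shuffled, _cfg())
        assert 0.3 < f < 0.7

    def test_matches_hand_distance_table_at_k1(self):
        # tiny dataset: recover the internal holdout, then recompute the
        # 1-NN error with an explicit distance loop
        rng = np.random.default_rng(3)
        ds = FeatureDataset(rng.normal(size=(8, 3)), np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        cfg = _cfg(knn_k=1)
        hold = _HoldoutFitness(ds, cfg, np.random.default_rng(cfg.seed))
        mask = np.array([1, 0, 1])
        got = hold(mask)
        cols = np.flatnonzero(mask)
        errors = 0
        for xv, yv in zip(hold._Xva, hold._yva):
            d = [np.sum((xv[cols] - xt[cols]) ** 2) for xt in hold._Xtr]
            errors += int(hold._ytr[int(np.argmin(d))] != yv)
        assert got == pytest.approx(errors / len(hold._yva))

    def test_empty_mask_rejected(self, planted_features):
        cfg = _cfg()
        hold = _HoldoutFitness(planted_features, cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            hold(np.zeros(planted_features.n_features, dtype=int))


class TestBestBookkeeping:
    def _particle(self, fit):
        x = np.array([1, 0], dtype=np.int8)
        return Particle(x, np.zeros(2), x.copy(), fit)

    def test_worsening_keeps_pbest(self):
        p = self._particle(0.1)
        old = p.pbest_position.copy()
        update_pbest_gbest([p], np.array([0.5]), old.copy(), 0.1)
        assert p.pbest_fitness == 0.1
        assert np.array_equal(p.pbest_position, old)

    def test_tie_keeps_incumbent(self):
        p = self._particle(0.2)
        p.position = np.array([0, 1], dtype=np.int8)  # different position, equal fitness
        update_pbest_gbest([p], np.array([0.2]), p.pbest_position.copy(), 0.2)
        assert np.array_equal(p.pbest_position, np.array([1, 0]))

    def test_gbest_bounded_by_min_pbest_across_iterations(self, planted_features):
        res = bpso_select(planted_features, _cfg(max_iter=8, seed=5))
        assert res.gbest_fitness == res.fitness_history.min()


class TestBpsoSelect:
    def test_full_run_determinism(self, planted_features):
        r1 = bpso_select(planted_features, _cfg(seed=9))
        r2 = bpso_select(planted_features, _cfg(seed=9))
        assert np.array_equal(r1.gbest_mask, r2.gbest_mask)
        assert np.array_equal(r1.fitness_history, r2.fitness_history)

    def test_history_monotone_nonincreasing(self, planted_features):
        for seed in range(5):
            res = bpso_select(planted_features, _cfg(seed=seed))
            assert np.all(np.diff(res.fitness_history) <= 0)

    def test_gbest_lower_bounded_by_exhaustive_optimum(self):
        ds = make_feature_fixture(
            FeatureFixtureSpec(n_samples=60, n_informative=1, n_noise=4, seed=3)
        )
        cfg = _cfg(swarm_size=10, max_iter=15, seed=2)
        hold = _HoldoutFitness(ds, cfg, np.random.default_rng(cfg.seed))
        exhaustive = min(
            hold(np.array(m)) for m in product([0, 1], repeat=5) if any(m)
        )
        res = bpso_select(ds, cfg)
        assert res.gbest_fitness >= exhaustive - 1e-12

    def test_selected_set_never_empty(self, planted_features):
        for seed in range(3):
            res = bpso_select(planted_features, _cfg(seed=seed, max_iter=5))
            assert res.n_selected >= 1

    def test_single_class_rejected(self):
        ds = FeatureDataset(np.random.default_rng(0).normal(size=(10, 3)), np.zeros(10, int))
        with pytest.raises(ValueError):
            bpso_select(ds, _cfg())

    def test_multi_run_batch_uses_distinct_seeds(self, planted_features):
        runs = bpso_select_runs(planted_features, _cfg(max_iter=5), n_runs=3)
        assert len(runs) == 3
        assert {r.config.seed for r in runs} == {0, 1, 2}


def test_config_validation():
    with pytest.raises(ValueError):
        BpsoConfig(swarm_size=1)
    with pytest.raises(ValueError):
        BpsoConfig(max_iter=0)
    with pytest.raises(ValueError):
        BpsoConfig(v_max=0.0)
    with pytest.raises(ValueError):
        BpsoConfig(knn_k=0)
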