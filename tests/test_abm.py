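"""Agent-based simulator: state invariants, determinism, clearance arithmetic,
sweeps, and mode comparisons.

Fast configurations (small arenas / fragment counts / short durations) are
used everywhere; the full observed-condition runs live in the acceptance
suite.
"""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from gcsearch.abm import (
    CrossoverResult,
    SimConfig,
    SweepCondition,
    SweepResult,
    compare_conditions,
    crossover_density,
    init_state,
    replicate_rates,
    run,
    step,
    sweep,
)
from gcsearch.calibration import MotilityModel
from gcsearch.errors import ValidationError
from gcsearch.spatial_stats import HardSphereNullConfig, monte_carlo_null


def small_cfg(**kw) -> SimConfig:
    base = dict(
        gc_radius=50.0,
        n_tbm=5,
        tbm_diameter=14.0,
        tbm_placement="random",
        n_fragments=120,
        duration=10.0,
        target_mean_nnd=30.0,
        nnd_tolerance=3.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestInitState:
    def test_dispersed_hits_target_nnd(self):
        cfg = SimConfig(tbm_placement="dispersed", n_fragments=0)
        st = init_state(cfg, np.random.default_rng(0))
        d = cdist(st.tbm_pos, st.tbm_pos)
        np.fill_diagonal(d, np.inf)
        assert abs(d.min(axis=1).mean() - 41.0) <= cfg.nnd_tolerance
        assert d.min() >= 27.0 - 1e-9  # hard-sphere non-overlap

    def test_random_placement_mean_nnd_matches_null(self):
        """Random TBM placement reproduces the hard-sphere Monte Carlo null
        built with the TBM radius (13.5 μm) — a cross-module consistency
        check; its mean exceeds the 10-μm null (30.5) but stays well below
        the dispersed 41."""
        cfg = SimConfig(tbm_placement="random", n_fragments=0)
        means = []
        for s in range(30):
            st = init_state(cfg, np.random.default_rng(s))
            d = cdist(st.tbm_pos, st.tbm_pos)
            np.fill_diagonal(d, np.inf)
            means.append(d.min(axis=1).mean())
        null = monte_carlo_null(
            HardSphereNullConfig(sphere_radius=13.5, n_runs=30, seed=99)
        )
        assert np.mean(means) == pytest.approx(null.mean, abs=1.0)

    def test_no_fragments_valid_and_inert(self):
        cfg = small_cfg(n_fragments=0, duration=1.0)
        res = run(cfg, seed=1)
        assert res.removals == 0
        assert res.clearance_rate == 0.0

    def test_fragments_clear_of_tbms_and_inside(self):
        cfg = small_cfg()
        st = init_state(cfg, np.random.default_rng(2))
        assert np.all(np.linalg.norm(st.frag_pos, axis=1) <= cfg.radius - cfg.fragment_radius + 1e-9)
        assert cdist(st.frag_pos, st.tbm_pos).min() > cfg.capture_radius

    def test_meander_chances_in_unit_interval(self):
        st = init_state(small_cfg(), np.random.default_rng(3))
        assert np.all((st.frag_meander >= 0) & (st.frag_meander <= 1))


class TestStep:
    def test_nothing_moves_nothing_cleared(self):
        """Degenerate speed 0 fragments + stationary TBMs: zero removals."""
        frozen = MotilityModel(speed_mu=-60.0, speed_sigma=1e-6, meander_mu=-60.0, meander_sigma=0.0)
        cfg = small_cfg(motility=frozen, duration=5.0)
        res = run(cfg, seed=4)
        assert res.removals == 0

    def test_certain_meander_gives_straight_radial_track(self):
        """meander_chance = 1 means every step moves directly away from the
        spawn point: the pre-reflection trajectory is a straight ray (MI=1)."""
        ballistic = MotilityModel(meander_mu=0.0, meander_sigma=0.0)
        cfg = small_cfg(n_tbm=0, n_fragments=10, motility=ballistic, boundary="reflect")
        rng = np.random.default_rng(5)
        st = init_state(cfg, rng)
        start = st.frag_pos.copy()
        traj = [start]
        for _ in range(8):  # few steps: stay below first reflection
            step(st, cfg)
            traj.append(st.frag_pos.copy())
        traj = np.stack(traj)
        disp = np.linalg.norm(traj[-1] - traj[0], axis=1)
        path = np.linalg.norm(np.diff(traj, axis=0), axis=2).sum(axis=0)
        inside = np.linalg.norm(traj[-1], axis=1) < cfg.radius - 5.0
        assert np.all(disp[inside] / path[inside] > 0.999)

    def test_contact_at_start_removed_first_step(self):
        cfg = small_cfg(n_tbm=1, n_fragments=1, gc_radius=50.0, tbm_diameter=27.0)
        st = init_state(cfg, np.random.default_rng(6))
        st.tbm_pos[0] = np.zeros(3)
        st.frag_pos[0] = np.array([13.0, 0.0, 0.0])  # inside capture radius 15.27
        step(st, cfg)
        assert st.removals == 1

    def test_fragment_count_conserved_and_agents_inside(self):
        cfg = small_cfg()
        st = init_state(cfg, np.random.default_rng(7))
        for _ in range(40):
            step(st, cfg)
            assert st.frag_pos.shape[0] == cfg.n_fragments
            assert np.all(np.linalg.norm(st.frag_pos, axis=1) <= cfg.radius - cfg.fragment_radius + 1e-6)
            assert np.all(np.linalg.norm(st.tbm_pos, axis=1) <= cfg.radius - cfg.tbm_radius + 1e-6)

    def test_migratory_tbms_move_and_stay_disjoint(self):
        cfg = small_cfg(tbm_mode="migratory")
        st = init_state(cfg, np.random.default_rng(8))
        before = st.tbm_pos.copy()
        for _ in range(20):
            step(st, cfg)
        assert np.linalg.norm(st.tbm_pos - before, axis=1).max() > 1.0
        d = cdist(st.tbm_pos, st.tbm_pos)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= cfg.tbm_diameter - 1e-6


class TestRun:
    def test_clearance_rate_arithmetic(self):
        cfg = small_cfg(n_fragments=100, duration=75.0)
        res = run(cfg, seed=9)
        assert res.clearance_rate == pytest.approx(100.0 * res.removals / (100 * 75.0))

    def test_bit_exact_seed_determinism(self):
        cfg = small_cfg(tbm_mode="migratory")
        r1, r2 = run(cfg, seed=123), run(cfg, seed=123)
        assert r1.removals == r2.removals
        np.testing.assert_array_equal(r1.removal_times, r2.removal_times)

    def test_different_seeds_differ(self):
        cfg = small_cfg()
        t1 = run(cfg, seed=1).removal_times
        t2 = run(cfg, seed=2).removal_times
        assert t1.shape != t2.shape or not np.array_equal(t1, t2)

    def test_migratory_speed_zero_equals_stationary(self):
        """tbm_speed = 0 migratory mode is distributionally indistinguishable
        from stationary mode (rank-sum p > 0.05 over 30 replicates)."""
        stat = replicate_rates(small_cfg(tbm_mode="stationary"), 30, seed=10)
        mig0 = replicate_rates(small_cfg(tbm_mode="migratory", tbm_speed=0.0), 30, seed=11)
        assert compare_conditions(stat, mig0) > 0.05

    def test_stationary_clearance_increases_with_tbm_diameter(self):
        lo = replicate_rates(small_cfg(tbm_diameter=10.0), 10, seed=12).mean()
        hi = replicate_rates(small_cfg(tbm_diameter=20.0), 10, seed=13).mean()
        assert hi > lo


class TestCompareConditions:
    def test_identical_vectors_p_one(self):
        x = np.linspace(0.5, 1.5, 12)
        assert compare_conditions(x, x) == pytest.approx(1.0)

    def test_separated_vectors_tiny_p(self, rng):
        a = 1.2 + rng.normal(scale=0.01, size=20)
        b = 0.6 + rng.normal(scale=0.01, size=20)
        assert compare_conditions(a, b) < 1e-6

    def test_single_replicates_warn_p_one(self):
        with pytest.warns(UserWarning, match="no power"):
            assert compare_conditions([1.2], [0.6]) == 1.0


class TestSweep:
    def test_fragment_count_bookkeeping(self):
        res = sweep(small_cfg(duration=2.0), "fragment_count", [10, 50, 100], reps=3, seed=0)
        assert len(res.conditions) == 18 // 3  # 3 values × 2 modes
        assert all(c.rates.size == 3 for c in res.conditions)
        assert len(res.comparisons) == 3

    def test_tbm_volume_axis_monotone_for_stationary(self):
        vols = [4 / 3 * np.pi * r**3 for r in (5.0, 10.0)]
        res = sweep(
            small_cfg(duration=5.0), "tbm_volume", vols, reps=10, seed=1, modes=("stationary",)
        )
        means = [c.rates.mean() for c in res.conditions]
        assert means[1] > means[0]

    def test_speed_grid_realizes_requested_mean_speed(self):
        res = sweep(
            small_cfg(duration=1.0, n_fragments=10),
            "speed_by_count_grid",
            [(6.8, 20)],
            reps=1,
            seed=2,
            modes=("stationary",),
        )
        assert res.conditions[0].summary["value"] == (6.8, 20)


class TestCrossoverDensity:
    @staticmethod
    def _synthetic_sweep(cross_at=500.0):
        """Construct clearance curves that cross exactly at ``cross_at``:
        stationary flat at 1.0, migratory = 1 + slope·(log d − log cross)."""
        densities = [50, 150, 500, 1500, 5000]
        rng = np.random.default_rng(0)
        conds = []
        for d in densities:
            stat = 1.0 + rng.normal(scale=0.01, size=8)
            mig = 1.0 - 0.5 * (np.log10(d) - np.log10(cross_at)) + rng.normal(scale=0.01, size=8)
            conds.append(SweepCondition({"axis": "fragment_count", "value": d, "tbm_mode": "stationary"}, stat))
            conds.append(SweepCondition({"axis": "fragment_count", "value": d, "tbm_mode": "migratory"}, mig))
        return SweepResult("fragment_count", conds, [])

    def test_recovers_constructed_crossover(self):
        res = crossover_density(self._synthetic_sweep(500.0), n_boot=100, seed=1)
        assert res.in_range
        assert res.density == pytest.approx(500.0, rel=0.1)
        assert res.ci_low < 500.0 < res.ci_high

    def test_parallel_curves_out_of_range(self):
        densities = [50, 150, 500, 1500]
        conds = []
        for d in densities:
            conds.append(SweepCondition({"axis": "fragment_count", "value": d, "tbm_mode": "stationary"}, np.full(4, 1.0)))
            conds.append(SweepCondition({"axis": "fragment_count", "value": d, "tbm_mode": "migratory"}, np.full(4, 0.5)))
        res = crossover_density(SweepResult("fragment_count", conds, []), n_boot=10)
        assert not res.in_range
        assert res.density is None

    def test_wrong_axis_rejected(self):
        with pytest.raises(ValidationError):
            crossover_density(SweepResult("tbm_volume", [], []))


class TestConfigValidation:
    def test_bad_mode_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(tbm_mode="teleporting")

    def test_tbm_larger_than_arena_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(gc_radius=10.0, tbm_diameter=27.0)

    def test_radius_from_volume_default(self):
        assert SimConfig().radius == pytest.approx(81.05, abs=0.05)
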