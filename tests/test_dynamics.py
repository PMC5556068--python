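"""Markov-chain transition law, kernel/oracle agreement and run drivers."""

from __future__ import annotations

import numpy as np
import pytest

from exclusim.dynamics import (
    ModelParams,
    RateSet,
    Trajectory,
    derive_seeds,
    empty_update_distribution,
    occupied_update_distribution,
    run,
    step,
)
from exclusim.lattice import LatticeConfig
from exclusim import kernels

from .conftest import brute_force_admissible, random_admissible_small


def make_params(L=9, **kw) -> ModelParams:
    defaults = dict(L=L, n_steps=10, record_every=1, seed=0)
    defaults.update(kw)
    return ModelParams(**defaults)


# A fixed 9x9 configuration with both types used by several tests:
#   tumor pair at (2,2)-(2,3); normal cells at (6,6) and (6,2).
def fixed_config() -> LatticeConfig:
    config = LatticeConfig.empty(9)
    config.state[2, 2] = config.state[2, 3] = 1
    config.state[6, 6] = 2
    config.state[6, 2] = 2
    return config


class TestOccupiedDistribution:
    def test_lone_cell_with_four_receivers(self):
        """alpha=0.1, rho=0.01, delta=0.001, n_e=4 -> Q=0.114."""
        config = LatticeConfig.empty(11)
        config.state[5, 5] = 1
        dist = occupied_update_distribution(config, (5, 5), make_params(L=11))
        assert dist.normalizer == pytest.approx(0.114)
        assert dist.outcomes[("quiescence",)] == pytest.approx(0.1 / 0.114)
        assert dist.outcomes[("death",)] == pytest.approx(0.01 / 0.114)
        migr = [p for ev, p in dist.outcomes.items() if ev[0] == "migrate_out"]
        assert len(migr) == 4
        assert all(p == pytest.approx(0.001 / 0.114) for p in migr)

    def test_enclosed_cell_cannot_migrate(self, rule):
        from exclusim.initial import dense_packing

        config = dense_packing(1, 9, rule)
        dist = occupied_update_distribution(config, (4, 4), make_params())
        assert dist.normalizer == pytest.approx(0.11)
        assert dist.outcomes[("quiescence",)] == pytest.approx(0.1 / 0.11)
        assert dist.outcomes[("death",)] == pytest.approx(0.01 / 0.11)
        assert dist.probability("migrate_out") == 0

    def test_empty_vertex_rejected(self):
        with pytest.raises(ValueError):
            occupied_update_distribution(LatticeConfig.empty(9), (4, 4), make_params())


class TestEmptyDistribution:
    def test_isolated_vertex_stays_empty(self):
        config = LatticeConfig.empty(9)
        dist = empty_update_distribution(config, (4, 4), make_params())
        assert dist.outcomes == {("stay_empty",): 1.0}

    def test_three_tumor_donors(self):
        """n1=3, I(1)=1, n2=0 -> R = 0.02 + 3*0.101 = 0.323."""
        config = LatticeConfig.empty(9)
        for y in [(3, 4), (4, 3), (5, 4)]:
            config.state[y] = 1
        dist = empty_update_distribution(config, (4, 4), make_params())
        assert dist.normalizer == pytest.approx(0.323)
        assert dist.outcomes[("stay_empty",)] == pytest.approx(0.02 / 0.323)
        assert dist.outcomes[("birth", 1)] == pytest.approx(0.3 / 0.323)
        sources = [ev for ev in dist.outcomes if ev[0] == "migrate_in"]
        assert len(sources) == 3
        for ev in sources:
            assert dist.outcomes[ev] == pytest.approx(0.001 / 0.323)

    def test_shadowed_vertex_blocks_tumor(self, rule):
        """Donors present but I(1)=0: a normal cell within the cross-exclusion
        shadow forbids tumor events at the vertex."""
        config = LatticeConfig.empty(13)
        config.state[6, 5] = 1  # adjacent tumor donor
        config.state[6, 8] = 2  # distance 2 from (6, 6) -> shadows type 1
        dist = empty_update_distribution(config, (6, 6), make_params(L=13))
        assert dist.probability("birth") == 0
        assert dist.probability("migrate_in") == 0
        assert dist.outcomes[("stay_empty",)] == pytest.approx(1.0)

    def test_border_vertex_stays_empty(self):
        config = fixed_config()
        dist = empty_update_distribution(config, (0, 4), make_params())
        assert dist.outcomes == {("stay_empty",): 1.0}

    @pytest.mark.parametrize("seed", range(8))
    def test_normalization(self, seed, rule):
        rng = np.random.default_rng(seed)
        config = random_admissible_small(rng, 9, rule)
        params = make_params()
        for x in [(r, c) for r in range(9) for c in range(9)]:
            if config.state[x] == 0:
                dist = empty_update_distribution(config, x, params)
            else:
                dist = occupied_update_distribution(config, x, params)
            assert abs(dist.total() - 1.0) < 1e-12


class TestKernelMatchesAnalyticDistribution:
    """Empirical outcome frequencies of the compiled resolver vs the exact law."""

    N = 20_000

    def _frequencies(self, config, x, params, seed):
        a, d, ro = params.rates.arrays()
        dmat = params.rule.as_matrix()
        kernels.seed_kernel_rng(seed)
        base = config.state.copy()
        counts = {}
        grid = base.copy()
        for _ in range(self.N):
            np.copyto(grid, base)
            code, t = kernels.resolve_vertex(grid, x[0], x[1], dmat, a, d, ro)
            if code in (kernels.EV_MIGRATE_OUT, kernels.EV_MIGRATE_IN):
                changed = np.argwhere(grid != base)
                key = (code, t, tuple(map(tuple, changed)))
            else:
                key = (code, t)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def _analytic(self, config, x, params):
        if config.state[x] != 0:
            return occupied_update_distribution(config, x, params)
        return empty_update_distribution(config, x, params)

    @pytest.mark.parametrize("x", [(2, 2), (6, 6), (4, 4)])
    def test_outcome_kind_frequencies(self, x):
        config = fixed_config()
        params = make_params()
        dist = self._analytic(config, x, params)
        counts = self._frequencies(config, x, params, seed=1234)
        kind_of = {0: ("quiescence", "stay_empty"), 1: ("death",), 2: ("migrate_out",),
                   3: ("birth",), 4: ("migrate_in",)}
        for code, kinds in kind_of.items():
            p = sum(dist.probability(k) for k in kinds)
            emp = sum(n for (c, *_), n in counts.items() if c == code) / self.N
            se = np.sqrt(max(p * (1 - p), 1e-12) / self.N)
            assert abs(emp - p) <= 4 * se + 1e-9, (x, code, emp, p)


class TestStep:
    def test_empty_grid_unchanged(self):
        params = make_params(rates=RateSet())
        config = LatticeConfig.empty(9)
        rng = np.random.default_rng(0)
        for _ in range(50):
            config, (x, event) = step(config, params, rng)
            assert event == ("stay_empty",)
        assert config.counts() == (0, 0)

    def test_count_change_bounded_and_admissible(self, rule):
        params = make_params(L=12)
        rng = np.random.default_rng(3)
        config = random_admissible_small(rng, 12, rule)
        for i in range(400):
            before = config.counts()
            config, _ = step(config, params, rng)
            after = config.counts()
            assert abs(after[0] - before[0]) <= 1
            assert abs(after[1] - before[1]) <= 1
            if i % 50 == 0:
                assert brute_force_admissible(config, rule)

    def test_death_free_chain_never_shrinks(self):
        params = make_params(
            L=11, rates=RateSet(rho1=0.0, rho2=0.0, delta1=0.0, delta2=0.0)
        )
        config = LatticeConfig.empty(11)
        config.state[5, 5] = 1
        config.state[2, 7] = 2
        rng = np.random.default_rng(7)
        prev = sum(config.counts())
        for _ in range(2000):
            config, _ = step(config, params, rng)
            total = sum(config.counts())
            assert total >= prev
            prev = total

    def test_death_only_chain_empties(self):
        params = make_params(
            L=20,
            rates=RateSet(alpha1=0.0, alpha2=0.0, delta1=0.0, delta2=0.0, rho1=0.05, rho2=0.05),
            n_steps=200_000,
            record_every=200_000,
        )
        traj, _ = run(params, initial=_half_full(20), engine="fast")
        assert traj.density1[-1] == 0
        assert traj.density2[-1] == 0


def _half_full(L):
    config = LatticeConfig.empty(L)
    config.state[1 : L - 1 : 2, 1 : L - 1 : 2] = 1
    return config


class TestRun:
    def test_zero_steps_records_initial_densities(self):
        params = make_params(L=30, n_steps=0, record_every=5, init_density=(0.01, 0.05))
        traj, _ = run(params)
        assert len(traj.steps) == 1
        assert traj.density1[0] == pytest.approx(round(0.01 * 900) / 900)
        assert traj.density2[0] == pytest.approx(round(0.05 * 900) / 900)

    def test_same_seed_identical_trajectories(self):
        params = make_params(L=25, n_steps=30_000, record_every=3_000, seed=11)
        t1, _ = run(params)
        t2, _ = run(params)
        assert np.array_equal(t1.density1, t2.density1)
        assert np.array_equal(t1.density2, t2.density2)

    def test_snapshots_are_admissible_and_at_right_steps(self, rule):
        params = make_params(
            L=25, n_steps=20_000, record_every=2_000, snapshot_steps=(0, 10_000, 20_000)
        )
        traj, snaps = run(params)
        assert sorted(snaps) == [0, 10_000, 20_000]
        for snap in snaps.values():
            assert brute_force_admissible(snap, rule)
        # final snapshot counts agree with the final recorded densities
        n1, n2 = snaps[20_000].counts()
        assert traj.density1[-1] == pytest.approx(n1 / 25**2)
        assert traj.density2[-1] == pytest.approx(n2 / 25**2)

    def test_reference_engine_matches_kernel_statistically(self):
        """Both engines implement the same law: compare mean final counts
        of a short chain over repeated seeded runs."""
        finals = {"fast": [], "reference": []}
        for engine in finals:
            for seed in range(12):
                params = make_params(
                    L=15, n_steps=2_000, record_every=2_000, seed=seed, init_density=(0.02, 0.05)
                )
                traj, _ = run(params, engine=engine)
                finals[engine].append(traj.density1[-1] + traj.density2[-1])
        mf, mr = np.mean(finals["fast"]), np.mean(finals["reference"])
        sd = np.std(finals["fast"] + finals["reference"], ddof=1)
        assert abs(mf - mr) <= 4 * sd / np.sqrt(6)

    def test_co_culture_setup_ratio_decreases(self):
        """Scaled co-culture setup: the normal:tumor density ratio falls from 9."""
        params = make_params(
            L=60, n_steps=3_000_000, record_every=300_000, seed=5, init_density=(0.01, 0.09)
        )
        traj, _ = run(params)
        ratio = traj.ratio
        assert ratio[0] == pytest.approx(9.0)
        assert ratio[-1] < ratio[0]


class TestSweep:
    def test_output_shape_and_single_rep_sd(self):
        from exclusim.dynamics import sweep_alpha_ratio

        base = make_params(L=20, n_steps=2_000, seed=3)
        df = sweep_alpha_ratio(base, ratios=[1, 2], n_reps=1)
        assert list(df["ratio"]) == [1, 2]
        assert df["sd_density1"].isna().all()
        df2 = sweep_alpha_ratio(base, ratios=[1], n_reps=3)
        assert df2.loc[0, "n_reps"] == 3
        assert np.isfinite(df2.loc[0, "sd_density1"])

    def test_relabeling_symmetry(self):
        """Swapping the type labels together with their rates, exclusion
        distances and initial densities swaps the mean final densities
        within Monte-Carlo error (reduced scale)."""
        from exclusim.lattice import ExclusionRule

        n, L, steps = 12, 24, 500_000

        def finals(params_list):
            out = []
            for p in params_list:
                traj, _ = run(p)
                out.append((traj.density1[-1], traj.density2[-1]))
            return np.array(out)

        orig = [
            make_params(L=L, rule=ExclusionRule(1, 3, 2), rates=RateSet(alpha2=0.2),
                        seed=s, n_steps=steps, record_every=steps, init_density=(0.01, 0.09))
            for s in derive_seeds(55, n)
        ]
        swap = [
            make_params(L=L, rule=ExclusionRule(d11=2, d12=3, d22=1), rates=RateSet(alpha1=0.2),
                        seed=s, n_steps=steps, record_every=steps, init_density=(0.09, 0.01))
            for s in derive_seeds(56, n)
        ]
        fo = finals(orig)
        fs = finals(swap)
        for a, b in [(fo[:, 0], fs[:, 1]), (fo[:, 1], fs[:, 0])]:
            se = np.sqrt(a.var(ddof=1) / n + b.var(ddof=1) / n)
            assert abs(a.mean() - b.mean()) <= 4 * se + 1e-3

    def test_derived_seeds_are_distinct(self):
        seeds = derive_seeds(42, 50)
        assert len(set(seeds)) == 50
        assert all(0 <= s < 2**31 for s in seeds)


def test_trajectory_ratio_sentinel():
    traj = Trajectory(
        steps=np.array([0, 1]), density1=np.array([0.0, 0.1]), density2=np.array([0.2, 0.2])
    )
    assert np.isnan(traj.ratio[0])
    assert traj.ratio[1] == pytest.approx(2.0)


def test_rateset_validation():
    with pytest.raises(ValueError):
        RateSet(alpha1=0.0, rho1=0.0)
    with pytest.raises(ValueError):
        RateSet(alpha1=-0.1)
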