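"""Simulator kernel: reaction statistics, toxin deposition, coarse-graining, runs."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import colicomp as cc
from colicomp import LatticeState, ModelParams, ScenarioSpec, Site
from colicomp.simulator import coarse_grain, deposit_toxin, run_competition, step
from conftest import random_mixed_lattice

ALLOWED_TRANSITIONS = {
    Site.AGAR: {Site.AGAR, Site.C, Site.X},
    Site.C: {Site.C, Site.C_ON},
    Site.C_ON: {Site.C_ON, Site.AGAR},
    Site.X: {Site.X, Site.X_STOP},
    Site.X_STOP: {Site.X_STOP},
}


class TestStep:
    def test_neutral_growth_uses_three_states(self, small_inoculum):
        """Without switching or toxin, only agar/C/X ever appear (two-strain Eden growth)."""
        p = ModelParams(s_C=0.0, sigma_x=0.0, seed=3)
        state = small_inoculum
        for _ in range(60):
            state = step(state, p)
        assert set(np.unique(state.grid)) <= {Site.AGAR.value, Site.C.value, Site.X.value}
        assert state.toxin.max() == 0.0

    def test_single_step_transitions_are_legal(self, rng):
        """Per-site transitions respect irreversibility: producers only decay,
        inhibited competitors never recover."""
        for trial in range(5):
            state = random_mixed_lattice(rng)
            p = ModelParams(s_C=0.3, d_Con=1.2, sigma_x=1500.0, seed=trial)
            new = step(state, p)
            for s_from, allowed in ALLOWED_TRANSITIONS.items():
                mask = state.grid == s_from
                observed = set(np.unique(new.grid[mask])) if mask.any() else set()
                assert observed <= {a.value for a in allowed}, s_from

    def test_time_advances_by_dt(self, mixed_lattice, small_params):
        new = step(mixed_lattice, small_params)
        assert new.time == pytest.approx(mixed_lattice.time + small_params.dt)

    def test_lysis_waiting_time_is_exponential(self):
        """Mean producer lifetime equals 1/d_Con (3 SE), from the per-step lysis rule."""
        d_con = 1.2
        size = 50
        grid = np.full((size, size), Site.C_ON.value, dtype=np.int8)
        state = LatticeState(grid=grid, toxin=np.zeros((size, size)),
                             rng=np.random.default_rng(42))
        p = ModelParams(r_C=1.0, r_X=1.0, d_Con=d_con, s_C=0.0, sigma_x=0.0, dt=0.01, seed=42)
        n0 = size * size
        counts = [n0]
        while counts[-1] > 0:
            state = step(state, p)
            counts.append(int((state.grid == Site.C_ON).sum()))
        counts = np.array(counts)
        deaths = counts[:-1] - counts[1:]
        lifetimes = np.repeat(np.arange(1, len(deaths) + 1) * p.dt, deaths)
        mean, se = lifetimes.mean(), lifetimes.std(ddof=1) / np.sqrt(n0)
        assert abs(mean - 1.0 / d_con) < 3 * se

    def test_probability_overflow_signals(self, mixed_lattice):
        p = ModelParams(r_C=5.4, r_X=5.4, dt=0.009, seed=0)
        from colicomp.simulator import _step_inplace, toxin_kernel_table

        kern = toxin_kernel_table(mixed_lattice.size, 1.0, 150.0, 2.0)
        born = np.zeros_like(mixed_lattice.grid, dtype=np.uint8)
        order = np.empty(mixed_lattice.grid.size, dtype=np.int64)
        with pytest.raises(ValueError, match="overflow"):
            _step_inplace(mixed_lattice.copy(), p, None, kern, born, order, dt=0.05)


class TestDepositToxin:
    def test_origin_receives_exactly_n_tox(self):
        field = np.zeros((21, 21))
        out = deposit_toxin(field, (10, 10), n_tox=2.5, lambda_tox=150.0, pixel_size_um=2.0)
        assert out[10, 10] == pytest.approx(2.5)

    def test_decay_length_gives_one_e_fold(self):
        field = np.zeros((160, 160))
        out = deposit_toxin(field, (0, 0), n_tox=1.0, lambda_tox=150.0, pixel_size_um=2.0)
        assert out[0, 75] == pytest.approx(np.exp(-1.0))

    def test_additivity_matches_double_loop_oracle(self, rng):
        """Repeated depositions add up exactly as the naive per-site oracle."""
        n = 30
        field = np.zeros((n, n))
        origins = [(5, 7), (5, 7), (20, 3)]
        for o in origins:
            field = deposit_toxin(field, o, 0.8, 100.0, 4.0)
        oracle = np.zeros((n, n))
        for oi, oj in origins:
            for i in range(n):
                for j in range(n):
                    d = np.hypot(i - oi, j - oj)
                    oracle[i, j] += 0.8 * np.exp(-d * 4.0 / 100.0)
        np.testing.assert_allclose(field, oracle, rtol=1e-12)
        assert field[5, 7] == pytest.approx(2 * 0.8 + 0.8 * np.exp(-np.hypot(15, 4) * 4 / 100))

    def test_kernel_table_path_matches_public_function(self, rng):
        """The fast lookup-table deposition used inside runs equals the direct formula."""
        from colicomp import _kernels
        from colicomp.simulator import toxin_kernel_table

        n = 25
        direct = deposit_toxin(np.zeros((n, n)), (11, 4), 1.3, 150.0, 10.0)
        table = np.zeros((n, n))
        kern = toxin_kernel_table(n, 1.3, 150.0, 10.0)
        _kernels.deposit_kernel(table, kern, 11, 4)
        np.testing.assert_allclose(table, direct, rtol=1e-12)

    def test_origin_outside_lattice_raises(self):
        with pytest.raises(ValueError):
            deposit_toxin(np.zeros((5, 5)), (9, 0), 1.0, 150.0, 2.0)


class TestCoarseGrain:
    def _touching_state(self, grid, **kw):
        return LatticeState(grid=grid, toxin=np.zeros_like(grid, dtype=float), **kw)

    def test_uniform_colony_maps_to_centered_block(self):
        grid = np.full((250, 250), Site.C.value, dtype=np.int8)
        state = self._touching_state(grid)
        new, newp = coarse_grain(state, ModelParams())
        inner = new.grid[100:150, 100:150]
        assert (inner == Site.C.value).all()
        outer = new.grid.copy()
        outer[100:150, 100:150] = Site.AGAR.value
        assert (outer == Site.AGAR.value).all()
        assert new.zoom_level == 1 and new.pixel_size_um == pytest.approx(10.0)

    def test_occupancy_threshold_at_13_of_25(self):
        """A block with 12 occupied sites becomes agar; 13 becomes a cell."""
        block_sites = [(i, j) for i in range(5) for j in range(5)]
        for n_occ, expected in [(12, Site.AGAR), (13, Site.C)]:
            grid = np.zeros((250, 250), dtype=np.int8)
            for i, j in block_sites[:n_occ]:  # all inside block (0,0); touches boundary
                grid[i, j] = Site.C.value
            state = self._touching_state(grid)
            new, _ = coarse_grain(state, ModelParams())
            assert new.grid[100, 100] == expected.value

    def test_tie_precedence_producer_over_reproducer_over_inhibited(self):
        block_sites = [(i, j) for i in range(5) for j in range(5)]
        for first, second, winner in [(Site.C, Site.X, Site.C),
                                      (Site.C_ON, Site.C, Site.C_ON),
                                      (Site.X_STOP, Site.X, Site.X_STOP)]:
            grid = np.zeros((250, 250), dtype=np.int8)
            for i, j in block_sites[:7]:  # 7 vs 7 tie inside block (0,0)
                grid[i, j] = first.value
            for i, j in block_sites[7:14]:
                grid[i, j] = second.value
            new, _ = coarse_grain(self._touching_state(grid), ModelParams())
            assert new.grid[100, 100] == winner.value

    def test_rates_and_dt_rescale(self):
        grid = np.full((250, 250), Site.X.value, dtype=np.int8)
        p = ModelParams()
        _, newp = coarse_grain(self._touching_state(grid), p)
        assert newp.r_C == pytest.approx(p.r_C / 5)
        assert newp.r_X == pytest.approx(p.r_X / 5)
        assert newp.s_C == p.s_C and newp.d_Con == p.d_Con and newp.sigma_x == p.sigma_x

    def test_disc_area_conserved_within_5pct(self, rng):
        """Physical occupied area of random discs survives block counting (+-5%),
        matching a direct block-counting oracle exactly."""
        for trial in range(5):
            grid = np.zeros((250, 250), dtype=np.int8)
            ii, jj = np.meshgrid(np.arange(250), np.arange(250), indexing="ij")
            r = rng.uniform(80, 124)
            disc = (ii - 124.5) ** 2 + (jj - 124.5) ** 2 <= r ** 2
            grid[disc] = Site.X.value
            grid[0, 0] = Site.X.value  # ensure boundary trigger
            state = self._touching_state(grid)
            new, _ = coarse_grain(state, ModelParams())
            area_before = disc.sum() * state.pixel_size_um ** 2
            area_after = (new.grid != 0).sum() * new.pixel_size_um ** 2
            assert abs(area_after - area_before) / area_before < 0.05
            # oracle: count occupied per 5x5 block by hand
            occ = 0
            for bi in range(50):
                for bj in range(50):
                    if (grid[5 * bi:5 * bi + 5, 5 * bj:5 * bj + 5] != 0).sum() >= 13:
                        occ += 1
            assert (new.grid != 0).sum() == occ

    def test_toxin_is_block_averaged(self, rng):
        grid = np.zeros((250, 250), dtype=np.int8)
        grid[0, 0] = Site.X.value
        toxin = rng.random((250, 250))
        state = LatticeState(grid=grid, toxin=toxin)
        new, _ = coarse_grain(state, ModelParams())
        expected = toxin.reshape(50, 5, 50, 5).mean(axis=(1, 3))
        np.testing.assert_allclose(new.toxin[100:150, 100:150], expected)

    def test_requires_boundary_contact(self):
        grid = np.zeros((250, 250), dtype=np.int8)
        grid[100:110, 100:110] = Site.C.value
        with pytest.raises(ValueError, match="boundary"):
            coarse_grain(LatticeState(grid=grid, toxin=np.zeros((250, 250))), ModelParams())


class TestRunCompetition:
    def test_fixed_seed_is_bitwise_reproducible(self, small_inoculum):
        p = ModelParams(t_end=3.0, seed=99)
        t1 = run_competition(small_inoculum, p, record_interval=0.5)
        t2 = run_competition(small_inoculum, p, record_interval=0.5)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        np.testing.assert_array_equal(t1.snapshots[-1][1], t2.snapshots[-1][1])
        np.testing.assert_array_equal(t1.final_toxin, t2.final_toxin)

    def test_site_count_is_conserved(self, small_inoculum):
        p = ModelParams(t_end=2.0, seed=5)
        traj = run_competition(small_inoculum, p)
        assert (traj.counts.sum(axis=1) == small_inoculum.size ** 2).all()

    def test_area_series_continuous_across_zoom(self):
        """Physical occupied area of a developed colony changes by < 5% across
        a coarse-graining event (the second zoom, where the disc is dense)."""
        init = cc.single_strain_inoculum(seed=4)
        p = ModelParams(s_C=0.0, sigma_x=0.0, t_end=23.0, seed=4)
        traj = run_competition(init, p, record_interval=0.1, store_snapshots=False)
        assert len(traj.zoom_events) >= 2, "expected two zooms within 23 h"
        t_zoom = traj.zoom_events[1][0]
        k = int(np.searchsorted(traj.times, t_zoom))
        total = traj.areas_um2[:, 1:].sum(axis=1)
        assert abs(total[k] - total[k - 1]) / total[k - 1] < 0.05

    def test_front_speed_preserved_across_zoom(self):
        """Radial expansion speed (um/h) of a single-strain colony changes by
        < 10% across the first coarse-graining (averaged over 3 seeds)."""
        pre, post = [], []
        for seed in range(3):
            init = cc.single_strain_inoculum(seed=seed)
            p = ModelParams(s_C=0.0, sigma_x=0.0, t_end=28.0, seed=seed)
            traj = run_competition(init, p, record_interval=0.5, store_snapshots=False)
            radius = np.sqrt(traj.areas_um2[:, 1:].sum(axis=1) / np.pi)
            t_zoom = traj.zoom_events[1][0]  # second zoom (~21 h) is the clean one
            for lo, hi, acc in [(t_zoom - 6, t_zoom - 1, pre), (t_zoom + 1, t_zoom + 6, post)]:
                m = (traj.times >= lo) & (traj.times <= hi)
                acc.append(np.polyfit(traj.times[m], radius[m], 1)[0])
        v_pre, v_post = np.mean(pre), np.mean(post)
        assert abs(v_post - v_pre) / v_pre < 0.10

    def test_sync_scenario_releases_all_producers(self, small_inoculum):
        """SYNC II: C grows 100 min, then every C lyses at once, leaving no C lineage."""
        p = ModelParams(t_end=3.0, seed=21)
        traj = run_competition(small_inoculum, p, scenario=ScenarioSpec.sync_ii(),
                               record_interval=0.25)
        k_before = int(np.searchsorted(traj.times, 100 / 60)) - 1
        assert traj.counts[k_before, Site.C] > 0
        assert traj.counts[-1, Site.C] == 0 and traj.counts[-1, Site.C_ON] == 0
        assert traj.final_toxin.max() > 0

    def test_all_off_scenario_never_switches(self, small_inoculum):
        p = ModelParams(s_C=0.5, t_end=2.0, seed=13)
        traj = run_competition(small_inoculum, p, scenario=ScenarioSpec.all_off())
        assert (traj.counts[:, Site.C_ON] == 0).all()
        assert (traj.counts[:, Site.X_STOP] == 0).all()

    def test_non_lysing_variant_deposits_on_replication(self, small_inoculum):
        p = ModelParams(t_end=1.0, seed=17)
        traj = run_competition(small_inoculum, p,
                               scenario=ScenarioSpec.non_lysing_all_on(),
                               record_interval=0.25)
        assert (traj.counts[:, Site.C_ON] == 0).all()
        assert traj.final_toxin.max() > 0  # toxin released while growing


class TestSteadyState:
    def test_analytic_ratio(self):
        assert cc.steady_state_producer_ratio(ModelParams(s_C=0.0)) == 0.0
        assert cc.steady_state_producer_ratio(ModelParams(s_C=1.2, d_Con=1.2)) == pytest.approx(1.0)
        assert cc.steady_state_producer_ratio(
            ModelParams(s_C=0.015, d_Con=1.2)) == pytest.approx(0.0125)
        assert cc.steady_state_producer_fraction(
            ModelParams(s_C=0.015, d_Con=1.2)) == pytest.approx(0.015 / 1.215)

    def test_zero_lysis_rate_signals(self):
        with pytest.raises(ValueError):
            ModelParams(d_Con=0.0)

    def test_ratio_matches_ode_integration(self):
        """Quasi-steady producer ratio agrees with integrating
        dCon/dt = s_C C - d_Con Con at constant C."""
        s_c, d_con, c0 = 0.015, 1.2, 1000.0
        sol = solve_ivp(lambda t, y: [s_c * c0 - d_con * y[0]], (0, 50), [0.0],
                        rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] / c0 == pytest.approx(s_c / d_con, rel=1e-6)

    def test_well_mixed_surrogate_equal_rates(self):
        """With s_C = d_Con the long-run producer ratio is 1 (3 SE)."""
        mean, se = cc.well_mixed_producer_ratio(0.02, 0.02, n_C=2000, seed=1)
        assert abs(mean - 1.0) < 3 * se


class TestParams:
    def test_dt_cap_enforced(self):
        with pytest.raises(ValueError, match="probability cap"):
            ModelParams(r_C=5.4, dt=0.02)

    def test_auto_dt_respects_fastest_rate(self):
        p = ModelParams(r_C=2.0, r_X=1.0, s_C=0.0, d_Con=1.2)
        assert p.dt == pytest.approx(0.05 / 2.0)

    def test_scenario_adjustments(self):
        base = ModelParams()
        off = cc.apply_scenario(base, ScenarioSpec.all_off())
        assert off.s_C == 0.0
        nl = cc.apply_scenario(base, ScenarioSpec.non_lysing_all_on())
        assert nl.r_C == pytest.approx(base.r_C / 2)
        assert nl.n_tox == pytest.approx(base.n_tox / 2)
        assert ScenarioSpec.sync_i().release_time_h == pytest.approx(100 / 60)
        assert ScenarioSpec.sync_ii().release_time_h == pytest.approx(100 / 60)
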