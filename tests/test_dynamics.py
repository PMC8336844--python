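"""Dynamics equations: schedules, boundaries, logistic limits, Allee, presets."""

import warnings

import numpy as np
import pytest

from ptfsim import colony, dynamics, fbm
from ptfsim.dynamics import Model, ModelSpec, make_schedule


def logistic_closed_form(t, o0, r, K):
    """O(t) = K O0 e^{rt} / (K + O0 (e^{rt} - 1)), t in frames."""
    e = np.exp(r * np.asarray(t, dtype=float))
    return K * o0 * e / (K + o0 * (e - 1.0))


class TestSchedule:
    def test_single_breakpoint_is_constant(self):
        s = make_schedule([(0.0, 3.5)])
        assert s(0.0) == s(10.0) == s(1e6) == 3.5

    def test_carrying_capacity_step_at_25_hours(self):
        s = make_schedule([(0.0, 1500.0), (25.0, 1000.0)])
        assert s(24.99) == 1500.0
        assert s(25.0) == 1000.0  # right-continuous
        assert s(40.0) == 1000.0

    def test_noise_switch_at_20_hours(self):
        sa = make_schedule([(0.0, 90.0), (20.0, 0.0)])
        sm = make_schedule([(0.0, 0.0), (20.0, 0.05)])
        assert (sa(19.9), sm(19.9)) == (90.0, 0.0)
        assert (sa(20.0), sm(20.0)) == (0.0, 0.05)

    def test_unsorted_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            make_schedule([(0.0, 1.0), (5.0, 2.0), (3.0, 3.0)])
        with pytest.raises(ValueError, match="t = 0"):
            make_schedule([(1.0, 1.0)])


class TestFbmWalk:
    def spec(self, sigma=90.0, boundary=None):
        return ModelSpec(
            model=Model.FBM_WALK,
            sigma_A=make_schedule(sigma),
            boundary=boundary,
        )

    def test_zero_noise_is_constant(self):
        pack = fbm.generate_fgn(100, 0.38, seed=0)
        series, status = dynamics.simulate_fbm_walk(1290.0, self.spec(0.0), 100, pack)
        assert status == "completed"
        assert np.all(series == 1290.0)

    def test_reflecting_boundary_confines_path(self):
        bnd = dynamics.BoundarySpec("reflecting", 0.0, 2500.0)
        pack = fbm.generate_fgn(10_000, 0.38, seed=1)
        series, status = dynamics.simulate_fbm_walk(
            1290.0, self.spec(90.0, bnd), 10_000, pack
        )
        assert status == "completed"
        assert series.min() >= 0.0 and series.max() <= 2500.0
        assert len(series) == 10_001

    def test_absorbing_boundary_truncates_at_first_exit(self):
        """The recorded absorption frame is the first exit frame of the
        unbounded walk (brute-force cross-check)."""
        bnd = dynamics.BoundarySpec("absorbing", 0.0, 2500.0)
        pack = fbm.generate_fgn(500, 0.38, seed=2)
        series, status = dynamics.simulate_fbm_walk(
            1.0, self.spec(500.0, bnd), 500, pack
        )
        free = 1.0 + 500.0 * np.cumsum(pack.increments)
        exits = np.nonzero((free <= 0.0) | (free >= 2500.0))[0]
        assert exits.size > 0
        first_exit = exits[0] + 1  # series index of the crossing frame
        assert status in ("absorbed_low", "absorbed_high")
        assert len(series) == first_exit + 1
        assert series[-1] in (0.0, 2500.0)

    def test_start_outside_bounds_rejected(self):
        bnd = dynamics.BoundarySpec("absorbing", 0.0, 2500.0)
        pack = fbm.generate_fgn(10, 0.38, seed=0)
        with pytest.raises(ValueError):
            dynamics.simulate_fbm_walk(3000.0, self.spec(90.0, bnd), 10, pack)


class TestSleDeterministicLimits:
    @pytest.mark.parametrize(
        "model", [Model.SLE_ADDITIVE, Model.SLE_COMBINED, Model.SLE_TIME_K]
    )
    @pytest.mark.parametrize("o0", [100.0, 300.0, 2500.0])
    def test_matches_logistic_closed_form(self, model, o0):
        """Zero noise: Euler at 5-min frames stays within 1% of the
        logistic closed form and converges to K."""
        spec = ModelSpec(model=model, r=make_schedule(0.02), K=make_schedule(1290.0))
        pack = fbm.generate_fgn(480, 0.38, seed=0)
        series, _ = dynamics.integrate_sle(o0, spec, 480, pack)
        expected = logistic_closed_form(np.arange(481), o0, 0.02, 1290.0)
        assert np.max(np.abs(series - expected) / expected) < 0.01
        assert series[-1] == pytest.approx(1290.0, rel=0.005)

    def test_multiplicative_zero_noise_converges(self):
        spec = ModelSpec(
            model=Model.SLE_MULTIPLICATIVE,
            r=make_schedule(0.005),
            K=make_schedule(1290.0),
        )
        pack = fbm.generate_fgn(4000, 0.38, seed=0)
        series, _ = dynamics.integrate_sle(300.0, spec, 4000, pack)
        assert series[-1] == pytest.approx(1290.0, rel=0.005)

    def test_time_dependent_K_tracks_each_level(self):
        spec = ModelSpec(
            model=Model.SLE_TIME_K,
            r=make_schedule(0.02),
            K=make_schedule([(0.0, 1500.0), (25.0, 1000.0)]),
        )
        pack = fbm.generate_fgn(480, 0.38, seed=0)
        series, _ = dynamics.integrate_sle(800.0, spec, 480, pack)
        assert series[25 * 12] == pytest.approx(1500.0, rel=0.01)
        assert series[-1] == pytest.approx(1000.0, rel=0.01)

    def test_non_positive_start_rejected(self):
        spec = ModelSpec(model=Model.SLE_COMBINED, r=make_schedule(0.02))
        pack = fbm.generate_fgn(10, 0.38, seed=0)
        with pytest.raises(ValueError):
            dynamics.integrate_sle(0.0, spec, 10, pack)


class TestSleNoise:
    def test_additive_noise_absorbs_at_zero(self):
        """Large additive kicks drive O below 0; the series must stop
        there (O < 0 would run away to -infinity)."""
        spec = ModelSpec(
            model=Model.SLE_ADDITIVE,
            r=make_schedule(0.02),
            K=make_schedule(1290.0),
            sigma_A=make_schedule(2000.0),
        )
        pack = fbm.generate_fgn(500, 0.38, seed=3)
        series, status = dynamics.integrate_sle(1290.0, spec, 500, pack)
        assert status == "absorbed_low"
        assert series[-1] == 0.0
        assert len(series) < 501

    def test_multiplicative_fluctuations_grow_with_state(self):
        """SD of one-frame jumps conditioned on high O exceeds that at
        low O: the noise amplitude in O scales with O."""
        spec = ModelSpec(
            model=Model.SLE_MULTIPLICATIVE,
            r=make_schedule(0.005),
            K=make_schedule(1290.0),
            sigma_M=make_schedule(0.05),
        )
        n = 50_000
        series, _ = dynamics.integrate_sle(
            1290.0,
            spec,
            n,
            fbm.generate_fgn(n, 0.38, seed=4),
            fbm.generate_fgn(n, 0.38, seed=5),
        )
        jumps, levels = np.diff(series), series[:-1]
        lo, hi = np.quantile(levels, [0.25, 0.75])
        sd_low = np.std(jumps[levels <= lo])
        sd_high = np.std(jumps[levels >= hi])
        assert sd_high > 1.2 * sd_low

    def test_missing_second_noise_pack_rejected(self):
        spec = ModelSpec(
            model=Model.SLE_COMBINED,
            r=make_schedule(0.01),
            sigma_M=make_schedule(0.05),
        )
        pack = fbm.generate_fgn(10, 0.38, seed=0)
        with pytest.raises(ValueError, match="second noise"):
            dynamics.integrate_sle(1290.0, spec, 10, pack, None)

    def test_overflow_cap_warns(self):
        spec = ModelSpec(
            model=Model.SLE_COMBINED,
            r=make_schedule(0.0),
            sigma_M=make_schedule(5.0),
        )
        n = 200
        with pytest.warns(RuntimeWarning, match="cap"):
            dynamics.integrate_sle(
                1290.0,
                spec,
                n,
                fbm.generate_fgn(n, 0.38, seed=6),
                fbm.generate_fgn(n, 0.38, seed=7),
            )


class TestAllee:
    def allee_spec(self, A=1000.0, on=0.0, r=0.025, K=1290.0):
        return ModelSpec(
            model=Model.SLE_ALLEE,
            r=make_schedule(r),
            K=make_schedule(K),
            allee_A=A,
            allee_on_time=on,
        )

    def test_collapse_below_threshold(self):
        """Strong Allee effect: O0 < A < K declines to (numerical) zero."""
        pack = fbm.generate_fgn(480, 0.38, seed=0)
        series, _ = dynamics.integrate_sle(500.0, self.allee_spec(), 480, pack)
        assert series[-1] < 1.0
        assert np.all(np.diff(series) <= 1e-9)  # monotone decline

    def test_growth_above_threshold(self):
        pack = fbm.generate_fgn(960, 0.38, seed=0)
        series, _ = dynamics.integrate_sle(1100.0, self.allee_spec(), 960, pack)
        assert series[-1] == pytest.approx(1290.0, rel=0.01)

    def test_fixed_points_zero_noise(self):
        """Equilibria at O in {0, A, K}: A repels, 0 and K attract."""
        spec = self.allee_spec()
        pack = fbm.generate_fgn(4000, 0.38, seed=0)
        at_A, _ = dynamics.integrate_sle(1000.0, spec, 10, pack)
        assert np.allclose(at_A, 1000.0)  # exactly at the unstable point
        # escape from the unstable point is exponentially slow: allow ~330 h
        just_above, _ = dynamics.integrate_sle(1001.0, spec, 4000, pack)
        just_below, _ = dynamics.integrate_sle(999.0, spec, 4000, pack)
        assert just_above[-1] == pytest.approx(1290.0, rel=0.01)
        assert just_below[-1] < 1.0

    def test_switch_on_time_gates_the_term(self):
        """Before the switch-on time the dynamics are plain logistic, so a
        start below A still grows towards K."""
        spec = self.allee_spec(on=43.0)
        pack = fbm.generate_fgn(720, 0.38, seed=0)
        series, _ = dynamics.integrate_sle(500.0, spec, 720, pack)
        pre_switch = series[: 43 * 12]
        assert np.all(np.diff(pre_switch) >= 0)  # growing, not collapsing
        assert pre_switch[-1] > pre_switch[0]
        assert series[43 * 12] == pytest.approx(1290.0, rel=0.02)

    def test_allee_requires_threshold_and_time(self):
        with pytest.raises(ValueError, match="allee"):
            ModelSpec(model=Model.SLE_ALLEE, r=make_schedule(0.02))


class TestPresets:
    def test_known_preset_values(self):
        add = dynamics.preset("fig3_additive")["pluripotent"]
        assert add.K(10.0) == 1290.0
        assert add.sigma_A(0.0) == 90.0
        assert add.r(0.0) == 0.02
        assert add.hurst == 0.38

        mult = dynamics.preset("fig3_multiplicative")["pluripotent"]
        assert (mult.r(0.0), mult.sigma_M(0.0)) == (0.005, 0.0045)

        ns = dynamics.preset("fig4_noise_switch")
        diff = ns["differentiated"]
        for t in (0.0, 19.0, 20.0, 39.0):
            assert diff.K(t) == 1000.0
            assert diff.sigma_A(t) == 90.0
            assert diff.sigma_M(t) == 0.0
        plur = ns["pluripotent"]
        assert (plur.sigma_A(19.9), plur.sigma_M(19.9)) == (90.0, 0.0)
        assert (plur.sigma_A(20.0), plur.sigma_M(20.0)) == (0.0, 0.05)

        tk = dynamics.preset("fig5_time_K")
        assert tk["pluripotent"].K(24.9) == 1500.0
        assert tk["pluripotent"].K(25.0) == 1000.0
        assert tk["differentiated"].K(0.0) == 1100.0
        assert tk["differentiated"].sigma_A(0.0) == 20.0

        d6 = dynamics.preset("fig6_time_K_differentiation")["differentiated"]
        assert d6.K(43.0) == 300.0
        assert d6.r(42.9) == 0.015
        assert d6.r(43.0) == 0.008

        al = dynamics.preset("fig6_allee")["pluripotent"]
        assert al.allee_A == 1000.0
        assert al.allee_on_time == 43.0
        assert (al.r(0.0), al.K(0.0)) == (0.025, 1290.0)
        assert (al.sigma_A(0.0), al.sigma_M(0.0)) == (35.0, 0.035)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            dynamics.preset("fig9_nonexistent")

    @pytest.mark.parametrize("name", dynamics.PRESET_NAMES)
    def test_config_round_trip_is_verbatim(self, name):
        for fate, spec in dynamics.preset(name).items():
            back = ModelSpec.from_dict(spec.to_dict())
            assert back == spec

    def test_multiplicative_model_refuses_additive_noise(self):
        with pytest.raises(ValueError, match="sigma_M only"):
            ModelSpec(
                model=Model.SLE_MULTIPLICATIVE,
                r=make_schedule(0.005),
                sigma_A=make_schedule(90.0),
            )


class TestClassifyFatesAllee:
    def run_allee_colony(self, A, seed, events=120):
        base = dynamics.preset("fig6_allee")["pluripotent"]
        spec = ModelSpec(
            model=Model.SLE_ALLEE,
            r=base.r,
            K=base.K,
            sigma_A=base.sigma_A,
            sigma_M=base.sigma_M,
            hurst=base.hurst,
            allee_A=A,
            allee_on_time=10.0,  # early switch: decisions resolve quickly
        )
        models = {f: spec for f in ("pluripotent", "differentiated", "unknown")}
        from ptfsim import fixtures

        cfg = fixtures.FixtureConfig()
        init = colony.init_colony(
            16,
            0,
            fixtures.make_initial_oct4_sampler(cfg),
            fixtures.make_cycle_sampler(cfg),
            seed=seed,
        )
        traj = colony.run_colony(
            init, models, events, seed, fixtures.make_cycle_sampler(cfg)
        )
        return colony.truncate_to_window(traj, 40.0)

    def test_refuses_non_allee_trajectory(self, oct4_sampler, cycle_sampler):
        init = colony.init_colony(2, 0, oct4_sampler, cycle_sampler, seed=1)
        traj = colony.run_colony(
            init, dynamics.preset("fig3_additive"), 2, 1, cycle_sampler
        )
        with pytest.raises(ValueError, match="Allee"):
            dynamics.classify_fates_allee(traj)

    def test_threshold_splits_leaves(self):
        traj = self.run_allee_colony(A=1000.0, seed=21)
        fates = dynamics.classify_fates_allee(traj)
        for leaf in traj.leaves():
            expected = (
                "differentiated" if leaf.series[-1] < 1000.0 else "pluripotent"
            )
            assert fates[leaf.cell_id] == expected

    def test_fraction_differentiated_monotone_in_threshold(self):
        """Raising the Allee threshold A can only differentiate more cells."""
        fractions = []
        for A in (600.0, 1000.0, 1200.0):
            traj = self.run_allee_colony(A=A, seed=22)
            dynamics.classify_fates_allee(traj)
            leaves = traj.leaves()
            fractions.append(
                np.mean([c.fate == "differentiated" for c in leaves])
            )
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[2] > fractions[0]  # the effect is actually active
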