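"""Cell-activity law, modulation, delay and time-integration tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoremod import (
    ActivityParams,
    DelayParams,
    EnergyField,
    MaterialParams,
    ModulationParams,
    ScenarioConfig,
    combined_activity,
    delayed_activity,
    interpolate_alpha,
    interpolate_n,
    modulation,
    osteoblast_activity,
    osteoclast_activity,
    run_scenario,
    scenario_preset,
)
from osteoremod.remodeling import (
    RATE_PERIOD_DAYS,
    RemodelingState,
    density_rate,
    step_density,
)
from osteoremod.geometry import build_mesh, BoneGeometry

from conftest import snapshot_at

P = ActivityParams()


class TestActivityLaw:
    def test_zero_at_and_below_homeostasis(self):
        for W in (0.0, P.W0 / 2, P.W0):
            assert osteoblast_activity(W) == 0.0
            assert osteoclast_activity(W) == 0.0
            assert combined_activity(W) == 0.0

    def test_osteoblast_linear_then_capped(self):
        mid = (P.W0 + P.W1) / 2
        assert osteoblast_activity(mid) == pytest.approx(P.A1 / 2, rel=2e-4)
        assert osteoblast_activity(P.W1) == P.A1
        assert osteoblast_activity(2 * P.W3) == P.A1

    def test_osteoclast_linear_then_capped(self):
        assert osteoclast_activity(P.W3) == P.A2
        assert osteoclast_activity(2 * P.W3) == P.A2
        mid = (P.W0 + P.W3) / 2
        assert osteoclast_activity(mid) == pytest.approx(
            P.k2 * (mid - P.W0), rel=1e-12
        )

    def test_combined_at_w2_balances_capped_formation(self):
        # at W2 the osteoclast branch offsets the A1 cap (W2 printed at
        # table precision, hence the percent-level agreement)
        assert osteoclast_activity(P.W2) == pytest.approx(-P.A1, rel=1e-2)
        assert combined_activity(P.W1) == pytest.approx(
            P.A1 + P.k2 * (P.W1 - P.W0), rel=1e-9
        )
        assert combined_activity(2 * P.W3) == pytest.approx(P.A1 + P.A2, rel=1e-12)

    def test_combined_zero_crossings_at_w0_and_w2(self):
        from scipy.optimize import brentq

        # the only sign change on (W0, W3] brackets the printed W2
        w_lo = P.W0 + 1e-9
        assert combined_activity(w_lo) > 0
        root = brentq(lambda W: combined_activity(W), P.W1, P.W3)
        assert round(root * 1e4, 2) == 3.72
        grid = np.linspace(P.W0, P.W3, 20001)
        signs = np.sign(combined_activity(grid))
        assert np.count_nonzero(np.diff(signs[signs != 0])) == 1

    def test_monotone_on_branches(self):
        rising = np.linspace(P.W0, P.W1, 200)
        falling = np.linspace(P.W1, P.W3, 200)
        assert np.all(np.diff(combined_activity(rising)) >= 0)
        assert np.all(np.diff(combined_activity(falling)) <= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ActivityParams(W0=4e-4)  # breaks ordering
        with pytest.raises(ValueError):
            ActivityParams(A1=1800.0)  # inconsistent with k1*(W1-W0)
        with pytest.raises(ValueError):
            ActivityParams(k2=375e5, A2=2232.38)  # wrong signs


class TestModulation:
    def test_reference_value_at_interface_density(self):
        expected = (1.0009 - 0.56) ** 13.6
        assert modulation(0.56, 1.0009, 13.6) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.46e-5, rel=5e-3)

    def test_vanishes_at_alpha_and_is_one_at_zero_density(self):
        assert modulation(1.0009, 1.0009, 13.6) == 0.0
        assert modulation(0.0, 1.0, 7.0) == 1.0

    def test_clamped_above_alpha(self):
        assert modulation(1.2, 1.0, 5.0) == 0.0

    @given(st.floats(0.0, 0.99), st.floats(0.001, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_density(self, rho, d):
        assert modulation(rho + d, 1.0009, 13.6) < modulation(rho, 1.0009, 13.6)


class TestInterpolation:
    def test_anchor_and_midpoint_values(self):
        assert interpolate_n(P.W1) == 13.6
        assert interpolate_n(P.W3) == 5.0
        assert interpolate_n(P.W0) == 13.6
        assert interpolate_n(2 * P.W3) == 5.0
        assert interpolate_n((P.W1 + P.W3) / 2) == pytest.approx(9.3, rel=1e-12)

    def test_quadratic_mode_differs_between_anchors(self):
        mod = ModulationParams(n_interpolation="quadratic")
        mid = (P.W1 + P.W3) / 2
        assert interpolate_n(mid, mod) == pytest.approx(13.6 + (5 - 13.6) * 0.25)
        assert interpolate_n(P.W1, mod) == 13.6
        assert interpolate_n(P.W3, mod) == 5.0

    def test_alpha_blend_per_cell_type(self):
        assert interpolate_alpha(P.W1, "ob") == 1.0009
        assert interpolate_alpha(P.W3, "ob") == 1.0007
        assert interpolate_alpha(P.W1, "oc") == 1.0
        assert interpolate_alpha(P.W3, "oc") == 1.0


class TestDelay:
    def test_none_mode_is_identity(self):
        assert delayed_activity(5.0, 0.0, DelayParams(mode="none"), 0.1) == 5.0

    def test_filtered_activity_converges_monotonically(self):
        delay = DelayParams(mode="slow")
        a = 0.0
        values = []
        for _ in range(5000):
            a = delayed_activity(10.0, a, delay, 0.5)
            values.append(a)
        values = np.array(values)
        assert np.all(np.diff(values) >= 0)
        assert values[-1] < 10.0
        assert values[-1] > values[0]

    def test_slow_rate_larger_than_low_rate(self):
        # a smaller coefficient means a longer intensity/time delay
        assert DelayParams(mode="slow").rate_per_day > DelayParams(mode="low").rate_per_day

    def test_slow_mode_delays_peak_global_activity(
        self, run_continuous, run_continuous_slow
    ):
        t_peak_none = run_continuous.times[
            np.argmax(np.abs(run_continuous.global_activity_oc))
        ]
        t_peak_slow = run_continuous_slow.times[
            np.argmax(np.abs(run_continuous_slow.global_activity_oc))
        ]
        assert t_peak_slow > t_peak_none

    def test_invalid_delay_rejected(self):
        with pytest.raises(ValueError):
            DelayParams(mode="fast")
        with pytest.raises(ValueError):
            DelayParams(mode="slow", coefficient=2.0)


class TestStepDensity:
    def _uniform_state(self, mesh, rho0, W):
        n = mesh.n_elements
        sed = np.full(n, 1.0)
        energy = EnergyField(sed=sed, total_energy=W, reference_sed=1.0)
        return RemodelingState(
            time=0.0,
            density=np.full(n, rho0),
            activity_ob=np.zeros(n),
            activity_oc=np.zeros(n),
            energy=energy,
            element_energy=np.full(n, W),
        )

    def test_homeostatic_energy_leaves_density_unchanged(self):
        mesh = build_mesh(BoneGeometry(), 0.3)
        state = self._uniform_state(mesh, 0.5, P.W0)
        new = step_density(
            state, 0.1, P, ModulationParams(), MaterialParams(), DelayParams(), mesh
        )
        assert np.array_equal(new.density, state.density)

    def test_spatial_homogeneity_preserved_without_modulation(self):
        # with modulation off and uniform energy, all elements evolve alike
        mesh = build_mesh(BoneGeometry(), 0.3)
        state = self._uniform_state(mesh, 0.5, P.W1)
        mod = ModulationParams(enabled=False)
        for _ in range(10):
            state = step_density(
                state, 0.1, P, mod, MaterialParams(), DelayParams(), mesh
            )
        assert np.ptp(state.density) == 0.0
        assert state.density[0] > 0.5

    def test_euler_rate_matches_activity_law(self):
        mesh = build_mesh(BoneGeometry(), 0.3)
        state = self._uniform_state(mesh, 0.5, P.W1)
        mod = ModulationParams(enabled=False)
        mat = MaterialParams()
        new = step_density(state, 0.1, P, mod, mat, DelayParams(), mesh)
        expected = 0.5 + combined_activity(P.W1) / (mat.rho_ref * RATE_PERIOD_DAYS) * 0.1
        assert new.density[0] == pytest.approx(expected, rel=1e-12)

    def test_formation_at_low_density_under_intermittent_energy(self):
        a_ob, a_oc, _ = density_rate(
            np.array([0.3]), np.array([P.W1]), P, ModulationParams(), MaterialParams()
        )
        assert a_ob[0] + a_oc[0] > 0

    def test_oversized_step_rejected(self):
        mesh = build_mesh(BoneGeometry(), 0.3)
        state = self._uniform_state(mesh, 0.5, P.W1)
        with pytest.raises(ValueError):
            step_density(
                state, 0.6, P, ModulationParams(), MaterialParams(), DelayParams(), mesh
            )


class TestScenarioRuns:
    def test_sedentary_run_is_homeostatic(self, run_sedentary):
        assert run_sedentary.mean_density_change_pct == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(
            run_sedentary.final_state.density, run_sedentary.initial_density,
            atol=1e-12,
        )

    def test_intermittent_forms_bone_near_interface(self, run_intermittent):
        res = run_intermittent
        assert res.mean_density_change_pct > 0
        delta = res.final_state.density - res.initial_density
        grid = res.mesh.element_grid(delta)
        radial = grid.mean(axis=0)
        r = res.mesh.element_r[: res.mesh.n_r]
        # formation on the trabecular/interface side, none in the cortex
        assert radial[r < 0.6].max() > 0.1
        assert np.all(np.abs(radial[r > 0.8]) < 1e-3)
        # the interface front moves inward (thicker cortex)
        assert res.front_radius[-1] < res.front_radius[0]

    def test_continuous_resorbs_bone_and_moves_front_outward(self, run_continuous):
        res = run_continuous
        assert res.mean_density_change_pct < 0
        assert res.front_radius[-1] > res.front_radius[0]

    def test_density_bounds_respected_throughout(self, run_continuous, run_intermittent):
        for res in (run_continuous, run_intermittent):
            cap = 1.0009 + 1e-12
            for snap in res.density_snapshots:
                assert np.all(snap >= res.config.density_floor - 1e-15)
                assert np.all(snap <= cap)

    def test_mass_ledger_consistent_with_density_change(
        self, run_continuous, run_intermittent
    ):
        for res in (run_continuous, run_intermittent):
            delta = res.final_state.density - res.initial_density
            net = 2.0 * float(delta @ res.mesh.element_volume)  # rho_ref = 1, half model
            assert res.mass_ledger.net == pytest.approx(net, rel=1e-9)
            assert res.mass_ledger.formed >= 0
            assert res.mass_ledger.resorbed <= 0

    def test_delay_slows_density_kinetics(self, run_continuous, run_continuous_slow):
        i7 = snapshot_at(run_continuous, 7.0)
        j7 = snapshot_at(run_continuous_slow, 7.0)
        drop_none = 1.0 - run_continuous.mean_density[i7] / run_continuous.mean_density[0]
        drop_slow = 1.0 - run_continuous_slow.mean_density[j7] / run_continuous_slow.mean_density[0]
        assert drop_slow < drop_none / 2

    def test_runs_are_deterministic(self):
        a = run_scenario(scenario_preset("intermittent", duration=2.0))
        b = run_scenario(scenario_preset("intermittent", duration=2.0))
        assert np.array_equal(a.final_state.density, b.final_state.density)
        assert np.array_equal(a.mean_density, b.mean_density)
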