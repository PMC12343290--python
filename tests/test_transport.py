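"""Finite-volume transport operator: conservation, limits, convergence, flow BC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermotrap as tt
from thermotrap.build import build
from thermotrap.transport import FlowBC, assemble_operator


def _operator(geometry, species, T=(27.0, 40.0), f_visc=1.3, bc=None, scheme="sg"):
    th = tt.thermal_field(geometry, *T)
    fl = tt.FluidProps.from_water(th.T_mean_C, f_visc)
    ff = tt.convection_field(geometry, th, fl)
    return assemble_operator(geometry, ff, tt.drift_field(species, th), species, bc=bc, scheme=scheme)


class TestOperator:
    def test_pure_diffusion_conserves_row_structure(self):
        g = tt.make_geometry(n_x=10, n_z=12)
        sp = tt.Species("x", 100.0, 0.0, 1.0)
        op = _operator(g, sp, T=(33.0, 33.0))
        # conservative operator: volume-weighted column sums vanish
        col = np.asarray(op.M.sum(axis=0)).ravel()
        assert np.max(np.abs(col)) < 1e-12

    def test_uniform_field_is_stationary_without_drift(self):
        g = tt.make_geometry(n_x=10, n_z=12)
        sp = tt.Species("x", 100.0, 0.0, 1.0)
        op = _operator(g, sp, T=(33.0, 33.0))
        ddt = op.ddt(np.ones(op.n))
        assert np.max(np.abs(ddt)) < 1e-14

    def test_grid_mismatch_rejected(self):
        g = tt.make_geometry(n_x=10, n_z=12)
        g2 = tt.make_geometry(n_x=12, n_z=12)
        th = tt.thermal_field(g, 27, 40)
        fl = tt.FluidProps.from_water(th.T_mean_C, 1.3)
        ff = tt.convection_field(g, th, fl)
        sp = tt.Species("x", 100.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            assemble_operator(g2, ff, 0.0, sp)

    def test_high_peclet_is_reported(self):
        g = tt.make_geometry(n_x=10, n_z=12)
        slow = tt.Species("slow", 2.0, 0.0, 1.0)  # tiny D -> huge cell Peclet
        with pytest.warns(UserWarning, match="Peclet"):
            _operator(g, slow)

    @pytest.mark.parametrize("scheme", ["sg", "upwind"])
    def test_soret_equilibrium_across_gap(self, scheme):
        """No-convection steady state equals the closed-form Soret profile.

        On a 64-cell cross-gap slice (horizontal orientation kills
        convection) the stationary profile is c(x) ~ exp(-S_T (T(x)-T_cold)).
        """
        g = tt.make_geometry(n_x=64, n_z=1, orientation="horizontal")
        sp = tt.Species("x", 100.0, 0.05, 1.0)
        op = _operator(g, sp)
        th = tt.thermal_field(g, 27, 40)
        init = tt.initial_state(g, [sp])
        steady = tt.steady_state(op, init=init)
        c = steady.c["x"][0]
        expected = np.exp(-sp.S_T_per_K * (th.T_x - 27.0))
        expected *= c.mean() / expected.mean()
        tol = 0.005 if scheme == "sg" else 0.02
        assert np.max(np.abs(c / expected - 1.0)) < tol


class TestStepping:
    def test_zero_dt_is_identity(self, small_components):
        op = small_components.operators["sfGFP"]
        c = np.linspace(0.5, 1.5, op.n)
        assert np.array_equal(op.step_vector(c, 0.0), c)

    def test_closed_trap_mass_conserved_over_1000_steps(self, small_components):
        comps = small_components
        sys = comps.system()
        state = tt.initial_state(comps.geometry, comps.species_list)
        m0 = tt.total_mass(state, "sfGFP", "all")
        for _ in range(1000):
            state = sys.step(state, 10.0)
        assert tt.total_mass(state, "sfGFP", "all") == pytest.approx(m0, rel=1e-9)

    def test_halving_dt_changes_day_old_bottom_signal_below_1pc(self, small_cfg):
        import copy

        results = []
        for dt_max in (1800.0, 900.0):
            cfg = copy.deepcopy(small_cfg)
            cfg["solver"]["dt_max_s"] = dt_max
            comps = build(cfg)
            series, _ = comps.system().run(
                tt.initial_state(comps.geometry, comps.species_list), 24 * 3600.0, comps.settings
            )
            results.append(series.sample_series("sfGFP", 500.0)[-1])
        assert abs(results[0] / results[1] - 1.0) < 0.01

    def test_linearity_in_initial_concentration(self, small_components):
        comps = small_components
        sys = comps.system()
        s1 = tt.initial_state(comps.geometry, comps.species_list)
        s2 = s1.copy()
        s2.c["sfGFP"] *= 2.0
        for _ in range(20):
            s1 = sys.step(s1, 300.0)
            s2 = sys.step(s2, 300.0)
        assert np.allclose(2.0 * s1.c["sfGFP"], s2.c["sfGFP"], rtol=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        D=st.floats(20.0, 800.0),
        S_T=st.floats(-0.05, 0.05),
        seed=st.integers(0, 2**16),
        scheme=st.sampled_from(["sg", "upwind"]),
    )
    def test_positivity_preserved(self, D, S_T, seed, scheme):
        """Exponential-fitting/upwind fluxes never drive concentrations negative."""
        g = tt.make_geometry(n_x=10, n_z=16)
        sp = tt.Species("x", D, S_T, 0.0)
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="cell Peclet number")
            op = _operator(g, sp, scheme=scheme)
        rng = np.random.default_rng(seed)
        c = rng.uniform(0.0, 5.0, op.n) * rng.integers(0, 2, op.n)
        for _ in range(30):
            c = op.step_vector(c, 200.0)
        assert c.min() >= -1e-13


class TestRun:
    def test_zero_gradient_run_keeps_series_constant(self, small_cfg):
        import copy

        cfg = copy.deepcopy(small_cfg)
        cfg["thermal"] = {"T_cold_C": 33.5, "T_hot_C": 33.5}
        comps = build(cfg)
        series, _ = comps.system().run(
            tt.initial_state(comps.geometry, comps.species_list), 4 * 3600.0, comps.settings
        )
        for key, values in series.samples.items():
            assert np.allclose(values, values[0], rtol=1e-12)

    def test_observer_position_outside_chamber_rejected(self, small_components):
        comps = small_components
        with pytest.raises(ValueError):
            comps.system().run(
                tt.initial_state(comps.geometry, comps.species_list),
                3600.0,
                comps.settings,
                record_positions_um=(40_000.0,),
            )


class TestSteadyState:
    def test_no_drift_no_flow_gives_uniform_mean(self):
        g = tt.make_geometry(n_x=12, n_z=20)
        sp = tt.Species("x", 100.0, 0.0, 2.5)
        op = _operator(g, sp, T=(33.0, 33.0))
        steady = tt.steady_state(op, init=tt.initial_state(g, [sp]))
        assert np.allclose(steady.c["x"], 2.5, rtol=1e-9)

    def test_steady_profile_is_log_linear_along_height(self, default_cfg_calibrated):
        """Single-species stationary profile decays exponentially with height."""
        import copy

        cfg = copy.deepcopy(default_cfg_calibrated)
        cfg["flow"] = {"enabled": False}
        comps = build(cfg)
        steady = tt.steady_state(
            comps.operators["sfGFP"], init=tt.initial_state(comps.geometry, comps.species_list)
        )
        prof = steady.gap_profile("sfGFP")
        z = comps.geometry.z_centers
        sel = (z > 0.1 * z[-1]) & (z < 0.9 * z[-1])  # middle 80%
        coeffs, res = np.polyfit(z[sel], np.log(prof[sel]), 1, full=True)[:2]
        ss_tot = np.var(np.log(prof[sel])) * sel.sum()
        r2 = 1.0 - res[0] / ss_tot
        assert r2 > 0.999

    def test_closed_steady_without_mass_reference_rejected(self, small_components):
        with pytest.raises(ValueError):
            tt.steady_state(small_components.operators["sfGFP"])


class TestTopFlow:
    def _flow_op(self, Q=11.0, feed=0.0, exchange=True):
        g = tt.make_geometry(n_x=12, n_z=30)
        sp = tt.Species("x", 100.0, 0.01, 1.0)
        bc = FlowBC(flow_rate_ul_h=Q, feed_uM=feed, channel_volume_ul=7.92, exchange=exchange)
        return g, sp, _operator(g, sp, bc=bc)

    def test_channel_only_washout_matches_cstr_closed_form(self):
        """With exchange off, the channel decays as exp(-Q t / V_ch)."""
        g, sp, op = self._flow_op(exchange=False)
        c = np.zeros(op.n)
        c[-1] = 1.0
        dt, n = 30.0, 240
        for _ in range(n):
            c = op.step_vector(c, dt)
        t = dt * n
        tau = op.bc.channel_volume_ul * 1e9 / op.bc.Q_um3_s
        # backward Euler of a scalar decay: (1 + dt/tau)^-n
        assert c[-1] == pytest.approx((1.0 + dt / tau) ** -n, rel=1e-9)
        assert c[-1] == pytest.approx(np.exp(-t / tau), rel=0.02)

    def test_feed_equal_to_channel_with_empty_trap_is_static(self):
        g, sp, op = self._flow_op(feed=1.0, exchange=False)
        c = np.zeros(op.n)
        c[-1] = 1.0
        out = op.step_vector(c, 600.0)
        assert out[-1] == pytest.approx(1.0, rel=1e-12)

    def test_zero_flow_keeps_closed_mass(self):
        g, sp, op = self._flow_op(Q=0.0)
        sys = tt.TransportSystem(g, {"x": op})
        state = tt.initial_state(g, [sp], bc=op.bc)
        m0 = tt.total_mass(state, "x", "all")
        for _ in range(50):
            state = sys.step(state, 600.0)
        assert tt.total_mass(state, "x", "all") == pytest.approx(m0, rel=1e-9)

    def test_discrete_mass_balance_with_outflow(self):
        """Mass change equals inflow minus outflow exactly (implicit accounting)."""
        g, sp, op = self._flow_op(Q=11.0, feed=0.5)
        sys = tt.TransportSystem(g, {"x": op})
        state = tt.initial_state(g, [sp], bc=op.bc)
        m0 = tt.total_mass(state, "x", "all")
        for _ in range(40):
            state = sys.step(state, 900.0)
        m1 = tt.total_mass(state, "x", "all")
        balance = m0 + state.added_pmol["x"] - state.removed_pmol["x"]
        assert m1 == pytest.approx(balance, rel=1e-9)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            FlowBC(flow_rate_ul_h=-1.0)


class TestTotalMass:
    def test_uniform_concentration_gives_volume_times_conc(self):
        g = tt.make_geometry()  # 60 ul
        sp = tt.Species("x", 100.0, 0.0, 1.0)
        state = tt.initial_state(g, [sp])
        assert tt.total_mass(state, "x", "trap") == pytest.approx(60.0, rel=1e-9)

    def test_region_additivity(self):
        g = tt.make_geometry(n_x=12, n_z=30)
        sp = tt.Species("x", 100.0, 0.0, 1.0)
        bc = FlowBC(flow_rate_ul_h=11.0, channel_volume_ul=5.0)
        state = tt.initial_state(g, [sp], bc=bc, channel_uM={"x": 2.0})
        assert tt.total_mass(state, "x", "trap") + tt.total_mass(
            state, "x", "channel"
        ) == pytest.approx(tt.total_mass(state, "x", "all"))

    def test_unknown_region_rejected(self):
        g = tt.make_geometry(n_x=12, n_z=30)
        state = tt.initial_state(g, [tt.Species("x", 100.0, 0.0, 1.0)])
        with pytest.raises(ValueError):
            tt.total_mass(state, "x", "everywhere")
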