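import math

import numpy as np
import pytest

from nosegc.flow import solve_flow
from nosegc.nose import ChannelNetwork, circular_segment, slot_segment
from nosegc.particles import (
    AIR_VISCOSITY,
    FluidLocal,
    ParticleState,
    deposition_curve,
    drag_response,
    impaction_factor,
    relaxation_time,
    run_deposition_study,
    step_particle,
    track_particles,
)


class TestDragResponse:
    def test_stokes_limit(self):
        assert drag_response(0.0) == 1.0

    def test_unit_reynolds_value(self):
        assert drag_response(1.0) == pytest.approx(1.15, rel=1e-12)

    def test_monotone_on_correlation_range(self):
        grid = np.linspace(0.0, 1000.0, 500)
        vals = drag_response(grid)
        assert np.all(np.diff(vals) >= 0.0)
        assert np.all(vals >= 1.0)

    def test_out_of_range_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="outside the drag correlation"):
            v = drag_response(2000.0)
        assert v == pytest.approx(drag_response(1000.0), rel=1e-12)


def _state(v=(0.0, 0.0, 0.0), d=10e-6, rho=1000.0):
    return ParticleState(position=np.zeros(3), velocity=np.array(v, float), diameter=d, density=rho)


def _fluid(v=(0.0, 0.0, 0.0)):
    return FluidLocal(velocity=np.array(v, float))


class TestStepParticle:
    def test_equilibrium_state_unchanged(self):
        s = _state(v=(0.1, 0.0, 0.0))
        out = step_particle(s, _fluid(v=(0.1, 0.0, 0.0)), dt=1e-4, gravity=False)
        assert np.allclose(out.velocity, s.velocity, atol=1e-15)
        assert np.allclose(out.position, s.velocity * 1e-4, rtol=1e-12)

    def test_stokes_terminal_velocity(self):
        # rho_p=1000, d=10 um, mu=1.81e-5: v_t ~ 3.0e-3 m/s
        s = _state()
        fluid = _fluid()
        tau = relaxation_time(10e-6, 1000.0)
        for _ in range(200):
            s = step_particle(s, fluid, dt=tau)
        v_t = (1000.0 - fluid.density) * 9.81 * (10e-6) ** 2 / (18.0 * AIR_VISCOSITY)
        assert -s.velocity[1] == pytest.approx(v_t, rel=0.01)
        assert v_t == pytest.approx(3.0e-3, rel=0.02)

    def test_drag_relaxation_efolds_over_tau(self):
        d, rho = 5e-6, 1200.0
        tau = relaxation_time(d, rho)
        s = ParticleState(np.zeros(3), np.array([0.0, 0.0, 0.0]), d, rho)
        fluid = _fluid(v=(1e-4, 0.0, 0.0))  # small slip: Stokes regime
        n = 50
        for _ in range(n):
            s = step_particle(s, fluid, dt=tau / n, gravity=False)
        slip_ratio = (fluid.velocity[0] - s.velocity[0]) / fluid.velocity[0]
        assert slip_ratio == pytest.approx(math.exp(-1.0), rel=0.01)

    def test_explicit_scheme_guards_stability(self):
        s = _state()
        with pytest.raises(ValueError, match="semi_implicit"):
            step_particle(s, _fluid(), dt=1.0, scheme="explicit")

    def test_scheme_equivalence_at_small_dt(self):
        d, rho = 20e-6, 900.0
        tau = relaxation_time(d, rho)
        dt = 0.05 * tau
        s_a = ParticleState(np.zeros(3), np.array([0.0, 0.01, 0.0]), d, rho)
        s_b = ParticleState(np.zeros(3), np.array([0.0, 0.01, 0.0]), d, rho)
        fluid = _fluid(v=(0.05, 0.0, 0.0))
        for _ in range(int(5 * tau / dt)):
            s_a = step_particle(s_a, fluid, dt=dt, scheme="semi_implicit")
            s_b = step_particle(s_b, fluid, dt=dt, scheme="explicit")
        scale = np.linalg.norm(s_a.position)
        assert np.linalg.norm(s_a.position - s_b.position) < 0.005 * scale

    def test_saffman_lift_pushes_down_shear_gradient(self):
        # particle lagging a shear flow du/dy > 0 feels a lateral force
        s = ParticleState(np.zeros(3), np.array([0.0, 0.0, 0.0]), 10e-6, 1000.0)
        grad = np.zeros((3, 3))
        grad[0, 1] = 100.0  # du_x/dy
        fluid = FluidLocal(velocity=np.array([0.1, 0.0, 0.0]), velocity_gradient=grad)
        out = step_particle(s, fluid, dt=1e-6, gravity=False, lift=True)
        ref = step_particle(s, FluidLocal(velocity=np.array([0.1, 0.0, 0.0])), dt=1e-6,
                            gravity=False, lift=True)
        assert out.velocity[1] > ref.velocity[1]


def _toy_channel(shape="slot", halfgap=1e-4, width=5e-3, length=1e-2, radius=2e-4):
    if shape == "slot":
        seg = slot_segment("c", halfgap, width, length, "respiratory")
    else:
        seg = circular_segment("c", radius, length, "respiratory")
    return ChannelNetwork(segments=(seg,), edges=(), inlet_ids=("c",), outlet_ids=("c",))


class TestTrackParticles:
    def test_tracers_follow_streamlines_without_gravity(self):
        net = _toy_channel("circular")
        fl = solve_flow(net, 1e-7)
        records = track_particles(net, fl, 500, 0.5e-6, 1000.0, seed=3, gravity=False)
        assert all(r.fate == "escaped" for r in records)

    def test_plug_flow_sedimentation_matches_analytic_fraction(self):
        # deposition fraction = min(1, v_t L / (U h)) with h the full gap
        halfgap, length = 1e-4, 1e-2
        net = _toy_channel("slot", halfgap=halfgap, length=length)
        u_mean = 0.2
        fl = solve_flow(net, u_mean * net.segment("c").cross_area)
        n = 2000
        d_p, rho_p = 10e-6, 1000.0
        records = track_particles(net, fl, n, d_p, rho_p, seed=11, profile="plug")
        v_t = (rho_p - 1.2) * 9.81 * d_p**2 / (18.0 * AIR_VISCOSITY)
        expected = min(1.0, v_t * length / (u_mean * 2 * halfgap))
        eff = sum(r.fate == "deposited" for r in records) / n
        se = math.sqrt(expected * (1.0 - expected) / n)
        assert abs(eff - expected) <= 3.0 * se

    def test_fate_closure_and_determinism(self, mouse_network, mouse_flow):
        a = track_particles(mouse_network, mouse_flow, 400, 8e-6, 1000.0, seed=21)
        b = track_particles(mouse_network, mouse_flow, 400, 8e-6, 1000.0, seed=21)
        assert a == b
        fates = [r.fate for r in a]
        assert fates.count("deposited") + fates.count("escaped") == 400
        assert fates.count("lost") == 0

    def test_deposit_positions_lie_on_network(self, mouse_network, mouse_flow):
        x_max = max(s.axial_start + s.length for s in mouse_network.segments)
        records = track_particles(mouse_network, mouse_flow, 300, 15e-6, 1000.0, seed=2)
        for r in records:
            if r.fate == "deposited":
                assert r.segment_id is not None
                assert 0.0 <= r.axial_position <= x_max + 1e-12


class TestImpactionFactor:
    def test_fifteen_micron_restful_mouse_value(self):
        # rho = 1 g/cm³, d = 15 um, Q = 25 mL/min = 0.4167 cm³/s
        assert impaction_factor(1.0, 15.0, 25.0 / 60.0) == pytest.approx(93.8, rel=1e-3)

    def test_quadratic_in_diameter(self):
        assert impaction_factor(1.0, 30.0, 0.4) == pytest.approx(
            4.0 * impaction_factor(1.0, 15.0, 0.4), rel=1e-12
        )

    def test_degenerate_zero_inputs(self):
        assert impaction_factor(0.0, 15.0, 0.4) == 0.0
        assert impaction_factor(1.0, 0.0, 0.4) == 0.0


class TestDepositionCurve:
    def test_all_escape_and_all_deposit_limits(self):
        net = _toy_channel("circular", radius=5e-4, length=2e-2)
        fl = solve_flow(net, 1e-7)
        recs = {
            0.2: track_particles(net, fl, 200, 0.2e-6, 1000.0, seed=1, gravity=False),
            60.0: track_particles(net, fl, 200, 60e-6, 1000.0, seed=2),
        }
        curve = deposition_curve(recs, 1.0, 1.0)
        assert curve.loc[0, "efficiency"] == 0.0
        assert curve.loc[1, "efficiency"] == 1.0

    def test_mouse_curve_monotone_in_impaction_factor(self, mouse_network, mouse_flow):
        curve = run_deposition_study(
            mouse_network, mouse_flow, [1.5, 3, 5, 8, 12, 15, 25, 43], 1000, seed=5
        )
        eff = curve["efficiency"].to_numpy()
        se = curve["se_binomial"].to_numpy()
        drops = np.diff(eff)
        allowance = 3.0 * np.sqrt(se[1:] ** 2 + se[:-1] ** 2)
        assert np.all(drops >= -allowance)
        assert eff[-1] > eff[0]  # 43 um beats 1.5 um
        assert np.all(curve["lost"].to_numpy() == 0)

    def test_large_impaction_factor_saturates(self, mouse_network, mouse_flow):
        curve = run_deposition_study(mouse_network, mouse_flow, [20, 43], 500, seed=9)
        assert np.all(curve["efficiency"].to_numpy() > 0.99)

    def test_efficiency_nondecreasing_in_flow_at_impaction_sizes(self, mouse_network):
        # holds where inertial impaction dominates (>= ~20 um here); at
        # smaller sizes sedimentation (which scales as 1/Q) can outweigh the
        # impaction gain, so the claim is regime-limited by construction
        from nosegc.pipeline import ML_MIN_TO_M3_S

        effs = {}
        for q_ml in (25.0, 50.0):
            fl = solve_flow(mouse_network, q_ml * ML_MIN_TO_M3_S, 0.1)
            curve = run_deposition_study(mouse_network, fl, [25, 43], 1000, seed=13)
            effs[q_ml] = curve.set_index("d_p_um")["efficiency"]
        for d in (25.0, 43.0):
            assert effs[50.0][d] >= effs[25.0][d] - 3.0 * math.sqrt(0.25 / 1000)

    def test_requires_two_sizes(self):
        with pytest.raises(ValueError, match="two particle sizes"):
            deposition_curve({10.0: []}, 1.0, 1.0)
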