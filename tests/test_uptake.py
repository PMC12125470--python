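import math

import numpy as np
import pytest

from nosegc.flow import solve_flow
from nosegc.nose import ChannelNetwork, circular_segment
from nosegc.odorants import MucosaSpec, Odorant, default_odorants, wall_permeability
from nosegc.uptake import (
    absorption_map,
    propagate_network_uptake,
    solubility_sweep,
    solve_channel_uptake,
    well_mixed_absorbed_fraction,
)

from oracles import fd_uptake_oracle, random_network


def _odorant(beta, d_a=6e-6, d_m=1e-9):
    return Odorant("probe", 100.0, 120.0, d_a, d_m, beta)


def _mucosa(d=10e-6):
    return MucosaSpec(thickness_d=d)


def _single_channel(radius=2e-4, length=5e-3, epithelium="olfactory"):
    seg = circular_segment("c", radius, length, epithelium)
    groups = {"olf": ("c",)} if epithelium == "olfactory" else {}
    return ChannelNetwork(
        segments=(seg,), edges=(), inlet_ids=("c",), outlet_ids=("c",), column_groups=groups
    )


class TestChannelSolver:
    def test_impermeable_wall_absorbs_nothing(self):
        seg = circular_segment("c", 2e-4, 5e-3, "olfactory")
        sol = solve_channel_uptake(seg, 0.05, _odorant(beta=1e12), _mucosa())
        assert sol.absorbed_fraction == pytest.approx(0.0, abs=1e-10)
        assert sol.outlet_conc == pytest.approx(1.0, abs=1e-10)

    def test_perfectly_absorbing_long_channel_absorbs_all(self):
        # Graetz number small: long, narrow, slow
        seg = circular_segment("c", 1e-4, 2e-2, "olfactory")
        sol = solve_channel_uptake(seg, 0.02, _odorant(beta=1e-9), _mucosa())
        assert sol.absorbed_fraction > 0.999

    def test_well_mixed_closed_form_example(self):
        # k_w = 1e-2 m/s, P = 1 mm, L = 5 mm, Q = 4.17e-8 m³/s
        assert well_mixed_absorbed_fraction(1e-2, 1e-3, 5e-3, 4.17e-8) == pytest.approx(
            1.0 - math.exp(-1.2), rel=2e-3
        )

    def test_solver_reaches_well_mixed_limit(self):
        # narrow channel, fast transverse diffusion, weak wall uptake
        seg = circular_segment("c", 5e-5, 5e-3, "olfactory")
        u = 0.2
        odorant = _odorant(beta=2.0, d_a=1e-5)  # k_w = 1e-9/(2*1e-5) = 5e-5 m/s
        k_w = wall_permeability(odorant, _mucosa())
        q = u * seg.cross_area
        expected = well_mixed_absorbed_fraction(k_w, seg.perimeter, seg.length, q)
        sol = solve_channel_uptake(seg, u, odorant, _mucosa())
        assert sol.absorbed_fraction == pytest.approx(expected, rel=0.02)

    def test_monotone_in_length_and_permeability(self):
        mucosa = _mucosa()
        fractions = []
        for length in (2e-3, 4e-3, 8e-3):
            seg = circular_segment("c", 2e-4, length, "olfactory")
            fractions.append(
                solve_channel_uptake(seg, 0.05, _odorant(1e-3), mucosa).absorbed_fraction
            )
        assert fractions[0] < fractions[1] < fractions[2]
        seg = circular_segment("c", 2e-4, 4e-3, "olfactory")
        by_beta = [
            solve_channel_uptake(seg, 0.05, _odorant(b), mucosa).absorbed_fraction
            for b in (1e-1, 1e-2, 1e-3)
        ]
        assert by_beta[0] < by_beta[1] < by_beta[2]

    def test_grid_convergence_within_one_percent(self):
        seg = circular_segment("c", 2e-4, 5e-3, "olfactory")
        kwargs = dict(mean_velocity=0.05, odorant=_odorant(1e-3), mucosa=_mucosa())
        a1 = solve_channel_uptake(seg, n_axial=200, n_transverse=64, **kwargs).absorbed_fraction
        a2 = solve_channel_uptake(seg, n_axial=400, n_transverse=128, **kwargs).absorbed_fraction
        assert a1 == pytest.approx(a2, rel=0.01)

    @pytest.mark.parametrize(
        "shape,half,length,u,beta",
        [
            ("circular", 2e-4, 5e-3, 0.05, 1e-3),
            ("slot", 1e-4, 6e-3, 0.20, 1e-3),
        ],
    )
    def test_matches_explicit_fd_oracle(self, shape, half, length, u, beta):
        # the full five-set oracle-equivalence sweep runs in the acceptance suite
        from nosegc.nose import slot_segment

        odorant = _odorant(beta)
        mucosa = _mucosa()
        k_w = wall_permeability(odorant, mucosa)
        if shape == "circular":
            seg = circular_segment("c", half, length, "olfactory")
        else:
            seg = slot_segment("c", half, 5e-3, length, "olfactory")
        sol = solve_channel_uptake(seg, u, odorant, mucosa, n_axial=400, n_transverse=96)
        ref = fd_uptake_oracle(shape, half, length, u, odorant.D_a, k_w)
        assert sol.absorbed_fraction == pytest.approx(ref, rel=0.01, abs=1e-4)

    def test_graetz_constant_wall_asymptote(self):
        # K -> infinity: mixed-mean decay rate approaches Nu_T = 3.657 for a
        # circular channel; compare the solver's asymptotic decay between L
        # and 2L against h = Nu D / d_h.
        odorant = _odorant(beta=1e-10)  # k_w enormous: constant-zero wall
        mucosa = _mucosa()
        r, u = 1.5e-4, 2.0  # fast enough that 1-a stays resolvable at 2L
        s1 = circular_segment("c", r, 6e-3, "olfactory")
        s2 = circular_segment("c", r, 12e-3, "olfactory")
        a1 = solve_channel_uptake(s1, u, odorant, mucosa, 600, 96).absorbed_fraction
        a2 = solve_channel_uptake(s2, u, odorant, mucosa, 1200, 96).absorbed_fraction
        q = u * s1.cross_area
        decay = -math.log((1.0 - a2) / (1.0 - a1)) / (s1.perimeter * 6e-3 / q)
        nu_theory = 3.657
        assert decay / (odorant.D_a / (2 * r)) == pytest.approx(nu_theory, rel=0.02)

    def test_resolution_floor_enforced(self):
        seg = circular_segment("c", 2e-4, 5e-3, "olfactory")
        with pytest.raises(ValueError, match="resolution"):
            solve_channel_uptake(seg, 0.05, _odorant(1e-3), _mucosa(), n_axial=2)


class TestNetworkPropagation:
    def test_nonabsorbing_network_lets_everything_escape(self, rng):
        seg = circular_segment("c", 2e-4, 5e-3, "nonabsorbing")
        net = ChannelNetwork(segments=(seg,), edges=(), inlet_ids=("c",), outlet_ids=("c",))
        fl = solve_flow(net, 1e-7)
        summ = propagate_network_uptake(net, fl, _odorant(1e-3), _mucosa())
        assert summ.total_fraction == 0.0
        assert summ.escaped_fraction == pytest.approx(1.0, abs=1e-12)

    def test_serial_composition_law(self):
        s1 = circular_segment("a", 2e-4, 3e-3, "respiratory")
        s2 = circular_segment("b", 2e-4, 5e-3, "olfactory")
        net = ChannelNetwork(
            segments=(s1, s2), edges=(("a", "b"),), inlet_ids=("a",), outlet_ids=("b",),
            column_groups={"olf": ("b",)},
        )
        fl = solve_flow(net, 1e-7)
        odorant, mucosa = _odorant(1e-3), _mucosa()
        a1 = solve_channel_uptake(s1, fl.mean_velocity["a"], odorant, mucosa).absorbed_fraction
        a2 = solve_channel_uptake(s2, fl.mean_velocity["b"], odorant, mucosa).absorbed_fraction
        summ = propagate_network_uptake(net, fl, odorant, mucosa)
        assert summ.total_fraction == pytest.approx(1.0 - (1.0 - a1) * (1.0 - a2), rel=1e-8)

    def test_anterior_depletion_of_very_soluble_odorant(self, mouse_network, mouse_flow):
        summ = propagate_network_uptake(
            mouse_network, mouse_flow, _odorant(1e-7), _mucosa(), 100, 32
        )
        assert summ.olfactory_fraction < summ.respiratory_fraction

    def test_flux_closure_on_random_networks(self, rng):
        mucosa = _mucosa()
        for _ in range(25):
            net = random_network(rng)
            fl = solve_flow(net, float(rng.uniform(1e-7, 2e-6)))
            for beta in (1e-6, 1e-3, 1e-1):
                summ = propagate_network_uptake(net, fl, _odorant(beta), mucosa, 60, 16)
                assert summ.total_fraction + summ.escaped_fraction == pytest.approx(
                    1.0, abs=1e-8
                )
                by_class_sum = sum(summ.by_class.values())
                assert by_class_sum == pytest.approx(summ.total_fraction, abs=1e-8)


class TestSolubilitySweep:
    def test_mouse_preset_olfactory_curve_unimodal_with_interior_max(
        self, mouse_network, mouse_flow
    ):
        grid = np.logspace(-10, 0, 21)
        sweep = solubility_sweep(mouse_network, mouse_flow, _mucosa(), grid, n_axial=100, n_transverse=32)
        olf = sweep["olfactory_fraction"].to_numpy()
        k = int(np.argmax(olf))
        assert 0 < k < len(grid) - 1
        # single interior maximum: rises (weakly) then falls (weakly)
        tol = 1e-12
        assert np.all(np.diff(olf[: k + 1]) >= -tol)
        assert np.all(np.diff(olf[k:]) <= tol)

    def test_total_fraction_monotone_nonincreasing_in_beta(self, mouse_network, mouse_flow):
        grid = np.logspace(-8, 0, 9)
        sweep = solubility_sweep(mouse_network, mouse_flow, _mucosa(), grid, n_axial=100, n_transverse=32)
        assert np.all(np.diff(sweep["total_fraction"].to_numpy()) <= 1e-10)

    def test_single_olfactory_channel_is_monotone(self):
        net = _single_channel()
        fl = solve_flow(net, 1e-7)
        grid = np.logspace(-8, 0, 9)
        sweep = solubility_sweep(net, fl, _mucosa(), grid, n_axial=100, n_transverse=32)
        assert np.all(np.diff(sweep["olfactory_fraction"].to_numpy()) <= 1e-10)

    def test_insoluble_limit_absorbs_nothing(self, mouse_network, mouse_flow):
        summ = propagate_network_uptake(
            mouse_network, mouse_flow, _odorant(1e6), _mucosa(), 100, 32
        )
        assert summ.total_fraction < 1e-6
        assert summ.olfactory_fraction < 1e-6

    def test_rat_olfactory_fraction_at_least_mouse(
        self, mouse_network, mouse_flow, rat_network, rat_flow
    ):
        grid = np.logspace(-8, -2, 7)
        mucosa = _mucosa()
        ms = solubility_sweep(mouse_network, mouse_flow, mucosa, grid, n_axial=100, n_transverse=32)
        rs = solubility_sweep(rat_network, rat_flow, mucosa, grid, n_axial=100, n_transverse=32)
        assert np.all(
            rs["olfactory_fraction"].to_numpy() >= ms["olfactory_fraction"].to_numpy()
        )


class TestAbsorptionMap:
    def test_high_solubility_peaks_in_anteriormost_bin(self, mouse_network, mouse_flow):
        amap = absorption_map(
            mouse_network, mouse_flow, _odorant(1e-7), _mucosa(), n_bins=20,
            n_axial=100, n_transverse=32,
        )
        occupied = amap[amap["flux_per_area"] > 0]
        assert occupied["flux_per_area"].idxmax() == occupied.index[0]

    def test_impermeable_walls_give_zero_map(self, mouse_network, mouse_flow):
        amap = absorption_map(
            mouse_network, mouse_flow, _odorant(1e12), _mucosa(), n_bins=10,
            n_axial=100, n_transverse=32,
        )
        assert np.all(amap["absorbed_flux"].to_numpy() < 1e-12)

    def test_integral_matches_total_absorbed(self, mouse_network, mouse_flow):
        odorant, mucosa = _odorant(1e-3), _mucosa()
        amap = absorption_map(mouse_network, mouse_flow, odorant, mucosa, n_bins=33)
        summ = propagate_network_uptake(mouse_network, mouse_flow, odorant, mucosa)
        assert amap["absorbed_flux"].sum() == pytest.approx(summ.total_fraction, rel=0.01)

    def test_two_segment_map_decomposes_into_single_channel_solves(self):
        s1 = circular_segment("a", 2e-4, 3e-3, "respiratory", axial_start=0.0)
        s2 = circular_segment("b", 2e-4, 3e-3, "olfactory", axial_start=3e-3)
        net = ChannelNetwork(
            segments=(s1, s2), edges=(("a", "b"),), inlet_ids=("a",), outlet_ids=("b",),
            column_groups={"olf": ("b",)},
        )
        fl = solve_flow(net, 1e-7)
        odorant, mucosa = _odorant(1e-3), _mucosa()
        amap = absorption_map(net, fl, odorant, mucosa, n_bins=2)
        a1 = solve_channel_uptake(s1, fl.mean_velocity["a"], odorant, mucosa).absorbed_fraction
        a2 = solve_channel_uptake(s2, fl.mean_velocity["b"], odorant, mucosa).absorbed_fraction
        assert amap.loc[0, "absorbed_flux"] == pytest.approx(a1, rel=1e-6)
        assert amap.loc[1, "absorbed_flux"] == pytest.approx((1 - a1) * a2, rel=1e-6)
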