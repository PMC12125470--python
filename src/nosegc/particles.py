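"""Lagrangian particle transport and deposition in channel networks.

The particle force balance is

    du_p/dt = 18 mu/(rho_p d_p²) * (C_D Re_p/24) * (u_f - u_p)
              + g (rho_p - rho_f)/rho_p + F_s,

with Schiller–Naumann drag (C_D Re_p/24 = 1 + 0.15 Re_p^0.687, Re_p <= 1000)
and optional Saffman lift (generalized form, constant 2.594). The default
integrator is semi-implicit: the linear-drag part is updated by its exact
exponential, so the step is unconditionally stable and exact for locally
constant fluid velocity; gravity and lift enter as constant forcing over the
step.

Network tracking walks particles through segments in topological order.
Inside a segment particles see the analytic fully developed profile
(Poiseuille in circular ducts, plane Poiseuille across slot gaps, plates
horizontal) with gravity transverse to the axis; walls trap on first
contact. Idealized circular-arc bends at segment entries provide the
inertial-impaction pathway: during a bend of angle theta and radius R_b the
particle drifts toward the outer wall with the exact linear-drag solution of
the centrifugal force balance. Junctions re-sample the transverse position
uniformly over the cross-section (the perfect-mixing analogue of the
odorant model). Everything is reproducible for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import AIR, AirProperties, NetworkFlow
from .nose import ChannelNetwork, ChannelSegment

__all__ = [
    "ParticleState",
    "FluidLocal",
    "DepositionRecord",
    "drag_response",
    "relaxation_time",
    "step_particle",
    "track_particles",
    "impaction_factor",
    "deposition_curve",
    "run_deposition_study",
]

SAFFMAN_K = 2.594
G_STANDARD = 9.81  # m/s²
#: Dynamic viscosity of air used for particle drag, Pa·s (≈310 K).
AIR_VISCOSITY = 1.81e-5


@dataclass
class ParticleState:
    position: np.ndarray  # m, 3-vector
    velocity: np.ndarray  # m/s, 3-vector
    diameter: float  # m
    density: float  # kg/m³

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (self.diameter > 0 and self.density > 0):
            raise ValueError("particle diameter and density must be positive")


@dataclass
class FluidLocal:
    velocity: np.ndarray  # m/s, 3-vector
    density: float = AIR.density  # kg/m³
    viscosity: float = AIR_VISCOSITY  # Pa·s
    velocity_gradient: np.ndarray | None = None  # 1/s, 3x3 (du_i/dx_j)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (self.density > 0 and self.viscosity > 0):
            raise ValueError("fluid density and viscosity must be positive")


def drag_response(re_p, clamp: bool = True):
    """Schiller–Naumann drag multiplier C_D Re_p / 24 = 1 + 0.15 Re_p^0.687.

    Tends to 1 in the Stokes limit. Outside the correlation range
    (Re_p > 1000) a warning is issued and, with ``clamp`` (default), the
    value at Re_p = 1000 is used.
    """
    re_arr = np.asarray(re_p, dtype=float)
    if np.any(re_arr < 0):
        raise ValueError("particle Reynolds number must be >= 0")
    if np.any(re_arr > 1000.0):
        warnings.warn("particle Reynolds number above 1000: outside the drag correlation")
        if clamp:
            re_arr = np.minimum(re_arr, 1000.0)
    out = 1.0 + 0.15 * re_arr**0.687
    return out if isinstance(re_p, np.ndarray) else float(out)


def relaxation_time(diameter: float, density: float, viscosity: float = AIR_VISCOSITY) -> float:
    """Stokes relaxation time tau = rho_p d_p² / (18 mu), seconds."""
    return density * diameter**2 / (18.0 * viscosity)


def _saffman_acceleration(state: ParticleState, fluid: FluidLocal) -> np.ndarray:
    """Generalized Saffman lift per unit particle mass (Li–Ahmadi form)."""
    if fluid.velocity_gradient is None:
        return np.zeros(3)
    grad = np.asarray(fluid.velocity_gradient, dtype=float)
    d_ij = 0.5 * (grad + grad.T)
    dd = float(np.sum(d_ij * d_ij))
    if dd == 0.0:
        return np.zeros(3)
    nu = fluid.viscosity / fluid.density
    coef = (
        2.0
        * SAFFMAN_K
        * math.sqrt(nu)
        * fluid.density
        / (state.density * state.diameter * dd**0.25)
    )
    return coef * (d_ij @ (fluid.velocity - state.velocity))


def step_particle(
    state: ParticleState,
    fluid: FluidLocal,
    dt: float,
    gravity: bool = True,
    lift: bool = False,
    scheme: str = "semi_implicit",
    g_vector: np.ndarray | None = None,
) -> ParticleState:
    """Advance one particle by ``dt`` under the drag/gravity/lift balance.

    ``semi_implicit`` uses the exact exponential update of the linear drag
    term; ``explicit`` is forward Euler and refuses dt > 0.1 tau.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    g_vec = np.array([0.0, -G_STANDARD, 0.0]) if g_vector is None else np.asarray(g_vector, float)
    tau = relaxation_time(state.diameter, state.density, fluid.viscosity)
    slip = fluid.velocity - state.velocity
    re_p = fluid.density * float(np.linalg.norm(slip)) * state.diameter / fluid.viscosity
    rate = drag_response(re_p) / tau
    accel_ext = np.zeros(3)
    if gravity:
        accel_ext = accel_ext + g_vec * (state.density - fluid.density) / state.density
    if lift:
        accel_ext = accel_ext + _saffman_acceleration(state, fluid)

    if scheme == "explicit":
        if dt > 0.1 * tau:
            raise ValueError(
                f"explicit scheme unstable: dt={dt:.3g} exceeds 0.1*tau={0.1 * tau:.3g}; "
                "use the semi_implicit scheme"
            )
        new_v = state.velocity + dt * (rate * slip + accel_ext)
        new_x = state.position + dt * state.velocity
    elif scheme == "semi_implicit":
        decay = math.exp(-rate * dt)
        settle = accel_ext / rate
        new_v = fluid.velocity + settle - (slip + settle) * decay
        # exact position integral for piecewise-constant fluid velocity
        new_x = (
            state.position
            + (fluid.velocity + settle) * dt
            - (slip + settle) * (1.0 - decay) / rate
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return ParticleState(
        position=new_x, velocity=new_v, diameter=state.diameter, density=state.density
    )


@dataclass(frozen=True)
class DepositionRecord:
    particle_id: int
    fate: str  # "deposited" | "escaped" | "lost"
    segment_id: str | None
    axial_position: float | None  # m from naris tip, for deposits
    flight_time: float  # s


# ---------------------------------------------------------------------------
# Network tracking (vectorized over particles inside each segment)


def _bend_displacement(tau: float, u_axial: float, theta: float, r_bend: float) -> float:
    """Outward drift during an idealized circular-arc bend.

    Linear-drag solution of dv/dt = -v/tau + u²/R_b over the transit time
    t_b = theta R_b / u, starting from zero lateral slip:
    delta = (u²/R_b) tau (t_b - tau (1 - exp(-t_b/tau))).
    """
    if theta <= 0.0 or u_axial <= 0.0:
        return 0.0
    t_b = theta * r_bend / u_axial
    return (u_axial**2 / r_bend) * tau * (t_b - tau * (1.0 - math.exp(-t_b / tau)))


def _transit_segment(
    seg: ChannelSegment,
    u_mean: float,
    x0: np.ndarray,
    y0: np.ndarray,
    v_settle: float,
    profile: str = "poiseuille",
):
    """Exact transit of a particle batch through one straight segment.

    Transverse coordinates (x, y) with gravity along -y; axial coordinate z.
    In the small-relaxation transverse dynamics the particle settles at its
    terminal velocity and rides the local axial fluid speed, so the
    trajectory integrates in closed form: y(t) = y0 - v_t t and z(t) is a
    cubic in t. A particle deposits if it reaches the lower wall before
    z = L (the exit time solves the monotone cubic by bisection); otherwise
    it exits. Returns (deposited mask, z at deposit, transit time, exit y).
    """
    n = x0.size
    half = seg.radius_or_halfgap
    v = v_settle
    if seg.shape == "circular":
        s_wall = np.sqrt(np.clip(half**2 - x0**2, 0.0, None))
        r2 = (x0**2 + y0**2) / half**2
        if profile == "plug":
            z_of = lambda t: u_mean * t
        else:
            z_of = lambda t: 2.0 * u_mean * (
                (1.0 - r2) * t + (y0 * v * t**2 - v**2 * t**3 / 3.0) / half**2
            )
    else:
        s_wall = np.full(n, half)
        if profile == "plug":
            z_of = lambda t: u_mean * t
        else:
            z_of = lambda t: 1.5 * u_mean * (
                (1.0 - (y0 / half) ** 2) * t
                + (y0 * v * t**2 - v**2 * t**3 / 3.0) / half**2
            )

    if v == 0.0 or profile == "plug":
        if profile == "plug":
            u_loc = np.full(n, u_mean)
        elif seg.shape == "circular":
            u_loc = 2.0 * u_mean * np.clip(1.0 - r2, 0.0, None)
        else:
            u_loc = 1.5 * u_mean * np.clip(1.0 - (y0 / half) ** 2, 0.0, None)
        if v == 0.0:
            # tracers: straight lines; zero-speed wall points count as trapped
            on_wall = u_loc <= 0.0
            t_exit = np.where(on_wall, np.inf, seg.length / np.where(on_wall, 1.0, u_loc))
            deposited = on_wall
            z_dep = np.where(on_wall, 0.0, np.nan)
            t_out = np.where(on_wall, 0.0, t_exit)
            return deposited, z_dep, t_out, y0.copy()
        t_dep = (y0 + s_wall) / v
        t_exit = seg.length / u_loc
        deposited = t_dep < t_exit
        z_dep = np.where(deposited, u_loc * t_dep, np.nan)
        t_out = np.where(deposited, t_dep, t_exit)
        return deposited, z_dep, t_out, y0 - v * t_out

    t_dep = (y0 + s_wall) / v  # time to reach the lower boundary
    z_at_dep = z_of(t_dep)
    deposited = z_at_dep < seg.length

    # exit time for escapers: z(t_exit) = L with z monotone on [0, t_dep]
    lo = np.zeros(n)
    hi = t_dep.copy()
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        above = z_of(mid) >= seg.length
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    t_exit = 0.5 * (lo + hi)

    t_out = np.where(deposited, t_dep, t_exit)
    z_dep = np.where(deposited, np.clip(z_at_dep, 0.0, seg.length), np.nan)
    return deposited, z_dep, t_out, y0 - v * t_out


def track_particles(
    network: ChannelNetwork,
    flow: NetworkFlow,
    n_particles: int,
    d_p: float,
    rho_p: float,
    seed: int,
    gravity: bool = True,
    profile: str = "poiseuille",
    air: AirProperties = AIR,
) -> list[DepositionRecord]:
    """Track ``n_particles`` of diameter ``d_p`` (m) and density ``rho_p``
    (kg/m³) from the inlet; returns one DepositionRecord per particle.

    ``profile`` selects the in-segment axial profile ("poiseuille" default,
    "plug" for validation against the plug-flow sedimentation closed form).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    mu = AIR_VISCOSITY
    tau = relaxation_time(d_p, rho_p, mu)
    v_settle = (rho_p - air.density) * G_STANDARD * d_p**2 / (18.0 * mu) if gravity else 0.0

    g, ends = _node_graph_cached(network)
    import networkx as nx

    node_order = list(nx.topological_sort(g))
    outlet_nodes = {ends[o][1] for o in network.outlet_ids}
    inlet_nodes = [ends[i][0] for i in network.inlet_ids]

    # particles waiting at each node
    waiting: dict[str, list[int]] = {n_: [] for n_ in g.nodes}
    ids = np.arange(n_particles)
    waiting[inlet_nodes[0]] = list(ids)
    fate = np.full(n_particles, "", dtype=object)
    fate_seg: dict[int, str | None] = {}
    fate_z: dict[int, float | None] = {}
    time_acc = np.zeros(n_particles)

    for node in node_order:
        batch = waiting.get(node, [])
        if not batch:
            continue
        if node in outlet_nodes:
            for pid in batch:
                fate[pid] = "escaped"
                fate_seg[pid] = None
                fate_z[pid] = None
            continue
        out_edges = list(g.out_edges(node, data=True))
        segs = [network.segment(d["seg"]) for _, _, d in out_edges]
        flows = np.array([max(flow.flow[s.id], 0.0) for s in segs])
        if flows.sum() <= 0:
            raise ValueError(f"no outgoing flow at node {node}")
        probs = flows / flows.sum()
        choice = rng.choice(len(segs), size=len(batch), p=probs)
        for k, seg in enumerate(segs):
            sel = [pid for pid, c in zip(batch, choice) if c == k]
            if not sel:
                continue
            m = len(sel)
            half = seg.radius_or_halfgap
            if seg.shape == "circular":
                rr = half * np.sqrt(rng.random(m))
                th = 2.0 * math.pi * rng.random(m)
                x0, y0 = rr * np.cos(th), rr * np.sin(th)
            else:
                x0 = np.zeros(m)
                y0 = half * (2.0 * rng.random(m) - 1.0)
            u_mean = flow.mean_velocity[seg.id]
            # bend impaction at segment entry
            if seg.bend_angle > 0.0 and seg.bend_radius:
                delta = _bend_displacement(tau, u_mean, seg.bend_angle, seg.bend_radius)
                x0 = x0 + delta
                t_b = seg.bend_angle * seg.bend_radius / u_mean
                time_acc[sel] += t_b
                if seg.shape == "circular":
                    hit0 = x0**2 + y0**2 >= half**2
                else:
                    hit0 = np.abs(x0) >= (seg.width or np.inf) / 2.0
                for j, pid in enumerate(sel):
                    if hit0[j]:
                        fate[pid] = "deposited"
                        fate_seg[pid] = seg.id
                        fate_z[pid] = seg.axial_start
                x0 = x0[~hit0]
                y0 = y0[~hit0]
                sel = [pid for j, pid in enumerate(sel) if not hit0[j]]
                if not sel:
                    continue
            dep, z_dep, t_tr, _ = _transit_segment(
                seg, u_mean, x0, y0, v_settle, profile=profile
            )
            finite_t = np.where(np.isfinite(t_tr), t_tr, 0.0)
            time_acc[sel] += finite_t
            dn = ends[seg.id][1]
            for j, pid in enumerate(sel):
                if dep[j]:
                    fate[pid] = "deposited"
                    fate_seg[pid] = seg.id
                    fate_z[pid] = seg.axial_start + float(z_dep[j])
                else:
                    waiting.setdefault(dn, []).append(pid)

    records = []
    for pid in range(n_particles):
        f = fate[pid] or "lost"
        records.append(
            DepositionRecord(
                particle_id=pid,
                fate=f,
                segment_id=fate_seg.get(pid),
                axial_position=fate_z.get(pid),
                flight_time=float(time_acc[pid]),
            )
        )
    return records


_node_graph_cache: dict[int, tuple] = {}


def _node_graph_cached(network: ChannelNetwork):
    from .flow import _node_graph

    key = id(network)
    if key not in _node_graph_cache:
        if len(_node_graph_cache) > 32:
            _node_graph_cache.clear()
        _node_graph_cache[key] = _node_graph(network)
    return _node_graph_cache[key]


# ---------------------------------------------------------------------------
# Impaction factor and deposition curves


def impaction_factor(rho_g_cm3: float, d_p_um: float, q_cm3_s: float) -> float:
    """Impaction factor IF = rho d_p² Q in g·µm²/s units
    (density in g/cm³, diameter in µm, flow in cm³/s)."""
    if rho_g_cm3 < 0 or d_p_um < 0 or q_cm3_s < 0:
        raise ValueError("impaction-factor inputs must be non-negative")
    return rho_g_cm3 * d_p_um**2 * q_cm3_s


def deposition_curve(
    records_by_size: dict[float, list[DepositionRecord]],
    rho_g_cm3: float,
    q_cm3_s: float,
) -> pd.DataFrame:
    """Deposition efficiency per particle size, keyed by impaction factor.

    ``records_by_size`` maps particle diameter (µm) to tracking records.
    Returns a DataFrame (d_p_um, impaction_factor, n, deposited, efficiency,
    se_binomial) sorted by impaction factor.
    """
    if len(records_by_size) < 2:
        raise ValueError("need at least two particle sizes for a deposition curve")
    rows = []
    for d_um, records in sorted(records_by_size.items()):
        n = len(records)
        dep = sum(1 for r in records if r.fate == "deposited")
        lost = sum(1 for r in records if r.fate == "lost")
        eff = dep / n
        rows.append(
            {
                "d_p_um": d_um,
                "impaction_factor": impaction_factor(rho_g_cm3, d_um, q_cm3_s),
                "n": n,
                "deposited": dep,
                "lost": lost,
                "efficiency": eff,
                "se_binomial": math.sqrt(max(eff * (1.0 - eff), 0.0) / n),
            }
        )
    return pd.DataFrame(rows).sort_values("impaction_factor", ignore_index=True)


def run_deposition_study(
    network: ChannelNetwork,
    flow: NetworkFlow,
    sizes_um,
    n_particles: int,
    rho_p: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Track all sizes and return the deposition-efficiency curve.

    ``sizes_um`` in micrometres; density default 1 g/cm³ (unit-density
    aerodynamic diameter convention).
    """
    records = {}
    for i, d_um in enumerate(sizes_um):
        records[float(d_um)] = track_particles(
            network, flow, n_particles, d_um * 1e-6, rho_p, seed=seed + 7919 * i
        )
    q_cm3_s = flow.Q_total * 1e6
    return deposition_curve(records, rho_p / 1000.0, q_cm3_s)
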