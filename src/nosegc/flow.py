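"""Steady laminar flow on channel networks, dimensionless screening, and the
secondary-flow-strength statistic.

The network solve is a nodal-pressure (Kirchhoff) problem with
Hagen–Poiseuille segment resistances. The dorsal-medial split is imposed:
the DM-feed segment is removed from the conductance Laplacian and replaced
by fixed flow injections at its endpoints, so it carries exactly
``dm_flow_fraction * Q_total`` while everything else splits by resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .nose import ChannelNetwork, ChannelSegment

__all__ = [
    "AirProperties",
    "NetworkFlow",
    "solve_flow",
    "segment_resistance",
    "DimensionlessReport",
    "dimensionless_numbers",
    "GridVelocityField",
    "secondary_strength",
    "synthetic_swirl_field",
]


@dataclass(frozen=True)
class AirProperties:
    """Air near body temperature."""

    density: float = 1.2  # kg/m³
    kinematic_viscosity: float = 1.5e-5  # m²/s

    @property
    def dynamic_viscosity(self) -> float:
        return self.density * self.kinematic_viscosity


AIR = AirProperties()


def segment_resistance(seg: ChannelSegment, air: AirProperties = AIR) -> float:
    """Hagen–Poiseuille resistance, Pa·s/m³.

    Circular: 8 mu L / (pi r^4). Slot of width w, gap 2b: 1.5 mu L / (w b³).
    """
    mu = air.dynamic_viscosity
    if seg.shape == "circular":
        return 8.0 * mu * seg.length / (math.pi * seg.radius_or_halfgap**4)
    # parallel-plate: Q = w (2b)³ dp / (12 mu L)
    b, w = seg.radius_or_halfgap, seg.width
    if w is None:
        raise ValueError(f"slot segment {seg.id} lacks a width")
    return 1.5 * mu * seg.length / (w * b**3)


@dataclass(frozen=True)
class NetworkFlow:
    """Per-segment flow solution at total inspired rate ``Q_total`` (m³/s)."""

    Q_total: float
    flow: dict[str, float]  # m³/s per segment
    mean_velocity: dict[str, float]  # m/s per segment
    resistance: dict[str, float]  # Pa·s/m³ per segment
    pressure_drop: float  # Pa, inlet to outlet
    dm_flow_fraction: float | None = None

    def column_velocities(self, network: ChannelNetwork) -> dict[str, float]:
        out = {}
        for ids in network.column_groups.values():
            for i in ids:
                out[i] = self.mean_velocity[i]
        return out


def _node_graph(network: ChannelNetwork) -> tuple[nx.MultiDiGraph, dict[str, tuple[str, str]]]:
    """Collapse the segment DAG to a junction-node multigraph.

    Each segment becomes an edge between an upstream node and a downstream
    node (a multigraph: parallel columns share both junctions). Junction
    nodes are shared by segments meeting there.
    """
    # Node naming: "in:<seg>" upstream end, "out:<seg>" downstream end; merge
    # out-nodes with in-nodes along adjacency via union-find.
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        parent[find(a)] = find(b)

    for s in network.segments:
        find(f"in:{s.id}")
        find(f"out:{s.id}")
    for u, v in network.edges:
        union(f"out:{u}", f"in:{v}")
    g = nx.MultiDiGraph()
    ends: dict[str, tuple[str, str]] = {}
    for s in network.segments:
        a, b = find(f"in:{s.id}"), find(f"out:{s.id}")
        if a == b:
            raise ValueError(f"segment {s.id} short-circuits a junction")
        g.add_edge(a, b, seg=s.id)
        ends[s.id] = (a, b)
    return g, ends


def solve_flow(
    network: ChannelNetwork,
    Q_total: float,
    dm_flow_fraction: float | None = None,
    dm_segment: str = "dm_feed",
    air: AirProperties = AIR,
) -> NetworkFlow:
    """Solve steady Poiseuille flow at inspired rate ``Q_total``.

    With ``dm_flow_fraction`` set (and ``dm_segment`` present), that segment
    carries exactly the given fraction of ``Q_total``; all remaining splits
    are resistance-proportional. Without it, the whole network splits by
    resistance.
    """
    if not Q_total > 0:
        raise ValueError("Q_total must be positive")
    g, ends = _node_graph(network)
    if not nx.is_weakly_connected(g):
        raise ValueError("channel network is disconnected")
    seg_ids = [s.id for s in network.segments]
    resist = {s.id: segment_resistance(s, air) for s in network.segments}

    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    inlet_nodes = {ends[i][0] for i in network.inlet_ids}
    outlet_nodes = {ends[o][1] for o in network.outlet_ids}

    imposed: dict[str, float] = {}
    if dm_flow_fraction is not None:
        if dm_segment not in resist:
            raise ValueError(f"dm segment {dm_segment!r} not in network")
        imposed[dm_segment] = dm_flow_fraction * Q_total

    a_mat = np.zeros((n, n))
    rhs = np.zeros(n)
    for sid in seg_ids:
        u, v = ends[sid]
        iu, iv = idx[u], idx[v]
        if sid in imposed:
            q = imposed[sid]
            rhs[iu] -= q
            rhs[iv] += q
        else:
            cond = 1.0 / resist[sid]
            a_mat[iu, iu] += cond
            a_mat[iv, iv] += cond
            a_mat[iu, iv] -= cond
            a_mat[iv, iu] -= cond
    # sources: +Q at each inlet node (split equally across inlets), -Q at outlets
    for node in inlet_nodes:
        rhs[idx[node]] += Q_total / len(inlet_nodes)
    for node in outlet_nodes:
        rhs[idx[node]] -= Q_total / len(outlet_nodes)
    # ground one outlet node
    ground = idx[sorted(outlet_nodes)[0]]
    a_mat[ground, :] = 0.0
    a_mat[ground, ground] = 1.0
    rhs[ground] = 0.0
    try:
        p = np.linalg.solve(a_mat, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError(f"singular flow system (disconnected network?): {exc}") from exc

    flow: dict[str, float] = {}
    for sid in seg_ids:
        u, v = ends[sid]
        if sid in imposed:
            flow[sid] = imposed[sid]
        else:
            flow[sid] = (p[idx[u]] - p[idx[v]]) / resist[sid]
    mean_velocity = {s.id: flow[s.id] / s.cross_area for s in network.segments}
    inlet_p = max(p[idx[ends[i][0]]] for i in network.inlet_ids)
    return NetworkFlow(
        Q_total=Q_total,
        flow=flow,
        mean_velocity=mean_velocity,
        resistance=resist,
        pressure_drop=float(inlet_p),
        dm_flow_fraction=dm_flow_fraction,
    )


# ---------------------------------------------------------------------------
# Dimensionless screening


@dataclass(frozen=True)
class DimensionlessReport:
    """Quasi-steady / laminar screening numbers at one station.

    Quasi-steady breathing requires Womersley W0 < 4 and Strouhal S < 1;
    laminar flow requires Re < 2300 (strict inequalities).
    """

    station: str
    Re: float
    W0: float
    S: float | None  # None when U = 0 with f > 0 (undefined)
    assumptions_ok: dict = field(default_factory=dict)


def dimensionless_numbers(
    segment: ChannelSegment,
    flow: NetworkFlow,
    breathing_frequency: float,
    stroke_length: float | None = None,
    air: AirProperties = AIR,
) -> DimensionlessReport:
    """Re, Womersley and Strouhal numbers for one segment.

    Re = U d_h / nu; W0 = (d_h/2) sqrt(2 pi f / nu); S = f L / U with the
    characteristic (stroke) length defaulting to the segment length.
    """
    if breathing_frequency < 0:
        raise ValueError("breathing_frequency must be >= 0")
    nu = air.kinematic_viscosity
    u = abs(flow.mean_velocity[segment.id])
    d_h = segment.hydraulic_diameter
    stroke = segment.length if stroke_length is None else stroke_length
    re = u * d_h / nu
    w0 = 0.5 * d_h * math.sqrt(2.0 * math.pi * breathing_frequency / nu)
    if breathing_frequency == 0.0:
        s: float | None = 0.0
    elif u == 0.0:
        s = None
    else:
        s = breathing_frequency * stroke / u
    flags = {
        "quasi_steady": (w0 < 4.0) and (s is not None and s < 1.0),
        "laminar": re < 2300.0,
        "strouhal_defined": s is not None,
    }
    return DimensionlessReport(station=segment.id, Re=re, W0=w0, S=s, assumptions_ok=flags)


# ---------------------------------------------------------------------------
# Secondary flow strength


@dataclass(frozen=True)
class GridVelocityField:
    """Velocity components on a regular grid.

    ``u`` is the axial component (z, nostrils to nasopharynx); ``v`` and
    ``w`` span the perpendicular plane. All arrays share a shape; ``spacing``
    is the grid step in metres.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    spacing: tuple[float, ...]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.u.shape == self.v.shape == self.w.shape):
            raise ValueError("velocity component arrays must share a shape")
        if any(h <= 0 for h in self.spacing):
            raise ValueError("grid spacing must be positive")
        if self.mask is not None and self.mask.shape != self.u.shape:
            raise ValueError("mask shape must match the velocity arrays")


def secondary_strength(
    field_: GridVelocityField, region_mask: np.ndarray | None = None
) -> tuple[np.ndarray, float | None, dict]:
    """Pointwise secondary-flow strength SS = sqrt(v²+w²)/sqrt(u²+v²+w²).

    Returns ``(ss_grid, regional_mean, report)``. Zero-velocity points get
    SS = NaN, are excluded from the mean and counted in the report. The mean
    is None (with a warning in the report) if the region has no moving air.
    """
    mask = region_mask if region_mask is not None else field_.mask
    sec2 = field_.v**2 + field_.w**2
    tot2 = field_.u**2 + sec2
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.sqrt(sec2 / tot2)
    zero = tot2 == 0.0
    ss[zero] = np.nan
    sel = ~zero if mask is None else (mask.astype(bool) & ~zero)
    n_sel = int(np.count_nonzero(sel))
    report = {
        "n_zero_velocity": int(np.count_nonzero(zero if mask is None else (mask.astype(bool) & zero))),
        "n_averaged": n_sel,
    }
    if n_sel == 0:
        report["warning"] = "region contains no moving air; mean SS undefined"
        return ss, None, report
    return ss, float(np.mean(ss[sel])), report


def synthetic_swirl_field(
    shape: tuple[int, int] = (41, 41),
    spacing: float = 1e-4,
    axial_speed: float = 0.1,
    swirl_ratio: float = 0.5,
) -> GridVelocityField:
    """Uniform axial flow plus solid-body in-plane rotation on a 2D plane.

    The rotation rate is set so that at the reference radius (half the plane
    extent) the in-plane speed equals ``swirl_ratio * axial_speed``; there
    SS = swirl_ratio / sqrt(1 + swirl_ratio²).
    """
    if swirl_ratio < 0:
        raise ValueError("swirl_ratio must be >= 0")
    ny, nz = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    z = (np.arange(nz) - (nz - 1) / 2.0) * spacing
    yy, zz = np.meshgrid(y, z, indexing="ij")
    r_ref = 0.5 * max(y.max(), z.max())
    omega = 0.0 if r_ref == 0 else swirl_ratio * axial_speed / r_ref
    u = np.full(shape, axial_speed)
    v = -omega * zz
    w = omega * yy
    return GridVelocityField(u=u, v=v, w=w, spacing=(spacing, spacing))
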