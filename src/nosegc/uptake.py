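"""Odorant advection–diffusion in channels with an absorbing air–mucus wall.

Each channel carries a steady, laminar, fully developed flow; the odorant
obeys a Graetz-type transport problem with axial advection, transverse
diffusion, and a Robin (third-type) wall condition

    D_a dC/dn = -k_w C,     k_w = D_m / (beta * d),

i.e. finite mucosal uptake limited by diffusion across a mucus film of
thickness d with equilibrium partition coefficient beta at the interface.
Axial diffusion is neglected (the axial Péclet number is large for every
preset). The solver is a conservative finite-volume scheme marched axially
with backward Euler, so the discrete flux closure inlet = outlet + absorbed
holds to machine precision.

Network-level propagation mixes mixed-mean concentrations perfectly at
junctions, splits flux proportionally to flow, and processes segments in
topological order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .flow import NetworkFlow, _node_graph
from .nose import ChannelNetwork, ChannelSegment
from .odorants import MucosaSpec, Odorant, wall_permeability

__all__ = [
    "UptakeSolution",
    "DepositionSummary",
    "solve_channel_uptake",
    "well_mixed_absorbed_fraction",
    "propagate_network_uptake",
    "solubility_sweep",
    "absorption_map",
]


@dataclass(frozen=True)
class UptakeSolution:
    """Single-channel uptake solution for unit inlet mixed-mean concentration.

    ``wall_flux_per_area`` is the absorbed molar flux per unit wall area per
    unit inlet flux, evaluated at the axial stations ``z`` (segment-local).
    """

    segment_id: str
    inlet_conc: float
    outlet_conc: float
    absorbed_fraction: float
    z: np.ndarray
    wall_flux_per_area: np.ndarray

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.absorbed_fraction <= 1.0 + 1e-12):
            raise ValueError(f"absorbed fraction out of [0,1]: {self.absorbed_fraction}")


def well_mixed_absorbed_fraction(k_w: float, perimeter: float, length: float, Q: float) -> float:
    """Plug-flow/well-mixed closed form 1 - exp(-k_w P L / Q).

    Valid when transverse diffusion is fast compared with both residence and
    wall-uptake times, so the cross-section stays uniform.
    """
    return 1.0 - math.exp(-k_w * perimeter * length / Q)


def solve_channel_uptake(
    segment: ChannelSegment,
    mean_velocity: float,
    odorant: Odorant,
    mucosa: MucosaSpec,
    n_axial: int = 200,
    n_transverse: int = 64,
) -> UptakeSolution:
    """Solve the Graetz problem with Robin wall uptake on one channel.

    Circular segments use the axisymmetric formulation with the Poiseuille
    profile u(r) = 2U(1-(r/R)²); slots use the planar formulation with
    u(y) = 1.5U(1-(y/b)²) across the half-gap (symmetry at the midplane).
    Inlet concentration is a flat unit profile (perfect upstream mixing).
    """
    if n_axial < 4 or n_transverse < 4:
        raise ValueError("resolution must be at least 4 points per dimension")
    if mean_velocity <= 0:
        raise ValueError("mean velocity must be positive for inspiration-phase uptake")
    d_a = odorant.D_a
    k_w = wall_permeability(odorant, mucosa)
    half = segment.radius_or_halfgap
    m = n_transverse
    dr = half / m
    dz = segment.length / n_axial

    if segment.shape == "circular":
        r_faces = np.arange(m + 1) * dr
        r_cent = 0.5 * (r_faces[:-1] + r_faces[1:])
        area = math.pi * (r_faces[1:] ** 2 - r_faces[:-1] ** 2)
        u_prof = 2.0 * mean_velocity * (1.0 - (r_cent / half) ** 2)
        face_meas = 2.0 * math.pi * r_faces  # perimeter of interior faces
        wall_meas = 2.0 * math.pi * half
    else:
        y_faces = np.arange(m + 1) * dr
        y_cent = 0.5 * (y_faces[:-1] + y_faces[1:])
        area = np.full(m, dr)  # per unit width, half the gap
        u_prof = 1.5 * mean_velocity * (1.0 - (y_cent / half) ** 2)
        face_meas = np.ones(m + 1)
        wall_meas = 1.0

    q_cell = u_prof * area  # axial volumetric flow per cell
    influx = float(q_cell.sum())

    # interior-face diffusive conductances (per unit axial length)
    g_face = d_a * face_meas[1:-1] / dr  # between cell i and i+1, i=0..m-2
    # wall conductance: half-cell diffusion in series with the mucus film
    if math.isinf(k_w):
        g_wall = d_a * wall_meas / (0.5 * dr)
    else:
        g_wall = wall_meas / (1.0 / k_w + 0.5 * dr / d_a)

    # backward-Euler step: (q/dz) C_new - L C_new = (q/dz) C_old
    diag = q_cell / dz
    ab = np.zeros((3, m))
    ab[0, 1:] = -g_face  # upper
    ab[2, :-1] = -g_face  # lower
    ab[1, :] = diag
    ab[1, :-1] += g_face
    ab[1, 1:] += g_face
    ab[1, -1] += g_wall

    c = np.ones(m)
    wall_flux = np.empty(n_axial)  # absorbed per unit axial length (per step)
    z_cent = (np.arange(n_axial) + 0.5) * dz
    for j in range(n_axial):
        c = solve_banded((1, 1), ab, diag * c, overwrite_b=True, check_finite=False)
        if not np.all(np.isfinite(c)):
            raise ArithmeticError(
                f"uptake marching diverged on segment {segment.id} at step {j} "
                f"(k_w={k_w:.3g}, U={mean_velocity:.3g})"
            )
        wall_flux[j] = g_wall * c[-1]

    outflux = float(q_cell @ c)
    absorbed = float(np.clip(1.0 - outflux / influx, 0.0, 1.0))
    # per unit wall area, normalized by inlet flux
    flux_per_area = wall_flux * dz / (influx * segment.perimeter * dz)
    return UptakeSolution(
        segment_id=segment.id,
        inlet_conc=1.0,
        outlet_conc=outflux / influx,
        absorbed_fraction=absorbed,
        z=z_cent,
        wall_flux_per_area=flux_per_area,
    )


@dataclass(frozen=True)
class DepositionSummary:
    """Network-level odorant deposition, normalized by the inlet odorant flux."""

    total_fraction: float
    by_class: dict[str, float]  # respiratory / olfactory / nonabsorbing
    escaped_fraction: float
    per_segment: pd.DataFrame  # columns: segment, epithelium, entering, absorbed

    @property
    def olfactory_fraction(self) -> float:
        return self.by_class.get("olfactory", 0.0)

    @property
    def respiratory_fraction(self) -> float:
        return self.by_class.get("respiratory", 0.0)


def _segment_solutions(
    network: ChannelNetwork,
    flow: NetworkFlow,
    odorant: Odorant,
    mucosa: MucosaSpec,
    n_axial: int,
    n_transverse: int,
) -> dict[str, UptakeSolution]:
    out = {}
    for s in network.segments:
        if s.epithelium == "nonabsorbing":
            out[s.id] = UptakeSolution(
                segment_id=s.id,
                inlet_conc=1.0,
                outlet_conc=1.0,
                absorbed_fraction=0.0,
                z=np.array([0.5 * s.length]),
                wall_flux_per_area=np.array([0.0]),
            )
        else:
            out[s.id] = solve_channel_uptake(
                s, flow.mean_velocity[s.id], odorant, mucosa, n_axial, n_transverse
            )
    return out


def propagate_network_uptake(
    network: ChannelNetwork,
    flow: NetworkFlow,
    odorant: Odorant,
    mucosa: MucosaSpec,
    n_axial: int = 200,
    n_transverse: int = 64,
    _solutions: dict[str, UptakeSolution] | None = None,
) -> DepositionSummary:
    """Propagate odorant through the network and tally absorbed fractions.

    Junctions mix perfectly: the node concentration is the flux-weighted mean
    of incoming streams and every outgoing segment draws it.
    """
    sols = _solutions or _segment_solutions(network, flow, odorant, mucosa, n_axial, n_transverse)
    g, ends = _node_graph(network)
    inlet_nodes = {ends[i][0] for i in network.inlet_ids}
    outlet_nodes = {ends[o][1] for o in network.outlet_ids}

    import networkx as nx

    node_influx: dict[str, float] = {n: 0.0 for n in g.nodes}
    node_inflow: dict[str, float] = {n: 0.0 for n in g.nodes}
    total_q = flow.Q_total
    for node in inlet_nodes:
        q_node = sum(flow.flow[sid] for sid, (a, _) in ends.items() if a == node)
        node_influx[node] += q_node * 1.0  # unit inlet concentration
        node_inflow[node] += q_node

    rows = []
    escaped = 0.0
    for node in nx.topological_sort(g):
        conc = node_influx[node] / node_inflow[node] if node_inflow[node] > 0 else 0.0
        if node in outlet_nodes:
            escaped += node_influx[node]
            continue
        for _, dn, data in g.out_edges(node, data=True):
            sid = data["seg"]
            f_in = conc * flow.flow[sid]
            a = sols[sid].absorbed_fraction
            seg = network.segment(sid)
            rows.append(
                {
                    "segment": sid,
                    "epithelium": seg.epithelium,
                    "entering_flux": f_in / total_q,
                    "absorbed_flux": f_in * a / total_q,
                    "absorbed_fraction_local": a,
                }
            )
            node_influx[dn] += f_in * (1.0 - a)
            node_inflow[dn] += flow.flow[sid]

    per_segment = pd.DataFrame(rows)
    by_class = {cls: 0.0 for cls in ("respiratory", "olfactory", "nonabsorbing")}
    for _, row in per_segment.iterrows():
        by_class[row["epithelium"]] += row["absorbed_flux"]
    total = float(per_segment["absorbed_flux"].sum())
    return DepositionSummary(
        total_fraction=total,
        by_class=by_class,
        escaped_fraction=escaped / total_q,
        per_segment=per_segment,
    )


def solubility_sweep(
    network: ChannelNetwork,
    flow: NetworkFlow,
    mucosa: MucosaSpec,
    beta_grid,
    template: Odorant | None = None,
    n_axial: int = 200,
    n_transverse: int = 64,
) -> pd.DataFrame:
    """Deposition fractions across a (sorted, positive) partition-coefficient grid.

    Returns a DataFrame (beta, total_fraction, olfactory_fraction,
    respiratory_fraction). With anterior respiratory scrubbing the olfactory
    curve is unimodal in log beta: very soluble odorants never reach the
    olfactory columns, insoluble ones never absorb.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if np.any(beta_grid <= 0) or np.any(np.diff(beta_grid) <= 0):
        raise ValueError("beta_grid must be positive and strictly increasing")
    if template is None:
        from .odorants import default_odorants

        template = default_odorants()[1]  # intermediate-solubility carrier
    rows = []
    for beta in beta_grid:
        summary = propagate_network_uptake(
            network, flow, template.with_beta(float(beta)), mucosa, n_axial, n_transverse
        )
        rows.append(
            {
                "beta": beta,
                "total_fraction": summary.total_fraction,
                "olfactory_fraction": summary.olfactory_fraction,
                "respiratory_fraction": summary.respiratory_fraction,
            }
        )
    return pd.DataFrame(rows)


def absorption_map(
    network: ChannelNetwork,
    flow: NetworkFlow,
    odorant: Odorant,
    mucosa: MucosaSpec,
    n_bins: int = 40,
    n_axial: int = 200,
    n_transverse: int = 64,
) -> pd.DataFrame:
    """Absorbed wall flux per unit area versus distance from the naris tip.

    Returns a DataFrame (bin_start, bin_end, wall_area, absorbed_flux,
    flux_per_area); fluxes are fractions of the inlet odorant flux, so
    sum(absorbed_flux) equals the network total absorbed fraction.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sols = _segment_solutions(network, flow, odorant, mucosa, n_axial, n_transverse)
    summary = propagate_network_uptake(
        network, flow, odorant, mucosa, _solutions=sols
    )
    entering = dict(
        zip(summary.per_segment["segment"], summary.per_segment["entering_flux"])
    )
    x_max = max(s.axial_start + s.length for s in network.segments)
    edges = np.linspace(0.0, x_max, n_bins + 1)
    flux_bins = np.zeros(n_bins)
    area_bins = np.zeros(n_bins)
    for s in network.segments:
        lo, hi = s.axial_start, s.axial_start + s.length
        density = s.wall_area / (hi - lo)
        overlap = np.clip(np.minimum(hi, edges[1:]) - np.maximum(lo, edges[:-1]), 0.0, None)
        if s.epithelium != "nonabsorbing":
            area_bins += density * overlap
        sol = sols[s.id]
        f_in = entering.get(s.id, 0.0)
        if f_in <= 0 or sol.absorbed_fraction == 0.0:
            continue
        # distribute this segment's absorbed flux by its axial profile
        z_abs = s.axial_start + sol.z
        dz = s.length / len(sol.z)
        seg_flux = f_in * sol.wall_flux_per_area * s.perimeter * dz
        idx = np.clip(np.searchsorted(edges, z_abs, side="right") - 1, 0, n_bins - 1)
        np.add.at(flux_bins, idx, seg_flux)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_area = np.where(area_bins > 0, flux_bins / area_bins, 0.0)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "wall_area": area_bins,
            "absorbed_flux": flux_bins,
            "flux_per_area": per_area,
        }
    )
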