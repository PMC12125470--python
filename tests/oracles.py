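"""Independent oracles and random fixtures shared by the test suite.

Everything here is implemented from the governing equations directly,
independent of the package's own numerical paths, so it can serve as a
cross-check: a dense linear-system solve for network flow, an explicit
node-centered finite-difference solve for channel uptake, and a recursive
series-parallel generator for random channel networks.
"""

from __future__ import annotations

import math

import numpy as np

from nosegc.flow import AIR, _node_graph
from nosegc.nose import ChannelNetwork, ChannelSegment, circular_segment, slot_segment


# ---------------------------------------------------------------------------
# Random series-parallel networks


def random_network(rng: np.random.Generator, max_depth: int = 3) -> ChannelNetwork:
    """Random series-parallel channel network with mixed epithelium classes."""
    counter = [0]

    def fresh_segment(axial: float) -> ChannelSegment:
        counter[0] += 1
        sid = f"s{counter[0]:03d}"
        epi = rng.choice(["respiratory", "olfactory", "nonabsorbing"], p=[0.5, 0.3, 0.2])
        length = float(rng.uniform(1e-3, 8e-3))
        if rng.random() < 0.7:
            return circular_segment(sid, float(rng.uniform(1e-4, 6e-4)), length, epi, axial)
        return slot_segment(
            sid, float(rng.uniform(4e-5, 2e-4)), float(rng.uniform(1e-3, 6e-3)), length, epi, axial
        )

    segments: list[ChannelSegment] = []
    edges: list[tuple[str, str]] = []

    def build(depth: int, axial: float) -> tuple[list[str], list[str], float]:
        """Returns (head ids, tail ids, axial extent)."""
        if depth == 0 or rng.random() < 0.3:
            seg = fresh_segment(axial)
            segments.append(seg)
            return [seg.id], [seg.id], seg.length
        if rng.random() < 0.5:  # series
            h1, t1, ext1 = build(depth - 1, axial)
            h2, t2, ext2 = build(depth - 1, axial + ext1)
            for a in t1:
                for b in h2:
                    edges.append((a, b))
            return h1, t2, ext1 + ext2
        # parallel
        n_par = int(rng.integers(2, 4))
        heads, tails, exts = [], [], []
        for _ in range(n_par):
            h, t, e = build(depth - 1, axial)
            heads += h
            tails += t
            exts.append(e)
        return heads, tails, max(exts)

    heads, tails, _ = build(max_depth, 0.0)
    inlet = circular_segment("inlet", 4e-4, 2e-3, "respiratory", 0.0)
    outlet = circular_segment("outlet", 4e-4, 2e-3, "nonabsorbing", 0.0)
    segments = [inlet] + segments + [outlet]
    edges += [("inlet", h) for h in heads] + [(t, "outlet") for t in tails]
    # olfactory segments must be grouped
    olf = tuple(s.id for s in segments if s.epithelium == "olfactory")
    groups = {"olf": olf} if olf else {}
    return ChannelNetwork(
        segments=tuple(segments),
        edges=tuple(edges),
        inlet_ids=("inlet",),
        outlet_ids=("outlet",),
        column_groups=groups,
    )


def junction_imbalance(network: ChannelNetwork, flow) -> float:
    """Largest relative junction flow imbalance (interior nodes)."""
    g, ends = _node_graph(network)
    inlets = {ends[i][0] for i in network.inlet_ids}
    outlets = {ends[o][1] for o in network.outlet_ids}
    worst = 0.0
    for node in g.nodes:
        if node in inlets or node in outlets:
            continue
        q_in = sum(flow.flow[d["seg"]] for _, _, d in g.in_edges(node, data=True))
        q_out = sum(flow.flow[d["seg"]] for _, _, d in g.out_edges(node, data=True))
        worst = max(worst, abs(q_in - q_out) / max(abs(q_in), 1e-300))
    return worst


def dense_flow_oracle(network: ChannelNetwork, q_total: float) -> dict[str, float]:
    """Brute-force flow solve: per-segment flows and node pressures as one
    least-squares system assembled straight from the physics (Ohm + Kirchhoff),
    without the package's Laplacian reduction. Resistance-only (no imposed
    DM split)."""
    from nosegc.flow import segment_resistance

    _, ends = _node_graph(network)
    nodes = sorted({n for pair in ends.values() for n in pair})
    seg_ids = [s.id for s in network.segments]
    n_s, n_n = len(seg_ids), len(nodes)
    sidx = {s: i for i, s in enumerate(seg_ids)}
    nidx = {n: n_s + j for j, n in enumerate(nodes)}
    rows, rhs = [], []
    # Ohm: q_i - (p_u - p_v)/R_i = 0, with pressures scaled by a typical
    # resistance so the system is well conditioned
    r_all = {s.id: segment_resistance(s, AIR) for s in network.segments}
    r_scale = float(np.median(list(r_all.values())))
    for s in network.segments:
        r = r_all[s.id]
        u, v = ends[s.id]
        row = np.zeros(n_s + n_n)
        row[sidx[s.id]] = 1.0
        row[nidx[u]] = -r_scale / r
        row[nidx[v]] = r_scale / r
        rows.append(row)
        rhs.append(0.0)
    # Kirchhoff with injections
    inlets = {ends[i][0] for i in network.inlet_ids}
    outlets = {ends[o][1] for o in network.outlet_ids}
    for node in nodes:
        row = np.zeros(n_s + n_n)
        for sid, (u, v) in ends.items():
            if v == node:
                row[sidx[sid]] += 1.0
            if u == node:
                row[sidx[sid]] -= 1.0
        inj = 0.0
        if node in inlets:
            inj -= q_total / len(inlets)
        if node in outlets:
            inj += q_total / len(outlets)
        rows.append(row)
        rhs.append(inj)
    # ground
    row = np.zeros(n_s + n_n)
    row[nidx[sorted(outlets)[0]]] = 1.0
    rows.append(row)
    rhs.append(0.0)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return {sid: float(sol[sidx[sid]]) for sid in seg_ids}


# ---------------------------------------------------------------------------
# Explicit finite-difference uptake oracle


def fd_uptake_oracle(
    shape: str,
    half: float,
    length: float,
    u_mean: float,
    d_a: float,
    k_w: float,
    m: int = 32,
) -> float:
    """Absorbed fraction from an explicit node-centered FD solve of the same
    Graetz/Robin problem (independent discretization: nodes on r_j = j dr
    including the wall, forward-Euler axial marching)."""
    dr = half / m
    r = np.arange(m + 1) * dr
    if shape == "circular":
        u = 2.0 * u_mean * (1.0 - (r / half) ** 2)
        weight = r.copy()  # for mixed-mean integrals (2 pi r dr)
    else:
        u = 1.5 * u_mean * (1.0 - (r / half) ** 2)
        weight = np.ones(m + 1)
    # nodes 0..m-1 are marched; the wall node follows the Robin closure
    u_march = u[:m]
    coef = d_a * (2.0 / dr**2 + 1.0 / (np.maximum(r[:m], dr / 2) * dr))
    dz = 0.45 * np.min(u_march[u_march > 0] / coef[u_march > 0])
    n_steps = int(math.ceil(length / dz))
    dz = length / n_steps

    c = np.ones(m + 1)
    robin = 1.0 / (1.0 + k_w * dr / d_a)
    c[m] = robin * c[m - 1]
    for _ in range(n_steps):
        lap = np.empty(m)
        lap[0] = (
            4.0 * (c[1] - c[0]) / dr**2
            if shape == "circular"
            else 2.0 * (c[1] - c[0]) / dr**2
        )
        j = np.arange(1, m)
        lap[1:] = (c[j + 1] - 2.0 * c[j] + c[j - 1]) / dr**2
        if shape == "circular":
            lap[1:] += (c[j + 1] - c[j - 1]) / (2.0 * r[j] * dr)
        c_new = c.copy()
        c_new[:m] = c[:m] + dz * d_a * lap / u[:m]
        c_new[m] = robin * c_new[m - 1]
        c = c_new

    flux_in = np.trapezoid(u * weight, dx=dr)
    flux_out = np.trapezoid(u * c * weight, dx=dr)
    return float(1.0 - flux_out / flux_in)
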