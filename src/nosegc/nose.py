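"""Synthetic channel-network noses.

A reduced-order nasal airway is a directed acyclic network of straight
channel segments: an anterior respiratory path (naris, vestibule) that
bifurcates into a wide ventral respiratory slot and a dorsal-medial (DM)
feed duct; the DM feed fans out into ``Np`` parallel olfactory columns
(standing in for the coiled ethmoid-turbinate channels) which reconverge
through a collector and merge with the respiratory path at the nasopharynx.

The generator is calibrated so that the summed wall area and airspace
volume of a species preset match morphometric targets (mouse: 2.90 cm²,
0.0291 mL); the ventral slot's half-gap and width are solved in closed form
to close the area/volume budget.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "ChannelSegment",
    "ChannelNetwork",
    "SyntheticNoseSpec",
    "circular_segment",
    "slot_segment",
    "build_nose",
    "calibrate_to_morphometry",
    "epithelium_profile",
    "elongated_tube_variant",
    "mouse_spec",
    "rat_spec",
    "write_vtk_centerlines",
]

EPITHELIUM_CLASSES = ("respiratory", "olfactory", "nonabsorbing")


@dataclass(frozen=True)
class ChannelSegment:
    """One straight channel of the network.

    ``radius_or_halfgap`` is the tube radius for ``shape='circular'`` and the
    half-gap b for ``shape='slot'`` (a parallel-plate passage of width
    ``width`` and gap 2b). ``axial_start`` is the distance of the segment's
    inlet from the naris tip. ``bend_angle``/``bend_radius`` describe an
    idealized circular-arc turn executed at the segment entry (used by the
    Lagrangian particle tracker for inertial impaction); zero angle means a
    straight junction.
    """

    id: str
    length: float
    shape: str  # "circular" | "slot"
    radius_or_halfgap: float
    perimeter: float
    cross_area: float
    epithelium: str
    axial_start: float = 0.0
    width: float | None = None  # slot width, m
    bend_angle: float = 0.0  # rad
    bend_radius: float | None = None  # m

    def __post_init__(self) -> None:
        if self.shape not in ("circular", "slot"):
            raise ValueError(f"segment {self.id}: unknown shape {self.shape!r}")
        if self.epithelium not in EPITHELIUM_CLASSES:
            raise ValueError(f"segment {self.id}: unknown epithelium {self.epithelium!r}")
        for name in ("length", "perimeter", "cross_area", "radius_or_halfgap"):
            if not getattr(self, name) > 0:
                raise ValueError(
                    f"segment {self.id}: {name} must be positive, got {getattr(self, name)!r}"
                )
        if not self.hydraulic_diameter > 0:
            raise ValueError(f"segment {self.id}: non-positive hydraulic diameter")

    @property
    def hydraulic_diameter(self) -> float:
        return 4.0 * self.cross_area / self.perimeter

    @property
    def wall_area(self) -> float:
        return self.perimeter * self.length

    @property
    def volume(self) -> float:
        return self.cross_area * self.length


def circular_segment(
    id: str,
    radius: float,
    length: float,
    epithelium: str,
    axial_start: float = 0.0,
    bend_angle: float = 0.0,
    bend_radius: float | None = None,
) -> ChannelSegment:
    return ChannelSegment(
        id=id,
        length=length,
        shape="circular",
        radius_or_halfgap=radius,
        perimeter=2.0 * math.pi * radius,
        cross_area=math.pi * radius**2,
        epithelium=epithelium,
        axial_start=axial_start,
        bend_angle=bend_angle,
        bend_radius=bend_radius,
    )


def slot_segment(
    id: str,
    halfgap: float,
    width: float,
    length: float,
    epithelium: str,
    axial_start: float = 0.0,
    bend_angle: float = 0.0,
    bend_radius: float | None = None,
) -> ChannelSegment:
    return ChannelSegment(
        id=id,
        length=length,
        shape="slot",
        radius_or_halfgap=halfgap,
        perimeter=2.0 * (width + 2.0 * halfgap),
        cross_area=2.0 * halfgap * width,
        epithelium=epithelium,
        axial_start=axial_start,
        width=width,
        bend_angle=bend_angle,
        bend_radius=bend_radius,
    )


@dataclass(frozen=True)
class ChannelNetwork:
    """Directed acyclic channel network from inlets to outlets."""

    segments: tuple[ChannelSegment, ...]
    edges: tuple[tuple[str, str], ...]  # (upstream id, downstream id)
    inlet_ids: tuple[str, ...]
    outlet_ids: tuple[str, ...]
    column_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    calibration_report: dict | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def segment(self, seg_id: str) -> ChannelSegment:
        return self._by_id[seg_id]

    @property
    def _by_id(self) -> dict[str, ChannelSegment]:
        return {s.id: s for s in self.segments}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(s.id for s in self.segments)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids")
        known = set(ids)
        for u, v in self.edges:
            if u not in known or v not in known:
                raise ValueError(f"edge ({u}, {v}) references unknown segment")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("channel network must be acyclic")
        reach_fwd: set[str] = set()
        for i in self.inlet_ids:
            reach_fwd |= {i} | nx.descendants(g, i)
        reach_bwd: set[str] = set()
        for o in self.outlet_ids:
            reach_bwd |= {o} | nx.ancestors(g, o)
        stranded = known - (reach_fwd & reach_bwd)
        if stranded:
            raise ValueError(f"segments not on an inlet->outlet path: {sorted(stranded)}")
        olfactory = {s.id for s in self.segments if s.epithelium == "olfactory"}
        grouped: list[str] = [i for ids_ in self.column_groups.values() for i in ids_]
        if len(grouped) != len(set(grouped)):
            raise ValueError("column_groups overlap")
        if self.column_groups and set(grouped) != olfactory:
            raise ValueError("column_groups must partition the olfactory segments")

    def topological_order(self) -> list[str]:
        g = self.to_networkx()
        order = [n for n in nx.lexicographical_topological_sort(g)]
        return order

    # -- morphometry -------------------------------------------------------
    def total_wall_area(self) -> float:
        return sum(s.wall_area for s in self.segments)

    def total_volume(self) -> float:
        return sum(s.volume for s in self.segments)

    def olfactory_segments(self) -> list[ChannelSegment]:
        return [s for s in self.segments if s.epithelium == "olfactory"]

    def scaled(self, transverse: float, axial: float) -> "ChannelNetwork":
        """Similarity-scale all transverse dimensions by ``transverse`` and
        axial ones by ``axial``; topology unchanged."""
        if not (transverse > 0 and axial > 0):
            raise ValueError("scale factors must be positive")
        new_segments = []
        for s in self.segments:
            new_segments.append(
                replace(
                    s,
                    length=s.length * axial,
                    radius_or_halfgap=s.radius_or_halfgap * transverse,
                    perimeter=s.perimeter * transverse,
                    cross_area=s.cross_area * transverse**2,
                    axial_start=s.axial_start * axial,
                    width=None if s.width is None else s.width * transverse,
                    bend_radius=None if s.bend_radius is None else s.bend_radius * axial,
                )
            )
        return replace(self, segments=tuple(new_segments))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "schema": "nosegc/channel-network/1",
            "segments": [
                {
                    "id": s.id,
                    "length": s.length,
                    "shape": s.shape,
                    "radius_or_halfgap": s.radius_or_halfgap,
                    "perimeter": s.perimeter,
                    "cross_area": s.cross_area,
                    "epithelium": s.epithelium,
                    "axial_start": s.axial_start,
                    "width": s.width,
                    "bend_angle": s.bend_angle,
                    "bend_radius": s.bend_radius,
                }
                for s in self.segments
            ],
            "edges": [list(e) for e in self.edges],
            "inlet_ids": list(self.inlet_ids),
            "outlet_ids": list(self.outlet_ids),
            "column_groups": {k: list(v) for k, v in self.column_groups.items()},
            "calibration_report": self.calibration_report,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ChannelNetwork":
        payload = json.loads(text)
        if payload.get("schema") != "nosegc/channel-network/1":
            raise ValueError("unknown network schema")
        segments = tuple(ChannelSegment(**d) for d in payload["segments"])
        return cls(
            segments=segments,
            edges=tuple((u, v) for u, v in payload["edges"]),
            inlet_ids=tuple(payload["inlet_ids"]),
            outlet_ids=tuple(payload["outlet_ids"]),
            column_groups={k: tuple(v) for k, v in payload["column_groups"].items()},
            calibration_report=payload.get("calibration_report"),
        )


# ---------------------------------------------------------------------------
# Specs and presets


@dataclass(frozen=True)
class SyntheticNoseSpec:
    """Parameters of a synthetic nose build.

    ``dm_flow_fraction`` is carried on the spec for downstream flow solves
    (the geometry itself does not impose it). ``respiratory_path_dimensions``
    maps anterior/posterior duct names to (radius, length) pairs in metres.
    """

    species_preset: str = "custom"
    n_parallel_columns: int = 6
    dm_flow_fraction: float = 0.1
    target_surface_area: float = 2.90  # cm²
    target_volume: float = 0.0291  # mL
    column_radius: float = 200e-6  # m
    column_length: float = 7e-3  # m (Lc)
    ventral_length: float = 12e-3  # m
    respiratory_path_dimensions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_MOUSE_PATH)
    )
    column_jitter: float = 0.01  # fractional seeded jitter on column radii
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.dm_flow_fraction < 1.0):
            raise ValueError("dm_flow_fraction must lie in (0, 1)")
        if self.n_parallel_columns < 1:
            raise ValueError("n_parallel_columns must be >= 1")
        for name in ("target_surface_area", "target_volume", "column_radius", "column_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


# (radius m, length m) for the serial ducts; bends are (angle rad, radius m)
_MOUSE_PATH = {
    "naris": (400e-6, 1.5e-3),
    "vestibule": (500e-6, 2.5e-3),
    "dm_feed": (300e-6, 3e-3),
    "collector": (400e-6, 2e-3),
    "nasopharynx": (500e-6, 3e-3),
}
_RAT_PATH = {
    "naris": (700e-6, 2e-3),
    "vestibule": (900e-6, 4e-3),
    "dm_feed": (500e-6, 5e-3),
    "collector": (700e-6, 3e-3),
    "nasopharynx": (900e-6, 5e-3),
}


def mouse_spec(seed: int = 0) -> SyntheticNoseSpec:
    """Mouse preset: morphometry targets from micro-CT measurements
    (2.90 cm², 0.0291 mL); 6 parallel olfactory columns of radius 200 µm and
    path length 7 mm; network numerics are stand-ins, not measured values."""
    return SyntheticNoseSpec(
        species_preset="mouse",
        n_parallel_columns=6,
        dm_flow_fraction=0.1,
        target_surface_area=2.90,
        target_volume=0.0291,
        column_radius=200e-6,
        column_length=7e-3,
        ventral_length=12e-3,
        respiratory_path_dimensions=dict(_MOUSE_PATH),
        random_seed=seed,
    )


def rat_spec(seed: int = 0) -> SyntheticNoseSpec:
    """Rat preset: literature-order morphometry stand-ins (14 cm², 0.26 mL);
    30 parallel olfactory columns of radius 300 µm and path length 12 mm —
    the rat ethmoid recess is the more convoluted of the two species."""
    return SyntheticNoseSpec(
        species_preset="rat",
        n_parallel_columns=30,
        dm_flow_fraction=0.1,
        target_surface_area=14.0,
        target_volume=0.26,
        column_radius=300e-6,
        column_length=12e-3,
        ventral_length=20e-3,
        respiratory_path_dimensions=dict(_RAT_PATH),
        random_seed=seed,
    )


SPECIES_SPECS = {"mouse": mouse_spec, "rat": rat_spec}


# ---------------------------------------------------------------------------
# Construction


def _solve_slot_closure(area_rem: float, vol_rem: float, length: float) -> tuple[float, float]:
    """Half-gap and width of the ventral slot that close the wall-area and
    volume budgets exactly: 2(w+2b)L = A_rem, 2bwL = V_rem."""
    if area_rem <= 0 or vol_rem <= 0:
        raise ValueError(
            "ventral-slot closure infeasible: fixed segments already exceed the "
            f"morphometric targets (remaining area {area_rem:.3g} m², volume {vol_rem:.3g} m³)"
        )
    disc = area_rem**2 - 16.0 * length * vol_rem
    if disc < 0:
        raise ValueError(
            "ventral-slot closure infeasible: targets imply a negative discriminant "
            f"(area {area_rem:.3g} m², volume {vol_rem:.3g} m³, length {length:.3g} m)"
        )
    halfgap = (area_rem - math.sqrt(disc)) / (8.0 * length)
    width = area_rem / (2.0 * length) - 2.0 * halfgap
    if halfgap <= 0 or width <= 0:
        raise ValueError("ventral-slot closure infeasible: non-positive derived dimension")
    return halfgap, width


def build_nose(spec: SyntheticNoseSpec) -> ChannelNetwork:
    """Build the synthetic nose network for ``spec``.

    Topology: naris -> vestibule -> {ventral slot, DM feed}; DM feed -> Np
    parallel olfactory columns -> collector; {ventral slot, collector} ->
    nasopharynx. The ventral slot dimensions are solved so the network hits
    the morphometric targets; per-column radii carry a small seeded jitter.
    """
    dims = spec.respiratory_path_dimensions
    rng = np.random.default_rng(spec.random_seed)
    npcols = spec.n_parallel_columns
    jit = spec.column_jitter * (2.0 * rng.random(npcols) - 1.0)

    r_nar, l_nar = dims["naris"]
    r_ves, l_ves = dims["vestibule"]
    r_dm, l_dm = dims["dm_feed"]
    r_col_, l_colr = dims["collector"]
    r_nas, l_nas = dims["nasopharynx"]

    x_split = l_nar + l_ves
    x_cols = x_split + l_dm
    x_collect = x_cols + spec.column_length
    x_merge = max(x_collect + l_colr, x_split + spec.ventral_length)

    segs: list[ChannelSegment] = [
        circular_segment("naris", r_nar, l_nar, "respiratory", axial_start=0.0),
        circular_segment(
            "vestibule", r_ves, l_ves, "respiratory", axial_start=l_nar,
            bend_angle=math.radians(60.0), bend_radius=2.5 * r_ves,
        ),
        circular_segment(
            "dm_feed", r_dm, l_dm, "respiratory", axial_start=x_split,
            bend_angle=math.radians(90.0), bend_radius=2.5 * r_dm,
        ),
        circular_segment(
            "collector", r_col_, l_colr, "nonabsorbing", axial_start=x_collect,
            bend_angle=math.radians(90.0), bend_radius=2.5 * r_col_,
        ),
        circular_segment("nasopharynx", r_nas, l_nas, "nonabsorbing", axial_start=x_merge),
    ]
    col_ids = []
    for i in range(npcols):
        r_i = spec.column_radius * (1.0 + jit[i])
        seg = circular_segment(
            f"olf_col_{i:02d}", r_i, spec.column_length, "olfactory", axial_start=x_cols,
            bend_angle=math.radians(45.0), bend_radius=4.0 * r_i,
        )
        segs.append(seg)
        col_ids.append(seg.id)

    area_fixed = sum(s.wall_area for s in segs)
    vol_fixed = sum(s.volume for s in segs)
    area_rem = spec.target_surface_area * 1e-4 - area_fixed  # cm² -> m²
    vol_rem = spec.target_volume * 1e-6 - vol_fixed  # mL -> m³
    halfgap, width = _solve_slot_closure(area_rem, vol_rem, spec.ventral_length)
    segs.append(
        slot_segment(
            "ventral", halfgap, width, spec.ventral_length, "respiratory",
            axial_start=x_split, bend_angle=math.radians(30.0), bend_radius=20.0 * halfgap,
        )
    )

    edges = [
        ("naris", "vestibule"),
        ("vestibule", "ventral"),
        ("vestibule", "dm_feed"),
        ("ventral", "nasopharynx"),
        ("collector", "nasopharynx"),
    ]
    edges += [("dm_feed", c) for c in col_ids]
    edges += [(c, "collector") for c in col_ids]

    return ChannelNetwork(
        segments=tuple(segs),
        edges=tuple(edges),
        inlet_ids=("naris",),
        outlet_ids=("nasopharynx",),
        column_groups={"olfactory_columns": tuple(col_ids)},
    )


def calibrate_to_morphometry(
    network: ChannelNetwork, target_area: float, target_volume: float
) -> ChannelNetwork:
    """Similarity-scale a network onto morphometric targets.

    ``target_area`` in cm², ``target_volume`` in mL. Wall area scales as
    (transverse x axial) and volume as (transverse² x axial), so the
    two-parameter scaling family solves both targets exactly:
    transverse = V_ratio/A_ratio, axial = A_ratio²/V_ratio.
    """
    if not (target_area > 0 and target_volume > 0):
        raise ValueError("morphometric targets must be positive")
    a_ratio = target_area * 1e-4 / network.total_wall_area()
    v_ratio = target_volume * 1e-6 / network.total_volume()
    transverse = v_ratio / a_ratio
    axial = a_ratio**2 / v_ratio
    out = network.scaled(transverse, axial)
    report = {
        "transverse_scale": transverse,
        "axial_scale": axial,
        "achieved_area_cm2": out.total_wall_area() * 1e4,
        "achieved_volume_mL": out.total_volume() * 1e6,
    }
    return replace(out, calibration_report=report)


def epithelium_profile(network: ChannelNetwork, n_bins: int):
    """Wall area per epithelium class binned by distance from the naris tip.

    Each segment's wall area is spread uniformly over its axial extent and
    apportioned to bins by overlap. Returns a pandas DataFrame with columns
    ``bin_start, bin_end, respiratory, olfactory, nonabsorbing, total,
    cumulative_total``.
    """
    import pandas as pd

    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x_max = max(s.axial_start + s.length for s in network.segments)
    bin_edges = np.linspace(0.0, x_max, n_bins + 1)
    acc = {cls: np.zeros(n_bins) for cls in EPITHELIUM_CLASSES}
    for s in network.segments:
        lo, hi = s.axial_start, s.axial_start + s.length
        density = s.wall_area / (hi - lo)
        overlap = np.clip(np.minimum(hi, bin_edges[1:]) - np.maximum(lo, bin_edges[:-1]), 0.0, None)
        acc[s.epithelium] += density * overlap
    total = sum(acc.values())
    return pd.DataFrame(
        {
            "bin_start": bin_edges[:-1],
            "bin_end": bin_edges[1:],
            "respiratory": acc["respiratory"],
            "olfactory": acc["olfactory"],
            "nonabsorbing": acc["nonabsorbing"],
            "total": total,
            "cumulative_total": np.cumsum(total),
        }
    )


def elongated_tube_variant(network: ChannelNetwork, packing: str = "column_length") -> ChannelNetwork:
    """Replace the parallel olfactory columns by one equal-volume tube.

    The amphibian-like "elongated tube" null architecture: a single circular
    olfactory duct carrying the whole DM feed, with airspace volume equal to
    the parallel olfactory region. Packing rules for the free dimension:

    - ``"column_length"`` (default): tube length = mean column path length
      Lc, radius from volume conservation (r_tube = sqrt(Np)*r for identical
      columns).
    - ``"dm_feed"``: tube cross-section continues the DM feed duct
      (radius = DM feed radius), length from volume conservation — the long,
      narrow reading of "elongated".
    """
    if not network.column_groups:
        raise ValueError("network has no olfactory column groups to replace")
    col_ids = [i for ids in network.column_groups.values() for i in ids]
    cols = [network.segment(i) for i in col_ids]
    v_olf = sum(s.volume for s in cols)
    mean_lc = sum(s.length for s in cols) / len(cols)
    x0 = min(s.axial_start for s in cols)

    if packing == "column_length":
        length = mean_lc
        radius = math.sqrt(v_olf / (math.pi * length))
    elif packing == "dm_feed":
        radius = network.segment("dm_feed").radius_or_halfgap
        length = v_olf / (math.pi * radius**2)
    else:
        raise ValueError(f"unknown packing rule {packing!r}")

    tube = circular_segment(
        "olf_tube", radius, length, "olfactory", axial_start=x0,
        bend_angle=math.radians(45.0), bend_radius=4.0 * radius,
    )
    col_set = set(col_ids)
    upstream = sorted({u for u, v in network.edges if v in col_set and u not in col_set})
    downstream = sorted({v for u, v in network.edges if u in col_set and v not in col_set})
    segments = tuple(s for s in network.segments if s.id not in col_set) + (tube,)
    edges = tuple((u, v) for u, v in network.edges if u not in col_set and v not in col_set)
    edges += tuple((u, "olf_tube") for u in upstream)
    edges += tuple(("olf_tube", v) for v in downstream)
    return replace(
        network,
        segments=segments,
        edges=edges,
        column_groups={"olfactory_columns": ("olf_tube",)},
        calibration_report=None,
    )


def write_vtk_centerlines(network: ChannelNetwork, path: str | Path) -> None:
    """Legacy-ASCII VTK polyline export of the network centerlines.

    Coordinates are a schematic layout (x = axial distance from the naris,
    y spreads parallel branches), intended for quick visual inspection only.
    """
    branch_y: dict[str, float] = {}
    parallel: dict[float, list[str]] = {}
    for s in network.segments:
        parallel.setdefault(round(s.axial_start, 9), []).append(s.id)
    for ids in parallel.values():
        n = len(ids)
        for k, sid in enumerate(sorted(ids)):
            branch_y[sid] = (k - (n - 1) / 2.0) * 1e-3
    points: list[tuple[float, float, float]] = []
    lines: list[tuple[int, int]] = []
    for s in network.segments:
        y = branch_y[s.id]
        i0 = len(points)
        points.append((s.axial_start, y, 0.0))
        points.append((s.axial_start + s.length, y, 0.0))
        lines.append((i0, i0 + 1))
    with Path(path).open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nnosegc channel network centerlines\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
        fh.write(f"LINES {len(lines)} {3 * len(lines)}\n")
        for a, b in lines:
            fh.write(f"2 {a} {b}\n")
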