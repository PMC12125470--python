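"""Gas-chromatograph efficiency of olfactory architectures.

The coiled parallel olfactory channels are treated as open-tubular GC
columns: odorant retention on the mucus (stationary phase) combined with
Taylor–Aris-type dispersion in the airstream gives a plate height

    H(u) = B/u + C_tot * u,
    B = 2 D_g,
    C_tot = f_g(k) r²/D_g + f_s(k) d_f²/D_s,

with the Golay mobile- and stationary-phase coefficients

    f_g(k) = (1 + 6k + 11k²) / (24 (1+k)²),
    f_s(k) = 2k / (3 (1+k)²),

and the theoretical plate number N = Lc / H. The optimum velocity and peak
plate number are closed-form: u_opt = sqrt(B/C_tot), H_min = 2 sqrt(B C_tot).

The stationary-film term is implemented but off by default in architecture
comparisons: with a full-thickness mucus film (10 µm) and liquid-phase
diffusivity it dominates C_tot and would place the optimum below every
physiological operating velocity, while the effective film participating in
rapid odorant exchange is poorly constrained. Sensitivity is one flag away.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .flow import NetworkFlow
from .nose import ChannelNetwork
from .odorants import MucosaSpec, Odorant

__all__ = [
    "GCColumnSpec",
    "PlateCurve",
    "retention_factor",
    "golay_plate_height",
    "plate_number_curve",
    "column_from_segment",
    "compare_architectures",
    "velocity_robustness",
]


@dataclass(frozen=True)
class GCColumnSpec:
    """Open-tubular column standing in for one olfactory flow path.

    ``Lc`` is the average distance an odorant travels from olfactory inlet
    to outlet; ``r`` the channel radius (or half-gap via the hydraulic-radius
    mapping); ``d_f`` the stationary mucus film thickness; ``k_ret`` the
    retention factor (stationary/mobile partition of solute amount).
    """

    Lc: float  # m
    r: float  # m
    d_f: float  # m
    D_gas: float  # m²/s
    D_stationary: float  # m²/s
    k_ret: float  # dimensionless
    film_term: bool = False

    def __post_init__(self) -> None:
        for name in ("Lc", "r", "d_f", "D_gas", "D_stationary"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.k_ret < 0:
            raise ValueError("retention factor must be >= 0")
        if not self.d_f < self.r:
            raise ValueError(f"film thickness d_f={self.d_f} must be below the radius r={self.r}")

    # -- Golay coefficients ------------------------------------------------
    @property
    def B(self) -> float:
        """Longitudinal-diffusion coefficient, B = 2 D_g (m²/s)."""
        return 2.0 * self.D_gas

    @property
    def C_tot(self) -> float:
        """Mass-transfer coefficient C (s)."""
        k = self.k_ret
        f_g = (1.0 + 6.0 * k + 11.0 * k**2) / (24.0 * (1.0 + k) ** 2)
        c = f_g * self.r**2 / self.D_gas
        if self.film_term:
            f_s = 2.0 * k / (3.0 * (1.0 + k) ** 2)
            c += f_s * self.d_f**2 / self.D_stationary
        return c

    @property
    def u_opt(self) -> float:
        return math.sqrt(self.B / self.C_tot)

    @property
    def H_min(self) -> float:
        return 2.0 * math.sqrt(self.B * self.C_tot)

    @property
    def N_peak(self) -> float:
        return self.Lc / self.H_min


def retention_factor(odorant: Odorant, r: float, d_f: float) -> float:
    """Retention factor from thin-film geometry and the partition coefficient.

    k = (V_stationary / V_mobile) / beta; for a thin annular film on a
    circular channel, k = 2 d_f / (beta r).
    """
    if not d_f < r:
        raise ValueError(f"film thickness d_f={d_f} must be below the radius r={r}")
    if not (d_f > 0 and r > 0):
        raise ValueError("film thickness and radius must be positive")
    return 2.0 * d_f / (odorant.beta * r)


def golay_plate_height(u: float, column: GCColumnSpec) -> float:
    """Golay plate height H(u) = B/u + C_tot u, metres."""
    if not u > 0:
        raise ValueError(f"carrier velocity must be positive, got {u}")
    return column.B / u + column.C_tot * u


@dataclass(frozen=True)
class PlateCurve:
    """Plate height/number versus carrier velocity for one column."""

    u: np.ndarray  # m/s
    H: np.ndarray  # m
    N: np.ndarray
    u_opt: float
    N_peak: float
    column: GCColumnSpec


def plate_number_curve(column: GCColumnSpec, u_grid) -> PlateCurve:
    """Evaluate N(u) = Lc/H(u); the optimum comes from the closed form."""
    u = np.asarray(u_grid, dtype=float)
    if np.any(u <= 0) or np.any(np.diff(u) <= 0):
        raise ValueError("u_grid must be positive and strictly increasing")
    h = column.B / u + column.C_tot * u
    return PlateCurve(
        u=u, H=h, N=column.Lc / h, u_opt=column.u_opt, N_peak=column.N_peak, column=column
    )


def column_from_segment(
    segment,
    Lc: float,
    odorant: Odorant,
    mucosa: MucosaSpec,
    film_term: bool = False,
) -> GCColumnSpec:
    """Build a column spec from a channel segment and an odorant.

    Non-circular segments map to an equivalent radius via half the hydraulic
    diameter. Retention comes from the mucus film geometry and beta.
    """
    r = segment.hydraulic_diameter / 2.0
    d_f = mucosa.thickness_d
    return GCColumnSpec(
        Lc=Lc,
        r=r,
        d_f=d_f,
        D_gas=odorant.D_a,
        D_stationary=mucosa.mucus_diffusivity(odorant),
        k_ret=retention_factor(odorant, r, d_f),
        film_term=film_term,
    )


def _architecture_entry(
    network: ChannelNetwork,
    flow: NetworkFlow,
    odorant: Odorant,
    mucosa: MucosaSpec,
    film_term: bool,
) -> dict:
    col_ids = [i for ids in network.column_groups.values() for i in ids]
    segs = [network.segment(i) for i in col_ids]
    flows = np.array([flow.flow[i] for i in col_ids])
    vels = np.array([flow.mean_velocity[i] for i in col_ids])
    u_oper = float((flows * vels).sum() / flows.sum())  # flow-weighted mean
    lc = float(np.mean([s.length for s in segs]))
    # representative column: flow-weighted mean radius
    r_mean = float((flows * [s.hydraulic_diameter / 2 for s in segs]).sum() / flows.sum())
    column = GCColumnSpec(
        Lc=lc,
        r=r_mean,
        d_f=mucosa.thickness_d,
        D_gas=odorant.D_a,
        D_stationary=mucosa.mucus_diffusivity(odorant),
        k_ret=retention_factor(odorant, r_mean, mucosa.thickness_d),
        film_term=film_term,
    )
    return {
        "n_columns": len(col_ids),
        "operating_velocity": u_oper,
        "velocity_range": [float(vels.min()), float(vels.max())],
        "u_opt": column.u_opt,
        "N_peak": column.N_peak,
        "N_operating": column.Lc / golay_plate_height(u_oper, column),
        "Lc": lc,
        "r": r_mean,
        "k_ret": column.k_ret,
        "olfactory_volume_m3": float(sum(s.volume for s in segs)),
        "column": column,
    }


def compare_architectures(
    parallel: ChannelNetwork,
    parallel_flow: NetworkFlow,
    tube: ChannelNetwork,
    tube_flow: NetworkFlow,
    odorant: Odorant,
    mucosa: MucosaSpec,
    film_term: bool = False,
) -> dict:
    """Compare the parallel-coil and elongated-tube olfactory architectures.

    Both must share the DM feed flow and the olfactory airspace volume
    (within 1%). Reports, per architecture: operating velocity, u_opt,
    N_peak, N at the operating velocity, and the parallel/tube ratios.
    """
    par = _architecture_entry(parallel, parallel_flow, odorant, mucosa, film_term)
    tub = _architecture_entry(tube, tube_flow, odorant, mucosa, film_term)
    v_par, v_tub = par["olfactory_volume_m3"], tub["olfactory_volume_m3"]
    if abs(v_par - v_tub) > 0.01 * v_par:
        raise ValueError(
            f"olfactory airspace volumes differ by more than 1%: {v_par:.4g} vs {v_tub:.4g} m³"
        )
    report = {
        "parallel": {k: v for k, v in par.items() if k != "column"},
        "tube": {k: v for k, v in tub.items() if k != "column"},
        "ratios": {
            "N_peak_parallel_over_tube": par["N_peak"] / tub["N_peak"],
            "N_operating_parallel_over_tube": par["N_operating"] / tub["N_operating"],
            "operating_velocity_tube_over_parallel": tub["operating_velocity"]
            / par["operating_velocity"],
        },
        "_columns": {"parallel": par["column"], "tube": tub["column"]},
    }
    return report


def comparison_report_json(report: dict) -> str:
    """Structured-text (JSON) rendering of a comparison report."""
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, indent=1)


def velocity_robustness(curve: PlateCurve, fraction: float) -> dict:
    """Velocity band [u1, u2] over which N(u) >= fraction * N_peak.

    For H = B/u + C u the endpoints are roots of C u² - (H_min/fraction) u +
    B = 0, so u1*u2 = B/C = u_opt² exactly; the log-width log(u2/u1) is the
    robustness measure (wider = efficiency less sensitive to velocity).
    """
    if not (0.0 < fraction):
        raise ValueError("fraction must be positive")
    if fraction >= 1.0:
        return {"u1": None, "u2": None, "log_width": 0.0, "empty": True, "fraction": fraction}
    col = curve.column
    b, c = col.B, col.C_tot
    h_max = col.H_min / fraction
    disc = h_max**2 - 4.0 * b * c
    u1 = (h_max - math.sqrt(disc)) / (2.0 * c)
    u2 = (h_max + math.sqrt(disc)) / (2.0 * c)
    return {
        "u1": u1,
        "u2": u2,
        "log_width": math.log(u2 / u1),
        "u1_times_u2": u1 * u2,
        "u_opt_squared": col.u_opt**2,
        "empty": False,
        "fraction": fraction,
    }
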