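"""Odorant physical chemistry.

Diffusivity estimation (Wilke–Chang), the air–mucus partition coefficient
``beta`` and the dimensionless wall-uptake parameter K that together define
how strongly an odorant is absorbed at the air–mucus interface of the nasal
wall.

Conventions
-----------
``beta`` is the *air-side ÷ mucus-side* equilibrium concentration ratio, so a
small ``beta`` means a highly mucus-soluble odorant that is scrubbed quickly
from the airstream.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

log = logging.getLogger(__name__)

__all__ = [
    "Odorant",
    "MucosaSpec",
    "wilke_chang_diffusivity",
    "wall_uptake_parameter",
    "wall_permeability",
    "load_odorant_table",
    "write_odorant_table",
    "default_odorants",
    "WATER_MOLAR_MASS",
    "WATER_ASSOCIATION_FACTOR",
]

#: Molar mass of water, g/mol (Wilke-Chang solvent default).
WATER_MOLAR_MASS = 18.01
#: Wilke-Chang association factor for water.
WATER_ASSOCIATION_FACTOR = 2.6
#: Dynamic viscosity of water at 310 K, cP.
WATER_VISCOSITY_310K_CP = 0.69


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not (value > 0):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class Odorant:
    """Physicochemical record of a single odorant.

    Parameters
    ----------
    name : str
    molar_mass : float
        g/mol.
    molar_volume : float
        Le Bas molar volume at the normal boiling point, cm³/mol.
    D_a : float
        Air-phase diffusivity, m²/s.
    D_m : float
        Mucus-phase diffusivity, m²/s.
    beta : float
        Air–mucus partition coefficient (air ÷ mucus), dimensionless.
    """

    name: str
    molar_mass: float
    molar_volume: float
    D_a: float
    D_m: float
    beta: float

    def __post_init__(self) -> None:
        _require_positive(
            molar_mass=self.molar_mass,
            molar_volume=self.molar_volume,
            D_a=self.D_a,
            D_m=self.D_m,
            beta=self.beta,
        )
        if not self.D_a > self.D_m:
            raise ValueError(
                f"air diffusivity D_a={self.D_a} must exceed mucus diffusivity D_m={self.D_m}"
            )

    def with_beta(self, beta: float) -> "Odorant":
        """Copy of this odorant with a different partition coefficient."""
        return replace(self, beta=beta)


@dataclass(frozen=True)
class MucosaSpec:
    """Mucus layer description and Wilke-Chang solvent inputs.

    ``thickness_d`` is the mucosal layer thickness d; the default 10 µm is an
    order-of-magnitude value for rodent airway mucus.
    """

    thickness_d: float = 10e-6  # m
    D_m_override: float | None = None  # m²/s
    solvent_viscosity: float = WATER_VISCOSITY_310K_CP  # cP
    temperature: float = 310.0  # K
    association_factor: float = WATER_ASSOCIATION_FACTOR
    solvent_molar_mass: float = WATER_MOLAR_MASS  # g/mol

    def __post_init__(self) -> None:
        _require_positive(
            thickness_d=self.thickness_d,
            solvent_viscosity=self.solvent_viscosity,
            temperature=self.temperature,
            association_factor=self.association_factor,
            solvent_molar_mass=self.solvent_molar_mass,
        )

    def mucus_diffusivity(self, odorant: Odorant) -> float:
        """Mucus-phase diffusivity: override, else the odorant's, else Wilke-Chang."""
        if self.D_m_override is not None:
            return self.D_m_override
        return odorant.D_m


def wilke_chang_diffusivity(
    solvent_molar_mass: float,
    association_factor: float,
    temperature: float,
    solvent_viscosity: float,
    solute_molar_volume: float,
) -> float:
    """Wilke–Chang estimate of a dilute-solute liquid diffusivity.

    D = 7.4e-8 * sqrt(phi * M_B) * T / (mu_B * V_A^0.6)   [cm²/s]

    with ``M_B`` the solvent molar mass (g/mol), ``phi`` the solvent
    association factor, ``T`` temperature (K), ``mu_B`` solvent viscosity
    (cP) and ``V_A`` the solute Le Bas molar volume (cm³/mol).

    Returns
    -------
    float
        Diffusivity in m²/s.
    """
    _require_positive(
        solvent_molar_mass=solvent_molar_mass,
        association_factor=association_factor,
        temperature=temperature,
        solvent_viscosity=solvent_viscosity,
        solute_molar_volume=solute_molar_volume,
    )
    d_cm2_s = (
        7.4e-8
        * math.sqrt(association_factor * solvent_molar_mass)
        * temperature
        / (solvent_viscosity * solute_molar_volume**0.6)
    )
    return d_cm2_s * 1e-4  # cm²/s -> m²/s


def wall_permeability(odorant: Odorant, mucosa: MucosaSpec) -> float:
    """Dimensional wall mass-transfer (uptake) coefficient k_w = D_m/(beta*d), m/s.

    This is the Robin-condition coefficient D_a * dC/dn = -k_w * C at the
    air–mucus interface: transport across a mucus film of thickness d with
    equilibrium partitioning beta at the interface.
    """
    d_m = mucosa.mucus_diffusivity(odorant)
    return d_m / (odorant.beta * mucosa.thickness_d)


def wall_uptake_parameter(d_in: float, odorant: Odorant, mucosa: MucosaSpec) -> float:
    """Dimensionless wall-uptake parameter K = d_in * D_m / (D_a * beta * d).

    ``d_in`` is the reference hydraulic diameter (nostril diameter) used to
    nondimensionalize the wall-normal coordinate; the wall condition then
    reads dC'/dy' + K C' = 0.
    """
    _require_positive(d_in=d_in, beta=odorant.beta, thickness_d=mucosa.thickness_d)
    return d_in * wall_permeability(odorant, mucosa) / odorant.D_a


# ---------------------------------------------------------------------------
# Table I/O

_COLUMNS = ["name", "molar_mass", "molar_volume", "D_a", "D_m", "beta"]


def _estimate_air_diffusivity(molar_mass: float, molar_volume: float) -> float:
    """Fuller-type gas-phase diffusivity estimate in air at 310 K, 1 atm (m²/s).

    D_AB [cm²/s] = 1e-3 T^1.75 sqrt(1/M_A + 1/M_air) / (P (V_A^{1/3} + V_air^{1/3})²)
    with the Fuller diffusion volume of air (19.7) and pressure 1 atm.
    """
    t = 310.0
    v_air, m_air = 19.7, 28.97
    d_cm2_s = (
        1e-3
        * t**1.75
        * math.sqrt(1.0 / molar_mass + 1.0 / m_air)
        / ((molar_volume ** (1 / 3) + v_air ** (1 / 3)) ** 2)
    )
    return d_cm2_s * 1e-4


def load_odorant_table(
    path: str | Path, mucosa: MucosaSpec | None = None
) -> tuple[list[Odorant], list[str]]:
    """Read a comma-separated odorant property table.

    Columns: ``name, molar_mass, molar_volume, D_a, D_m, beta``; empty cells
    for ``D_a``/``D_m`` are filled from the Fuller-type gas estimate and the
    Wilke-Chang correlation respectively.

    Returns
    -------
    (odorants, errors)
        ``errors`` holds one human-readable message per rejected row; rows
        failing invariants are rejected, the rest still load.
    """
    mucosa = mucosa or MucosaSpec()
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise ValueError(f"odorant table {path} missing required columns: {missing}")
        odorants: list[Odorant] = []
        errors: list[str] = []
        n_rows = 0
        for i, row in enumerate(reader, start=2):  # line numbers incl. header
            n_rows += 1
            try:
                name = (row["name"] or "").strip()
                molar_mass = float(row["molar_mass"])
                molar_volume = float(row["molar_volume"])
                beta = float(row["beta"])
                d_a = float(row["D_a"]) if (row["D_a"] or "").strip() else _estimate_air_diffusivity(
                    molar_mass, molar_volume
                )
                if (row["D_m"] or "").strip():
                    d_m = float(row["D_m"])
                else:
                    d_m = wilke_chang_diffusivity(
                        mucosa.solvent_molar_mass,
                        mucosa.association_factor,
                        mucosa.temperature,
                        mucosa.solvent_viscosity,
                        molar_volume,
                    )
                odorants.append(
                    Odorant(
                        name=name,
                        molar_mass=molar_mass,
                        molar_volume=molar_volume,
                        D_a=d_a,
                        D_m=d_m,
                        beta=beta,
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"{path.name}:{i}: {exc}")
    if n_rows == 0:
        log.warning("odorant table %s has a header but no data rows", path)
    for msg in errors:
        log.warning("rejected odorant row: %s", msg)
    return odorants, errors


def write_odorant_table(odorants: list[Odorant], path: str | Path) -> None:
    """Write odorants to the comma-separated table format (full precision)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for o in odorants:
            writer.writerow(
                [o.name, repr(o.molar_mass), repr(o.molar_volume), repr(o.D_a), repr(o.D_m), repr(o.beta)]
            )


def default_odorants() -> list[Odorant]:
    """Built-in three-odorant panel spanning the solubility range.

    Methyl benzoate (very mucus-soluble), isoamyl acetate (intermediate) and
    cyclohexane (low solubility). Molar masses/Le Bas volumes are standard
    handbook values; betas are order-of-magnitude air/water partition values.
    """
    mucosa = MucosaSpec()
    rows = [
        # name, M (g/mol), V_LeBas (cm³/mol), beta
        ("Methyl Benzoate", 136.15, 157.2, 1e-6),
        ("Isoamyl Acetate", 130.19, 163.4, 1e-4),
        ("Cyclohexane", 84.16, 118.2, 1e-1),
    ]
    out = []
    for name, m, v, beta in rows:
        d_m = wilke_chang_diffusivity(
            mucosa.solvent_molar_mass,
            mucosa.association_factor,
            mucosa.temperature,
            mucosa.solvent_viscosity,
            v,
        )
        out.append(
            Odorant(
                name=name,
                molar_mass=m,
                molar_volume=v,
                D_a=_estimate_air_diffusivity(m, v),
                D_m=d_m,
                beta=beta,
            )
        )
    return out
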