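"""Deterministic calculators: nanoparticle-uptake bookkeeping and oxygen
partial-pressure conversion.

Uptake arithmetic converts an ICP-MS gadolinium mass into particle counts
and uptake fractions for gadolinium-chelate nanoparticles (nominally 10 Gd
atoms per particle, from the 1 mmol/L Gd == 0.1 mmol/L particle
equivalence). The gadolinium molar mass is fixed at 157.25 g/mol.

Oxygen readings convert between mmHg and percent of a reference
(atmospheric) pressure, 760 mmHg by default; the reference is configurable
because incubator calibrations sometimes imply a slightly different one.
"""

from __future__ import annotations

from dataclasses import dataclass

M_GD_G_PER_MOL = 157.25
AVOGADRO = 6.02214076e23

__all__ = [
    "M_GD_G_PER_MOL",
    "AVOGADRO",
    "UptakeRecord",
    "OxygenReading",
    "np_count_from_gd_mass",
    "uptake_fraction",
    "per_cell_load",
    "mmHg_to_percent",
    "percent_to_mmHg",
    "uptake_record",
]


@dataclass
class UptakeRecord:
    """All derived uptake quantities for one sample, inputs echoed."""

    gd_mass_ug: float
    gd_per_np: float
    np_count: float
    gd_mol: float
    incubation_volume_ul: float | None = None
    incubation_conc_mmol_l: float | None = None
    uptake_percent: float | None = None
    n_cells: int | None = None
    gd_mol_per_cell: float | None = None


@dataclass
class OxygenReading:
    """A pO2 value in both mmHg and percent of the reference pressure."""

    po2_mmHg: float
    po2_percent: float
    atm_mmHg: float = 760.0


def gd_mol_from_mass(gd_mass_ug: float) -> float:
    """Moles of Gd in ``gd_mass_ug`` micrograms."""
    if gd_mass_ug < 0:
        raise ValueError("gd_mass_ug must be non-negative")
    return gd_mass_ug * 1e-6 / M_GD_G_PER_MOL


def np_count_from_gd_mass(gd_mass_ug: float, gd_per_np: float = 10.0) -> float:
    """Number of nanoparticles carrying ``gd_mass_ug`` µg of gadolinium.

    count = (mass / M_Gd) / gd_per_np * N_A. Linear in mass, inversely
    linear in the per-particle stoichiometry.
    """
    if gd_per_np <= 0:
        raise ValueError("gd_per_np must be positive")
    return gd_mol_from_mass(gd_mass_ug) / gd_per_np * AVOGADRO


def uptake_fraction(
    gd_mass_ug: float, incubation_volume_ul: float, incubation_conc_mmol_l: float
) -> float:
    """Percent of the incubated gadolinium recovered in the sample.

    100 * (moles recovered) / (incubation volume x concentration), with the
    volume in µl and the Gd concentration in mmol/L.
    """
    if incubation_volume_ul <= 0 or incubation_conc_mmol_l <= 0:
        raise ValueError("incubation volume and concentration must be positive")
    incubated_mol = incubation_volume_ul * 1e-6 * incubation_conc_mmol_l * 1e-3
    return 100.0 * gd_mol_from_mass(gd_mass_ug) / incubated_mol


def per_cell_load(gd_mass_ug: float, n_cells: int) -> float:
    """Average gadolinium amount per cell, in mol/cell."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return gd_mol_from_mass(gd_mass_ug) / n_cells


def uptake_record(
    gd_mass_ug: float,
    gd_per_np: float = 10.0,
    incubation_volume_ul: float | None = None,
    incubation_conc_mmol_l: float | None = None,
    n_cells: int | None = None,
) -> UptakeRecord:
    """Compute every uptake quantity derivable from the given inputs."""
    rec = UptakeRecord(
        gd_mass_ug=gd_mass_ug,
        gd_per_np=gd_per_np,
        np_count=np_count_from_gd_mass(gd_mass_ug, gd_per_np),
        gd_mol=gd_mol_from_mass(gd_mass_ug),
        incubation_volume_ul=incubation_volume_ul,
        incubation_conc_mmol_l=incubation_conc_mmol_l,
        n_cells=n_cells,
    )
    if incubation_volume_ul is not None and incubation_conc_mmol_l is not None:
        rec.uptake_percent = uptake_fraction(
            gd_mass_ug, incubation_volume_ul, incubation_conc_mmol_l
        )
    if n_cells is not None:
        rec.gd_mol_per_cell = per_cell_load(gd_mass_ug, n_cells)
    return rec


def mmHg_to_percent(po2_mmHg: float, atm_mmHg: float = 760.0) -> float:
    """Oxygen partial pressure as percent of the reference pressure."""
    if atm_mmHg <= 0:
        raise ValueError("reference pressure must be positive")
    return 100.0 * po2_mmHg / atm_mmHg


def percent_to_mmHg(po2_percent: float, atm_mmHg: float = 760.0) -> float:
    """Inverse of :func:`mmHg_to_percent`; the roundtrip is exact."""
    if atm_mmHg <= 0:
        raise ValueError("reference pressure must be positive")
    return po2_percent * atm_mmHg / 100.0
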