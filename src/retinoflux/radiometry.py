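"""Scintillation-count (DPM) to molar amount/concentration conversions.

Unit policy: DPM and Ci for radioactivity, mol for amounts, uM for
concentrations, L for volumes, um for cell geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DPM_PER_CI",
    "TracerSpec",
    "CellGeometry",
    "CountRecord",
    "cell_volume",
    "dpm_to_total_amount",
    "amount_to_dpm",
    "cellular_concentration",
    "chamber_concentration",
    "teer_area_corrected",
]

#: disintegrations per minute in one curie
DPM_PER_CI = 2.22e12


@dataclass(frozen=True)
class TracerSpec:
    """Radiochemical constants of a labeled analyte.

    ``specific_activity`` is in Ci per mmol of the *labeled* compound;
    ``labeled_fraction`` is the fraction of total analyte carrying the label
    (default 0.05, i.e. 5% hot).
    """

    specific_activity: float = 30.0
    labeled_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.specific_activity > 0:
            raise ValueError("specific_activity must be > 0")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CellGeometry:
    """Per-cell volume model: a cell is area x height; n_cells per well/insert."""

    area: float = 402.0  # um^2
    height: float = 3.4  # um
    n_cells: int = 0

    def __post_init__(self) -> None:
        if self.area < 0 or self.height < 0:
            raise ValueError("area and height must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass(frozen=True)
class CountRecord:
    """One scintillation reading."""

    dpm: float
    channel: str = "H3"  # "H3" or "C14"
    compartment: str = "lysate"  # apical | basolateral | lysate
    time: float = 0.0  # minutes

    def __post_init__(self) -> None:
        if self.dpm < 0:
            raise ValueError("dpm must be >= 0")


def cell_volume(geometry: CellGeometry) -> float:
    """Single-cell volume in litres (area um^2 x height um; 1 um^3 = 1e-15 L)."""
    return geometry.area * geometry.height * 1e-15


def dpm_to_total_amount(dpm: float, tracer: TracerSpec) -> float:
    """Total analyte amount (mol) represented by a DPM reading.

    labeled mmol = dpm / (DPM_PER_CI x specific_activity); the total scales
    up by the inverse labeled fraction.
    """
    if dpm < 0:
        raise ValueError("dpm must be >= 0")
    labeled_mmol = dpm / (DPM_PER_CI * tracer.specific_activity)
    return labeled_mmol * 1e-3 / tracer.labeled_fraction


def amount_to_dpm(amount_mol: float, tracer: TracerSpec) -> float:
    """Inverse of :func:`dpm_to_total_amount` (used by the simulator)."""
    if amount_mol < 0:
        raise ValueError("amount must be >= 0")
    labeled_mmol = amount_mol * 1e3 * tracer.labeled_fraction
    return labeled_mmol * DPM_PER_CI * tracer.specific_activity


def cellular_concentration(
    dpm: float, tracer: TracerSpec, geometry: CellGeometry
) -> float:
    """Accumulated cellular concentration (uM) from a lysate DPM reading."""
    if geometry.n_cells <= 0:
        raise ValueError("n_cells must be > 0 to compute a cellular concentration")
    volume = geometry.n_cells * cell_volume(geometry)
    if volume <= 0:
        raise ValueError("total cell volume is zero")
    return dpm_to_total_amount(dpm, tracer) / volume * 1e6


def chamber_concentration(dpm: float, tracer: TracerSpec, volume: float) -> float:
    """Chamber-fluid concentration (uM) from a DPM reading over ``volume`` litres."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return dpm_to_total_amount(dpm, tracer) / volume * 1e6


def teer_area_corrected(resistance: float, area: float = 1.12) -> float:
    """Area-corrected transendothelial resistance, Ohm x cm^2."""
    if resistance < 0 or area < 0:
        raise ValueError("resistance and area must be >= 0")
    return resistance * area
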