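"""Transwell apparent-permeability analysis.

Pe_app = slope(Q vs t) / (A * C0), where Q(t) is the cumulative analyte
amount that has crossed into the basolateral chamber, corrected for the
amounts withdrawn (and volume-replaced) by earlier samples.

Unit policy: concentrations uM (= umol/L), volumes L, times min, membrane
area cm^2; Pe_app is reported in cm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TranswellGeometry",
    "TranswellAssay",
    "PermeabilityResult",
    "MassBalanceResult",
    "cumulative_basolateral_amount",
    "apparent_permeability",
    "mass_balance",
    "normalize_basolateral",
]

#: umol/min per (cm/s * cm^2 * uM): 60 s/min * 1e-3 L/cm^3
_CM_PER_S_TO_L_PER_MIN = 60.0 * 1e-3


@dataclass(frozen=True)
class TranswellGeometry:
    """Two-chamber insert geometry; defaults match a 12-well format insert."""

    membrane_area: float = 1.12  # cm^2
    apical_volume: float = 5.5e-4  # L
    basolateral_volume: float = 1.5e-3  # L
    sample_volume: float = 5.0e-5  # L per basolateral draw
    apical_sample_volume: float = 5.0e-5  # L per apical draw (not replaced)

    def __post_init__(self) -> None:
        for name in ("membrane_area", "apical_volume", "basolateral_volume", "sample_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.sample_volume >= self.basolateral_volume:
            raise ValueError("sample_volume must be smaller than basolateral_volume")


@dataclass
class TranswellAssay:
    """Measured (or simulated) concentration series for one channel/replicate.

    Basolateral draws are replaced with equal buffer volume; apical draws are
    not.  ``lysate_amount`` is the end-point analyte amount in the cell
    monolayer, umol (``None`` when not collected).
    """

    geometry: TranswellGeometry
    baso_times: np.ndarray  # min
    baso_conc: np.ndarray  # uM, measured before each draw
    apical_times: np.ndarray  # min (typically 0 and 60)
    apical_conc: np.ndarray  # uM
    lysate_amount: float | None = None  # umol
    channel: str = "H3"
    replicate: int = 0

    def __post_init__(self) -> None:
        self.baso_times = np.asarray(self.baso_times, dtype=float)
        self.baso_conc = np.asarray(self.baso_conc, dtype=float)
        self.apical_times = np.asarray(self.apical_times, dtype=float)
        self.apical_conc = np.asarray(self.apical_conc, dtype=float)
        if self.baso_times.shape != self.baso_conc.shape:
            raise ValueError("basolateral times/concentrations must align")
        if self.apical_times.shape != self.apical_conc.shape:
            raise ValueError("apical times/concentrations must align")
        if np.any(np.diff(self.baso_times) <= 0):
            raise ValueError("basolateral times must be strictly increasing")

    @property
    def c0(self) -> float:
        """Apical reference concentration: the t=0 apical measurement."""
        if self.apical_times.size and self.apical_times[0] == 0.0:
            return float(self.apical_conc[0])
        raise ValueError("no t=0 apical measurement; supply a nominal C0 explicitly")


@dataclass(frozen=True)
class PermeabilityResult:
    pe_app: float  # cm/s
    slope: float  # umol/min
    c0: float  # uM
    r_squared: float
    channel: str = "H3"
    window: tuple = (None, None)


@dataclass(frozen=True)
class MassBalanceResult:
    fraction_recovered: float
    apical_end: float  # umol, incl. withdrawn apical samples
    basolateral_cumulative: float  # umol
    lysate: float  # umol
    initial: float  # umol loaded apically
    channel: str = "H3"

    @property
    def components(self) -> dict:
        return {
            "apical_end_umol": self.apical_end,
            "basolateral_cumulative_umol": self.basolateral_cumulative,
            "lysate_umol": self.lysate,
        }


def cumulative_basolateral_amount(
    times: np.ndarray,
    conc: np.ndarray,
    geometry: TranswellGeometry,
    sample_volume: float | None = None,
) -> np.ndarray:
    """Sampling-corrected cumulative basolateral amount Q(t), umol.

    Q(t_k) = C_k * V_b + sum_{j<k} C_j * v_s : the chamber content at the
    k-th draw plus the analyte withdrawn by all earlier draws (each of which
    was volume-replaced with fresh buffer).
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    v_s = geometry.sample_volume if sample_volume is None else sample_volume
    if v_s >= geometry.basolateral_volume:
        raise ValueError("sample volume must be smaller than the chamber volume")
    withdrawn = np.concatenate(([0.0], np.cumsum(conc[:-1] * v_s)))
    return conc * geometry.basolateral_volume + withdrawn


def apparent_permeability(
    times: np.ndarray,
    q: np.ndarray,
    c0: float,
    area: float = 1.12,
    window: tuple | None = None,
    channel: str = "H3",
) -> PermeabilityResult:
    """OLS slope of Q(t) over the regression window, converted to Pe_app cm/s.

    The default window excludes t=0 (short lag before linear accumulation)
    and uses all later points.  ``window=(lo, hi)`` restricts to
    lo <= t <= hi; pass ``window=(0, None)`` to include t=0.
    """
    times = np.asarray(times, dtype=float)
    q = np.asarray(q, dtype=float)
    if not c0 > 0:
        raise ValueError("c0 must be > 0")
    if not area > 0:
        raise ValueError("area must be > 0")
    if window is None:
        mask = times > 0
        lo, hi = None, None
    else:
        lo, hi = window
        mask = np.ones_like(times, dtype=bool)
        if lo is not None:
            mask &= times >= lo
        if hi is not None:
            mask &= times <= hi
    t_w, q_w = times[mask], q[mask]
    if t_w.size < 3:
        raise ValueError(f"regression window contains {t_w.size} points; need >= 3")
    res = stats.linregress(t_w, q_w)
    slope = float(res.slope)  # umol/min
    pe = slope / (area * c0) / _CM_PER_S_TO_L_PER_MIN  # -> cm/s
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return PermeabilityResult(
        pe_app=max(pe, 0.0) if abs(pe) < 1e-30 else pe,
        slope=slope,
        c0=c0,
        r_squared=min(max(r2, 0.0), 1.0),
        channel=channel,
        window=(lo, hi),
    )


def mass_balance(assay: TranswellAssay) -> MassBalanceResult:
    """Fraction of the initially loaded analyte recovered at assay end.

    recovered = (apical chamber at end + apical sample withdrawals)
                + sampling-corrected cumulative basolateral amount
                + monolayer lysate,
    all divided by C0 * initial apical volume.  Apical draws shrink the
    apical volume (no replacement); their contents count as recovered.
    """
    missing = []
    if assay.apical_times.size < 2:
        missing.append("end-point apical sample")
    if assay.baso_times.size == 0:
        missing.append("basolateral series")
    if assay.lysate_amount is None:
        missing.append("lysate")
    if missing:
        raise ValueError("mass balance needs: " + ", ".join(missing))

    g = assay.geometry
    initial = assay.c0 * g.apical_volume  # umol
    if initial <= 0:
        raise ValueError("initial apical load is zero")

    # apical draws before the final one reduce the chamber volume
    n_prior = assay.apical_times.size - 1
    v_end = g.apical_volume - n_prior * g.apical_sample_volume
    if v_end <= 0:
        raise ValueError("apical sampling exceeds the apical volume")
    apical_end = float(assay.apical_conc[-1]) * v_end
    apical_withdrawn = float(np.sum(assay.apical_conc[:-1])) * g.apical_sample_volume

    q = cumulative_basolateral_amount(assay.baso_times, assay.baso_conc, g)
    lysate = float(assay.lysate_amount)
    recovered = apical_end + apical_withdrawn + float(q[-1]) + lysate
    return MassBalanceResult(
        fraction_recovered=recovered / initial,
        apical_end=apical_end + apical_withdrawn,
        basolateral_cumulative=float(q[-1]),
        lysate=lysate,
        initial=initial,
        channel=assay.channel,
    )


def normalize_basolateral(series: np.ndarray, reference: float) -> np.ndarray:
    """Element-wise division of a basolateral series by a positive reference
    (apical C0 or the accumulated cellular concentration)."""
    if not reference > 0:
        raise ValueError("reference must be > 0")
    return np.asarray(series, dtype=float) / reference
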