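"""Mass-action equilibrium speciation of retinol (ROH) among its serum carriers.

Total ROH, RBP and TTR are distributed over five species,

    ROH + RBP        <-> ROH-RBP         (dissociation constant ``kd_roh_rbp``)
    ROH-RBP + TTR    <-> ROH-RBP-TTR     (dissociation constant ``kd_holo_ttr``)

with TTR binding only the holo (ROH-loaded) form of RBP.  The coupled
equilibria reduce to a single monotone scalar residual in free ROH which is
solved by safeguarded bracketing; no randomness is involved.

All concentrations are in micromolar (uM).  A dissociation constant of
``math.inf`` abolishes the corresponding complex, which is how the
non-binding mutant carriers (muRBP towards TTR, muTTR towards holo-RBP)
are represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "EquilibriumSystem",
    "SpeciationState",
    "solve_binary",
    "solve_ternary",
    "fraction_free",
]

#: variants map onto how the holo-RBP <-> TTR equilibrium is treated:
#: both mutants abolish RBP-TTR complexation, nothing else.
VARIANTS = ("wt", "muRBP", "muTTR")


@dataclass(frozen=True)
class EquilibriumSystem:
    """Total concentrations and dissociation constants of one speciation problem.

    Parameters
    ----------
    total_roh, total_rbp, total_ttr
        Total (free + complexed) concentrations, uM.
    kd_roh_rbp
        Dissociation constant of the ROH:RBP complex, uM.
    kd_holo_ttr
        Dissociation constant of the holo-RBP:TTR complex, uM.  ``math.inf``
        abolishes ternary complex formation (mutant carriers).
    """

    total_roh: float
    total_rbp: float
    total_ttr: float
    kd_roh_rbp: float = 0.1
    kd_holo_ttr: float = 0.25

    def __post_init__(self) -> None:
        for name in ("total_roh", "total_rbp", "total_ttr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("kd_roh_rbp", "kd_holo_ttr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def from_config(cls, config: dict) -> "EquilibriumSystem":
        """Build a system from a JSON-style config block.

        Recognised keys: ``total_roh_uM``, ``total_rbp_uM``, ``total_ttr_uM``,
        ``kd_roh_rbp_uM``, ``kd_holo_ttr_uM`` and optionally
        ``variant`` in ``{"wt", "muRBP", "muTTR"}``.
        """
        variant = config.get("variant", "wt")
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        kd_holo_ttr = float(config.get("kd_holo_ttr_uM", 0.25))
        if variant in ("muRBP", "muTTR"):
            kd_holo_ttr = math.inf
        return cls(
            total_roh=float(config["total_roh_uM"]),
            total_rbp=float(config["total_rbp_uM"]),
            total_ttr=float(config.get("total_ttr_uM", 0.0)),
            kd_roh_rbp=float(config.get("kd_roh_rbp_uM", 0.1)),
            kd_holo_ttr=kd_holo_ttr,
        )


@dataclass(frozen=True)
class SpeciationState:
    """Solved five-species distribution, all concentrations in uM."""

    free_roh: float
    apo_rbp: float
    holo_rbp: float
    free_ttr: float
    ternary: float
    system: EquilibriumSystem = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "free_roh_uM": self.free_roh,
            "apo_rbp_uM": self.apo_rbp,
            "holo_rbp_uM": self.holo_rbp,
            "free_ttr_uM": self.free_ttr,
            "ternary_uM": self.ternary,
        }

    def residuals(self) -> dict:
        """Mass-balance and mass-action residuals (diagnostics)."""
        s = self.system
        out = {
            "roh_balance": self.free_roh + self.holo_rbp + self.ternary - s.total_roh,
            "rbp_balance": self.apo_rbp + self.holo_rbp + self.ternary - s.total_rbp,
            "ttr_balance": self.free_ttr + self.ternary - s.total_ttr,
        }
        if self.holo_rbp > 0:
            out["kd_roh_rbp"] = (
                self.free_roh * self.apo_rbp / self.holo_rbp - s.kd_roh_rbp
            )
        if self.ternary > 0 and math.isfinite(s.kd_holo_ttr):
            out["kd_holo_ttr"] = (
                self.holo_rbp * self.free_ttr / self.ternary - s.kd_holo_ttr
            )
        return out


def solve_binary(
    total_ligand: float, total_protein: float, kd: float
) -> tuple[float, float]:
    """Closed-form 1:1 binding equilibrium.

    Returns ``(free, bound)`` ligand concentrations, the physically valid
    root of the binding quadratic.
    """
    if total_ligand < 0 or total_protein < 0:
        raise ValueError("totals must be >= 0")
    if not kd > 0:
        raise ValueError("kd must be > 0")
    if math.isinf(kd):
        return total_ligand, 0.0
    s = total_ligand + total_protein + kd
    disc = s * s - 4.0 * total_ligand * total_protein
    # smaller quadratic root in its cancellation-free form
    bound = 2.0 * total_ligand * total_protein / (s + math.sqrt(max(disc, 0.0)))
    bound = min(max(bound, 0.0), total_ligand, total_protein)
    return total_ligand - bound, bound


def _protein_species(
    free_roh: float, system: EquilibriumSystem
) -> tuple[float, float, float, float]:
    """Protein species (apo_rbp, holo_rbp, free_ttr, ternary) at a trial free ROH.

    With free ROH ``R`` fixed, the RBP balance closes through a quadratic in
    apo-RBP ``B``:  writing a = R/K1 and c = R/(K1*K2),

        c(1+a) B^2 + [(1+a) + c(T_tot - B_tot)] B - B_tot = 0.
    """
    r = free_roh
    k1 = system.kd_roh_rbp
    b_tot, t_tot = system.total_rbp, system.total_ttr
    a = r / k1
    if math.isinf(system.kd_holo_ttr) or t_tot == 0.0:
        b = b_tot / (1.0 + a)
        return b, a * b, t_tot, 0.0
    c = r / (k1 * system.kd_holo_ttr)
    qa = c * (1.0 + a)
    qb = (1.0 + a) + c * (t_tot - b_tot)
    if qa == 0.0:  # r == 0: no complexes at all
        return b_tot, 0.0, t_tot, 0.0
    b = (-qb + math.sqrt(qb * qb + 4.0 * qa * b_tot)) / (2.0 * qa)
    b = max(b, 0.0)
    holo = a * b
    ttr = t_tot / (1.0 + holo / system.kd_holo_ttr)
    ternary = holo * ttr / system.kd_holo_ttr
    return b, holo, ttr, ternary


def solve_ternary(system: EquilibriumSystem) -> SpeciationState:
    """Solve the coupled ROH/RBP/TTR equilibria.

    The ROH balance residual ``g(R) = R + holo(R) + ternary(R) - total_roh``
    is strictly increasing in the free ROH concentration ``R``, so the root
    is bracketed on ``[0, total_roh]`` and polished with Brent's method to
    an absolute tolerance well below 1e-12 uM.

    Reduces exactly to :func:`solve_binary` when ``total_ttr == 0`` or the
    holo-RBP:TTR dissociation constant is infinite.
    """
    r_tot = system.total_roh
    if r_tot == 0.0:
        return SpeciationState(
            free_roh=0.0,
            apo_rbp=system.total_rbp,
            holo_rbp=0.0,
            free_ttr=system.total_ttr,
            ternary=0.0,
            system=system,
        )

    def residual(r: float) -> float:
        _, holo, _, ternary = _protein_species(r, system)
        return r + holo + ternary - r_tot

    lo, hi = 0.0, r_tot
    if residual(hi) < -1e-9 * max(r_tot, 1.0):  # pragma: no cover - defensive
        raise ArithmeticError(
            f"speciation residual does not bracket a root: g({hi}) = {residual(hi)}"
        )
    free = brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    apo, holo, ttr, ternary = _protein_species(free, system)
    state = SpeciationState(
        free_roh=free,
        apo_rbp=apo,
        holo_rbp=holo,
        free_ttr=ttr,
        ternary=ternary,
        system=system,
    )
    bad = {k: v for k, v in state.residuals().items() if abs(v) > 1e-6 * max(r_tot, 1.0)}
    if bad:  # pragma: no cover - defensive
        raise ArithmeticError(f"speciation solver failed to converge: residuals {bad}")
    return state


def fraction_free(state: SpeciationState, total_roh: float | None = None) -> float:
    """Percent of total ROH that is unbound."""
    if total_roh is None:
        total_roh = state.system.total_roh
    if not total_roh > 0:
        raise ValueError("total_roh must be > 0")
    return 100.0 * state.free_roh / total_roh
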