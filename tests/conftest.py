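"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from retinoflux import EquilibriumSystem, KineticParams, Timecourse, predict_biphasic


def bisect_binary_oracle(total_ligand, total_protein, kd, tol=1e-12):
    """Independent 1:1 binding oracle: bisection on the scalar residual
    f(b) = (L - b)(P - b) - kd*b, monotone decreasing on [0, min(L, P)]."""
    lo, hi = 0.0, min(total_ligand, total_protein)
    if hi == 0.0:
        return total_ligand, 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (total_ligand - mid) * (total_protein - mid) - kd * mid > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    bound = 0.5 * (lo + hi)
    return total_ligand - bound, bound


def bisect_ternary_oracle(system: EquilibriumSystem, tol=1e-9):
    """Independent coupled-equilibria oracle: nested bisections only.

    Inner loop solves the RBP balance for apo-RBP at fixed free ROH; outer
    loop bisects the ROH balance in free ROH.  No closed forms shared with
    the implementation under test.
    """
    k1, k2 = system.kd_roh_rbp, system.kd_holo_ttr
    r_tot, b_tot, t_tot = system.total_roh, system.total_rbp, system.total_ttr

    def species_at(r):
        # bisect apo-RBP: residual b + holo + ternary - b_tot is increasing in b
        lo, hi = 0.0, b_tot
        for _ in range(80):
            b = 0.5 * (lo + hi)
            holo = r * b / k1
            if np.isinf(k2) or t_tot == 0.0:
                ternary, ttr = 0.0, t_tot
            else:
                ttr = t_tot / (1.0 + holo / k2)
                ternary = holo * ttr / k2
            if b + holo + ternary - b_tot < 0:
                lo = b
            else:
                hi = b
        return b, holo, ttr, ternary

    lo, hi = 0.0, r_tot
    for _ in range(100):  # run to machine precision; derived species amplify R error
        r = 0.5 * (lo + hi)
        _, holo, _, ternary = species_at(r)
        if r + holo + ternary - r_tot < 0:
            lo = r
        else:
            hi = r
    r = 0.5 * (lo + hi)
    apo, holo, ttr, ternary = species_at(r)
    return {"free_roh": r, "apo_rbp": apo, "holo_rbp": holo,
            "free_ttr": ttr, "ternary": ternary}


@pytest.fixture
def study_params() -> KineticParams:
    """Biphasic parameters in the regime of the fitted accumulation curves."""
    return KineticParams(kp=90.0, k1=0.02, kp_star=70.0, k1_star=0.01, ccell_star=36.0)


@pytest.fixture
def five_min_grid() -> np.ndarray:
    """5-min sampling over 2 h, first draw at 5 min."""
    return np.arange(5.0, 125.0, 5.0)


@pytest.fixture
def noiseless_timecourses(study_params, five_min_grid) -> list[Timecourse]:
    return [
        Timecourse(cf=cf, times=five_min_grid,
                   ccell=predict_biphasic(study_params, cf, five_min_grid))
        for cf in (0.1, 0.4, 2.0)
    ]
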