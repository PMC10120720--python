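"""Seeded synthetic-data generation for every pipeline stage.

Two forward models are provided:

* accumulation time courses following the biphasic uptake model on a
  5-minute grid (replicated, optional counting noise), and
* a three-compartment Transwell transfer model (apical -> cell ->
  basolateral for the transcellular analyte, direct apical -> basolateral
  for the paracellular control) integrated with a fixed-step RK4 scheme,
  with sampling events that withdraw volume (basolateral draws replaced,
  apical draws not).  Total mass is conserved exactly before noise.

The cell compartment uses a lumped first-order exchange (surface-clearance
influx, first-order transfer to the basolateral side, optional efflux back
to the apical chamber) — a deliberately simple stand-in that reproduces the
short basolateral lag.

Noise models: ``none``, ``gaussian_cv`` (multiplicative, truncated at 0) and
``poisson_counts`` (Poisson on the DPM a scintillation counter would read
for each measured aliquot, converted back through the tracer spec).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import KineticParams, Timecourse, predict_biphasic
from .permeability import TranswellAssay, TranswellGeometry
from .radiometry import CellGeometry, TracerSpec, amount_to_dpm, cell_volume, dpm_to_total_amount
from .speciation import EquilibriumSystem

__all__ = [
    "AccumulationBlock",
    "ChannelSpec",
    "TranswellBlock",
    "SimulationConfig",
    "simulate_accumulation",
    "simulate_transwell",
    "random_equilibrium_systems",
]

NOISE_MODELS = ("none", "gaussian_cv", "poisson_counts")


@dataclass(frozen=True)
class AccumulationBlock:
    """Forward-model settings for accumulation time courses.

    Defaults follow the assay layout: 0.1/0.4/2 uM fluid concentrations
    sampled every 5 min over 2 h in triplicate.
    """

    params: KineticParams = KineticParams(
        kp=90.0, k1=0.02, kp_star=70.0, k1_star=0.01, ccell_star=36.0
    )
    cf_values: tuple = (0.1, 0.4, 2.0)
    times: tuple = tuple(float(t) for t in range(5, 125, 5))
    n_replicates: int = 3


@dataclass(frozen=True)
class ChannelSpec:
    """One tracer channel of the Transwell simulator.

    ``route='paracellular'`` sends a direct apical->basolateral flux
    Pe*A*(C_a - C_b); ``route='transcellular'`` interposes the cell
    compartment: influx Pe*A*C_a, first-order transfer ``k_cb`` to the
    basolateral chamber and optional efflux ``k_ca`` back to the apical one.
    """

    name: str = "H3"
    c0: float = 2.0  # uM loaded apically
    pe: float = 4.8e-6  # cm/s, apical-side clearance
    route: str = "transcellular"
    k_cb: float = 0.05  # 1/min, cell -> basolateral
    k_ca: float = 0.0  # 1/min, cell -> apical efflux

    def __post_init__(self) -> None:
        if self.route not in ("transcellular", "paracellular"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.c0 < 0 or self.pe < 0 or self.k_cb < 0 or self.k_ca < 0:
            raise ValueError("channel parameters must be >= 0")


@dataclass(frozen=True)
class TranswellBlock:
    geometry: TranswellGeometry = TranswellGeometry()
    channels: tuple = (
        ChannelSpec(name="H3", c0=2.0, pe=4.8e-6, route="transcellular"),
        ChannelSpec(name="C14", c0=2.0, pe=0.6e-6, route="paracellular"),
    )
    baso_times: tuple = (0.0, 15.0, 30.0, 45.0, 60.0)
    apical_times: tuple = (0.0, 60.0)
    duration: float = 60.0  # min
    n_replicates: int = 1
    dt: float = 0.1  # min, RK4 step


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    noise_model: str = "none"
    noise_scale: float = 0.0  # CV for gaussian_cv; unused for poisson_counts
    accumulation: AccumulationBlock = AccumulationBlock()
    transwell: TranswellBlock = TranswellBlock()
    tracer: TracerSpec = TracerSpec()
    cell_geometry: CellGeometry = CellGeometry(n_cells=100_000)

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def _apply_conc_noise(
    conc: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    volume_l: float,
) -> np.ndarray:
    """Noise a concentration array in place of the measurement process.

    ``volume_l`` is the fluid volume each reading integrates over (aliquot or
    lysed cell volume), needed to express the reading as DPM for Poisson noise.
    """
    if config.noise_model == "none":
        return conc
    if config.noise_model == "gaussian_cv":
        noisy = conc * (1.0 + config.noise_scale * rng.standard_normal(conc.shape))
        return np.maximum(noisy, 0.0)
    # poisson_counts: uM -> mol in the counted volume -> DPM -> Poisson -> back
    amount_mol = conc * 1e-6 * volume_l
    dpm = np.vectorize(lambda a: amount_to_dpm(a, config.tracer))(amount_mol)
    dpm_noisy = rng.poisson(dpm).astype(float)
    back = np.vectorize(lambda d: dpm_to_total_amount(d, config.tracer))(dpm_noisy)
    return back / (1e-6 * volume_l)


def simulate_accumulation(config: SimulationConfig) -> list[Timecourse]:
    """Generate accumulation time courses from the biphasic forward model."""
    rng = np.random.default_rng(config.seed)
    block = config.accumulation
    v_cells = config.cell_geometry.n_cells * cell_volume(config.cell_geometry)
    out = []
    for cf in block.cf_values:
        times = np.asarray(block.times, dtype=float)
        clean = predict_biphasic(block.params, cf, times)
        ccell = np.tile(clean[:, None], (1, block.n_replicates))
        ccell = _apply_conc_noise(ccell, config, rng, max(v_cells, 1e-30))
        out.append(Timecourse(cf=cf, times=times, ccell=ccell, label="free"))
    return out


def timecourses_to_frame(timecourses: list[Timecourse]):
    """Long-format DataFrame in the CSV schema the fitting stage reads."""
    import pandas as pd

    rows = []
    for tc in timecourses:
        for j in range(tc.n_replicates):
            for i, t in enumerate(tc.times):
                rows.append(
                    {
                        "time_min": t,
                        "replicate": j,
                        "ccell_uM": tc.ccell[i, j],
                        "label": tc.label,
                        "cf_uM": tc.cf,
                    }
                )
    return pd.DataFrame(rows)


def _channel_derivative(spec: ChannelSpec, geom: TranswellGeometry, state, v_a):
    """d/dt of (apical, cell, basolateral) amounts, umol/min."""
    n_a, n_c, n_b = state
    c_a = n_a / v_a  # umol / L = uM
    c_b = n_b / geom.basolateral_volume  # uM
    clearance = spec.pe * 60.0 * 1e-3 * geom.membrane_area  # L/min
    if spec.route == "paracellular":
        j_ab = clearance * (c_a - c_b)  # umol/min
        return np.array([-j_ab, 0.0, j_ab])
    j_ac = clearance * c_a
    j_cb = spec.k_cb * n_c
    j_ca = spec.k_ca * n_c
    return np.array([-j_ac + j_ca, j_ac - j_ca - j_cb, j_cb])


def _integrate_channel(
    spec: ChannelSpec, block: TranswellBlock
) -> tuple[np.ndarray, np.ndarray, float, list]:
    """RK4 integration with exact handling of sampling events.

    Returns (baso_conc at draws, apical_conc at apical draws, lysate umol,
    event log).  Concentrations are recorded *before* each withdrawal.
    """
    geom = block.geometry
    events = sorted(
        {(float(t), "baso") for t in block.baso_times}
        | {(float(t), "apical") for t in block.apical_times}
    )
    if events and events[-1][0] > block.duration:
        raise ValueError("sampling schedule exceeds assay duration")

    v_a = geom.apical_volume
    state = np.array([spec.c0 * v_a, 0.0, 0.0])  # umol
    t_now = 0.0
    baso_read, apical_read = {}, {}

    def advance(t_to: float):
        nonlocal state, t_now
        while t_now < t_to - 1e-12:
            h = min(block.dt, t_to - t_now)
            k1 = _channel_derivative(spec, geom, state, v_a)
            k2 = _channel_derivative(spec, geom, state + 0.5 * h * k1, v_a)
            k3 = _channel_derivative(spec, geom, state + 0.5 * h * k2, v_a)
            k4 = _channel_derivative(spec, geom, state + h * k3, v_a)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t_now += h

    log = []
    for t_ev, kind in events:
        advance(t_ev)
        if kind == "baso":
            c_b = state[2] / geom.basolateral_volume
            baso_read[t_ev] = c_b
            state[2] -= c_b * geom.sample_volume  # replaced with fresh buffer
            log.append({"t": t_ev, "event": "baso_draw", "conc_uM": c_b})
        else:
            c_a = state[0] / v_a
            apical_read[t_ev] = c_a
            is_final = t_ev >= block.duration - 1e-12
            if not is_final:  # final apical read does not shrink the chamber
                state[0] -= c_a * geom.apical_sample_volume
                v_a -= geom.apical_sample_volume
            log.append({"t": t_ev, "event": "apical_draw", "conc_uM": c_a})
    advance(block.duration)
    lysate = float(state[1])
    baso = np.array([baso_read[float(t)] for t in block.baso_times])
    apical = np.array([apical_read[float(t)] for t in block.apical_times])
    return baso, apical, lysate, log


def simulate_transwell(config: SimulationConfig) -> dict:
    """Simulate the dual-tracer Transwell assay.

    Returns ``{(channel_name, replicate): TranswellAssay}``.  Replicates share
    the deterministic forward trajectory and differ only through noise.
    """
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from accumulation
    block = config.transwell
    geom = block.geometry
    out = {}
    for spec in block.channels:
        baso, apical, lysate, _ = _integrate_channel(spec, block)
        for rep in range(block.n_replicates):
            b = _apply_conc_noise(baso.copy(), config, rng, geom.sample_volume)
            a = _apply_conc_noise(apical.copy(), config, rng, geom.apical_sample_volume)
            lys = lysate
            if config.noise_model == "gaussian_cv":
                lys = max(lysate * (1.0 + config.noise_scale * rng.standard_normal()), 0.0)
            elif config.noise_model == "poisson_counts":
                dpm = amount_to_dpm(lysate * 1e-6, config.tracer)
                lys = dpm_to_total_amount(float(rng.poisson(dpm)), config.tracer) * 1e6
            out[(spec.name, rep)] = TranswellAssay(
                geometry=geom,
                baso_times=np.asarray(block.baso_times, dtype=float),
                baso_conc=b,
                apical_times=np.asarray(block.apical_times, dtype=float),
                apical_conc=a,
                lysate_amount=lys,
                channel=spec.name,
                replicate=rep,
            )
    return out


def random_equilibrium_systems(
    n: int,
    seed: int = 0,
    total_range: tuple = (0.01, 10.0),
    kd_range: tuple = (0.01, 1.0),
) -> list[EquilibriumSystem]:
    """Reproducible random speciation problems for oracle testing.

    Log-uniform draws over the stated ranges; the first draws are forced to
    the degenerate edges (no TTR, no RBP) so they are always exercised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def logu(lo, hi, size=None):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    systems = []
    for i in range(n):
        roh, rbp, ttr = logu(*total_range, 3)
        kd1, kd2 = logu(*kd_range, 2)
        if i == 0:
            ttr = 0.0
        elif i == 1:
            rbp = 0.0
        systems.append(
            EquilibriumSystem(
                total_roh=float(roh),
                total_rbp=float(rbp),
                total_ttr=float(ttr),
                kd_roh_rbp=float(kd1),
                kd_holo_ttr=float(kd2),
            )
        )
    return systems
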