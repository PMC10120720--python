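"""End-to-end pipeline: speciation -> simulate (or load) -> fit -> permeability -> report.

Unit policy (stated in every output header): concentrations uM, time min,
volume L, Pe cm/s.  Outputs are written atomically (temp file + rename)
together with a manifest recording seed, versions and per-file SHA256.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io import write_timecourses, write_transwell_assays
from .kinetics import compare_models, fit_accumulation
from .permeability import apparent_permeability, cumulative_basolateral_amount, mass_balance
from .speciation import EquilibriumSystem, fraction_free, solve_ternary
from .synthetic import SimulationConfig, simulate_accumulation, simulate_transwell

__all__ = ["PipelineConfig", "run_pipeline", "speciation_table", "DEFAULT_CONDITIONS"]

UNIT_POLICY = {"concentration": "uM", "time": "min", "volume": "L", "pe": "cm/s"}

#: delivery-mode conditions of the study design (totals in uM)
DEFAULT_CONDITIONS = (
    {"delivery_mode": "free", "total_roh_uM": 0.1, "total_rbp_uM": 0, "total_ttr_uM": 0},
    {"delivery_mode": "free", "total_roh_uM": 0.4, "total_rbp_uM": 0, "total_ttr_uM": 0},
    {"delivery_mode": "free", "total_roh_uM": 2, "total_rbp_uM": 0, "total_ttr_uM": 0},
    {"delivery_mode": "ROH-RBP", "total_roh_uM": 2, "total_rbp_uM": 2, "total_ttr_uM": 0},
    {"delivery_mode": "ROH-muRBP", "total_roh_uM": 2, "total_rbp_uM": 2, "total_ttr_uM": 0,
     "variant": "muRBP"},
    {"delivery_mode": "ROH-RBP-TTR", "total_roh_uM": 2, "total_rbp_uM": 2, "total_ttr_uM": 4},
    {"delivery_mode": "ROH-RBP-muTTR", "total_roh_uM": 2, "total_rbp_uM": 2, "total_ttr_uM": 4,
     "variant": "muTTR"},
)


@dataclass
class PipelineConfig:
    seed: int = 0
    alpha: float = 0.05
    out_dir: str = "results"
    speciation_conditions: tuple = DEFAULT_CONDITIONS
    kd_roh_rbp: float = 0.1
    kd_holo_ttr: float = 0.25
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fit_n_starts: int = 6
    run_speciation: bool = True
    run_accumulation: bool = True
    run_permeability: bool = True

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            cfg.simulation = SimulationConfig(
                seed=sim.get("seed", cfg.seed),
                noise_model=sim.get("noise_model", "none"),
                noise_scale=sim.get("noise_scale", 0.0),
            )
        return cfg


def speciation_table(
    conditions=DEFAULT_CONDITIONS, kd_roh_rbp: float = 0.1, kd_holo_ttr: float = 0.25
) -> list[dict]:
    """Delivery-mode speciation table, values rounded to 2 decimals at output."""
    rows = []
    for cond in conditions:
        cfg = dict(cond)
        cfg.setdefault("kd_roh_rbp_uM", kd_roh_rbp)
        cfg.setdefault("kd_holo_ttr_uM", kd_holo_ttr)
        system = EquilibriumSystem.from_config(cfg)
        state = solve_ternary(system)
        rows.append(
            {
                "delivery_mode": cond.get("delivery_mode", "custom"),
                "total_roh_uM": system.total_roh,
                "free_roh_uM": round(state.free_roh, 4),
                "roh_rbp_uM": round(state.holo_rbp, 4),
                "roh_rbp_ttr_uM": round(state.ternary, 4),
                "percent_free": round(fraction_free(state), 1)
                if system.total_roh > 0
                else None,
            }
        )
    return rows


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage on synthetic data and write report + manifest.

    Returns the report dict.  Any stage failure propagates after the partial
    manifest is written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "units": UNIT_POLICY,
        "seed": config.seed,
        "version": __version__,
    }
    manifest: dict = {"seed": config.seed, "version": __version__, "files": {}}

    sim = SimulationConfig(
        seed=config.seed,
        noise_model=config.simulation.noise_model,
        noise_scale=config.simulation.noise_scale,
        accumulation=config.simulation.accumulation,
        transwell=config.simulation.transwell,
        tracer=config.simulation.tracer,
        cell_geometry=config.simulation.cell_geometry,
    )

    try:
        if config.run_speciation:
            report["speciation"] = speciation_table(
                config.speciation_conditions, config.kd_roh_rbp, config.kd_holo_ttr
            )

        if config.run_accumulation:
            tcs = simulate_accumulation(sim)
            write_timecourses(tcs, out_dir / "accumulation.csv")
            manifest["files"]["accumulation.csv"] = _sha256(out_dir / "accumulation.csv")
            fit_mono = fit_accumulation(tcs, "monophasic", n_starts=config.fit_n_starts,
                                        seed=config.seed)
            fit_bi = fit_accumulation(tcs, "biphasic", n_starts=config.fit_n_starts,
                                      seed=config.seed)
            cmp_res = compare_models(fit_mono, fit_bi, alpha=config.alpha)
            report["accumulation_fit"] = {
                "monophasic": {"kp": fit_mono.params.kp, "k1": fit_mono.params.k1,
                               "sse": fit_mono.sse},
                "biphasic": {
                    "kp": fit_bi.params.kp, "k1": fit_bi.params.k1,
                    "kp_star": fit_bi.params.kp_star, "k1_star": fit_bi.params.k1_star,
                    "ccell_star": fit_bi.params.ccell_star, "sse": fit_bi.sse,
                },
                "comparison": {
                    "f_statistic": cmp_res.f_statistic,
                    "p_value": cmp_res.p_value,
                    "delta_aic": cmp_res.delta_aic,
                    "preferred": cmp_res.preferred,
                },
            }

        if config.run_permeability:
            assays = simulate_transwell(sim)
            write_transwell_assays(assays, out_dir / "transwell.csv")
            manifest["files"]["transwell.csv"] = _sha256(out_dir / "transwell.csv")
            pe_rows, mb_rows = [], []
            for (channel, rep), assay in sorted(assays.items()):
                q = cumulative_basolateral_amount(
                    assay.baso_times, assay.baso_conc, assay.geometry
                )
                pe = apparent_permeability(
                    assay.baso_times, q, assay.c0,
                    area=assay.geometry.membrane_area, channel=channel,
                )
                pe_rows.append({"channel": channel, "replicate": rep,
                                "pe_app_cm_s": pe.pe_app, "r_squared": pe.r_squared})
                mb = mass_balance(assay)
                mb_rows.append({"channel": channel, "replicate": rep,
                                "fraction_recovered": mb.fraction_recovered})
            summary = {}
            for channel in {r["channel"] for r in pe_rows}:
                vals = [r["pe_app_cm_s"] for r in pe_rows if r["channel"] == channel]
                summary[channel] = {"mean": float(np.mean(vals)),
                                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
            report["permeability"] = {"per_assay": pe_rows, "summary": summary}
            report["mass_balance"] = mb_rows
    finally:
        _atomic_write(out_dir / "manifest.json",
                      json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    text = json.dumps(report, indent=2, sort_keys=True) + "\n"
    _atomic_write(out_dir / "report.json", text)
    manifest["files"]["report.json"] = _sha256(out_dir / "report.json")
    _atomic_write(out_dir / "manifest.json",
                  json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
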