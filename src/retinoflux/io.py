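"""CSV/JSON readers and writers for the assay schemas.

CSV dialect: comma-separated, header row required, UTF-8, '.' decimal.
Time-course schema: ``time_min, replicate, ccell_uM, label, cf_uM``
(``dpm`` instead of ``ccell_uM`` is accepted when a tracer and cell geometry
are supplied).  Transwell schema: ``time_min, compartment, channel,
replicate, conc_uM`` with lysate rows carrying ``amount_umol``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import Timecourse
from .permeability import TranswellAssay, TranswellGeometry
from .radiometry import CellGeometry, TracerSpec, cellular_concentration, chamber_concentration

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_transwell_assays",
    "write_transwell_assays",
    "load_json",
    "dump_json",
]


def load_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_timecourses(
    path,
    tracer: TracerSpec | None = None,
    cell_geometry: CellGeometry | None = None,
) -> list[Timecourse]:
    """Load accumulation time courses from the long-format CSV schema."""
    df = pd.read_csv(path)
    if "ccell_uM" not in df.columns:
        if "dpm" not in df.columns:
            raise ValueError("need a ccell_uM or dpm column")
        if tracer is None or cell_geometry is None:
            raise ValueError("dpm input requires tracer and cell_geometry")
        df["ccell_uM"] = [
            cellular_concentration(d, tracer, cell_geometry) for d in df["dpm"]
        ]
    if "label" not in df.columns:
        df["label"] = "free"
    out = []
    for (label, cf), grp in df.groupby(["label", "cf_uM"], sort=True):
        wide = grp.pivot_table(index="time_min", columns="replicate", values="ccell_uM")
        out.append(
            Timecourse(
                cf=float(cf),
                times=wide.index.to_numpy(dtype=float),
                ccell=wide.to_numpy(dtype=float),
                label=str(label),
            )
        )
    return out


def write_timecourses(timecourses: list[Timecourse], path) -> None:
    from .synthetic import timecourses_to_frame

    timecourses_to_frame(timecourses).to_csv(path, index=False)


def read_transwell_assays(
    path,
    geometry: TranswellGeometry | None = None,
    tracer: TracerSpec | None = None,
) -> dict:
    """Load Transwell assays keyed by ``(channel, replicate)``."""
    geometry = geometry or TranswellGeometry()
    df = pd.read_csv(path)
    if "conc_uM" not in df.columns:
        if "dpm" not in df.columns:
            raise ValueError("need a conc_uM or dpm column")
        if tracer is None:
            raise ValueError("dpm input requires a tracer spec")
        vol = {"apical": geometry.apical_sample_volume, "basolateral": geometry.sample_volume}
        df["conc_uM"] = [
            chamber_concentration(d, tracer, vol.get(c, geometry.sample_volume))
            for d, c in zip(df["dpm"], df["compartment"])
        ]
    out = {}
    for (channel, rep), grp in df.groupby(["channel", "replicate"], sort=True):
        baso = grp[grp.compartment == "basolateral"].sort_values("time_min")
        apical = grp[grp.compartment == "apical"].sort_values("time_min")
        lysate_rows = grp[grp.compartment == "lysate"]
        lysate = None
        if len(lysate_rows):
            if "amount_umol" in lysate_rows.columns and lysate_rows["amount_umol"].notna().any():
                lysate = float(lysate_rows["amount_umol"].dropna().iloc[0])
            else:
                lysate = float(lysate_rows["conc_uM"].iloc[0])
        out[(str(channel), int(rep))] = TranswellAssay(
            geometry=geometry,
            baso_times=baso["time_min"].to_numpy(dtype=float),
            baso_conc=baso["conc_uM"].to_numpy(dtype=float),
            apical_times=apical["time_min"].to_numpy(dtype=float),
            apical_conc=apical["conc_uM"].to_numpy(dtype=float),
            lysate_amount=lysate,
            channel=str(channel),
            replicate=int(rep),
        )
    return out


def write_transwell_assays(assays: dict, path) -> None:
    rows = []
    for (channel, rep), assay in assays.items():
        for t, c in zip(assay.baso_times, assay.baso_conc):
            rows.append(
                {"time_min": t, "compartment": "basolateral", "channel": channel,
                 "replicate": rep, "conc_uM": c, "amount_umol": np.nan}
            )
        for t, c in zip(assay.apical_times, assay.apical_conc):
            rows.append(
                {"time_min": t, "compartment": "apical", "channel": channel,
                 "replicate": rep, "conc_uM": c, "amount_umol": np.nan}
            )
        if assay.lysate_amount is not None:
            rows.append(
                {"time_min": assay.baso_times[-1], "compartment": "lysate",
                 "channel": channel, "replicate": rep, "conc_uM": np.nan,
                 "amount_umol": assay.lysate_amount}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
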