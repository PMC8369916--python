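"""CSV/JSON readers and writers for the pipeline's tabular schemas.

Schemas (all plain text):

* concentration-response: ``cell_id, construct, compound, role,
  concentration_molar, response, co_agonist, co_agonist_molar``
* current trace: ``time_ms, current_pA`` plus a JSON sidecar with
  ``capacitance_pF, application_start_ms, application_end_ms, mode,
  holding_mV, sampling_khz``
* plate assay: ``experiment_id, construct, well, condition, time_min, od486``
* potentiation pairs: ``cell_id, condition, i_before_nA, i_after_nA``

Synthetic datasets additionally get a ground-truth JSON sidecar recording
their generating parameters, for test harnesses and provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import ConcentrationSeries
from .kinetics import ApplicationProtocol, CurrentTrace
from .open_probability import PotentiationPair
from .surface_expression import PlateAssay, WellSeries

__all__ = [
    "write_crc_csv", "read_crc_csv",
    "write_trace", "read_trace",
    "write_plate_csv", "read_plate_csv",
    "write_pairs_csv", "read_pairs_csv",
    "write_ground_truth",
]


def write_crc_csv(series_list: Sequence[ConcentrationSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for c, r in zip(s.concentration, s.response):
            rows.append({
                "cell_id": s.cell_id, "construct": s.construct,
                "compound": s.compound, "role": s.role,
                "concentration_molar": c, "response": r,
                "co_agonist": s.co_agonist, "co_agonist_molar": s.co_agonist_molar,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_crc_csv(path: str | Path) -> list[ConcentrationSeries]:
    df = pd.read_csv(path)
    out = []
    for (cell, compound), g in df.groupby(["cell_id", "compound"], sort=True):
        g = g.sort_values("concentration_molar")
        co = g["co_agonist"].iloc[0]
        co_m = g["co_agonist_molar"].iloc[0]
        out.append(ConcentrationSeries(
            cell_id=str(cell),
            construct=str(g["construct"].iloc[0]),
            compound=str(compound),
            role=str(g["role"].iloc[0]),
            concentration=g["concentration_molar"].to_numpy(float),
            response=g["response"].to_numpy(float),
            co_agonist=None if pd.isna(co) else str(co),
            co_agonist_molar=None if pd.isna(co_m) else float(co_m),
        ))
    return out


def write_trace(trace: CurrentTrace, csv_path: str | Path) -> None:
    """Write a trace CSV and its protocol JSON sidecar (same stem, .json)."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_ms": trace.time_ms, "current_pA": trace.current_pA}).to_csv(
        csv_path, index=False
    )
    sidecar = dataclasses.asdict(trace.protocol)
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trace(csv_path: str | Path) -> CurrentTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    protocol = ApplicationProtocol(**meta)
    return CurrentTrace(
        time_ms=df["time_ms"].to_numpy(float),
        current_pA=df["current_pA"].to_numpy(float),
        protocol=protocol,
    )


def write_plate_csv(assays: Sequence[PlateAssay], path: str | Path) -> None:
    rows = []
    for a in assays:
        for w in a.wells:
            for t, od in zip(w.time_min, w.od486):
                rows.append({
                    "experiment_id": a.experiment_id, "construct": a.construct,
                    "well": w.well, "condition": w.condition,
                    "time_min": t, "od486": od,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> list[PlateAssay]:
    df = pd.read_csv(path)
    out = []
    for (exp, construct), g in df.groupby(["experiment_id", "construct"], sort=True):
        wells = []
        for well, wg in g.groupby("well", sort=True):
            wg = wg.sort_values("time_min")
            wells.append(WellSeries(
                time_min=wg["time_min"].to_numpy(float),
                od486=wg["od486"].to_numpy(float),
                well=str(well),
                condition=str(wg["condition"].iloc[0]),
            ))
        out.append(PlateAssay(wells=wells, construct=str(construct),
                              experiment_id=str(exp)))
    return out


def write_pairs_csv(pairs: Sequence[PotentiationPair], path: str | Path) -> None:
    pd.DataFrame([
        {"cell_id": p.cell_id, "condition": p.condition,
         "i_before_nA": p.i_before, "i_after_nA": p.i_after}
        for p in pairs
    ]).to_csv(path, index=False)


def read_pairs_csv(path: str | Path) -> list[PotentiationPair]:
    df = pd.read_csv(path)
    return [
        PotentiationPair(i_before=float(r.i_before_nA), i_after=float(r.i_after_nA),
                         cell_id=str(r.cell_id), condition=str(r.condition))
        for r in df.itertuples()
    ]


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Ground-truth JSON sidecar for a synthetic dataset."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True, default=default))
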