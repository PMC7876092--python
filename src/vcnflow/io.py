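"""Readers and writers for the package's plain-text interchange formats.

CSV is the canonical interchange: event tables (one row per event, one column
per channel), ground-truth sidecars, Ct replicate tables, and JSON reports.
Channel-name mapping from instrument exports is applied at read time.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import StructuralError
from .gating import SIGNAL, EventTable
from .qpcr import CtMeasurement
from .synthetic import CellGroundTruth

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_ground_truth",
    "write_ground_truth",
    "read_ct_table",
    "write_json",
]

_CENSORED_TOKENS = {"", "undetermined", "censored", "na", "nan"}


def read_event_table(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    label: str | None = None,
    require: tuple[str, ...] = (SIGNAL,),
) -> EventTable:
    """Load an event table from CSV.

    ``channel_map`` renames instrument columns to canonical channel names
    (e.g. ``{"FL1-A": "signal"}``).  Columns named ``event_id`` are treated
    as an index, not a channel.  Raises a structural error naming any
    required channel that is missing after mapping.
    """
    path = Path(path)
    if path.suffix.lower() not in {".csv", ".txt", ".tsv"}:
        raise StructuralError(
            f"unsupported event-table format {path.suffix!r}; CSV expected"
        )
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    data = pd.read_csv(path, sep=sep)
    if channel_map:
        data = data.rename(columns=dict(channel_map))
    if "event_id" in data.columns:
        data = data.drop(columns="event_id")
    missing = [c for c in require if c not in data.columns]
    if missing:
        raise StructuralError(
            f"{path}: missing channel(s) {missing}; found {list(data.columns)}"
        )
    return EventTable(data, label=label if label is not None else path.stem)


def write_event_table(events: EventTable, path: str | Path) -> Path:
    """Write an event table to CSV with an explicit event_id column."""
    path = Path(path)
    out = events.data.copy()
    out.insert(0, "event_id", np.arange(len(out)))
    out.to_csv(path, index=False)
    return path


def write_ground_truth(truth: CellGroundTruth, path: str | Path) -> Path:
    """Sidecar CSV with per-cell true copy counts."""
    path = Path(path)
    pd.DataFrame(
        {"event_id": np.arange(truth.n_cells), "copies": truth.copies}
    ).to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> CellGroundTruth:
    data = pd.read_csv(path)
    if "copies" not in data.columns:
        raise StructuralError(f"{path}: missing 'copies' column")
    return CellGroundTruth(data["copies"].to_numpy())


def read_ct_table(path: str | Path) -> dict[tuple[str, str], CtMeasurement]:
    """Load a Ct replicate table keyed by (sample, target).

    Expected columns: ``sample``, ``target``, ``ct`` and optionally
    ``replicate`` and ``efficiency``.  A blank or "Undetermined" ct marks a
    censored replicate; a measurement is censored when all of its replicates
    are.
    """
    data = pd.read_csv(Path(path), dtype={"ct": str})
    for col in ("sample", "target", "ct"):
        if col not in data.columns:
            raise StructuralError(f"{path}: missing column {col!r}")
    out: dict[tuple[str, str], CtMeasurement] = {}
    for (sample, target), group in data.groupby(["sample", "target"], sort=False):
        cts = []
        for raw in group["ct"]:
            token = str(raw).strip().lower()
            if token in _CENSORED_TOKENS:
                continue
            cts.append(float(raw))
        eff = 2.0
        if "efficiency" in group.columns and group["efficiency"].notna().any():
            eff = float(group["efficiency"].dropna().iloc[0])
        if cts:
            meas = CtMeasurement(target=str(target), replicates=tuple(cts), efficiency=eff)
        else:
            meas = CtMeasurement(target=str(target), censored=True, efficiency=eff)
        out[(str(sample), str(target))] = meas
    return out


def write_json(payload: dict, path: str | Path) -> Path:
    """Write a JSON document deterministically (sorted keys, fixed layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
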