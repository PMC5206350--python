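"""Readers and writers for the pipeline's comma-separated tables.

No domain-standard format exists for ruler-based phytomer observations,
so the column names of the plain CSV tables are part of the public
contract.  Reading validates types and value ranges; writing and
re-reading is lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TableValidationError",
    "read_observations",
    "read_dissection",
    "read_truth",
    "write_table",
    "write_config_echo",
]

OBSERVATION_COLUMNS = {
    "treatment": str,
    "tiller_id": str,
    "day": int,
    "rank": int,
    "distance": float,
    "reference_ligule_rank": int,
}
DISSECTION_COLUMNS = {
    "treatment": str,
    "tiller_id": str,
    "rank": int,
    "blade": float,
    "sheath": float,
    "internode": float,
    "phytomer_length": float,
    "maturity": str,
}
TRUTH_COLUMNS = {
    "treatment": str,
    "tiller_id": str,
    "rank": int,
    "final_length": float,
    "initiation_day": float,
    "true_emergence_day": float,
    "true_cessation_day": float,
}


class TableValidationError(ValueError):
    """A table violates the schema (missing columns, bad values)."""


def _read(path, required: dict, nullable: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing required columns {missing}")
    for col, typ in required.items():
        if col not in nullable and df[col].isna().any():
            bad = int(df[col].isna().idxmax())
            raise TableValidationError(f"{path}: missing value in {col!r} at row {bad}")
        if typ in (int, float):
            try:
                df[col] = df[col].astype(float if typ is float else int)
            except (TypeError, ValueError) as exc:
                raise TableValidationError(f"{path}: column {col!r}: {exc}") from None
    return df


def read_observations(path, resolution: float = 0.5) -> pd.DataFrame:
    """Read and validate a daily tip-to-ligule distance table."""
    df = _read(path, OBSERVATION_COLUMNS)
    neg = df.index[df["distance"] < 0]
    if len(neg):
        raise TableValidationError(
            f"{path}: negative distance at row {int(neg[0])}"
        )
    off = np.abs(np.round(df["distance"] / resolution) * resolution - df["distance"])
    if (off > 1e-9).any():
        row = int(off.idxmax())
        logger.warning(
            "%s: distance %.3f at row %d is off the %.1f mm grid",
            path,
            df.loc[row, "distance"],
            row,
            resolution,
        )
    return df


def read_dissection(path) -> pd.DataFrame:
    """Read and validate a dissection (component lengths) table."""
    df = _read(path, DISSECTION_COLUMNS)
    for col in ("blade", "sheath", "internode", "phytomer_length"):
        neg = df.index[df[col] < 0]
        if len(neg):
            raise TableValidationError(f"{path}: negative {col} at row {int(neg[0])}")
    bad = ~df["maturity"].isin(["mature", "immature"])
    if bad.any():
        raise TableValidationError(
            f"{path}: maturity must be mature/immature at row {int(bad.idxmax())}"
        )
    return df


def read_truth(path) -> pd.DataFrame:
    """Read a generator ground-truth table.

    Apex phytomers that never emerged within the simulated range carry a
    missing emergence day.
    """
    return _read(path, TRUTH_COLUMNS, nullable=("true_emergence_day",))


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_config_echo(config, path) -> Path:
    """Serialize the run configuration next to its outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = asdict(config) if is_dataclass(config) else dict(config)
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
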