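"""Measurement CSV reading, calibration-model JSON, run configuration.

The measurement CSV dialect is fixed (comma separator, point decimal,
UTF-8, header row) to avoid locale ambiguity: one row per leaf with
columns species_code, plant_id, leaf_id, I0_before, I0_after, Itr_1..Itr_4
(Itr_3/Itr_4 may be blank for the two-point protocol), fresh_mass_mg,
dry_mass_mg, leaf_area_cm2 (optional), image_path (optional). Rows that
violate physical invariants are rejected individually with row-numbered
messages; the rest of the file still loads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibrate import CalibrationModel
from .core import LeafRecord, TransmissionRecord, tau_from_transmission
from .errors import LeafTHzError, MeasurementFormatError

__all__ = [
    "RunConfig",
    "ReadResult",
    "read_measurements",
    "save_model",
    "load_model",
    "file_digest",
]


REQUIRED_COLUMNS = [
    "species_code", "leaf_id", "I0_before", "I0_after", "Itr_1", "Itr_2",
    "fresh_mass_mg", "dry_mass_mg",
]
OPTIONAL_COLUMNS = ["plant_id", "Itr_3", "Itr_4", "leaf_area_cm2", "image_path"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis-wide settings: test level, interval coverage, paths."""

    alpha_level: float = 0.05
    confidence: float = 0.95
    species_file: str | None = None
    output_dir: str = "."
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")


@dataclass
class ReadResult:
    """Validated records plus per-row rejection messages."""

    records: list[tuple[LeafRecord, TransmissionRecord]]
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.errors


def _parse_float(row, col: str, row_number: int) -> float:
    raw = row[col]
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise MeasurementFormatError(
            f"row {row_number}, column {col!r}: cannot parse {raw!r} as a number"
        ) from None


def read_measurements(path, tau_method: str = "pooled", strict_protocol: bool = False) -> ReadResult:
    """Parse a measurement CSV into (LeafRecord, TransmissionRecord) pairs.

    Optical depth is computed per leaf (intensities pooled before the log
    by default) and stored on the LeafRecord. Blank Itr_3/Itr_4 yield the
    two-point protocol. Missing required columns raise
    MeasurementFormatError; individual bad rows are collected in
    ``result.errors`` as (row_number, message), numbering rows from 2
    (row 1 is the header).
    """
    try:
        df = pd.read_csv(path, dtype=str, encoding="utf-8")
    except Exception as exc:  # malformed file as a whole
        raise MeasurementFormatError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementFormatError(f"missing required column(s): {', '.join(missing)}")
    records: list[tuple[LeafRecord, TransmissionRecord]] = []
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        row_number = int(idx) + 2
        try:
            itr = []
            for col in ("Itr_1", "Itr_2", "Itr_3", "Itr_4"):
                if col in df.columns and isinstance(row[col], str) and row[col].strip():
                    itr.append(_parse_float(row, col, row_number))
            trans = TransmissionRecord(
                I0_before=_parse_float(row, "I0_before", row_number),
                I0_after=_parse_float(row, "I0_after", row_number),
                I_tr_points=tuple(itr),
            )
            la = None
            if "leaf_area_cm2" in df.columns and isinstance(row["leaf_area_cm2"], str) and row["leaf_area_cm2"].strip():
                la = _parse_float(row, "leaf_area_cm2", row_number)
            leaf = LeafRecord(
                species_code=str(row["species_code"]),
                leaf_id=str(row["leaf_id"]),
                fresh_mass=_parse_float(row, "fresh_mass_mg", row_number),
                dry_mass=_parse_float(row, "dry_mass_mg", row_number),
                leaf_area=la,
                plant_id=str(row["plant_id"]) if "plant_id" in df.columns else None,
                image_path=(
                    str(row["image_path"])
                    if "image_path" in df.columns
                    and isinstance(row["image_path"], str)
                    and row["image_path"].strip()
                    else None
                ),
            )
            if strict_protocol:
                from .core import validate_protocol

                validate_protocol(leaf.species_code, trans.n_points, strict=True)
            leaf.tau = tau_from_transmission(trans, method=tau_method)
            records.append((leaf, trans))
        except (LeafTHzError, ValueError) as exc:
            errors.append((row_number, str(exc)))
    return ReadResult(records=records, errors=errors)


def file_digest(path) -> str:
    """SHA-256 hex digest of a file's bytes (input provenance for models)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def save_model(model: CalibrationModel, path, metadata: dict | None = None) -> None:
    """Write a fitted calibration as deterministic, sorted-key JSON."""
    payload = {
        "model": dataclasses.asdict(model),
        "metadata": metadata or {},
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )


def load_model(path) -> tuple[CalibrationModel, dict]:
    """Read a calibration model written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return CalibrationModel(**payload["model"]), payload.get("metadata", {})
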