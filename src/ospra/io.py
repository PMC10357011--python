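"""CSV persistence for calibration tables and measurement records.

Two files mirror the instrument app's data model:

``calibration_data.csv``
    one row per unit: ``unit_id``, wavelength polynomial ``wl_c0..wl_c5``,
    linearisation ``lin_a``/``lin_b`` and the per-photosite sensitivity
    blocks ``sr_0..`` (radiance) and ``si_0..`` (irradiance).

``data.csv`` (append-only)
    one row per measurement: metadata, then per-photosite wavelength
    (``wl_*``), calibrated value (``val_*``) and raw dark-subtracted count
    (``raw_*``) blocks.  Raw counts make every row re-calibratable.

All floats are serialised with ``repr``, i.e. the shortest string that
round-trips bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np

from .acquisition import CountSpectrum
from .radiometry import CalibratedSpectrum, CalibrationRecord, counts_to_spectrum

__all__ = [
    "read_calibration",
    "write_calibration",
    "lookup_unit",
    "append_measurement",
    "read_measurements",
    "recalibrate",
]

_MEAS_META = (
    "unit_id",
    "label",
    "timestamp",
    "mode",
    "integration_ms",
    "n_scans",
    "n_saturated",
)


def _fmt(x) -> str:
    return repr(float(x)) if isinstance(x, (float, np.floating)) else str(x)


# ---------------------------------------------------------------- calibration


def _calib_header(n: int, extra_cols: Sequence[str]) -> list[str]:
    return (
        ["unit_id"]
        + [f"wl_c{k}" for k in range(6)]
        + ["lin_a", "lin_b"]
        + [f"sr_{p}" for p in range(n)]
        + [f"si_{p}" for p in range(n)]
        + list(extra_cols)
    )


def write_calibration(records: Sequence[CalibrationRecord], path) -> None:
    if not records:
        raise ValueError("no calibration records to write")
    n = records[0].n_photosites
    extra_cols: list[str] = []
    for rec in records:
        for key in rec.extra:
            if key not in extra_cols:
                extra_cols.append(key)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_calib_header(n, extra_cols))
        for rec in records:
            if rec.n_photosites != n:
                raise ValueError("all records must have the same photosite count")
            row = [rec.unit_id]
            row += [_fmt(c) for c in rec.wavelength_coeffs]
            row += [_fmt(rec.lin_a), _fmt(rec.lin_b)]
            row += [_fmt(v) for v in rec.S_r]
            row += [_fmt(v) for v in rec.S_i]
            row += [rec.extra.get(k, "") for k in extra_cols]
            writer.writerow(row)


def read_calibration(path) -> list[CalibrationRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        rows = list(reader)
    n = sum(1 for col in header if col.startswith("sr_"))
    required = ["unit_id"] + [f"wl_c{k}" for k in range(6)] + ["lin_a", "lin_b"]
    required += [f"sr_{p}" for p in range(n)] + [f"si_{p}" for p in range(n)]
    for col in required:
        if col not in header:
            raise ValueError(f"calibration file is missing required column {col!r}")
    if n == 0:
        raise ValueError("calibration file is missing required column 'sr_0'")
    known = set(required)
    extra_cols = [c for c in header if c not in known]
    records, seen = [], set()
    for row in rows:
        uid = row["unit_id"]
        if uid in seen:
            raise ValueError(f"duplicate unit_id {uid!r} in calibration file")
        seen.add(uid)
        records.append(
            CalibrationRecord(
                unit_id=uid,
                wavelength_coeffs=tuple(float(row[f"wl_c{k}"]) for k in range(6)),
                lin_a=float(row["lin_a"]),
                lin_b=float(row["lin_b"]),
                S_r=np.array([float(row[f"sr_{p}"]) for p in range(n)]),
                S_i=np.array([float(row[f"si_{p}"]) for p in range(n)]),
                extra={k: row[k] for k in extra_cols},
            )
        )
    return records


def lookup_unit(records: Sequence[CalibrationRecord], unit_id: str) -> CalibrationRecord:
    for rec in records:
        if rec.unit_id == unit_id:
            return rec
    raise KeyError(f"no calibration for unit {unit_id!r}")


# --------------------------------------------------------------- measurements


def _meas_header(n: int) -> list[str]:
    return (
        list(_MEAS_META)
        + [f"wl_{p}" for p in range(n)]
        + [f"val_{p}" for p in range(n)]
        + [f"raw_{p}" for p in range(n)]
    )


def _meas_row(rec: CalibratedSpectrum) -> list[str]:
    row = [
        rec.unit_id,
        rec.label,
        rec.timestamp,
        rec.mode,
        _fmt(rec.integration_ms),
        str(rec.n_scans),
        str(rec.n_saturated),
    ]
    row += [_fmt(v) for v in rec.wavelengths]
    row += [_fmt(v) for v in rec.values]
    row += [_fmt(v) for v in rec.raw_counts]
    return row


def append_measurement(record: CalibratedSpectrum, path) -> None:
    """Append one measurement row, creating the file (with header) if
    needed.  Existing rows are never rewritten; appending a row identical
    to the last one is rejected (the app's re-save guard)."""
    path = Path(path)
    header = _meas_header(len(record.values))
    row = _meas_row(record)
    if path.exists() and path.stat().st_size > 0:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            existing_header = next(reader, None)
            last = None
            for last in reader:
                pass
        if existing_header != header:
            raise ValueError(
                "measurement file schema does not match this record "
                f"({len(existing_header or [])} vs {len(header)} columns)"
            )
        if last == row:
            raise ValueError("refusing to re-save: identical to the last saved row")
        with open(path, "a", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerow(row)
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            writer.writerow(row)


def read_measurements(path) -> list[CalibratedSpectrum]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        rows = list(reader)
    n = sum(1 for col in header if col.startswith("wl_") and not col.startswith("wl_c"))
    for col in list(_MEAS_META) + [f"{b}_{p}" for b in ("wl", "val", "raw") for p in range(n)]:
        if col not in header:
            raise ValueError(f"measurement file is missing required column {col!r}")
    out = []
    for row in rows:
        out.append(
            CalibratedSpectrum(
                unit_id=row["unit_id"],
                label=row["label"],
                timestamp=row["timestamp"],
                mode=row["mode"],
                integration_ms=float(row["integration_ms"]),
                n_scans=int(row["n_scans"]),
                n_saturated=int(row["n_saturated"]),
                wavelengths=np.array([float(row[f"wl_{p}"]) for p in range(n)]),
                values=np.array([float(row[f"val_{p}"]) for p in range(n)]),
                raw_counts=np.array([float(row[f"raw_{p}"]) for p in range(n)]),
            )
        )
    return out


def recalibrate(
    record: CalibratedSpectrum, new_calib: CalibrationRecord
) -> CalibratedSpectrum:
    """Recompute calibrated values from the stored raw counts with a
    different calibration; all metadata is preserved."""
    if record.raw_counts is None or len(record.raw_counts) == 0:
        raise ValueError("record has no raw counts; cannot recalibrate")
    counts = CountSpectrum(
        c=record.raw_counts,
        integration_ms=record.integration_ms,
        n_scans=record.n_scans,
        n_saturated=record.n_saturated,
    )
    fresh = counts_to_spectrum(
        counts, new_calib, record.mode, label=record.label, timestamp=record.timestamp
    )
    fresh.unit_id = record.unit_id
    return fresh
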