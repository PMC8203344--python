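"""Record and manifest I/O.

Two record formats are supported:

* a minimal WFDB dialect — single-channel format-16 ``.hea``/``.dat`` pairs
  with an explicit gain/baseline and mV units in the header (multi-channel
  files and headers without gain metadata are rejected rather than guessed);
* two-column delimited text (sample index, amplitude in mV), header row
  optional, with the sampling rate supplied by the caller or a manifest.

Amplitudes in memory are always mV; the WFDB reader/writer is the only
place the ADC gain is applied.  Readers never resample.
"""
from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from .records import ECGRecord, LABELS

_WFDB_FORMAT = 16  # little-endian int16
_DEFAULT_GAIN = 200.0  # adu per mV


# ---------------------------------------------------------------------------
# WFDB dialect
# ---------------------------------------------------------------------------

def _write_wfdb(record: ECGRecord, path: str, gain: float = _DEFAULT_GAIN) -> None:
    base, _ = os.path.splitext(path)
    name = os.path.basename(base)
    baseline = 0
    adc = np.round(record.samples * gain).astype("<i2") + baseline
    checksum = int(np.sum(adc, dtype=np.int16))
    init_val = int(adc[0])
    with open(base + ".hea", "w") as fh:
        fh.write(f"{name} 1 {record.fs:g} {record.n_samples}\n")
        fh.write(
            f"{name}.dat {_WFDB_FORMAT} {gain:g}({baseline})/mV 16 0 "
            f"{init_val} {checksum} 0 ECG\n"
        )
        fh.write(f"# label: {record.label}\n")
    adc.tofile(base + ".dat")


_GAIN_RE = re.compile(r"^(?P<gain>[-\d.eE+]+)(\((?P<baseline>-?\d+)\))?(/(?P<units>\w+))?$")


def _read_wfdb(path: str) -> ECGRecord:
    base, _ = os.path.splitext(path)
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"malformed WFDB header line: {lines[0]!r}")
    name, n_sig, fs, n_samp = head[0], int(head[1]), float(head[2]), int(head[3])
    if n_sig != 1:
        raise ValueError(f"only single-channel records are supported, got {n_sig} signals")
    sig = lines[1].split()
    if len(sig) < 3:
        raise ValueError(f"malformed WFDB signal line: {lines[1]!r}")
    if int(sig[1]) != _WFDB_FORMAT:
        raise ValueError(f"only format {_WFDB_FORMAT} is supported, got {sig[1]}")
    m = _GAIN_RE.match(sig[2])
    if m is None or m.group("units") is None:
        raise ValueError(
            f"gain/units metadata missing or malformed in {hea}: {sig[2]!r}; "
            "refusing to guess amplitude units"
        )
    if m.group("units") != "mV":
        raise ValueError(f"unsupported amplitude units {m.group('units')!r}; expected mV")
    gain = float(m.group("gain"))
    if gain == 0:
        raise ValueError("ADC gain must be non-zero")
    baseline = int(m.group("baseline") or 0)
    label = "unknown"
    for ln in lines[2:]:
        if ln.startswith("#") and "label:" in ln:
            label = ln.split("label:", 1)[1].strip()
    adc = np.fromfile(base + ".dat", dtype="<i2")
    if adc.size != n_samp:
        raise ValueError(f"{base}.dat holds {adc.size} samples, header says {n_samp}")
    samples = (adc.astype(float) - baseline) / gain
    return ECGRecord(samples=samples, fs=fs, label=label, record_id=name, source=hea)


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def _write_csv(record: ECGRecord, path: str) -> None:
    frame = pd.DataFrame(
        {"sample": np.arange(record.n_samples), "mV": record.samples}
    )
    frame.to_csv(path, index=False)


def _read_csv(path: str, fs: float, label: str = "unknown") -> ECGRecord:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"expected two columns (index, mV) in {path}")
    samples = frame.iloc[:, 1].to_numpy(dtype=float)
    name = os.path.splitext(os.path.basename(path))[0]
    return ECGRecord(samples=samples, fs=fs, label=label, record_id=name, source=path)


# ---------------------------------------------------------------------------
# Public interface
# ---------------------------------------------------------------------------

def write_record(record: ECGRecord, path: str, format: str = "wfdb", gain: float = _DEFAULT_GAIN) -> None:
    """Write ``record`` to ``path`` in the named format (``wfdb`` | ``csv``)."""
    if format == "wfdb":
        _write_wfdb(record, path, gain=gain)
    elif format == "csv":
        _write_csv(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_record(
    path: str, format: str = "wfdb", fs: float | None = None, label: str = "unknown"
) -> ECGRecord:
    """Read a record.  CSV needs ``fs`` (Hz) since the text carries none."""
    if format == "wfdb":
        return _read_wfdb(path)
    if format == "csv":
        if fs is None:
            raise ValueError("fs is required when reading CSV records")
        return _read_csv(path, fs=fs, label=label)
    raise ValueError(f"unknown format {format!r}")


_MANIFEST_COLUMNS = ["record_id", "path", "label", "fs"]


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    """Write a dataset manifest (record_id, path, label, fs) as CSV."""
    _validate_manifest(manifest)
    manifest.to_csv(path, index=False)


def read_manifest(path: str) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    _validate_manifest(manifest)
    return manifest


def _validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    ids = manifest["record_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise ValueError(f"duplicate record_id values: {dupes}")
    bad = set(manifest["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown label tokens: {sorted(bad)}")


def write_dataset(
    records: list[ECGRecord], out_dir: str, format: str = "wfdb"
) -> pd.DataFrame:
    """Write every record plus a ``manifest.csv``; returns the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        rid = rec.record_id or f"rec{i:03d}"
        ext = ".hea" if format == "wfdb" else ".csv"
        path = os.path.join(out_dir, rid + ext)
        write_record(rec, path, format=format)
        rows.append(dict(record_id=rid, path=path, label=rec.label, fs=rec.fs))
    manifest = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest


def load_dataset(manifest_path: str) -> list[ECGRecord]:
    """Read every record listed in a manifest."""
    manifest = read_manifest(manifest_path)
    records = []
    for row in manifest.itertuples(index=False):
        fmt = "wfdb" if str(row.path).endswith((".hea", ".dat")) else "csv"
        rec = read_record(str(row.path), format=fmt, fs=float(row.fs), label=str(row.label))
        rec.record_id = str(row.record_id)
        rec.label = str(row.label)
        records.append(rec)
    return records
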