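"""Reading and writing the pipeline's external formats.

Signals arrive either as a single-column CSV (header ``value``, one sample
per row) or as a WFDB-style record: a text ``.hea`` header naming the
signal files plus a binary ``.dat`` holding ADC samples in format 16
(little-endian int16) or format 212 (two 12-bit samples packed into three
bytes, the classic arrhythmia-corpus layout). The reader implemented here
is deliberately minimal — single segment, formats 16 and 212, gain/baseline
conversion to physical units — which covers the records this pipeline
consumes.

Clinical tables are CSV with a header row; empty cells and ``?`` (the
Cleveland convention) are read as missing. Beat reports and annotations
are plain CSV with deterministic layouts.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RecordSpec
from .core import ECGSignal
from .tabular import ClinicalTable

__all__ = [
    "read_signal",
    "write_signal_csv",
    "write_wfdb_record",
    "read_clinical_table",
    "read_annotations",
    "write_beat_report",
    "read_beat_report",
]

MISSING_SENTINELS = ["", "?"]
REPORT_COLUMNS = [
    "record_id", "beat_index", "r_sample",
    "RR_s", "QRS_s", "QT_s", "PR_s", "P_s", "T_s", "label",
]


# --------------------------------------------------------------------------
# signals

def _read_signal_csv(path: Path) -> np.ndarray:
    frame = pd.read_csv(path)
    if frame.shape[1] < 1 or len(frame) == 0:
        raise ValueError(f"no samples in {path}")
    col = "value" if "value" in frame.columns else frame.columns[0]
    values = pd.to_numeric(frame[col], errors="coerce")
    if values.isna().any():
        raise ValueError(f"non-numeric samples in {path}")
    return values.to_numpy(dtype=float)


def _parse_gain_spec(token: str) -> tuple[float, float]:
    """'200(1024)/mV' -> (gain, baseline); defaults gain=200, baseline=0."""
    spec = token.split("/")[0]
    baseline = 0.0
    if "(" in spec:
        spec, rest = spec.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(spec) if spec else 0.0
    if gain == 0:
        gain = 200.0
    return gain, baseline


def _read_dat(path: Path, fmt: int, n_sig: int, n_samples: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        usable = (b.size // 3) * 3
        b = b[:usable].reshape(-1, 3).astype(np.int32)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        pairs = np.stack([first, second], axis=1).ravel()
        pairs[pairs > 2047] -= 4096  # 12-bit two's complement
        adc = pairs
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    total = n_sig * n_samples
    if adc.size < total:
        raise ValueError(f"{path} holds {adc.size} samples, header promises {total}")
    return adc[:total].reshape(n_samples, n_sig)


def _read_signal_wfdb(header_path: Path, lead: str | None) -> tuple[np.ndarray, float]:
    lines = [
        ln.strip() for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty WFDB header {header_path}")
    rec = lines[0].split()
    if len(rec) < 3:
        raise ValueError(f"malformed WFDB record line in {header_path}")
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0])
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise ValueError(f"header {header_path} promises {n_sig} signal lines")

    names, gains, baselines, fmts, files = [], [], [], [], []
    for ln in sig_lines:
        tok = ln.split()
        files.append(tok[0])
        fmts.append(int(tok[1].split("x")[0].split(":")[0].split("+")[0]))
        gain, base = _parse_gain_spec(tok[2]) if len(tok) > 2 else (200.0, 0.0)
        gains.append(gain)
        baselines.append(base)
        names.append(tok[-1] if len(tok) > 3 else f"sig{len(names)}")

    if len(set(files)) != 1 or len(set(fmts)) != 1:
        raise ValueError("only single-file, single-format WFDB records are supported")
    dat_path = header_path.parent / files[0]
    if not dat_path.exists():
        raise FileNotFoundError(dat_path)
    if n_samples == 0:
        per = 2 if fmts[0] == 16 else 1.5
        n_samples = int(dat_path.stat().st_size // (per * n_sig))
    adc = _read_dat(dat_path, fmts[0], n_sig, n_samples)

    if lead is not None and lead in names:
        ch = names.index(lead)
    elif lead is not None and n_sig > 1:
        raise ValueError(f"lead {lead!r} not in record (has {names})")
    else:
        ch = 0
    physical = (adc[:, ch].astype(float) - baselines[ch]) / gains[ch]
    return physical, fs


def read_signal(spec: RecordSpec) -> ECGSignal:
    """Read one lead of a record as an ECGSignal in physical units.

    ``spec.signal_path`` may point at a CSV of samples or at a WFDB-style
    ``.hea`` header (or its basename). The CSV path takes ``spec.fs``; a
    WFDB header carries its own sampling frequency.
    """
    path = Path(spec.signal_path)
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if path.suffix != ".csv" and header.exists():
        samples, fs = _read_signal_wfdb(header, spec.lead)
    elif path.exists():
        samples, fs = _read_signal_csv(path), spec.fs
    else:
        raise FileNotFoundError(path)
    if samples.size < 2:
        raise ValueError(f"no samples (need >= 2) in {path}")
    return ECGSignal(samples, fs, spec.record_id)


def write_signal_csv(signal: ECGSignal, path: str | Path) -> None:
    """One sample per row under the header ``value``."""
    pd.DataFrame({"value": signal.samples}).to_csv(path, index=False)


def write_wfdb_record(
    path_stem: str | Path,
    samples: np.ndarray,
    fs: float,
    leads: list[str] | None = None,
    gain: float = 200.0,
    baseline: float = 0.0,
) -> Path:
    """Write a minimal format-16 WFDB record (.hea + .dat); returns the header path.

    ``samples`` is (n,) or (n, n_sig) in physical units; values are
    quantized to ADC integers with the given gain/baseline.
    """
    stem = Path(path_stem)
    arr = np.atleast_2d(np.asarray(samples, dtype=float))
    if arr.shape[0] < arr.shape[1]:
        arr = arr.T
    n, n_sig = arr.shape
    leads = leads or [f"lead{i}" for i in range(n_sig)]
    adc = np.round(arr * gain + baseline).astype("<i2")
    dat = stem.with_suffix(".dat")
    adc.reshape(-1).tofile(dat)
    lines = [f"{stem.name} {n_sig} {fs:g} {n}"]
    for name in leads:
        lines.append(f"{dat.name} 16 {gain:g}({baseline:g})/mV 16 0 0 0 0 {name}")
    hea = stem.with_suffix(".hea")
    hea.write_text("\n".join(lines) + "\n")
    return hea


# --------------------------------------------------------------------------
# clinical tables and annotations

def read_clinical_table(path: str | Path, outcome: str = "target") -> ClinicalTable:
    """CSV with a header row; empty cells and '?' are missing values."""
    frame = pd.read_csv(path, na_values=MISSING_SENTINELS, keep_default_na=True)
    if len(frame) == 0:
        raise ValueError(f"zero data rows in {path}")
    return ClinicalTable(frame, outcome)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Beat annotations as a two-column CSV 'sample,label'; labels are opaque."""
    frame = pd.read_csv(path, dtype={"label": str})
    if not {"sample", "label"} <= set(frame.columns):
        raise ValueError("annotation CSV needs 'sample' and 'label' columns")
    return frame[["sample", "label"]].sort_values("sample").reset_index(drop=True)


# --------------------------------------------------------------------------
# beat reports

def write_beat_report(labels: pd.DataFrame, path: str | Path) -> None:
    """Write labelled beats as CSV, one row per beat, ordered by r_sample.

    ``labels`` is the frame produced by ``classify_beats`` (feature columns
    plus ``label``); reruns on the same input produce byte-identical files.
    """
    if len(labels) == 0:
        raise ValueError("empty label set")
    out = labels.rename(columns={"record": "record_id"}).sort_values(
        "r_sample", kind="stable"
    )
    out = out.reset_index(drop=True)
    out["beat_index"] = out.index
    # %.17g keeps the CSV round-trip exact at float64 precision
    out[REPORT_COLUMNS].to_csv(
        path, index=False, lineterminator="\n", float_format="%.17g"
    )


def read_beat_report(path: str | Path) -> pd.DataFrame:
    """Re-parse a beat report; inverse of ``write_beat_report``."""
    frame = pd.read_csv(
        path, dtype={"record_id": str, "label": str}, float_precision="round_trip"
    )
    missing = set(REPORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"beat report missing columns {sorted(missing)}")
    return frame
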