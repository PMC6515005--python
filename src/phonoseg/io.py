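"""Reading and writing of recordings, detections and reports.

Recordings travel as two-column CSV (``ecg,pcg`` header, one row per
sample) with the sampling rate given by the caller or a ``# fs=...``
comment line.  Detected sounds are written as a per-sound CSV with all
boundaries in ms, and summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import Recording
from .metrics import TimingSummary, ValidationReport
from .rpeaks import RPeakSeries
from .segmentation import CandidateSegment, HeartSound

__all__ = [
    "read_recording",
    "write_recording",
    "write_sounds_csv",
    "read_sounds_csv",
    "write_rpeaks_csv",
    "read_rpeaks_csv",
    "write_summary_json",
]

SOUND_COLUMNS = ["ref_rpeak_ms", "label", "c1_ms", "c2_ms", "split_ms",
                 "start_ms", "end_ms", "degenerate_flag"]


def read_recording(path, format: str = "csv", fs: float | None = None,
                   ecg_col: str = "ecg", pcg_col: str = "pcg") -> Recording:
    """Load a paired ECG/PCG record.

    CSV: two named columns (default ``ecg`` and ``pcg``); the sampling
    rate comes from a leading ``# fs=<Hz>`` comment line or the ``fs``
    argument (default 1000 Hz).  The method's rule constants are tied to
    1-ms resolution, so records at other rates are accepted but must be
    resampled by the caller first; the CLI refuses them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "wfdb":
        raise ValueError(
            "WFDB input requires the optional 'wfdb' package, which is not "
            "installed; convert the record to two-column CSV instead"
        )
    if format != "csv":
        raise ValueError(f"unknown format {format!r} (expected 'csv')")

    header_fs = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "fs=" in first:
        header_fs = float(first.split("fs=")[1].split()[0])
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path} is empty") from exc
    if df.shape[1] < 2:
        raise ValueError(
            f"{path} has {df.shape[1]} column(s); need an ECG and a PCG channel"
        )
    cols = {c.lower(): c for c in df.columns}
    if ecg_col.lower() in cols and pcg_col.lower() in cols:
        ecg = df[cols[ecg_col.lower()]].to_numpy(dtype=float)
        pcg = df[cols[pcg_col.lower()]].to_numpy(dtype=float)
    elif df.shape[1] == 2:
        ecg = df.iloc[:, 0].to_numpy(dtype=float)
        pcg = df.iloc[:, 1].to_numpy(dtype=float)
    else:
        raise ValueError(
            f"cannot resolve channels: columns {list(df.columns)} contain "
            f"neither {ecg_col!r} nor {pcg_col!r}"
        )
    use_fs = fs if fs is not None else (header_fs if header_fs else 1000.0)
    if len(ecg) != len(pcg) or np.isnan(ecg).any() or np.isnan(pcg).any():
        raise ValueError("ECG and PCG channels have inconsistent lengths "
                         "or missing samples")
    return Recording(ecg=ecg, pcg=pcg, fs=use_fs)


def write_recording(rec: Recording, path) -> None:
    """Write a record as two-column CSV with an ``# fs=`` header line.

    Samples are printed at full float64 precision so a round-trip
    reproduces them exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write("ecg,pcg\n")
        np.savetxt(fh, np.column_stack([rec.ecg, rec.pcg]), fmt="%.17g",
                   delimiter=",")


def sounds_frame(sounds: list[HeartSound], fs: float) -> pd.DataFrame:
    ms = 1000.0 / fs
    rows = []
    for s in sounds:
        g = s.segment
        rows.append({
            "ref_rpeak_ms": round(s.ref_rpeak * ms, 1),
            "label": s.label,
            "c1_ms": round(g.c1 * ms, 1),
            "c2_ms": round(g.c2 * ms, 1),
            "split_ms": round(g.split * ms, 1),
            "start_ms": round(g.start * ms, 1),
            "end_ms": round(g.end * ms, 1),
            "degenerate_flag": int(g.degenerate),
        })
    return pd.DataFrame(rows, columns=SOUND_COLUMNS)


def write_sounds_csv(sounds: list[HeartSound], fs: float, path) -> None:
    sounds_frame(sounds, fs).to_csv(path, index=False)


def read_sounds_csv(path, fs: float = 1000.0) -> list[HeartSound]:
    df = pd.read_csv(path)
    k = fs / 1000.0
    out = []
    for _, row in df.iterrows():
        seg = CandidateSegment(
            start=int(round(row.start_ms * k)),
            end=int(round(row.end_ms * k)),
            split=int(round(row.split_ms * k)),
            c1=int(round(row.c1_ms * k)),
            c2=int(round(row.c2_ms * k)),
            degenerate=bool(row.degenerate_flag),
        )
        out.append(HeartSound(segment=seg, label=str(row.label),
                              ref_rpeak=int(round(row.ref_rpeak_ms * k))))
    return out


def write_rpeaks_csv(peaks: RPeakSeries, path) -> None:
    peaks.to_frame().to_csv(path, index=False)


def read_rpeaks_csv(path, fs: float = 1000.0) -> RPeakSeries:
    df = pd.read_csv(path)
    return RPeakSeries(indices=df["sample_index"].to_numpy(dtype=int), fs=fs)


def write_summary_json(path, summary: TimingSummary | None = None,
                       report: ValidationReport | None = None,
                       extra: dict | None = None) -> None:
    payload: dict = {}
    if summary is not None:
        payload["timing"] = summary.stats
    if report is not None:
        payload["validation"] = report.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)
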