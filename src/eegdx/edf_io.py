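"""Minimal EDF round-trip for synthetic cohorts.

Writes standard 16-bit EDF (one data record per second, physical units
µV) plus sidecar files: ``covariates.csv`` for the per-subject covariate
table and ``metadata.json`` carrying generator ground truth (group
labels, blink times, noise-burst spans). Reading goes through
MNE-Python's EDF reader, which also serves as the independent check that
the written files are valid EDF.

Quantization: each channel is scaled to its own physical range over
32767 digital steps, so round-trip error is bounded by half a step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import mne

from .simulate import RawRecording

__all__ = ["write_edf", "read_edf", "write_cohort", "read_cohort"]

_DIG_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _fmt_num(v: float, width: int = 8) -> bytes:
    for fmt in (f"{v:.6g}", f"{v:.4g}", f"{v:.2g}", f"{v:.0f}"):
        if len(fmt) <= width:
            return _pad(fmt, width)
    raise ValueError(f"cannot format {v} in {width} chars")


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF; whole seconds only and an
    integer per-second sample count are required."""
    path = Path(path)
    sr = rec.sample_rate
    if abs(sr - round(sr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    sr = int(round(sr))
    data = np.vstack([rec.eeg, rec.eog])
    n_ch, n_samp = data.shape
    n_records = n_samp // sr
    if n_records * sr != n_samp:
        raise ValueError("EDF writer requires a whole number of seconds")
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    scale = _DIG_MAX / phys_max
    digital = np.round(data * scale[:, None]).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"X X X {rec.subject_id}", 80),
            _pad(f"Startdate 01-JAN-2000 {rec.subject_id}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        b"".join(_pad(name, 16) for name in rec.channel_names),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad("uV", 8) for _ in range(n_ch)),
        b"".join(_fmt_num(-phys_max[i]) for i in range(n_ch)),
        b"".join(_fmt_num(phys_max[i]) for i in range(n_ch)),
        b"".join(_pad(str(-_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_pad(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(sr), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(block)
        for r in range(n_records):
            fh.write(digital[:, r * sr : (r + 1) * sr].tobytes())
    return path


def read_edf(path: str | Path, subject_id: str | None = None, group: int = 0) -> RawRecording:
    """Read an EDF file back into a RawRecording via MNE. Channels whose
    name starts with ``EOG`` become the EOG block."""
    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    names = raw.ch_names
    data = raw.get_data() * 1e6  # MNE reads volts
    is_eog = np.array([n.upper().startswith("EOG") for n in names])
    return RawRecording(
        subject_id=subject_id or Path(path).stem,
        group=group,
        sample_rate=float(raw.info["sfreq"]),
        eeg=data[~is_eog],
        eog=data[is_eog],
        channel_names=[n for n in names if not n.upper().startswith("EOG")]
        + [n for n in names if n.upper().startswith("EOG")],
    )


def write_cohort(
    recs: list[RawRecording], covariates: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write one EDF per subject plus covariates.csv and metadata.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {}
    for rec in recs:
        write_edf(rec, out_dir / f"{rec.subject_id}.edf")
        meta[rec.subject_id] = {
            "group": rec.group,
            "annotations": _jsonable(rec.annotations),
        }
    covariates.to_csv(out_dir / "covariates.csv", index=False)
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=1))
    return out_dir


def read_cohort(out_dir: str | Path) -> tuple[list[RawRecording], pd.DataFrame]:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "metadata.json").read_text())
    recs = []
    for subject_id in sorted(meta):
        rec = read_edf(out_dir / f"{subject_id}.edf", subject_id, meta[subject_id]["group"])
        rec.annotations = meta[subject_id]["annotations"]
        recs.append(rec)
    covariates = pd.read_csv(out_dir / "covariates.csv")
    return recs, covariates


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
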