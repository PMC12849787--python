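"""Reading and writing recordings: EDF (+ CSV annotation sidecar) and NPZ.

EDF reading goes through MNE. Writing uses a small built-in plain-EDF encoder
(16-bit, one data record per second) so synthetic subjects can be exported to
the clinical exchange format; seizure annotations travel in a CSV sidecar with
columns ``start_s,end_s,label`` next to the EDF file.

The NPZ bundle is the lossless round-trip format: ``data`` (uV), ``fs``,
``channel_labels``, ``seizure_intervals`` (n x 2 seconds), ``subject_id``.
"""

from __future__ import annotations

import csv
import io as _stdio
from pathlib import Path

import numpy as np

from .errors import FormatError, RecordIOError
from .records import EEGRecord, Interval

__all__ = ["read_record", "write_npz", "write_edf", "write_annotations_csv",
           "read_annotations_csv", "sidecar_path"]


def sidecar_path(edf_path: str | Path) -> Path:
    """CSV annotation sidecar conventionally stored next to the EDF."""
    return Path(edf_path).with_suffix(".csv")


def write_annotations_csv(intervals: list[Interval], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "label"])
        for a, b in intervals:
            w.writerow([f"{a:.6f}", f"{b:.6f}", "seizure"])


def read_annotations_csv(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row.get("label", "seizure").strip().lower() == "seizure":
                out.append((float(row["start_s"]), float(row["end_s"])))
    return sorted(out)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecord, path: str | Path, annotations: bool = True) -> Path:
    """Write a plain EDF file (16-bit), one data record per second.

    The sampling rate must be a whole number of samples per second; a trailing
    partial second is dropped. Values are quantized to the per-channel
    physical range, so the round-trip error is bounded by range/2^15.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError(f"EDF export needs an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per channel per 1-s data record
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise FormatError("record shorter than one EDF data record (1 s)")
    M = rec.n_channels
    data = rec.data[:, : n_rec * spr]

    # the header stores the range as ASCII; quantize against the *parsed*
    # header strings so writer and reader agree on the scale exactly
    pmax_str = [f"{max(abs(data[i]).max(), 1.0):.6g}"[:7]
                for i in range(M)]
    pmax = np.array([float(s) for s in pmax_str])
    digital = np.clip(np.round(data / pmax[:, None] * 32767.0), -32768, 32767).astype("<i2")

    buf = _stdio.BytesIO()
    buf.write(_pad("0", 8))
    buf.write(_pad(rec.subject_id, 80))
    buf.write(_pad("synthetic EEG", 80))
    buf.write(_pad("01.01.01", 8))
    buf.write(_pad("00.00.00", 8))
    buf.write(_pad(str(256 * (M + 1)), 8))
    buf.write(_pad("", 44))
    buf.write(_pad(str(n_rec), 8))
    buf.write(_pad("1", 8))           # record duration, seconds
    buf.write(_pad(str(M), 4))
    for lab in rec.channel_labels:
        buf.write(_pad(lab, 16))
    for _ in range(M):
        buf.write(_pad("", 80))        # transducer
    for _ in range(M):
        buf.write(_pad("uV", 8))
    for s in pmax_str:
        buf.write(_pad("-" + s, 8))
    for s in pmax_str:
        buf.write(_pad(s, 8))
    for _ in range(M):
        buf.write(_pad("-32768", 8))
    for _ in range(M):
        buf.write(_pad("32767", 8))
    for _ in range(M):
        buf.write(_pad("", 80))        # prefiltering
    for _ in range(M):
        buf.write(_pad(str(spr), 8))
    for _ in range(M):
        buf.write(_pad("", 32))
    # data records: channel-major within each 1-s record
    for r in range(n_rec):
        sl = digital[:, r * spr:(r + 1) * spr]
        buf.write(sl.tobytes(order="C"))
    path.write_bytes(buf.getvalue())
    if annotations:
        write_annotations_csv(rec.seizure_intervals, sidecar_path(path))
    return path


def write_npz(rec: EEGRecord, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        data=rec.data,
        fs=np.float64(rec.fs),
        channel_labels=np.array(rec.channel_labels, dtype=object),
        seizure_intervals=np.array(rec.seizure_intervals, dtype=np.float64).reshape(-1, 2),
        subject_id=np.array(rec.subject_id),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def _read_npz(path: Path) -> EEGRecord:
    try:
        with np.load(path, allow_pickle=True) as z:
            if "fs" not in z:
                raise FormatError(f"{path}: NPZ bundle is missing 'fs'")
            if "data" not in z:
                raise FormatError(f"{path}: NPZ bundle is missing 'data'")
            intervals = [tuple(map(float, iv)) for iv in z["seizure_intervals"]]
            return EEGRecord(
                data=np.asarray(z["data"], dtype=np.float64),
                fs=float(z["fs"]),
                channel_labels=[str(c) for c in z["channel_labels"]],
                seizure_intervals=intervals,
                subject_id=str(z["subject_id"]) if "subject_id" in z else "subject",
            )
    except FormatError:
        raise
    except Exception as exc:
        raise RecordIOError(f"cannot read NPZ bundle {path}: {exc}") from exc


def _read_edf(path: Path) -> EEGRecord:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    except Exception as exc:
        raise RecordIOError(f"cannot read EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    side = sidecar_path(path)
    if side.exists():
        intervals = read_annotations_csv(side)
    else:
        intervals = sorted(
            (float(on), float(on) + float(du))
            for on, du, desc in zip(raw.annotations.onset, raw.annotations.duration,
                                    raw.annotations.description)
            if "seiz" in str(desc).lower()
        )
    return EEGRecord(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        seizure_intervals=intervals,
        subject_id=path.stem,
    )


def read_record(path: str | Path, format: str | None = None) -> EEGRecord:
    """Read a recording from EDF or NPZ; format inferred from the suffix."""
    path = Path(path)
    if not path.exists():
        raise RecordIOError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise RecordIOError(f"empty file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "npz":
        return _read_npz(path)
    if fmt == "edf":
        return _read_edf(path)
    raise RecordIOError(f"unsupported format {fmt!r} (expected 'edf' or 'npz')")
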