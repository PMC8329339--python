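"""Reading and writing recordings, labels, Δ traces and event lists.

The native recording format is plain delimited text: a header line
``# fs=<Hz>`` (optionally ``# channels=a,b,c``), then one whitespace-
separated row of samples per channel.  EDF input is supported when the
optional ``mne`` dependency is installed.  Seizure labels travel in a JSON
sidecar; events and Δ traces are written as small TSV files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .detector import Event
from .symbolize import Recording


def read_recording(path: str | Path, format: str = "delimited") -> Recording:
    """Load a recording from delimited text or (optionally) EDF."""
    if format == "delimited":
        return _read_delimited(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown recording format {format!r}")


def _read_delimited(path: str | Path) -> Recording:
    path = Path(path)
    fs = None
    labels = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("channels="):
                    labels = [c.strip() for c in body[9:].split(",")]
                continue
            try:
                rows.append(np.array(line.split(), dtype=np.float64))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: unparsable sample row ({err})")
    if fs is None:
        raise ValueError(f"{path}: missing required '# fs=<Hz>' header line")
    if not rows:
        raise ValueError(f"{path}: no sample rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows; channel lengths {sorted(widths)}")
    samples = np.vstack(rows)
    if not np.isfinite(samples).all():
        raise ValueError(f"{path}: recording contains NaN/inf samples")
    return Recording(samples, fs=fs, channel_labels=labels)


def _read_edf(path: str | Path) -> Recording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF reading requires the optional 'mne' dependency "
            "(pip install hdseizure[edf])") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data(), fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


def write_recording(rec: Recording, path: str | Path, fmt: str = "%.6g") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write("# channels=" + ",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples, fmt=fmt)


def read_labels(path: str | Path) -> list[tuple[float, float]]:
    data = json.loads(Path(path).read_text())
    return [(float(a), float(b)) for a, b in data["seizures"]]


def write_labels(labels, path: str | Path, **meta) -> None:
    payload = {"seizures": [[float(a), float(b)] for a, b in labels], **meta}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_events(events: list[Event], path: str | Path) -> None:
    """Three-column TSV: onset_s, offset_s, peak Δ."""
    with open(path, "w") as fh:
        fh.write("onset_s\toffset_s\tpeak_delta\n")
        for e in events:
            fh.write(f"{e.onset_s:.3f}\t{e.offset_s:.3f}\t{e.peak_delta:.4f}\n")


def read_events(path: str | Path) -> list[Event]:
    events = []
    for line in Path(path).read_text().splitlines()[1:]:
        on, off, peak = line.split("\t")
        events.append(Event(float(on), float(off), float(peak)))
    return events


def write_events_bed(events: list[Event], fs: float, path: str | Path,
                     name: str = "recording") -> None:
    """BED-like half-open intervals in sample coordinates."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(f"{name}\t{int(round(e.onset_s * fs))}"
                     f"\t{int(round(e.offset_s * fs))}\tseizure\t{e.peak_delta:.4f}\n")


def write_delta_trace(times: np.ndarray, delta: np.ndarray, path: str | Path) -> None:
    """Two-column TSV of window start time and Δ."""
    with open(path, "w") as fh:
        fh.write("time_s\tdelta\n")
        for t, d in zip(times, delta):
            fh.write(f"{t:.3f}\t{d:.5f}\n")


def bandpass(rec: Recording, lo: float = 0.5, hi: float = 120.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (second-order sections), per channel.

    Off by default in the pipeline; synthetic data needs no preprocessing.
    """
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError(f"band ({lo}, {hi}) must lie inside (0, fs/2)")
    sos = butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return Recording(sosfiltfilt(sos, rec.samples, axis=1), fs=rec.fs,
                     channel_labels=rec.channel_labels)
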