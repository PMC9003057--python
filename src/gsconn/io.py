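"""Readers and writers for recordings, events and ground-truth files.

Two input dialects are supported: EDF (read through mne, channel labels
honored verbatim) and a delimited-text dialect — one header row of
channel labels, one column per channel, tab-separated — with a sidecar
events file holding one stimulus time in seconds per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import ContinuousRecording, TimeWindow
from .synthetic import CouplingSpec

__all__ = [
    "write_recording_text",
    "read_recording_text",
    "read_recording_edf",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
]


def events_path_for(data_path: str | Path) -> Path:
    """Sidecar convention: subject01.tsv -> subject01.events.txt."""
    p = Path(data_path)
    return p.with_suffix(".events.txt")


def write_recording_text(rec: ContinuousRecording, data_path: str | Path) -> Path:
    """Write the delimited-text dialect plus the events sidecar."""
    p = Path(data_path)
    p.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(rec.channel_labels)
    np.savetxt(
        p, rec.samples.T, fmt="%.6f", delimiter="\t", header=header, comments=""
    )
    np.savetxt(events_path_for(p), rec.events, fmt="%.6f")
    return p


def read_recording_text(
    data_path: str | Path, rate_hz: float, events_path: str | Path | None = None
) -> ContinuousRecording:
    """Read the delimited-text dialect; the sampling rate comes from config."""
    p = Path(data_path)
    with open(p) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
    samples = np.loadtxt(p, delimiter="\t", skiprows=1).T
    if samples.ndim == 1:
        samples = samples[None, :]
    ev_path = Path(events_path) if events_path is not None else events_path_for(p)
    events = np.loadtxt(ev_path, ndmin=1) if ev_path.exists() else np.empty(0)
    return ContinuousRecording(
        samples=samples, rate_hz=rate_hz, channel_labels=labels, events=events
    )


def read_recording_edf(
    data_path: str | Path, events_path: str | Path | None = None
) -> ContinuousRecording:
    """Read an EDF file via mne; events come from the sidecar if present,
    otherwise from the file's annotations."""
    import mne

    raw = mne.io.read_raw_edf(str(data_path), preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    ev_path = (
        Path(events_path) if events_path is not None else events_path_for(data_path)
    )
    if ev_path.exists():
        events = np.loadtxt(ev_path, ndmin=1)
    else:
        events = np.asarray(raw.annotations.onset, dtype=float)
    return ContinuousRecording(
        samples=samples,
        rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


def read_recording(
    data_path: str | Path,
    rate_hz: float | None = None,
    events_path: str | Path | None = None,
) -> ContinuousRecording:
    """Dispatch on extension: .edf via mne, anything else as delimited text."""
    p = Path(data_path)
    if p.suffix.lower() == ".edf":
        return read_recording_edf(p, events_path)
    if rate_hz is None:
        raise ValueError("rate_hz is required for delimited-text recordings")
    return read_recording_text(p, rate_hz, events_path)


def _coupling_to_dict(c: CouplingSpec) -> dict:
    return {
        "drive": c.drive,
        "response": c.response,
        "link": c.link,
        "baseline_strength": c.baseline_strength,
        "lag_s": c.lag_s,
        "strength_by_window": [
            [w.start_s, w.end_s, s] for w, s in c.strength_by_window
        ],
    }


def _coupling_from_dict(d: dict) -> CouplingSpec:
    return CouplingSpec(
        drive=d["drive"],
        response=d["response"],
        link=d.get("link", "affine"),
        baseline_strength=d.get("baseline_strength", 0.0),
        lag_s=d.get("lag_s", 0.0),
        strength_by_window=tuple(
            (TimeWindow(a, b), s) for a, b, s in d.get("strength_by_window", [])
        ),
    )


def write_ground_truth(
    couplings_by_subject: dict[str, list[CouplingSpec]], path: str | Path
) -> None:
    payload = {
        subj: [_coupling_to_dict(c) for c in cs]
        for subj, cs in couplings_by_subject.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> dict[str, list[CouplingSpec]]:
    payload = json.loads(Path(path).read_text())
    return {
        subj: [_coupling_from_dict(d) for d in ds] for subj, ds in payload.items()
    }
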