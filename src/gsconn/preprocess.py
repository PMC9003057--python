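"""Filtering, epoching and window slicing for event-locked EEG.

The pipeline mirrors standard event-related practice: notch out the
power-line component on the continuous recording, band-pass into the
rhythm of interest (theta 4-8 Hz or mu 8-14 Hz by default), cut epochs
time-locked to each stimulus, then slice epochs into analysis windows.
Filtering happens on the continuous signal, before epoching, so filter
edge transients never fall inside an epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousRecording",
    "BandSpec",
    "EpochedRecording",
    "TimeWindow",
    "notch_filter",
    "bandpass",
    "epochize",
    "slice_window",
    "THETA",
    "MU",
]


@dataclass
class ContinuousRecording:
    """Multichannel continuous signal in microvolts with stimulus events.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel series in microvolts.
    rate_hz : float
        Sampling rate; 250 Hz in the reference acquisition setup.
    channel_labels : list of str
        10-10 montage names, one per row of ``samples``.
    events : ndarray
        Stimulus onset times in seconds, strictly increasing.
    """

    samples: np.ndarray
    rate_hz: float
    channel_labels: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.events.size:
            if np.any(np.diff(self.events) <= 0):
                raise ValueError("events must be strictly increasing")
            if self.events[0] < 0 or self.events[-1] > self.duration_s:
                raise ValueError("events must lie within the recording span")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass(frozen=True)
class BandSpec:
    """A frequency band of interest with its Butterworth design order.

    ``filter_order`` is the order of each pass of the zero-phase
    (forward-backward) Butterworth band-pass; 4 per pass is the default.
    """

    name: str
    low_hz: float
    high_hz: float
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges ({self.low_hz}, {self.high_hz})")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    def validate_for_rate(self, rate_hz: float) -> None:
        if self.high_hz >= rate_hz / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high_hz} Hz >= Nyquist "
                f"({rate_hz / 2} Hz)"
            )


THETA = BandSpec("theta", 4.0, 8.0)
MU = BandSpec("mu", 8.0, 14.0)


@dataclass
class EpochedRecording:
    """Event-locked epochs: trials x channels x time, in microvolts.

    Sample 0 of each epoch corresponds to ``event + t_start_s``; the
    stimulus falls at index ``round(-t_start_s * rate_hz)``.
    """

    epochs: np.ndarray
    rate_hz: float
    t_start_s: float
    t_end_s: float
    channel_labels: list[str]
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (trials x channels x time)")
        if self.epochs.shape[0] < 1:
            raise ValueError("need at least one trial")
        expected = round((self.t_end_s - self.t_start_s) * self.rate_hz)
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != "
                f"round((t_end - t_start) * rate) = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


@dataclass(frozen=True)
class TimeWindow:
    """Analysis window relative to the stimulus, half-open [start_s, end_s)."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"empty window ({self.start_s}, {self.end_s})")

    def n_samples(self, rate_hz: float) -> int:
        return round((self.end_s - self.start_s) * rate_hz)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.start_s:g},{self.end_s:g})s"


#: The five standard analysis windows: prestimulus plus four post-stimulus
#: half-second frames.
DEFAULT_WINDOWS = (
    TimeWindow(-1.0, 0.0),
    TimeWindow(0.0, 0.5),
    TimeWindow(0.5, 1.0),
    TimeWindow(1.0, 1.5),
    TimeWindow(1.5, 2.0),
)


def notch_filter(
    rec: ContinuousRecording, freq_hz: float, quality: float = 30.0
) -> ContinuousRecording:
    """Reject a narrow-band (power-line) component with a zero-phase IIR notch.

    Parameters
    ----------
    rec : ContinuousRecording
    freq_hz : float
        Notch centre frequency, e.g. 50 for European mains interference.
    quality : float
        Quality factor of the notch (centre / bandwidth); default 30.
    """
    if not 0 < freq_hz < rec.rate_hz / 2:
        raise ValueError(
            f"notch frequency {freq_hz} Hz outside (0, Nyquist={rec.rate_hz / 2})"
        )
    b, a = signal.iirnotch(freq_hz, quality, fs=rec.rate_hz)
    filtered = signal.filtfilt(b, a, rec.samples, axis=-1)
    return replace(rec, samples=filtered)


def _band_sos(band: BandSpec, rate_hz: float) -> np.ndarray:
    band.validate_for_rate(rate_hz)
    return signal.butter(
        band.filter_order,
        [band.low_hz, band.high_hz],
        btype="bandpass",
        fs=rate_hz,
        output="sos",
    )


def bandpass(rec: ContinuousRecording, band: BandSpec) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward-backward (``sosfiltfilt``), doubling the
    effective roll-off and cancelling phase distortion -- latency of
    event-locked features is preserved.
    """
    sos = _band_sos(band, rec.rate_hz)
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return replace(rec, samples=filtered)


def epochize(
    rec: ContinuousRecording,
    t_start_s: float = -1.0,
    t_end_s: float = 2.0,
    band: BandSpec | None = None,
) -> EpochedRecording:
    """Cut one epoch per stimulus event, spanning [event+t_start, event+t_end).

    Events without ``|t_start_s|`` seconds of history or ``t_end_s`` seconds
    of future in the recording are dropped with a logged warning -- padding
    would corrupt downstream trajectory statistics.
    """
    if t_start_s >= t_end_s:
        raise ValueError("t_start_s must precede t_end_s")
    n_len = round((t_end_s - t_start_s) * rec.rate_hz)
    epochs = []
    for ev in rec.events:
        i0 = round((ev + t_start_s) * rec.rate_hz)
        if i0 < 0 or i0 + n_len > rec.n_samples:
            logger.warning(
                "dropping event at %.3f s: insufficient margin for "
                "[%g, %g] s epoch",
                ev,
                t_start_s,
                t_end_s,
            )
            continue
        epochs.append(rec.samples[:, i0 : i0 + n_len])
    if not epochs:
        raise ValueError("no events with sufficient margins; cannot epoch")
    return EpochedRecording(
        epochs=np.stack(epochs),
        rate_hz=rec.rate_hz,
        t_start_s=t_start_s,
        t_end_s=t_end_s,
        channel_labels=list(rec.channel_labels),
        band=band,
    )


def slice_window(ep: EpochedRecording, win: TimeWindow) -> np.ndarray:
    """Return the trials x channels x time block for one analysis window.

    Sample convention is half-open [start, end), so adjacent windows tile
    the epoch without duplicated samples.
    """
    tol = 0.5 / ep.rate_hz
    if win.start_s < ep.t_start_s - tol or win.end_s > ep.t_end_s + tol:
        raise ValueError(
            f"window {win} outside epoch [{ep.t_start_s}, {ep.t_end_s}] s"
        )
    i0 = round((win.start_s - ep.t_start_s) * ep.rate_hz)
    n = win.n_samples(ep.rate_hz)
    return ep.epochs[:, :, i0 : i0 + n]
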