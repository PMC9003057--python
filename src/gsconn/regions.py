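"""Sensor groups and 3-D state trajectories.

Each cortical area of interest is represented by exactly three sensors;
their band-limited series are treated as the three state variables of a
trajectory x(t) = (x1(t), x2(t), x3(t)) in a 3-D state space. Directed
functional connectivity between two areas is then assessed by how well
one area's trajectory predicts the other's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import TimeWindow

__all__ = [
    "RegionDefinition",
    "RegionTrajectory",
    "default_montage",
    "extract_trajectory",
]


def _norm_label(label: str) -> str:
    """Case-insensitive channel-label key (EDF headers vary: FCz vs Fcz)."""
    return label.strip().lower()


@dataclass(frozen=True)
class RegionDefinition:
    """A named group of exactly three 10-10 channels."""

    name: str
    channels: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.channels) != 3:
            raise ValueError(
                f"region {self.name!r} needs exactly 3 channels, "
                f"got {len(self.channels)}"
            )
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass
class RegionTrajectory:
    """3 x N state trajectory of one region within one analysis window.

    Columns from all trials are concatenated along time; ``trial_index``
    records which trial each sample column came from.
    """

    values: np.ndarray
    region: RegionDefinition
    window: TimeWindow | None = None
    trial_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise ValueError("trajectory must be a 3 x N array")
        if self.values.shape[1] < 1:
            raise ValueError("trajectory must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite")
        if self.trial_index is None:
            self.trial_index = np.zeros(self.values.shape[1], dtype=int)
        else:
            self.trial_index = np.asarray(self.trial_index, dtype=int)
            if self.trial_index.shape != (self.values.shape[1],):
                raise ValueError("trial_index must have one entry per column")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def default_montage() -> list[RegionDefinition]:
    """The five standard 3-sensor areas over parietal, frontal and motor cortex.

    P (parietal), F (frontal), MCL / MCR / MCZ (left, right and midline
    motor cortex): 15 distinct sensors in total.
    """
    return [
        RegionDefinition("P", ("P4", "Pz", "P3")),
        RegionDefinition("F", ("F4", "Fz", "F3")),
        RegionDefinition("MCL", ("Fc3", "C3", "Cp3")),
        RegionDefinition("MCR", ("Fc4", "C4", "Cp4")),
        RegionDefinition("MCZ", ("Fcz", "Cz", "Cpz")),
    ]


def check_disjoint(regions: list[RegionDefinition]) -> None:
    """Raise if any channel appears in more than one region."""
    seen: dict[str, str] = {}
    for reg in regions:
        for ch in reg.channels:
            key = _norm_label(ch)
            if key in seen:
                raise ValueError(
                    f"channel {ch} shared between regions "
                    f"{seen[key]} and {reg.name}"
                )
            seen[key] = reg.name


def extract_trajectory(
    windowed: np.ndarray,
    region: RegionDefinition,
    labels: list[str],
    window: TimeWindow | None = None,
) -> RegionTrajectory:
    """Build the region's 3 x N trajectory from a windowed epoch block.

    Parameters
    ----------
    windowed : ndarray, shape (trials, channels, time)
        Output of :func:`gsconn.preprocess.slice_window`.
    region : RegionDefinition
    labels : list of str
        Channel labels of the ``channels`` axis. Lookup is label-driven and
        case-insensitive, so channel storage order never matters.
    window : TimeWindow, optional
        Provenance metadata only.

    Trials are concatenated along time, so N = trials x window_samples;
    rows follow the region's channel order.
    """
    windowed = np.asarray(windowed, dtype=float)
    if windowed.ndim != 3:
        raise ValueError("windowed must be 3-D (trials x channels x time)")
    lut = {_norm_label(lab): i for i, lab in enumerate(labels)}
    rows = []
    for ch in region.channels:
        try:
            rows.append(lut[_norm_label(ch)])
        except KeyError:
            raise KeyError(
                f"channel {ch!r} of region {region.name} not found in recording"
            ) from None
    n_trials, _, n_time = windowed.shape
    # (trials, 3, time) -> (3, trials * time), trial-major along time
    values = windowed[:, rows, :].transpose(1, 0, 2).reshape(3, n_trials * n_time)
    trial_index = np.repeat(np.arange(n_trials), n_time)
    return RegionTrajectory(
        values=values, region=region, window=window, trial_index=trial_index
    )
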