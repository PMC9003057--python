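"""YAML analysis configuration shared by the CLI subcommands.

Defaults reproduce the reference study conditions: 250 Hz sampling,
50 Hz notch, theta (4-8 Hz) and mu (8-14 Hz) bands, epochs from -1 to
+2 s around each stimulus, five analysis windows with the designated
prestimulus window (-1, 0) s, the five 3-sensor regions, and the
3-10-10-3 softmax cross-predictor trained with Adam (lr 0.001, 1000
full-batch iterations, 50/50 split).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import TrainConfig
from .preprocess import BandSpec, TimeWindow, DEFAULT_WINDOWS, THETA, MU
from .regions import RegionDefinition, default_montage
from .synthetic import CouplingSpec, SimConfig

__all__ = ["AnalysisConfig", "SimGroupSpec", "load_config", "config_hash"]


@dataclass
class SimGroupSpec:
    """One simulated group: its size and ground-truth couplings."""

    name: str
    n_subjects: int
    couplings: list[CouplingSpec] = field(default_factory=list)


@dataclass
class AnalysisConfig:
    """Everything one run needs, resolved from a single YAML file."""

    seed: int = 0
    rate_hz: float = 250.0
    notch_hz: float = 50.0
    bands: list[BandSpec] = field(default_factory=lambda: [THETA, MU])
    epoch_start_s: float = -1.0
    epoch_end_s: float = 2.0
    windows: list[TimeWindow] = field(default_factory=lambda: list(DEFAULT_WINDOWS))
    prestimulus: TimeWindow = TimeWindow(-1.0, 0.0)
    regions: list[RegionDefinition] = field(default_factory=default_montage)
    model: TrainConfig = field(default_factory=TrainConfig)
    alpha: float = 0.05
    family: str = "per_window"
    groups: dict[str, list[str]] = field(default_factory=dict)
    sim_groups: list[SimGroupSpec] = field(default_factory=list)
    sim_n_trials: int = 30
    sim_noise_sigma: float = 0.05
    sim_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.prestimulus not in self.windows:
            raise ValueError(
                "config must designate exactly one prestimulus window that is "
                "also listed under windows"
            )

    def sim_config(self, group: SimGroupSpec, band: BandSpec | None = None) -> SimConfig:
        return SimConfig(
            n_trials=self.sim_n_trials,
            rate_hz=self.rate_hz,
            band=band if band is not None else self.bands[0],
            regions=list(self.regions),
            couplings=list(group.couplings),
            noise_sigma=self.sim_noise_sigma,
            seed=self.seed,
            between_subject_jitter=self.sim_jitter,
        )


def _parse_band(entry: dict) -> BandSpec:
    return BandSpec(
        name=entry["name"],
        low_hz=float(entry["low"]),
        high_hz=float(entry["high"]),
        filter_order=int(entry.get("order", 4)),
    )


def _parse_window(pair) -> TimeWindow:
    return TimeWindow(float(pair[0]), float(pair[1]))


def _parse_coupling(entry: dict) -> CouplingSpec:
    sbw = tuple(
        (TimeWindow(float(a), float(b)), float(s))
        for a, b, s in entry.get("strengths", [])
    )
    return CouplingSpec(
        drive=entry["drive"],
        response=entry["response"],
        link=entry.get("link", "affine"),
        baseline_strength=float(entry.get("baseline", 0.0)),
        lag_s=float(entry.get("lag_s", 0.0)),
        strength_by_window=sbw,
    )


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse the YAML config; every key is optional and falls back to the
    study-condition defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "rate_hz" in raw:
        kwargs["rate_hz"] = float(raw["rate_hz"])
    if "notch_hz" in raw:
        kwargs["notch_hz"] = float(raw["notch_hz"])
    if "bands" in raw:
        kwargs["bands"] = [_parse_band(b) for b in raw["bands"]]
    if "epoch" in raw:
        kwargs["epoch_start_s"] = float(raw["epoch"]["start_s"])
        kwargs["epoch_end_s"] = float(raw["epoch"]["end_s"])
    if "windows" in raw:
        kwargs["windows"] = [_parse_window(w) for w in raw["windows"]]
    if "prestimulus" in raw:
        kwargs["prestimulus"] = _parse_window(raw["prestimulus"])
    if "regions" in raw:
        kwargs["regions"] = [
            RegionDefinition(r["name"], tuple(r["channels"])) for r in raw["regions"]
        ]
    model_raw = dict(raw.get("model", {}))
    if "hidden_layers" in model_raw:
        model_raw["hidden_layers"] = tuple(model_raw["hidden_layers"])
    kwargs["model"] = TrainConfig(seed=int(raw.get("seed", 0)), **model_raw)
    stats_raw = raw.get("stats", {})
    if "alpha" in stats_raw:
        kwargs["alpha"] = float(stats_raw["alpha"])
    if "family" in stats_raw:
        kwargs["family"] = stats_raw["family"]
    if "groups" in raw:
        kwargs["groups"] = {
            name: [str(p) for p in paths] for name, paths in raw["groups"].items()
        }
    sim_raw = raw.get("simulate", {})
    if "n_trials" in sim_raw:
        kwargs["sim_n_trials"] = int(sim_raw["n_trials"])
    if "noise_sigma" in sim_raw:
        kwargs["sim_noise_sigma"] = float(sim_raw["noise_sigma"])
    if "jitter" in sim_raw:
        kwargs["sim_jitter"] = float(sim_raw["jitter"])
    if "groups" in sim_raw:
        kwargs["sim_groups"] = [
            SimGroupSpec(
                name=name,
                n_subjects=int(spec["n_subjects"]),
                couplings=[_parse_coupling(c) for c in spec.get("couplings", [])],
            )
            for name, spec in sim_raw["groups"].items()
        ]
    return AnalysisConfig(**kwargs)


def config_hash(path: str | Path) -> str:
    """sha256 of the raw config text, recorded in run manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
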