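"""Event-locked surrogate recordings with known directed couplings.

Each simulated subject is a continuous multichannel recording in which
five 3-channel regions carry band-limited Gaussian noise, and selected
region pairs are coupled through an instantaneous (memoryless) function
of the drive region's 3-D state:

    y_d(t) = c(t) * F_d(x(t)) + (1 - c(t)) * eta_d(t),

where c(t) follows a per-window strength schedule relative to each
stimulus event and eta is independent band-limited noise. The (1 - c)
mixing keeps the response variance roughly independent of the coupling
strength, so changes in estimated R2 reflect coupling, not amplitude.
Events are spaced 6-8 s apart, mirroring typical inter-trial pauses in
cued motor-task protocols.

The generator exists so that every pipeline stage and every statistical
property can be exercised against known ground truth; it makes no claim
of biophysical realism (no neural mass dynamics, volume conduction or
1/f background).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .preprocess import BandSpec, ContinuousRecording, TimeWindow, THETA, _band_sos
from .regions import RegionDefinition, check_disjoint, default_montage

__all__ = ["CouplingSpec", "SimConfig", "simulate_subject", "simulate_group"]

LINK_FUNCTIONS = ("affine", "tanh", "quadratic")


@dataclass(frozen=True)
class CouplingSpec:
    """A directed ground-truth coupling with a window-dependent strength.

    ``strength_by_window`` maps analysis windows (relative to each event)
    to coupling strengths in [0, 1]; outside all windows the strength is
    ``baseline_strength``. ``link`` selects the functional form F: affine,
    tanh (saturating) or quadratic, with seeded random parameters.

    ``lag_s`` delays the response by a fixed interval: y(t) depends on
    x(t - lag_s). The cross-predictor models instantaneous dependence
    only, so a sufficiently lagged coupling is a realistic negative — a
    genuine dependence the estimator is not built to see.
    """

    drive: str
    response: str
    strength_by_window: tuple[tuple[TimeWindow, float], ...] = ()
    link: str = "affine"
    baseline_strength: float = 0.0
    lag_s: float = 0.0

    def __post_init__(self) -> None:
        if self.drive == self.response:
            raise ValueError("a region cannot drive itself")
        if self.link not in LINK_FUNCTIONS:
            raise ValueError(f"link must be one of {LINK_FUNCTIONS}")
        sbw = tuple(
            (w, float(s)) for w, s in dict(self.strength_by_window).items()
        )
        for w, s in sbw:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"strength {s} for window {w} outside [0, 1]")
        if not 0.0 <= self.baseline_strength <= 1.0:
            raise ValueError("baseline_strength outside [0, 1]")
        if self.lag_s < 0:
            raise ValueError("lag_s must be >= 0")
        object.__setattr__(self, "strength_by_window", sbw)

    @classmethod
    def constant(
        cls, drive: str, response: str, strength: float, link: str = "affine"
    ) -> "CouplingSpec":
        """A coupling with the same strength at all times."""
        return cls(
            drive=drive,
            response=response,
            strength_by_window=(),
            link=link,
            baseline_strength=strength,
        )


@dataclass
class SimConfig:
    """Study-condition defaults for one simulated subject or group.

    Defaults mirror the reference acquisition protocol: 30 trials
    sampled at 250 Hz, five 3-sensor regions, theta-band (4-8 Hz)
    signals, events 6-8 s apart.
    """

    n_trials: int = 30
    rate_hz: float = 250.0
    band: BandSpec = THETA
    regions: list[RegionDefinition] = field(default_factory=default_montage)
    couplings: list[CouplingSpec] = field(default_factory=list)
    noise_sigma: float = 0.05
    seed: int = 0
    amplitude_uv: float = 10.0
    gap_range_s: tuple[float, float] = (6.0, 8.0)
    between_subject_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        check_disjoint(self.regions)


def _toposort(
    regions: list[RegionDefinition], couplings: list[CouplingSpec]
) -> list[RegionDefinition]:
    """Order regions so every drive precedes its response; reject cycles
    and multi-parent nodes (generation is feed-forward, one drive per
    response)."""
    names = [r.name for r in regions]
    parent: dict[str, str] = {}
    for c in couplings:
        if c.drive not in names or c.response not in names:
            raise ValueError(f"coupling {c.drive}->{c.response} names unknown region")
        if c.response in parent:
            raise ValueError(
                f"region {c.response} has multiple incoming couplings; "
                "generation supports one drive per response"
            )
        parent[c.response] = c.drive
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(nm: str) -> None:
        if state.get(nm) == 1:
            raise ValueError("coupling graph contains a cycle")
        if state.get(nm) == 2:
            return
        state[nm] = 1
        if nm in parent:
            visit(parent[nm])
        state[nm] = 2
        order.append(nm)

    for nm in names:
        visit(nm)
    by_name = {r.name: r for r in regions}
    return [by_name[nm] for nm in order]


def _bandlimited_noise(
    rng: np.random.Generator, n_rows: int, n_samples: int, band: BandSpec, rate_hz: float
) -> np.ndarray:
    """Unit-variance rows of Gaussian noise band-passed into ``band``."""
    sos = _band_sos(band, rate_hz)
    white = rng.standard_normal((n_rows, n_samples))
    x = _signal.sosfiltfilt(sos, white, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)


def _apply_link(link: str, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map the standardized 3 x N drive state through a seeded random F."""
    a = rng.normal(0.0, 1.0, size=(3, 3))
    # keep the map well-conditioned so the relation is learnable
    a += np.sign(np.linalg.det(a) or 1.0) * 0.5 * np.eye(3)
    if link == "affine":
        b = rng.normal(0.0, 0.1, size=(3, 1))
        u = a @ x + b
    elif link == "tanh":
        u = np.tanh(a @ x)
    else:  # quadratic
        u = (a @ x) ** 2
    return _standardize(u)


def _coupling_profile(
    n_samples: int,
    rate_hz: float,
    events: np.ndarray,
    spec: CouplingSpec,
) -> np.ndarray:
    """Per-sample coupling strength c(t) from the window schedule."""
    c = np.full(n_samples, spec.baseline_strength)
    for win, strength in spec.strength_by_window:
        for ev in events:
            i0 = max(0, round((ev + win.start_s) * rate_hz))
            i1 = min(n_samples, round((ev + win.end_s) * rate_hz))
            c[i0:i1] = strength
    return c


def simulate_subject(
    cfg: SimConfig,
) -> tuple[ContinuousRecording, list[CouplingSpec]]:
    """Generate one subject's continuous recording plus its ground truth.

    Uncoupled regions carry independent band-limited noise; each coupled
    response region mixes an instantaneous function of its drive's state
    with fresh noise according to the window schedule. The same SimConfig
    reproduces the identical recording.
    """
    order = _toposort(cfg.regions, cfg.couplings)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 11]))

    lo, hi = cfg.gap_range_s
    gaps = rng.uniform(lo, hi, size=cfg.n_trials)
    events = 3.0 + np.cumsum(gaps) - gaps[0]
    n_samples = round((events[-1] + 3.0) * cfg.rate_hz)

    incoming = {c.response: c for c in cfg.couplings}
    signals: dict[str, np.ndarray] = {}
    for region in order:
        eta = _bandlimited_noise(rng, 3, n_samples, cfg.band, cfg.rate_hz)
        spec = incoming.get(region.name)
        if spec is None:
            clean = eta
        else:
            x = _standardize(signals[spec.drive])
            if spec.lag_s > 0:
                shift = round(spec.lag_s * cfg.rate_hz)
                x = np.roll(x, shift, axis=-1)
            f_of_x = _apply_link(spec.link, x, rng)
            c = _coupling_profile(n_samples, cfg.rate_hz, events, spec)
            clean = c * f_of_x + (1.0 - c) * eta
        meas_noise = cfg.noise_sigma * _bandlimited_noise(
            rng, 3, n_samples, cfg.band, cfg.rate_hz
        )
        signals[region.name] = cfg.amplitude_uv * (clean + meas_noise)

    labels: list[str] = []
    rows: list[np.ndarray] = []
    for region in cfg.regions:
        labels.extend(region.channels)
        rows.append(signals[region.name])
    rec = ContinuousRecording(
        samples=np.vstack(rows),
        rate_hz=cfg.rate_hz,
        channel_labels=labels,
        events=events,
    )
    return rec, list(cfg.couplings)


def _jitter_couplings(
    couplings: list[CouplingSpec], sd: float, rng: np.random.Generator
) -> list[CouplingSpec]:
    if sd == 0:
        return list(couplings)
    out = []
    for c in couplings:
        sbw = tuple(
            (w, float(np.clip(s + rng.normal(0.0, sd), 0.0, 1.0)))
            for w, s in c.strength_by_window
        )
        base = float(np.clip(c.baseline_strength + rng.normal(0.0, sd), 0.0, 1.0))
        out.append(replace(c, strength_by_window=sbw, baseline_strength=base))
    return out


def simulate_group(
    cfg: SimConfig, n_subjects: int
) -> list[tuple[ContinuousRecording, list[CouplingSpec]]]:
    """Generate a group of subjects sharing one coupling topology.

    Per-subject seeds derive from (cfg.seed, subject index); coupling
    strengths are jittered across subjects with standard deviation
    ``cfg.between_subject_jitter`` (clipped to [0, 1]) to create
    realistic between-subject variance.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    subjects = []
    for k in range(n_subjects):
        ss = np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 23, k])
        subj_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        jrng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 29, k])
        )
        couplings = _jitter_couplings(
            cfg.couplings, cfg.between_subject_jitter, jrng
        )
        sub_cfg = replace(cfg, seed=subj_seed, couplings=couplings)
        subjects.append(simulate_subject(sub_cfg))
    return subjects
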