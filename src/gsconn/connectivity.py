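"""Pairwise R-squared connectivity matrices and baseline correction.

Connectivity between a drive area and a response area is the validation
R-squared of the cross-predictor, pooled over the three output
dimensions:

    R2 = 1 - sum_d sum_i (y_d(t_i) - y'_d(t_i))^2
           / sum_d sum_i (y_d(t_i) - ybar_d)^2

one pooled ratio over all D*N points, not an average of per-dimension
scores. It is at most 1 and unbounded below. The 5x5 matrix of all
ordered region pairs, computed per subject / band / time window, is the
time-resolved connectivity network; subtracting the prestimulus matrix
isolates event-related change.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TrainConfig, fit_batch, normalize01
from .preprocess import BandSpec, TimeWindow
from .regions import RegionTrajectory

__all__ = [
    "R2Score",
    "ConnectivityMatrix",
    "r2_score",
    "pairwise_matrix",
    "baseline_correct",
    "pair_seed",
    "matrices_to_frame",
    "frame_to_matrices",
    "write_matrices_csv",
    "read_matrices_csv",
    "write_matrices_json",
    "read_matrices_json",
]


@dataclass(frozen=True)
class R2Score:
    """Pooled multivariate coefficient of determination (<= 1)."""

    value: float
    d: int
    n: int


def r2_score(actual: np.ndarray, predicted: np.ndarray) -> R2Score:
    """Pooled R-squared between actual and predicted D x N trajectories.

    The residual sum of squares over all D*N points is divided by the
    pooled squared deviation of the actual values from their per-dimension
    means. Perfect prediction scores 1; predicting each dimension's mean
    scores exactly 0; worse-than-mean predictions go negative.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: actual {a.shape}, predicted {p.shape}")
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("need a D x N array with N >= 2")
    resid = np.sum((a - p) ** 2)
    total = np.sum((a - a.mean(axis=1, keepdims=True)) ** 2)
    if total <= 0:
        raise ValueError("actual trajectory has zero total variance")
    return R2Score(value=float(1.0 - resid / total), d=a.shape[0], n=a.shape[1])


@dataclass
class ConnectivityMatrix:
    """R x R directed connectivity: entry (i, j) = R2 for drive i -> response j.

    The diagonal is masked (NaN): self-prediction is trivially near-perfect
    and would distort group statistics.
    """

    values: np.ndarray
    regions: list[str]
    band: BandSpec | None = None
    window: TimeWindow | None = None
    subject_id: str = ""
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = len(self.regions)
        if self.values.shape != (r, r):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{r} regions"
            )
        np.fill_diagonal(self.values, np.nan)

    def offdiag(self) -> np.ndarray:
        """Off-diagonal entries in row-major (drive, response) order."""
        r = len(self.regions)
        mask = ~np.eye(r, dtype=bool)
        return self.values[mask]

    def get(self, drive: str, response: str) -> float:
        i = self.regions.index(drive)
        j = self.regions.index(response)
        return float(self.values[i, j])


def pair_seed(
    base_seed: int,
    i: int,
    j: int,
    band: str = "",
    window_index: int = 0,
    subject: str = "",
) -> int:
    """Deterministic per-fit training seed.

    Derived by hashing (base seed, subject, band, window index, drive
    index, response index) through a SeedSequence so every ordered pair
    of every matrix trains independently yet reproducibly. The subject
    must participate in the hash: sharing initialization and split seeds
    across a group correlates the estimator's finite-sample bias across
    subjects, which a paired test would then mistake for signal.
    """
    digest = hashlib.sha256(f"{subject}|{band}".encode()).digest()
    label_key = int.from_bytes(digest[:4], "little")
    ss = np.random.SeedSequence(
        [int(base_seed) & 0x7FFFFFFF, label_key, window_index, i, j]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def pairwise_matrix(
    trajectories: dict[str, RegionTrajectory],
    cfg: TrainConfig = TrainConfig(),
    band: BandSpec | None = None,
    window: TimeWindow | None = None,
    window_index: int = 0,
    subject_id: str = "",
    symmetrize: bool = False,
) -> ConnectivityMatrix:
    """Fit every ordered region pair and assemble the connectivity matrix.

    Each pair (i, j), i != j, is min-max normalized per trajectory, then a
    fresh cross-predictor i -> j is trained with a seed derived from
    (cfg.seed, subject_id, band, window_index, i, j); the held-out
    validation R-squared is stored at entry (i, j). With ``symmetrize`` the matrix is
    replaced by max(M, M.T) (off by default: the estimator is directed).
    """
    names = list(trajectories)
    if len(names) < 2:
        raise ValueError("need at least 2 regions")
    n_set = {trajectories[nm].n_samples for nm in names}
    if len(n_set) > 1:
        raise ValueError(f"trajectories have unequal sample counts: {n_set}")

    normed = {nm: normalize01(trajectories[nm])[0] for nm in names}
    r = len(names)
    values = np.full((r, r), np.nan)
    band_name = band.name if band is not None else ""
    pairs = [(i, j) for i in range(r) for j in range(r) if i != j]
    drives = [normed[names[i]] for i, _ in pairs]
    targets = [normed[names[j]] for _, j in pairs]
    cfgs = [
        replace(
            cfg,
            seed=pair_seed(
                cfg.seed,
                i,
                j,
                band=band_name,
                window_index=window_index,
                subject=subject_id,
            ),
        )
        for i, j in pairs
    ]
    try:
        outcomes = fit_batch(drives, targets, cfgs)
    except Exception as exc:
        raise RuntimeError(
            f"pairwise fits failed (band={band_name or 'n/a'}, "
            f"window={window}): {exc}"
        ) from exc
    for (i, j), outcome in zip(pairs, outcomes):
        values[i, j] = outcome.r2_validation
    if symmetrize:
        values = np.fmax(values, values.T)
    return ConnectivityMatrix(
        values=values,
        regions=names,
        band=band,
        window=window,
        subject_id=subject_id,
    )


def baseline_correct(
    matrices: dict[TimeWindow, ConnectivityMatrix],
    prestim_window: TimeWindow,
) -> dict[TimeWindow, ConnectivityMatrix]:
    """Subtract the prestimulus matrix from every window (itself included).

    The corrected prestimulus matrix is exactly zero off-diagonal, and the
    correction is idempotent: a second application subtracts zero.
    """
    if prestim_window not in matrices:
        raise KeyError(f"prestimulus window {prestim_window} not in matrices")
    base = matrices[prestim_window]
    corrected = {}
    for win, mat in matrices.items():
        if mat.regions != base.regions:
            raise ValueError(
                f"region order mismatch between {win} and prestimulus matrix"
            )
        corrected[win] = ConnectivityMatrix(
            values=mat.values - base.values,
            regions=list(mat.regions),
            band=mat.band,
            window=mat.window,
            subject_id=mat.subject_id,
            baseline_corrected=True,
        )
    return corrected


# ---------------------------------------------------------------------------
# long-format serialization


def matrices_to_frame(
    matrices: dict[TimeWindow, ConnectivityMatrix]
) -> pd.DataFrame:
    """Long-format table: one row per (window, drive, response) link."""
    rows = []
    for win, mat in matrices.items():
        band = mat.band.name if mat.band is not None else ""
        for i, src in enumerate(mat.regions):
            for j, dst in enumerate(mat.regions):
                if i == j:
                    continue
                rows.append(
                    {
                        "subject": mat.subject_id,
                        "band": band,
                        "window_start": win.start_s,
                        "window_end": win.end_s,
                        "drive": src,
                        "response": dst,
                        "r2": mat.values[i, j],
                        "corrected": mat.baseline_corrected,
                    }
                )
    return pd.DataFrame(rows)


def frame_to_matrices(
    frame: pd.DataFrame, band: BandSpec | None = None
) -> dict[TimeWindow, ConnectivityMatrix]:
    """Rebuild per-window matrices from the long-format table.

    If ``band`` is given only rows of that band are used; otherwise the
    table must contain a single band.
    """
    df = frame
    if band is not None:
        df = df[df["band"] == band.name]
    elif df["band"].nunique() > 1:
        raise ValueError("table contains several bands; pass band explicitly")
    if df.empty:
        raise ValueError("no rows to rebuild matrices from")
    regions = list(dict.fromkeys(df["drive"]))
    out: dict[TimeWindow, ConnectivityMatrix] = {}
    for (ws, we), sub in df.groupby(["window_start", "window_end"], sort=True):
        win = TimeWindow(float(ws), float(we))
        r = len(regions)
        values = np.full((r, r), np.nan)
        for _, row in sub.iterrows():
            i = regions.index(row["drive"])
            j = regions.index(row["response"])
            values[i, j] = row["r2"]
        out[win] = ConnectivityMatrix(
            values=values,
            regions=regions,
            band=band,
            window=win,
            subject_id=str(sub["subject"].iloc[0]),
            baseline_corrected=bool(sub["corrected"].iloc[0]),
        )
    return out


def write_matrices_csv(
    matrices: dict[TimeWindow, ConnectivityMatrix], path: str | Path
) -> None:
    matrices_to_frame(matrices).to_csv(path, index=False)


def read_matrices_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"subject": str}, keep_default_na=True, na_values=[""]
    )


def write_matrices_json(
    matrices: dict[TimeWindow, ConnectivityMatrix], path: str | Path
) -> None:
    """Per-subject JSON archive; lossless round trip with the reader."""
    payload = []
    for win, mat in matrices.items():
        payload.append(
            {
                "subject": mat.subject_id,
                "band": mat.band.name if mat.band is not None else None,
                "window": [win.start_s, win.end_s],
                "regions": mat.regions,
                "corrected": mat.baseline_corrected,
                "values": [
                    [None if np.isnan(v) else v for v in row]
                    for row in mat.values
                ],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_matrices_json(
    path: str | Path, band: BandSpec | None = None
) -> dict[TimeWindow, ConnectivityMatrix]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for entry in payload:
        win = TimeWindow(*entry["window"])
        values = np.array(
            [[np.nan if v is None else v for v in row] for row in entry["values"]]
        )
        out[win] = ConnectivityMatrix(
            values=values,
            regions=list(entry["regions"]),
            band=band,
            window=win,
            subject_id=entry["subject"] or "",
            baseline_corrected=bool(entry["corrected"]),
        )
    return out
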