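"""Group-level inference on connectivity matrices.

Within a group, each post-stimulus window is contrasted against the
prestimulus window with a paired t-test per directed link; between
groups, each link is contrasted with an unpaired (Welch) t-test. p-values
are Bonferroni-corrected over the family of links tested together — by
default the 20 directed links of one window and band.

Paired contrasts operate on uncorrected matrices: the baseline
subtraction is common to both operands of the paired difference, so it
cancels exactly and the test is identical either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import ConnectivityMatrix
from .preprocess import BandSpec, TimeWindow

__all__ = [
    "GroupStack",
    "within_group_test",
    "between_group_test",
    "bonferroni",
    "plot_significance",
]

FAMILIES = ("per_window", "per_band", "global")


@dataclass
class GroupStack:
    """Connectivity values of one group: subjects x windows x region x region.

    All subjects must share the region order, window set and band.
    """

    values: np.ndarray
    windows: list[TimeWindow]
    regions: list[str]
    group_label: str = ""
    band: BandSpec | None = None
    prestim_window: TimeWindow | None = None
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = len(self.regions)
        expected = (self.values.shape[0], len(self.windows), r, r)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"(subjects, windows, R, R) = {expected}"
            )
        if self.values.shape[0] < 2:
            raise ValueError("a group needs at least 2 subjects")
        if self.prestim_window is None:
            self.prestim_window = self.windows[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_matrices(
        cls,
        per_subject: list[dict[TimeWindow, ConnectivityMatrix]],
        group_label: str = "",
        prestim_window: TimeWindow | None = None,
    ) -> "GroupStack":
        """Stack per-subject window->matrix maps into one tensor."""
        if len(per_subject) < 2:
            raise ValueError("a group needs at least 2 subjects")
        first = per_subject[0]
        windows = sorted(first, key=lambda w: (w.start_s, w.end_s))
        regions = list(first[windows[0]].regions)
        band = first[windows[0]].band
        tensors = []
        for subj in per_subject:
            if sorted(subj, key=lambda w: (w.start_s, w.end_s)) != windows:
                raise ValueError("subjects have mismatched window sets")
            mats = []
            for win in windows:
                mat = subj[win]
                if list(mat.regions) != regions:
                    raise ValueError("subjects have mismatched region order")
                mats.append(mat.values)
            tensors.append(np.stack(mats))
        subject_ids = [subj[windows[0]].subject_id for subj in per_subject]
        return cls(
            values=np.stack(tensors),
            windows=windows,
            regions=regions,
            group_label=group_label,
            band=band,
            prestim_window=prestim_window,
            subject_ids=subject_ids,
        )

    def window_index(self, window: TimeWindow) -> int:
        try:
            return self.windows.index(window)
        except ValueError:
            raise KeyError(f"window {window} not in stack") from None


def _link_index(regions: list[str]):
    """Ordered (i, j, drive, response) for all directed links."""
    for i, src in enumerate(regions):
        for j, dst in enumerate(regions):
            if i != j:
                yield i, j, src, dst


def bonferroni(p_raw: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni-corrected p-values, capped at 1."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * m)


def _family_size(stack: GroupStack, family: str) -> int:
    r = len(stack.regions)
    links = r * (r - 1)
    if family == "per_window":
        return links
    if family == "per_band":
        # all post-stimulus windows of one band share the family
        return links * max(1, len(stack.windows) - 1)
    if family == "global":
        return links * max(1, len(stack.windows) - 1) * 2
    raise ValueError(f"unknown correction family {family!r}; use one of {FAMILIES}")


def _finalize(
    frame: pd.DataFrame,
    alpha: float,
    m: int,
    contrast: str,
    window: TimeWindow,
    band: BandSpec | None,
) -> pd.DataFrame:
    frame["p_corrected"] = bonferroni(frame["p_raw"].to_numpy(), m)
    frame["significant"] = frame["p_corrected"] < alpha
    frame.attrs.update(
        {
            "contrast": contrast,
            "window": (window.start_s, window.end_s),
            "alpha": alpha,
            "family_size": m,
            "band": band.name if band is not None else "",
        }
    )
    return frame


def within_group_test(
    stack: GroupStack,
    window: TimeWindow,
    alpha: float = 0.05,
    family: str = "per_window",
) -> pd.DataFrame:
    """Paired t-test of each link's R2 in ``window`` against prestimulus.

    Expects uncorrected matrices (the paired difference against the
    prestimulus value IS the baseline contrast). Links whose paired
    differences have zero variance are flagged degenerate with t = 0 and
    p = 1. Returns one row per directed link with columns
    (drive, response, t, p_raw, p_corrected, significant, degenerate).
    """
    if stack.n_subjects < 3:
        raise ValueError("paired contrast needs at least 3 subjects")
    prestim = stack.prestim_window
    if window == prestim:
        raise ValueError("cannot contrast the prestimulus window with itself")
    wi = stack.window_index(window)
    pi = stack.window_index(prestim)
    rows = []
    for i, j, src, dst in _link_index(stack.regions):
        post = stack.values[:, wi, i, j]
        pre = stack.values[:, pi, i, j]
        diffs = post - pre
        if np.allclose(diffs.std(ddof=1), 0.0):
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p = sps.ttest_rel(post, pre)
            degenerate = False
        rows.append(
            {
                "drive": src,
                "response": dst,
                "mean_diff": float(diffs.mean()),
                "t": float(t),
                "p_raw": float(p),
                "degenerate": degenerate,
            }
        )
    frame = pd.DataFrame(rows)
    m = _family_size(stack, family)
    return _finalize(frame, alpha, m, "within", window, stack.band)


def between_group_test(
    stack_a: GroupStack,
    stack_b: GroupStack,
    window: TimeWindow,
    alpha: float = 0.05,
    family: str = "per_window",
) -> pd.DataFrame:
    """Welch's unpaired t-test of each link's R2 between two groups.

    Positive t means group A exceeds group B on that link. Both stacks
    must share windows, regions and band.
    """
    if stack_a.regions != stack_b.regions:
        raise ValueError("groups have mismatched region order")
    if stack_a.windows != stack_b.windows:
        raise ValueError("groups have mismatched window sets")
    if stack_a.n_subjects < 2 or stack_b.n_subjects < 2:
        raise ValueError("each group needs at least 2 subjects")
    wi = stack_a.window_index(window)
    rows = []
    for i, j, src, dst in _link_index(stack_a.regions):
        a = stack_a.values[:, wi, i, j]
        b = stack_b.values[:, wi, i, j]
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
            degenerate = False
        rows.append(
            {
                "drive": src,
                "response": dst,
                "mean_diff": float(a.mean() - b.mean()),
                "t": float(t),
                "p_raw": float(p),
                "degenerate": degenerate,
            }
        )
    frame = pd.DataFrame(rows)
    m = _family_size(stack_a, family)
    return _finalize(frame, alpha, m, "between", window, stack_a.band)


def plot_significance(
    results: pd.DataFrame,
    regions: list[str],
    ax=None,
    title: str | None = None,
):
    """Heatmap of signed significant links for one window (optional view).

    Cell (i, j) shows the t statistic of drive i -> response j where the
    corrected p is below alpha, masked elsewhere — a matrix rendering of
    the usual significance topography figures.
    """
    import matplotlib.pyplot as plt

    r = len(regions)
    grid = np.full((r, r), np.nan)
    for _, row in results.iterrows():
        if row["significant"]:
            i = regions.index(row["drive"])
            j = regions.index(row["response"])
            grid[i, j] = row["t"]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    vmax = np.nanmax(np.abs(grid)) if np.any(np.isfinite(grid)) else 1.0
    im = ax.imshow(grid, cmap="coolwarm", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(r), regions)
    ax.set_yticks(range(r), regions)
    ax.set_xlabel("response")
    ax.set_ylabel("drive")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, shrink=0.8, label="t (corrected p < α)")
    return ax
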