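"""Simulation-study harness: simulated groups -> connectivity stacks.

Monte-Carlo studies (statistical calibration, power analyses) need the
full pipeline — simulate, filter, epoch, slice, fit all ordered pairs —
repeated over many subjects and repetitions. Running each subject's
matrix separately wastes most of its time on Python overhead for tiny
networks, so this harness collects every (subject, pair) fit of one
analysis window into a single stacked :func:`gsconn.model.fit_batch`
call. Per-pair seeds are derived exactly as in
:func:`gsconn.connectivity.pairwise_matrix`, so the resulting stack is
the one the sequential pipeline would produce.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .connectivity import pair_seed, pairwise_matrix
from .model import TrainConfig, fit_batch, normalize01
from .preprocess import TimeWindow, bandpass, epochize, notch_filter, slice_window
from .regions import RegionDefinition, extract_trajectory
from .stats import GroupStack, within_group_test
from .synthetic import CouplingSpec, SimConfig, simulate_group, simulate_subject

__all__ = [
    "simulate_group_stack",
    "detectability_study",
    "monotonicity_study",
    "fwe_study",
    "power_study",
]


def simulate_group_stack(
    sim_cfg: SimConfig,
    n_subjects: int,
    windows: list[TimeWindow],
    model_cfg: TrainConfig,
    prestim_window: TimeWindow | None = None,
    notch_hz: float | None = 50.0,
    group_label: str = "",
) -> GroupStack:
    """Simulate a group and estimate its full connectivity stack.

    The epoch span is the hull of ``windows``. Returns the uncorrected
    subjects x windows x R x R stack ready for the group tests.
    """
    epoch_start = min(w.start_s for w in windows)
    epoch_end = max(w.end_s for w in windows)
    regions = sim_cfg.regions
    r = len(regions)
    names = [reg.name for reg in regions]
    pairs = [(i, j) for i in range(r) for j in range(r) if i != j]

    subject_ids = [f"{group_label}_s{k:02d}" for k in range(n_subjects)]
    subjects = simulate_group(sim_cfg, n_subjects)
    # normalized trajectories per subject per window
    per_subject: list[list[dict[int, np.ndarray]]] = []
    for rec, _ in subjects:
        if notch_hz is not None:
            rec = notch_filter(rec, notch_hz)
        filtered = bandpass(rec, sim_cfg.band)
        epochs = epochize(filtered, epoch_start, epoch_end, band=sim_cfg.band)
        by_window = []
        for win in windows:
            block = slice_window(epochs, win)
            normed = {}
            for ri, reg in enumerate(regions):
                traj = extract_trajectory(block, reg, epochs.channel_labels, window=win)
                normed[ri] = normalize01(traj)[0]
            by_window.append(normed)
        per_subject.append(by_window)

    values = np.full((n_subjects, len(windows), r, r), np.nan)
    for wi in range(len(windows)):
        drives, targets, cfgs, where = [], [], [], []
        for si in range(n_subjects):
            normed = per_subject[si][wi]
            for i, j in pairs:
                drives.append(normed[i])
                targets.append(normed[j])
                cfgs.append(
                    replace(
                        model_cfg,
                        seed=pair_seed(
                            model_cfg.seed,
                            i,
                            j,
                            band=sim_cfg.band.name,
                            window_index=wi,
                            subject=subject_ids[si],
                        ),
                    )
                )
                where.append((si, i, j))
        outcomes = fit_batch(drives, targets, cfgs)
        for (si, i, j), out in zip(where, outcomes):
            values[si, wi, i, j] = out.r2_validation

    return GroupStack(
        values=values,
        windows=list(windows),
        regions=names,
        group_label=group_label,
        band=sim_cfg.band,
        prestim_window=prestim_window if prestim_window is not None else windows[0],
        subject_ids=subject_ids,
    )


def _windowed_trajectories(rec, band, window, regions, notch_hz=50.0):
    """Notch, band-pass, epoch and slice one analysis window."""
    filtered = bandpass(notch_filter(rec, notch_hz), band)
    epochs = epochize(filtered, window.start_s, window.end_s, band=band)
    block = slice_window(epochs, window)
    return {
        reg.name: extract_trajectory(block, reg, epochs.channel_labels, window=window)
        for reg in regions
    }


def detectability_study(
    n_seeds: int = 10,
    base_seed: int = 0,
    n_trials: int = 30,
    noise_sigma: float = 0.05,
    window: TimeWindow = TimeWindow(0.0, 0.5),
    model_cfg: TrainConfig = TrainConfig(),
):
    """Single strength-1 affine link P->MCZ against an uncoupled background.

    For each seed: simulate one subject at the study conditions (30 trials,
    250 Hz, theta band, measurement noise sigma), run the full pipeline for
    one post-stimulus window and fit the complete 5x5 matrix. Reports the
    coupled entry, the largest entry among pairs with no link in either
    direction (the reverse direction of an invertible coupling is itself
    functionally dependent, so it is not a false positive), and whether the
    coupled entry clears 0.8 and the spurious ceiling by 0.3.

    Returns a list of per-seed dicts.
    """
    results = []
    for s in range(n_seeds):
        seed = base_seed + s
        sim = SimConfig(
            seed=seed,
            n_trials=n_trials,
            noise_sigma=noise_sigma,
            couplings=[CouplingSpec.constant("P", "MCZ", 1.0)],
        )
        rec, _ = simulate_subject(sim)
        trajs = _windowed_trajectories(rec, sim.band, window, sim.regions)
        mat = pairwise_matrix(
            trajs,
            replace(model_cfg, seed=seed),
            band=sim.band,
            window=window,
            subject_id=f"seed{seed}",
        )
        coupled = mat.get("P", "MCZ")
        linked = {("P", "MCZ"), ("MCZ", "P")}
        spurious = max(
            mat.get(a, b)
            for a in mat.regions
            for b in mat.regions
            if a != b and (a, b) not in linked
        )
        results.append(
            {
                "seed": seed,
                "coupled_r2": coupled,
                "max_uncoupled_r2": spurious,
                "detected": coupled >= 0.8 and coupled - spurious >= 0.3,
            }
        )
    return results


def monotonicity_study(
    strengths: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 10,
    base_seed: int = 0,
    n_trials: int = 10,
    window: TimeWindow = TimeWindow(0.0, 0.5),
    model_cfg: TrainConfig = TrainConfig(),
):
    """Mean estimated R2 of one affine link as its strength varies.

    Two-region network (drive P, response MCZ), one seeded subject per
    (strength, seed) cell; all cells are fitted in one stacked batch.
    Returns {strength: mean validation R2 over seeds}.
    """
    regions = [
        RegionDefinition("P", ("P4", "Pz", "P3")),
        RegionDefinition("MCZ", ("Fcz", "Cz", "Cpz")),
    ]
    drives, targets, cfgs, cells = [], [], [], []
    for c in strengths:
        for s in range(n_seeds):
            seed = base_seed + 1000 * int(round(100 * c)) + s
            sim = SimConfig(
                seed=seed,
                n_trials=n_trials,
                regions=list(regions),
                couplings=[CouplingSpec.constant("P", "MCZ", c)],
            )
            rec, _ = simulate_subject(sim)
            trajs = _windowed_trajectories(rec, sim.band, window, regions)
            drives.append(normalize01(trajs["P"])[0])
            targets.append(normalize01(trajs["MCZ"])[0])
            cfgs.append(replace(model_cfg, seed=seed))
            cells.append(c)
    outcomes = fit_batch(drives, targets, cfgs)
    means = {}
    for c in strengths:
        vals = [o.r2_validation for o, cc in zip(outcomes, cells) if cc == c]
        means[c] = float(np.mean(vals))
    return means


#: Reduced problem sizes for Monte-Carlo inference studies. The type-I
#: arm only exercises the null distribution of the test statistic, so the
#: cheapest consistent estimator settings suffice; the power arm must
#: leave the predictor enough data and updates to express the coupling
#: step.
FWE_WINDOWS = (TimeWindow(-0.25, 0.0), TimeWindow(0.0, 0.25))
FWE_MODEL = TrainConfig(iterations=200, batch_size=None, min_samples=40)
POWER_WINDOWS = (TimeWindow(-0.5, 0.0), TimeWindow(0.0, 0.5))
POWER_MODEL = TrainConfig(iterations=200, batch_size=50)


def fwe_study(
    n_reps: int = 100,
    base_seed: int = 0,
    n_subjects: int = 10,
    alpha: float = 0.05,
):
    """Family-wise false-positive rate of the within-group test under the null.

    Each repetition simulates a fresh group with no coupling change
    (independent regions in both windows), runs the pipeline at the
    reduced problem size and asks whether any of the 20 Bonferroni-
    corrected links comes out significant. Returns (rate, n_reps).
    """
    windows = list(FWE_WINDOWS)
    errors = 0
    for r in range(n_reps):
        seed = base_seed + r
        stack = simulate_group_stack(
            SimConfig(seed=seed, n_trials=2),
            n_subjects,
            windows,
            replace(FWE_MODEL, seed=seed),
            group_label=f"null{r}",
        )
        res = within_group_test(stack, windows[1], alpha=alpha)
        errors += bool(res["significant"].any())
    return errors / n_reps, n_reps


def power_study(
    n_runs: int = 5,
    base_seed: int = 0,
    n_subjects: int = 10,
    n_trials: int = 10,
    alpha: float = 0.05,
):
    """Recovery rate of a 0.1 -> 0.9 coupling step by the within-group test.

    The stepped link P->MCZ sits at strength 0.1 before the stimulus and
    0.9 in the post window; a run counts as a hit when that link is
    significant after Bonferroni correction. Returns (hits, n_runs).
    """
    windows = list(POWER_WINDOWS)
    post = windows[1]
    link = CouplingSpec(
        drive="P",
        response="MCZ",
        baseline_strength=0.1,
        strength_by_window=((post, 0.9),),
    )
    hits = 0
    for r in range(n_runs):
        seed = base_seed + r
        stack = simulate_group_stack(
            SimConfig(seed=seed, n_trials=n_trials, couplings=[link]),
            n_subjects,
            windows,
            replace(POWER_MODEL, seed=seed),
            group_label=f"step{r}",
        )
        res = within_group_test(stack, post, alpha=alpha)
        row = res[(res["drive"] == "P") & (res["response"] == "MCZ")]
        hits += bool(row["significant"].iloc[0])
    return hits, n_runs
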