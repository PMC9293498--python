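"""Synthetic event-related BOLD data with known ground truth.

Emulates the structure of a five-category event-related visual experiment:
balanced stimulus classes, randomized inter-stimulus intervals, class-specific
activation confined to a compact posterior ("occipital-like") voxel cluster,
and i.i.d. Gaussian scanner noise on top of a constant baseline.  Every voxel's
time series is

    y(t) = baseline + sum_trials beta_true(voxel, trial) * (boxcar (*) HRF)(t) + noise,

where beta_true equals the class's effect size inside that class's active
cluster and 0 elsewhere, and (*) is convolution with the canonical double-gamma
hemodynamic response.

Because the downstream cumulant features are permutation-invariant across
voxels, class identity is carried by activation *amplitude* (one effect size
per class), not by which voxels activate; the default active cluster is shared
by all classes.  A fast path (:func:`make_beta_table`) skips the BOLD forward
model and draws trial-wise betas directly as beta_true + Gaussian noise.

What this generator does not model: hemodynamic variability across voxels,
temporal autocorrelation, physiological noise, motion, or anatomical
variability across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import build_design_matrix
from .selection import TrialFeatureTable

__all__ = ["SyntheticSpec", "RunSizingError", "make_events", "make_bold_run", "make_beta_table"]


class RunSizingError(ValueError):
    """Run length too short for the requested trial schedule."""


def default_cluster(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """A compact corner block of ~400 voxels (10 x 10 x 4 on the default grid).

    Linear indices are C-order (x slowest here since we ravel the (x, y, z)
    grid with numpy's default order).
    """
    nx, ny, nz = grid_shape
    bx, by, bz = min(10, nx), min(10, ny), min(4, nz)
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:bx, :by, :bz] = True
    return np.flatnonzero(mask.ravel())


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults mirror the emulated study's structure.

    5 balanced classes x 52 trials = 260 events; TR 2 s; stimulus duration 1 s;
    ISI uniform on [4, 8] s; down-scaled 16 x 16 x 12 grid (the full-scale
    63 x 53 x 46 acquisition grid is available by passing ``grid_shape``).
    ``effect_size`` is one mean beta per class in its active cluster; the
    defaults are linearly spaced 0.5..2.5 against unit noise.
    """

    n_classes: int = 5
    trials_per_class: int = 52
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    tr: float = 2.0
    isi: tuple[float, float] = (4.0, 8.0)
    stim_duration: float = 1.0
    active_cluster: dict[int, np.ndarray] | None = None
    effect_size: tuple[float, ...] | float | None = None
    noise_sd: float = 1.0
    baseline: float = 100.0
    initial_rest: float = 10.0
    final_rest: float = 20.0
    n_scans: int | None = None  # fixed run length; auto-sized when None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.trials_per_class < 1:
            raise ValueError("n_classes and trials_per_class must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.isi[0] > self.isi[1] or self.isi[0] < 0:
            raise ValueError("isi range must satisfy 0 <= lo <= hi")
        if self.effect_size is None:
            self.effect_size = tuple(
                0.5 * (c + 1) for c in range(self.n_classes)
            )
        elif np.isscalar(self.effect_size):
            self.effect_size = (float(self.effect_size),) * self.n_classes
        else:
            self.effect_size = tuple(float(e) for e in self.effect_size)
        if len(self.effect_size) != self.n_classes:
            raise ValueError("one effect size per class required")
        if not np.all(np.isfinite(self.effect_size)):
            raise ValueError("effect sizes must be finite")
        if self.active_cluster is None:
            shared = default_cluster(self.grid_shape)
            self.active_cluster = {c: shared for c in range(1, self.n_classes + 1)}
        n_vox = int(np.prod(self.grid_shape))
        for c, idx in self.active_cluster.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n_vox):
                raise ValueError(f"active cluster for class {c} outside the grid")
            self.active_cluster[c] = idx

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


def make_events(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Randomized balanced event schedule: onset, duration, condition, trial_id."""
    conditions = np.repeat(np.arange(1, spec.n_classes + 1), spec.trials_per_class)
    rng.shuffle(conditions)
    isis = rng.uniform(spec.isi[0], spec.isi[1], size=spec.n_trials)
    onsets = np.empty(spec.n_trials)
    t = spec.initial_rest
    for i in range(spec.n_trials):
        onsets[i] = t
        t += spec.stim_duration + isis[i]
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(spec.n_trials, spec.stim_duration),
            "condition": conditions.astype(int),
            "trial_id": np.arange(spec.n_trials, dtype=int),
        }
    )


def true_beta_matrix(spec: SyntheticSpec, events: pd.DataFrame) -> np.ndarray:
    """Trials x voxels ground-truth betas implied by the spec's clusters."""
    betas = np.zeros((spec.n_trials, spec.n_voxels))
    conds = events.sort_values("trial_id")["condition"].to_numpy()
    for i, c in enumerate(conds):
        betas[i, spec.active_cluster[int(c)]] = spec.effect_size[int(c) - 1]
    return betas


def make_bold_run(spec: SyntheticSpec):
    """Simulate one 4-D BOLD run.

    Returns ``(bold, events, ground_truth)`` where ``bold`` is a
    :class:`~lrbsf.io.BoldRun`, ``events`` the trial schedule, and
    ``ground_truth`` the trials x voxels beta matrix used in the forward
    model.  Identical seeds give bit-identical output.
    """
    from .io import BoldRun  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    events = make_events(spec, rng)
    last_end = float(events["onset"].iloc[-1] + events["duration"].iloc[-1])
    needed = int(np.ceil((last_end + spec.final_rest) / spec.tr))
    if spec.n_scans is None:
        n_scans = needed
    else:
        n_scans = spec.n_scans
        if n_scans * spec.tr < last_end:
            raise RunSizingError(
                f"run of {n_scans} scans ({n_scans * spec.tr:g} s) too short for "
                f"{spec.n_trials} trials ending at {last_end:g} s"
            )
    design = build_design_matrix(
        events, n_scans=n_scans, tr=spec.tr, mode="beta_series"
    )
    trial_cols = design.columns_of_kind("trial")
    regressors = design.X[:, trial_cols]  # scans x trials
    betas = true_beta_matrix(spec, events)
    signal = regressors @ betas  # scans x voxels
    noise = (
        rng.normal(0.0, spec.noise_sd, size=signal.shape)
        if spec.noise_sd > 0
        else 0.0
    )
    data = (spec.baseline + signal + noise).T.reshape(spec.grid_shape + (n_scans,))
    bold = BoldRun(data=data, tr=spec.tr)
    return bold, events, betas


def make_beta_table(spec: SyntheticSpec) -> TrialFeatureTable:
    """Fast path: draw the trials x voxels beta table directly.

    Bypasses the BOLD forward model and GLM: each entry is
    beta_true + N(0, noise_sd).  Labels are attached and classes balanced.
    """
    rng = np.random.default_rng(spec.seed)
    events = make_events(spec, rng)
    betas = true_beta_matrix(spec, events)
    if spec.noise_sd > 0:
        betas = betas + rng.normal(0.0, spec.noise_sd, size=betas.shape)
    conds = events.sort_values("trial_id")["condition"].to_numpy(int)
    return TrialFeatureTable(
        values=betas,
        labels=conds,
        trial_ids=events.sort_values("trial_id")["trial_id"].to_numpy(int),
        voxel_indices=np.arange(spec.n_voxels),
    )
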