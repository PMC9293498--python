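"""Voxel selection by t statistic and trial-feature table assembly.

Voxels are ranked by the absolute value of a condition-vs-baseline t statistic
and the top N are kept as the decoder's input dimensions; N between 50 and 5000
is the documented operating range, with the best accuracy typically between
400 and 500 features.  Ranking can come from a whole-run GLM contrast
(:func:`rank_voxels`) or, inside cross-validation folds, from the training
trials' beta table alone (:func:`rank_voxels_from_trials`) so that test trials
never influence the selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "VoxelSet",
    "TrialFeatureTable",
    "rank_voxels",
    "rank_voxels_from_trials",
    "select_top_n",
    "build_trial_table",
    "N_FEATURES_MIN",
    "N_FEATURES_MAX",
]

N_FEATURES_MIN = 50
N_FEATURES_MAX = 5000


@dataclass
class VoxelSet:
    """Ordered selection of voxel linear indices."""

    indices: np.ndarray
    source_contrast: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("voxel indices must be unique")

    @property
    def n(self) -> int:
        return self.indices.size


@dataclass
class TrialFeatureTable:
    """Trials x voxels matrix of beta features with class labels."""

    values: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    voxel_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x voxels)")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("one label per trial required")
        if self.trial_ids.shape[0] != self.values.shape[0]:
            raise ValueError("one trial_id per trial required")
        if self.voxel_indices.shape[0] != self.values.shape[1]:
            raise ValueError("one voxel index per column required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        if self.labels.size == 0:
            raise ValueError("label set must be non-empty")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset_trials(self, rows: np.ndarray) -> "TrialFeatureTable":
        return TrialFeatureTable(
            values=self.values[rows],
            labels=self.labels[rows],
            trial_ids=self.trial_ids[rows],
            voxel_indices=self.voxel_indices,
        )


def _order_by_abs(t: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """|t| descending; ties broken by ascending linear index (stable)."""
    # lexsort: primary key last. Sort by index ascending, then by -|t|.
    order = np.lexsort((indices, -np.abs(t)))
    return indices[order]


def rank_voxels(tmap, mask: np.ndarray | None = None, alpha: float | None = None) -> np.ndarray:
    """Order voxels by |t| of a contrast map, best first.

    Parameters
    ----------
    tmap : TStatMap
        Per-voxel t statistics (its ``voxel_indices`` are honored if set).
    mask : bool array, optional
        Restricts the ranking; must select at least one voxel.
    alpha : float, optional
        Uncorrected two-sided p-value pre-filter (e.g. 0.001) applied before
        ranking; off by default.

    Degenerate +/-inf t values sort first (they are maximally significant).
    """
    t = np.asarray(tmap.t, dtype=float).ravel()
    indices = (
        np.asarray(tmap.voxel_indices)
        if tmap.voxel_indices is not None
        else np.arange(t.size)
    )
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).ravel()
        keep = mask[indices]
        if not keep.any():
            raise ValueError("mask selects no voxels")
        t, indices = t[keep], indices[keep]
    if alpha is not None:
        p = 2.0 * stats.t.sf(np.abs(t), df=tmap.dof)
        keep = p < alpha
        t, indices = t[keep], indices[keep]
    return _order_by_abs(t, indices)


def rank_voxels_from_trials(
    values: np.ndarray, voxel_indices: np.ndarray | None = None
) -> np.ndarray:
    """Rank voxels by the one-sample t of training-trial betas against zero.

    This is the trial-table analog of a pooled condition-vs-baseline contrast
    and is what cross-validation folds use, computed on training rows only.
    Zero-variance voxels get t = 0 (uninformative) unless their mean is also
    nonzero, in which case they are maximally significant.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if n > 1 else np.zeros(values.shape[1])
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    degenerate = ~ok & (mean != 0.0)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    indices = (
        np.asarray(voxel_indices) if voxel_indices is not None else np.arange(t.size)
    )
    return _order_by_abs(t, indices)


def select_top_n(
    ranked: np.ndarray, n: int, enforce_limits: bool = False
) -> VoxelSet:
    """First ``n`` voxels of a ranking.

    ``enforce_limits`` additionally requires 50 <= n <= 5000, the documented
    operating range of the method.
    """
    ranked = np.asarray(ranked, dtype=int)
    if n > ranked.size:
        raise ValueError(f"requested n={n} voxels but only {ranked.size} are ranked")
    if n < 1:
        raise ValueError("n must be positive")
    if enforce_limits and not (N_FEATURES_MIN <= n <= N_FEATURES_MAX):
        raise ValueError(
            f"n={n} outside the documented range "
            f"[{N_FEATURES_MIN}, {N_FEATURES_MAX}]"
        )
    return VoxelSet(indices=ranked[:n].copy(), source_contrast="|t| ranking")


def build_trial_table(
    trial_betas: np.ndarray,
    voxel_set: VoxelSet,
    labels: np.ndarray,
    trial_ids: np.ndarray | None = None,
) -> TrialFeatureTable:
    """Column-subset the full trials x all-voxels beta matrix.

    Columns come out in ``voxel_set`` order; permuting the set permutes the
    columns identically.
    """
    trial_betas = np.asarray(trial_betas, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != trial_betas.shape[0]:
        raise ValueError("labels length must equal the number of trials")
    if voxel_set.indices.size and voxel_set.indices.max() >= trial_betas.shape[1]:
        raise ValueError(
            f"voxel index {voxel_set.indices.max()} out of range for "
            f"{trial_betas.shape[1]} voxels"
        )
    if trial_ids is None:
        trial_ids = np.arange(trial_betas.shape[0])
    return TrialFeatureTable(
        values=trial_betas[:, voxel_set.indices],
        labels=labels,
        trial_ids=trial_ids,
        voxel_indices=voxel_set.indices,
    )
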