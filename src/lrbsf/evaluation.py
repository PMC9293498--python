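"""Monte-Carlo cross-validation and decoding protocols.

The evaluation protocol mirrors the study design it emulates: trials are
repeatedly split at random into 90% training / 10% test (stratified by class),
the whole pipeline — voxel selection on the training rows only, cumulant
compression, decoder fit — is rerun inside each repetition, test trials are
scored, and the accuracy is averaged over repetitions (default 100).  Pairwise
decoding runs every one of the C(5,2) = 10 unordered class pairs; multiclass
decoding scores all five classes at once against a 20% chance level.

Randomness is controlled by a single integer seed; each repetition draws from
its own counter-derived stream, so adding repetitions never perturbs earlier
ones and identical configurations reproduce byte-identical reports.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decoder as _decoder
from .cumulants import transform_table
from .selection import (
    TrialFeatureTable,
    build_trial_table,
    rank_voxels_from_trials,
    select_top_n,
)

__all__ = [
    "McCvConfig",
    "PipelineSettings",
    "McCvReport",
    "PairwiseReport",
    "stratified_split",
    "pairwise_combinations",
    "monte_carlo_cv",
    "pairwise_decode",
    "feature_sweep",
]


@dataclass(frozen=True)
class McCvConfig:
    """Monte-Carlo cross-validation settings: 100 reps of 90/10 by default."""

    reps: int = 100
    test_frac: float = 0.10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.test_frac < 1.0):
            raise ValueError("test_frac must lie strictly between 0 and 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class PipelineSettings:
    """Per-fold pipeline knobs: selection size, cumulant convention, theta.

    ``selection`` is 'fold' (recompute the voxel ranking inside every training
    fold; the leakage-safe default) or 'fixed' (rank once on all trials before
    splitting, reproducing a whole-data selection).
    """

    n_features: int = 450
    cumulant_mode: str = "paper"
    eight_feature: bool = False
    zscore_trials: bool = False
    theta: float = 1.0
    selection: str = "fold"
    joint_kde: bool = False
    balanced_accuracy: bool = False

    def __post_init__(self) -> None:
        if self.selection not in ("fold", "fixed"):
            raise ValueError("selection must be 'fold' or 'fixed'")


@dataclass
class McCvReport:
    """Per-repetition accuracies plus their mean and standard deviation."""

    per_rep_accuracy: list[float]
    mean_accuracy: float
    sd: float
    reps: int
    test_frac: float
    seed: int
    n_features: int
    classes: list[int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "reps": self.reps,
                "test_frac": self.test_frac,
                "seed": self.seed,
                "n_features": self.n_features,
                "mean_accuracy": self.mean_accuracy,
                "sd": self.sd,
                "per_rep_accuracy": self.per_rep_accuracy,
            },
            sort_keys=True,
        )


@dataclass
class PairwiseReport:
    """One McCvReport per unordered class pair, plus the grand mean."""

    pairs: list[tuple[int, int]]
    reports: list[McCvReport]
    mean_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_a": [a for a, _ in self.pairs],
                "class_b": [b for _, b in self.pairs],
                "mean_accuracy": [r.mean_accuracy for r in self.reports],
                "sd": [r.sd for r in self.reports],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs": [list(p) for p in self.pairs],
                "mean_accuracy": self.mean_accuracy,
                "reports": [json.loads(r.to_json()) for r in self.reports],
            },
            sort_keys=True,
        )


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    # counter-derived stream: rep k is reproducible regardless of total reps
    return np.random.default_rng(np.random.SeedSequence((seed, rep)))


def stratified_split(
    table: TrialFeatureTable, test_frac: float, rng: np.random.Generator
):
    """Per-class proportional split into (train, test) row indices.

    Test count per class is round-half-up of n_c * test_frac, at least 1 and
    at most n_c - 1; the split is disjoint and exhaustive.
    """
    if not (0.0 < test_frac < 1.0):
        raise ValueError("test_frac must lie strictly between 0 and 1")
    labels = table.labels
    train_rows, test_rows = [], []
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        if rows.size < 2:
            raise ValueError(f"class {c} has fewer than 2 trials; cannot split")
        n_test = int(np.floor(rows.size * test_frac + 0.5))  # round half up
        n_test = min(max(n_test, 1), rows.size - 1)
        perm = rng.permutation(rows)
        test_rows.append(perm[:n_test])
        train_rows.append(perm[n_test:])
    train = np.sort(np.concatenate(train_rows))
    test = np.sort(np.concatenate(test_rows))
    return train, test


def pairwise_combinations(labels) -> list[tuple[int, int]]:
    """All C(n, 2) unordered label pairs in lexicographic order."""
    labels = sorted(set(int(x) for x in labels))
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    return list(itertools.combinations(labels, 2))


def _run_one_rep(
    table: TrialFeatureTable,
    settings: PipelineSettings,
    rng: np.random.Generator,
    test_frac: float,
    fixed_ranking: np.ndarray | None,
) -> float:
    train_rows, test_rows = stratified_split(table, test_frac, rng)
    train, test = table.subset_trials(train_rows), table.subset_trials(test_rows)
    if fixed_ranking is None:
        ranking = rank_voxels_from_trials(train.values, train.voxel_indices)
    else:
        ranking = fixed_ranking
    n = min(settings.n_features, ranking.size)
    voxel_set = select_top_n(ranking, n)
    # map linear voxel indices back to columns of the table
    col_of = {int(v): j for j, v in enumerate(table.voxel_indices)}
    cols = np.asarray([col_of[int(v)] for v in voxel_set.indices])
    train_sel = TrialFeatureTable(
        train.values[:, cols], train.labels, train.trial_ids, voxel_set.indices
    )
    test_sel = TrialFeatureTable(
        test.values[:, cols], test.labels, test.trial_ids, voxel_set.indices
    )
    kw = dict(
        mode=settings.cumulant_mode,
        eight_feature=settings.eight_feature,
        zscore_trials=settings.zscore_trials,
    )
    train_feats = transform_table(train_sel, **kw)
    test_feats = transform_table(test_sel, **kw)
    model = _decoder.fit_decoder(
        train_feats, theta=settings.theta, joint=settings.joint_kde
    )
    result = _decoder.predict_table(model, test_feats)
    if settings.balanced_accuracy:
        accs = [
            100.0 * np.mean(result.predicted[test.labels == c] == c)
            for c in np.unique(test.labels)
        ]
        return float(np.mean(accs))
    return float(result.accuracy)


def monte_carlo_cv(
    table: TrialFeatureTable,
    settings: PipelineSettings = PipelineSettings(),
    mc: McCvConfig = McCvConfig(),
) -> McCvReport:
    """Repeated stratified 90/10 decoding of one class set.

    Each repetition re-runs selection (training rows only, unless
    ``settings.selection == 'fixed'``), cumulant compression, decoder training
    and test scoring.  Fully reproducible from ``mc.seed``.
    """
    fixed_ranking = None
    if settings.selection == "fixed":
        fixed_ranking = rank_voxels_from_trials(table.values, table.voxel_indices)
    accs = []
    for rep in range(mc.reps):
        try:
            accs.append(
                _run_one_rep(
                    table, settings, _rep_rng(mc.seed, rep), mc.test_frac, fixed_ranking
                )
            )
        except Exception as exc:  # annotate with the failing repetition
            raise RuntimeError(f"Monte-Carlo repetition {rep} failed: {exc}") from exc
    accs_arr = np.asarray(accs)
    return McCvReport(
        per_rep_accuracy=[float(a) for a in accs],
        mean_accuracy=float(accs_arr.mean()),
        sd=float(accs_arr.std(ddof=1)) if len(accs) > 1 else 0.0,
        reps=mc.reps,
        test_frac=mc.test_frac,
        seed=mc.seed,
        n_features=settings.n_features,
        classes=[int(c) for c in table.classes()],
    )


def pairwise_decode(
    table: TrialFeatureTable,
    settings: PipelineSettings = PipelineSettings(),
    mc: McCvConfig = McCvConfig(),
) -> PairwiseReport:
    """One-vs-one decoding over every unordered class pair."""
    pairs = pairwise_combinations(table.classes())
    reports = []
    for a, b in pairs:
        rows = np.flatnonzero((table.labels == a) | (table.labels == b))
        reports.append(monte_carlo_cv(table.subset_trials(rows), settings, mc))
    mean = float(np.mean([r.mean_accuracy for r in reports]))
    return PairwiseReport(pairs=pairs, reports=reports, mean_accuracy=mean)


def feature_sweep(
    table: TrialFeatureTable,
    n_grid,
    settings: PipelineSettings = PipelineSettings(),
    mc: McCvConfig = McCvConfig(),
    protocol: str = "multiclass",
) -> pd.DataFrame:
    """Accuracy-vs-number-of-features curve.

    Returns a tidy frame with columns n_features, mean_accuracy, sd, reps,
    seed — one row per grid point.  ``protocol`` is 'multiclass' or
    'pairwise' (grand mean over the 10 pairs).
    """
    n_grid = sorted(int(n) for n in n_grid)
    if n_grid and n_grid[-1] > table.n_voxels:
        raise ValueError(
            f"largest grid point {n_grid[-1]} exceeds {table.n_voxels} voxels"
        )
    rows = []
    for n in n_grid:
        s = PipelineSettings(
            n_features=n,
            cumulant_mode=settings.cumulant_mode,
            eight_feature=settings.eight_feature,
            zscore_trials=settings.zscore_trials,
            theta=settings.theta,
            selection=settings.selection,
            joint_kde=settings.joint_kde,
            balanced_accuracy=settings.balanced_accuracy,
        )
        if protocol == "pairwise":
            rep = pairwise_decode(table, s, mc)
            mean, sd = rep.mean_accuracy, float(
                np.std([r.mean_accuracy for r in rep.reports], ddof=1)
            )
        else:
            r = monte_carlo_cv(table, s, mc)
            mean, sd = r.mean_accuracy, r.sd
        rows.append(
            {
                "n_features": n,
                "mean_accuracy": mean,
                "sd": sd,
                "reps": mc.reps,
                "seed": mc.seed,
            }
        )
    return pd.DataFrame(rows)
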