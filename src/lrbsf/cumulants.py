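"""Higher-order moment and cumulant features for trial-wise voxel patterns.

Each trial contributes an n-voxel vector of GLM beta estimates.  That vector is
compressed into at most eight scalar statistics: the second- and fourth-order
empirical moments M_pq = E[x^(p-q) (x*)^q] and cumulant-style combinations of
them (psi20, psi21, psi40, psi41, psi42).  Because the beta features are real,
conjugation is the identity, so M20 = M21 = E[x^2] and M40 = M41 = M42 = E[x^4];
complex-valued signals are out of scope.

Two cumulant conventions are provided:

``paper``
    The formulas exactly as published for this decoder:
    psi40 = M40 - 3 M20^2, psi41 = M40 - 3 M20 M21, psi42 = M42 - M20^2 - 2 M21.
    Note psi41 is built from M40 (not M41) and psi42 subtracts 2*M21 rather than
    2*M21^2 — these deviate from textbook cumulant algebra but are kept verbatim
    as the default, since the published accuracies may rest on them.

``standard``
    The textbook fourth-order cumulants familiar from modulation-classification
    work: psi40 = M40 - 3 M20^2, psi41 = M41 - 3 M21 M20,
    psi42 = M42 - M20^2 - 2 M21^2.  For a zero-mean Gaussian input all three
    vanish in expectation.

For real input psi20 and psi21 coincide numerically (both reduce to mean(x^2));
both are still emitted so the feature layout is convention-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MomentSet",
    "CumulantVector",
    "CumulantFeatureTable",
    "empirical_moment",
    "moment_set",
    "cumulant_features",
    "transform_table",
    "FEATURE_NAMES_FIVE",
    "FEATURE_NAMES_EIGHT",
]

FEATURE_NAMES_FIVE = ("psi20", "psi21", "psi40", "psi41", "psi42")
FEATURE_NAMES_EIGHT = FEATURE_NAMES_FIVE + ("m20", "m21", "m42")


@dataclass(frozen=True)
class MomentSet:
    """Empirical second- and fourth-order moments of one trial vector."""

    m20: float
    m21: float
    m40: float
    m41: float
    m42: float


@dataclass(frozen=True)
class CumulantVector:
    """Per-trial cumulant features; length 5, or 8 with the raw-moment extras."""

    psi20: float
    psi21: float
    psi40: float
    psi41: float
    psi42: float
    mode: str = "paper"
    moments: MomentSet | None = None

    def as_array(self, eight_feature: bool = False) -> np.ndarray:
        vals = [self.psi20, self.psi21, self.psi40, self.psi41, self.psi42]
        if eight_feature:
            if self.moments is None:
                raise ValueError("eight-feature output requires stored moments")
            vals += [self.moments.m20, self.moments.m21, self.moments.m42]
        return np.asarray(vals, dtype=float)


@dataclass
class CumulantFeatureTable:
    """Trials x features matrix of cumulant features with class labels."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    trial_ids: np.ndarray
    mode: str = "paper"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D trials x features matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match table width")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def _as_vector(x: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("moment of an empty vector is undefined")
    return arr


def empirical_moment(x: Sequence[float] | np.ndarray, p: int, q: int) -> float:
    """Empirical moment M_pq = mean over n of x(n)^(p-q) * conj(x(n))^q.

    The expectation is the sample mean.  Input is real-valued, so the conjugate
    is the identity and M_pq reduces to mean(x^p); the (p, q) split is kept so
    the definition reads the same as in the complex-signal literature.
    """
    if q < 0 or p < q:
        raise ValueError(f"moment indices require p >= q >= 0, got p={p}, q={q}")
    arr = _as_vector(x)
    return float(np.mean(arr ** (p - q) * arr**q))


def moment_set(x: Sequence[float] | np.ndarray) -> MomentSet:
    """All five moments the cumulant features are built from."""
    arr = _as_vector(x)
    x2 = float(np.mean(arr**2))
    x4 = float(np.mean(arr**4))
    # real input: M20 = M21, M40 = M41 = M42
    return MomentSet(m20=x2, m21=x2, m40=x4, m41=x4, m42=x4)


def cumulant_features(
    x: Sequence[float] | np.ndarray, mode: str = "paper"
) -> CumulantVector:
    """Compress one trial vector into the five psi features.

    Parameters
    ----------
    x : array-like
        Non-empty real vector (the trial's selected-voxel betas).
    mode : {"paper", "standard"}
        Which psi41/psi42 convention to use (see module docstring).
    """
    if mode not in ("paper", "standard"):
        raise ValueError(f"unknown cumulant mode {mode!r}")
    m = moment_set(x)
    psi20 = m.m20
    psi21 = m.m21
    psi40 = m.m40 - 3.0 * m.m20**2
    if mode == "paper":
        psi41 = m.m40 - 3.0 * m.m20 * m.m21
        psi42 = m.m42 - m.m20**2 - 2.0 * m.m21
    else:
        psi41 = m.m41 - 3.0 * m.m21 * m.m20
        psi42 = m.m42 - m.m20**2 - 2.0 * m.m21**2
    return CumulantVector(psi20, psi21, psi40, psi41, psi42, mode=mode, moments=m)


def transform_table(
    table,
    mode: str = "paper",
    eight_feature: bool = False,
    zscore_trials: bool = False,
) -> CumulantFeatureTable:
    """Map a trials x voxels beta table to a trials x (5 or 8) feature table.

    Each row is compressed independently (row-local computation), so the output
    width no longer depends on how many voxels were selected.  ``zscore_trials``
    optionally standardizes each trial vector (mean 0, sd 1) before the moments
    are taken; off by default.  Constant-zero rows are allowed and produce a
    zero feature row.
    """
    values = np.asarray(table.values, dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("input table must be a non-empty trials x voxels matrix")
    names = FEATURE_NAMES_EIGHT if eight_feature else FEATURE_NAMES_FIVE
    out = np.empty((values.shape[0], len(names)), dtype=float)
    for i, row in enumerate(values):
        if zscore_trials:
            sd = row.std(ddof=0)
            row = (row - row.mean()) / (sd if sd > 0 else 1.0)
        out[i] = cumulant_features(row, mode=mode).as_array(eight_feature)
    return CumulantFeatureTable(
        values=out,
        feature_names=names,
        labels=np.asarray(table.labels),
        trial_ids=np.asarray(table.trial_ids),
        mode=mode,
    )
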