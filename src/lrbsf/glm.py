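"""Design-matrix construction and per-voxel ordinary least squares.

The voxel time series Y_j is modeled as a linear combination of explanatory
time courses plus i.i.d. Gaussian noise: Y = X b + e, with X the J x L design
matrix.  Two design layouts are supported:

* ``condition`` — one HRF-convolved regressor per stimulus condition, plus any
  nuisance columns and a constant baseline (the 5 + 6 + 1 = 12-regressor layout
  of a five-condition event-related visual experiment).
* ``beta_series`` — one HRF-convolved regressor per individual trial
  ("least-squares-all": a single model containing every trial), plus nuisance
  and baseline.  The fitted per-trial betas are the decoder's raw features.

Convolution uses the canonical double-gamma hemodynamic response (peak 6 s,
undershoot 16 s, peak/undershoot ratio 1/6) via nilearn.  The solve is by QR
decomposition; rank is judged against a tolerance of 1e-10 times the largest
singular value.  No prewhitening/AR modeling is applied: noise is taken as
white, matching the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import compute_regressor

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "TStatMap",
    "CollinearityError",
    "build_design_matrix",
    "fit_glm",
    "t_contrast",
]

_RANK_TOL = 1e-10

COLUMN_KINDS = ("condition", "trial", "nuisance", "baseline")


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class DesignMatrix:
    """J x L design with labeled columns.

    ``column_labels`` is a list of ``(name, kind)`` pairs, kind one of
    'condition', 'trial', 'nuisance', 'baseline'.
    """

    X: np.ndarray
    column_labels: list[tuple[str, str]]
    tr: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design must be 2-D")
        if self.X.shape[1] != len(self.column_labels):
            raise ValueError("one label per column required")
        kinds = {k for _, k in self.column_labels}
        bad = kinds - set(COLUMN_KINDS)
        if bad:
            raise ValueError(f"unknown column kinds: {sorted(bad)}")
        n_base = sum(1 for _, k in self.column_labels if k == "baseline")
        if n_base > 1:
            raise ValueError("at most one baseline column allowed")

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]

    def columns_of_kind(self, kind: str) -> list[int]:
        return [i for i, (_, k) in enumerate(self.column_labels) if k == kind]

    def names(self) -> list[str]:
        return [n for n, _ in self.column_labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.names())


@dataclass
class GlmFit:
    """OLS estimates per voxel: beta (L x V), residual variance, dof.

    ``R`` is the upper-triangular factor of the thin QR of X, kept so that
    t contrasts can form c' (X'X)^-1 c without re-decomposing.
    ``voxel_indices`` maps fit columns back to linear voxel indices when a
    mask restricted the fit.
    """

    beta: np.ndarray
    sigma2: np.ndarray
    dof: int
    design: DesignMatrix
    R: np.ndarray
    voxel_indices: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.beta.shape[1]

    def trial_betas(self) -> np.ndarray:
        """Trials x voxels matrix of the 'trial'-kind coefficients."""
        idx = self.design.columns_of_kind("trial")
        if not idx:
            raise ValueError("design has no trial columns (not beta_series mode)")
        return self.beta[idx, :]


@dataclass
class TStatMap:
    """Per-voxel t statistic for a single contrast."""

    t: np.ndarray
    contrast: np.ndarray
    dof: int
    voxel_indices: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # True where sigma2 == 0


def _hrf_regressor(
    onsets: np.ndarray, durations: np.ndarray, frame_times: np.ndarray
) -> np.ndarray:
    cond = (
        np.asarray(onsets, dtype=float),
        np.asarray(durations, dtype=float),
        np.ones(len(onsets)),
    )
    reg, _ = compute_regressor(cond, "spm", frame_times, oversampling=50)
    return reg[:, 0]


def build_design_matrix(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    mode: str = "condition",
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Build a condition-wise or trial-wise (beta-series) design.

    Parameters
    ----------
    events : DataFrame
        Columns ``onset`` (s), ``duration`` (s), ``condition`` (int label),
        ``trial_id`` (unique int).
    n_scans, tr : int, float
        Run length in volumes and repetition time in seconds.
    mode : {"condition", "beta_series"}
        One regressor per condition, or one per trial.
    nuisance : (n_scans, m) array, optional
        Passed through unconvolved (e.g. realignment parameters).

    The baseline is a constant-1 column, always appended last.
    """
    if mode not in ("condition", "beta_series"):
        raise ValueError(f"unknown design mode {mode!r}")
    run_length = n_scans * tr
    ends = events["onset"].to_numpy(float) + events["duration"].to_numpy(float)
    if (events["onset"] < 0).any() or (ends > run_length).any():
        raise ValueError(
            f"events extend beyond the run: run length {run_length:g} s, "
            f"last event ends at {ends.max():g} s"
        )
    frame_times = np.arange(n_scans) * tr
    cols: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    if mode == "condition":
        for cond in sorted(events["condition"].unique()):
            sel = events[events["condition"] == cond]
            cols.append(
                _hrf_regressor(
                    sel["onset"].to_numpy(), sel["duration"].to_numpy(), frame_times
                )
            )
            labels.append((f"condition_{cond}", "condition"))
    else:
        for _, row in events.sort_values("trial_id").iterrows():
            cols.append(
                _hrf_regressor(
                    np.array([row["onset"]]), np.array([row["duration"]]), frame_times
                )
            )
            labels.append((f"trial_{int(row['trial_id'])}", "trial"))
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance rows must equal n_scans")
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            labels.append((f"nuisance_{j}", "nuisance"))
    cols.append(np.ones(n_scans))
    labels.append(("baseline", "baseline"))
    X = np.column_stack(cols)
    _check_rank(X, [n for n, _ in labels])
    return DesignMatrix(X=X, column_labels=labels, tr=tr)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more time points than regressors: J={X.shape[0]}, L={X.shape[1]}"
        )
    s = np.linalg.svd(X, compute_uv=False)
    rank = int(np.sum(s > _RANK_TOL * s[0]))
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR: the trailing pivots span
        # the (near-)dependent directions
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        offenders = [names[i] for i in piv[rank:]]
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"dependent columns: {offenders}"
        )


def fit_glm(bold, design: DesignMatrix) -> GlmFit:
    """Per-voxel OLS of the BOLD run on the design.

    ``bold`` is a BoldRun (4-D data, optional mask).  Returns coefficient
    estimates, residual variance RSS/dof, and the QR factor for contrasts.
    """
    data = np.asarray(bold.data, dtype=float)
    if data.ndim != 4:
        raise ValueError("BOLD data must be 4-D (x, y, z, t)")
    if data.shape[3] != design.n_scans:
        raise ValueError(
            f"time dimension mismatch: BOLD has {data.shape[3]} volumes, "
            f"design expects {design.n_scans}"
        )
    mask = getattr(bold, "mask", None)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        voxel_indices = np.flatnonzero(mask.ravel())
    else:
        voxel_indices = None
    Y = data.reshape(-1, data.shape[3])
    if voxel_indices is not None:
        Y = Y[voxel_indices]
    Y = Y.T  # scans x voxels
    X = design.X
    _check_rank(X, design.names())
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    sigma2 = np.maximum(sigma2, 0.0)  # guard tiny negative round-off
    # residual variance at round-off scale is an exact interpolation
    tol = 1e-20 * np.mean(Y**2, axis=0)
    sigma2[sigma2 <= tol] = 0.0
    return GlmFit(
        beta=beta,
        sigma2=sigma2,
        dof=dof,
        design=design,
        R=R,
        voxel_indices=voxel_indices,
    )


def t_contrast(fit: GlmFit, c: np.ndarray) -> TStatMap:
    """t = c'b / sqrt(sigma2 * c'(X'X)^-1 c) per voxel.

    Voxels with zero residual variance (e.g. noiseless simulations) get
    t = +/-inf with the sign of c'b and are flagged in ``degenerate``.
    """
    c = np.asarray(c, dtype=float).ravel()
    if c.shape[0] != fit.design.n_regressors:
        raise ValueError(
            f"contrast length {c.shape[0]} != {fit.design.n_regressors} regressors"
        )
    if not np.any(c):
        raise ValueError("contrast vector must be nonzero")
    effect = c @ fit.beta
    # c'(X'X)^-1 c = ||R^-T c||^2
    w = np.linalg.solve(fit.R.T, c)
    var_scale = float(w @ w)
    degenerate = fit.sigma2 == 0.0
    denom = np.sqrt(fit.sigma2 * var_scale)
    # in degenerate voxels an effect at round-off scale counts as zero
    zero_tol = 1e-10 * (1.0 + np.abs(c) @ np.abs(fit.beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            degenerate,
            np.where(np.abs(effect) <= zero_tol, 0.0, np.sign(effect) * np.inf),
            effect / np.where(denom == 0.0, 1.0, denom),
        )
    return TStatMap(
        t=t,
        contrast=c,
        dof=fit.dof,
        voxel_indices=fit.voxel_indices,
        degenerate=degenerate,
    )
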