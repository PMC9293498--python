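"""File formats and configuration.

NIfTI-1 for BOLD runs, masks and beta/t maps (via nibabel; voxel size recorded
in the header, 3 mm isotropic by default, TR in the 4th zoom); tab-separated
event tables with header ``onset  duration  condition  trial_id``; CSV for
design matrices and feature tables; JSON for reports and trained models; YAML
for pipeline configuration.  Voxel indices are 0-based linear indices into the
C-order raveled (x, y, z) grid; world coordinates come from the NIfTI affine,
which is preserved on round trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .evaluation import McCvConfig, PipelineSettings
from .selection import TrialFeatureTable, VoxelSet
from .cumulants import CumulantFeatureTable

__all__ = [
    "BoldRun",
    "PipelineConfig",
    "read_bold",
    "write_bold",
    "read_mask",
    "read_events",
    "write_events",
    "write_volume",
    "read_trial_table",
    "write_trial_table",
    "read_cumulant_table",
    "write_cumulant_table",
    "read_voxel_set",
    "write_voxel_set",
    "load_config",
    "save_config",
]

EVENT_COLUMNS = ("onset", "duration", "condition", "trial_id")
DEFAULT_VOXEL_MM = 3.0


@dataclass
class BoldRun:
    """4-D BOLD grid (x, y, z, t) with repetition time and optional mask."""

    data: np.ndarray
    tr: float
    affine: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD must be 4-D, got {self.data.ndim}-D")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.affine is None:
            self.affine = np.diag([DEFAULT_VOXEL_MM] * 3 + [1.0])
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match the spatial grid")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def write_bold(bold: BoldRun, path) -> None:
    img = nib.Nifti1Image(bold.data, bold.affine)
    zooms = img.header.get_zooms()[:3] + (bold.tr,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold(path, tr: float | None = None) -> BoldRun:
    """Load a 4-D NIfTI; TR comes from the header unless overridden.

    A 3-D file or a missing/zero header TR without an explicit ``tr`` raises.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D BOLD file, got {data.ndim}-D")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ValueError(
                f"{path}: no repetition time in header; pass tr explicitly"
            )
    return BoldRun(data=data, tr=float(tr), affine=np.asarray(img.affine))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3-D")
    return data > 0


def write_volume(values: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3-D map (beta, t, mask) as NIfTI-1."""
    if affine is None:
        affine = np.diag([DEFAULT_VOXEL_MM] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=float), affine), str(path))


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, columns=list(EVENT_COLUMNS))


def read_events(path, run_length: float | None = None) -> pd.DataFrame:
    """Load and validate a TSV event table.

    Conditions are mapped to integer labels 1..n_classes in first-appearance
    order when they are not already integers; unsorted rows are sorted by
    onset (stable by trial_id); overlapping trials warn; an onset beyond
    ``run_length`` (when given) raises.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: event table is empty")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["trial_id"].duplicated().any():
        raise ValueError(f"{path}: trial_id values must be unique")
    cond = df["condition"]
    if not pd.api.types.is_integer_dtype(cond):
        mapping = {c: i + 1 for i, c in enumerate(pd.unique(cond))}
        df["condition"] = cond.map(mapping)
    df = df.sort_values(["onset", "trial_id"], kind="stable").reset_index(drop=True)
    ends = df["onset"] + df["duration"]
    if (df["onset"].to_numpy()[1:] < ends.to_numpy()[:-1]).any():
        warnings.warn("event table contains overlapping trials", stacklevel=2)
    if run_length is not None and (ends > run_length).any():
        raise ValueError(
            f"{path}: events extend beyond the run ({run_length:g} s)"
        )
    return df


def write_trial_table(table: TrialFeatureTable, path) -> None:
    df = pd.DataFrame(table.values, columns=[str(v) for v in table.voxel_indices])
    df["label"] = table.labels
    df["trial_id"] = table.trial_ids
    df.to_csv(path, index=False)


def read_trial_table(path) -> TrialFeatureTable:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy(int)
    trial_ids = df.pop("trial_id").to_numpy(int)
    return TrialFeatureTable(
        values=df.to_numpy(float),
        labels=labels,
        trial_ids=trial_ids,
        voxel_indices=np.asarray([int(c) for c in df.columns]),
    )


def write_cumulant_table(table: CumulantFeatureTable, path) -> None:
    df = pd.DataFrame(table.values, columns=list(table.feature_names))
    df["label"] = table.labels
    df["trial_id"] = table.trial_ids
    df.to_csv(path, index=False)


def read_cumulant_table(path, mode: str = "paper") -> CumulantFeatureTable:
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy(int)
    trial_ids = df.pop("trial_id").to_numpy(int)
    return CumulantFeatureTable(
        values=df.to_numpy(float),
        feature_names=tuple(df.columns),
        labels=labels,
        trial_ids=trial_ids,
        mode=mode,
    )


def write_voxel_set(vs: VoxelSet, path) -> None:
    pd.DataFrame({"voxel": vs.indices}).to_csv(path, index=False)


def read_voxel_set(path) -> VoxelSet:
    df = pd.read_csv(path)
    return VoxelSet(indices=df["voxel"].to_numpy(int))


@dataclass
class PipelineConfig:
    """Everything one decoding run needs; round-trips through YAML losslessly."""

    bold: str | None = None
    events: str | None = None
    mask: str | None = None
    table: str | None = None  # precomputed trial-beta CSV (skips the GLM)
    output_dir: str = "."
    n_features: int = 450
    cumulant_mode: str = "paper"
    eight_feature: bool = False
    zscore_trials: bool = False
    theta: float = 1.0
    selection: str = "fold"
    joint_kde: bool = False
    balanced_accuracy: bool = False
    protocol: str = "pairwise"  # or "multiclass"
    reps: int = 100
    test_frac: float = 0.10
    seed: int = 0
    log_level: str = "INFO"

    def settings(self) -> PipelineSettings:
        return PipelineSettings(
            n_features=self.n_features,
            cumulant_mode=self.cumulant_mode,
            eight_feature=self.eight_feature,
            zscore_trials=self.zscore_trials,
            theta=self.theta,
            selection=self.selection,
            joint_kde=self.joint_kde,
            balanced_accuracy=self.balanced_accuracy,
        )

    def mc(self) -> McCvConfig:
        return McCvConfig(
            reps=self.reps, test_frac=self.test_frac, seed=self.seed
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.settings()  # validate derived settings eagerly
    cfg.mc()
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
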