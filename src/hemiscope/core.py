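"""Core data containers shared across the analysis pipeline.

These are thin, explicit containers for the quantities the pipeline passes
around: the task boxcar (the binary move/rest indicator that serves both as
GLM regressor and as correlation target for the physiological envelopes),
uniformly sampled physiological signals (data-glove finger angle, surface
EMG), voxelwise beta volumes with their co-registered integer label
atlases, and small result records.

All containers hold plain numpy arrays; no global state, no lazy I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TaskBoxcar",
    "SampledSeries",
    "EnvelopeSeries",
    "BetaVolume",
    "LabelAtlas",
    "KinematicsResult",
    "MirrorEmgResult",
    "RoiSummary",
    "AnovaResult",
    "StepwiseResult",
    "MOTOR_SEGMENTS",
    "HEMISPHERES",
]

#: Anatomical motor segments of the ROI set (bilateral; 6 x 2 labels).
MOTOR_SEGMENTS = (
    "cerebellum",
    "SMA",
    "PM",
    "precentral",
    "postcentral",
    "insula",
)

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class TaskBoxcar:
    """Binary move/rest block indicator on a uniform time grid.

    The task alternates rest and movement blocks of equal length
    ``block_s``, starting with rest, for ``total_s`` seconds.  ``values``
    holds the indicator sampled every ``dt`` seconds.
    """

    block_s: float
    total_s: float
    dt: float
    values: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def sample_times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Indicator values at arbitrary times (0/1 float array).

        Times at or beyond ``total_s`` evaluate to rest (0).
        """
        times = np.asarray(times, dtype=float)
        inside = (times >= 0) & (times < self.total_s)
        move = (times % (2.0 * self.block_s)) >= self.block_s
        return np.where(inside & move, 1.0, 0.0)

    def move_mask(self, times: Optional[np.ndarray] = None) -> np.ndarray:
        """Boolean movement mask on this boxcar's grid (or a given grid)."""
        if times is None:
            return self.values.astype(bool)
        return self.sample(times) > 0.5


@dataclass(frozen=True)
class SampledSeries:
    """Uniformly sampled 1-D physiological signal.

    ``values`` are physical units — degrees for glove angle, arbitrary
    amplitude units for EMG.  The grid is strictly uniform at rate ``fs``.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("SampledSeries values must be 1-D")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def sample_times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class EnvelopeSeries:
    """Non-negative amplitude envelope of a physiological signal."""

    values: np.ndarray
    fs: float
    source: str = "emg"  # {"glove", "emg"}

    @property
    def sample_times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


@dataclass
class BetaVolume:
    """3-D grid of first-level GLM coefficients with a voxel→world affine."""

    data: np.ndarray
    affine: np.ndarray
    subject: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"BetaVolume expects a 3-D grid, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


@dataclass
class LabelAtlas:
    """Integer label volume plus a table mapping label → (segment, hemisphere).

    ``table`` is a DataFrame with columns ``label``, ``segment``,
    ``hemisphere``; 0 is background.
    """

    data: np.ndarray
    affine: np.ndarray
    table: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("atlas grid must be integer-valued")
        self.affine = np.asarray(self.affine, dtype=float)
        required = {"label", "segment", "hemisphere"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"label table needs columns {sorted(required)}")
        present = set(np.unique(self.data)) - {0}
        known = set(self.table["label"].astype(int))
        if not present.issubset(known):
            raise ValueError(
                f"atlas contains labels missing from the table: {sorted(present - known)}"
            )

    def label_of(self, segment: str, hemisphere: str) -> int:
        sel = self.table[
            (self.table["segment"] == segment)
            & (self.table["hemisphere"] == hemisphere)
        ]
        if len(sel) != 1:
            raise KeyError(f"no unique label for ({segment}, {hemisphere})")
        return int(sel["label"].iloc[0])

    def hemisphere_of(self, label: int) -> str:
        sel = self.table[self.table["label"] == label]
        if len(sel) != 1:
            raise KeyError(f"unknown label {label}")
        return str(sel["hemisphere"].iloc[0])

    @property
    def segments(self) -> list:
        return list(dict.fromkeys(self.table["segment"]))


@dataclass(frozen=True)
class KinematicsResult:
    """Glove-derived task performance summary for one hand/run."""

    n_movements: int
    compliance_r: float
    mirror_r: float


@dataclass(frozen=True)
class MirrorEmgResult:
    """EMG mirror-contraction summary.

    ``mm_score`` is exactly ``task_corr * pct_mve_mean``: the envelope–boxcar
    correlation weighted by the mean task amplitude expressed as a
    percentage of the maximal voluntary extension (MVE) recording.
    """

    pct_mve_mean: float
    task_corr: float
    mm_score: float


@dataclass(frozen=True)
class RoiSummary:
    """Per-segment ROI summary: proportional-threshold voxel set statistics."""

    segment: str
    hemisphere: str
    n_selected: int
    mean_beta: float
    li: Optional[float] = None


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    ss_num: float = float("nan")
    ss_den: float = float("nan")


@dataclass
class StepwiseResult:
    """Outcome of forward/backward stepwise regression."""

    selected: list = field(default_factory=list)   # factor names in entry order
    coefficients: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)    # final-model partial-F p per factor
    steps: list = field(default_factory=list)      # log of (action, factor, p)
    r_squared: float = float("nan")
    intercept: float = float("nan")
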