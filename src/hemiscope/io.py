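"""Format readers/writers and packaged fixture tables.

Formats: NIfTI-1 volumes (plain or gzipped) via nibabel; 2-column
delimited signal files ``time_s,value``; RFC-4180 CSV tables with header
rows.  The packaged fixtures are CSV transcriptions of the study's
per-subject clinical and performance tables (20 patients, 15 controls)
with equipment-failure cells preserved as missing, never imputed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BetaVolume, LabelAtlas, SampledSeries

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_atlas",
    "read_signal",
    "write_signal",
    "FixtureTables",
    "load_fixtures",
]

_FIXTURE_SHA256 = {
    "table1.csv": "b787e6b73871a6848129dea20c82b800543e063e1685f530ebd976be486178e1",
    "table2.csv": "8faa510803199528b645810a5ad7b6b960a6c2f66862f17728ddcf4ef039d5a8",
    "table3.csv": "2ba3fa7dc909240a95b64a6424f07fb95c42702e8925860fcf4353473566e378",
}


def read_nifti(path: str | Path) -> BetaVolume:
    """Load a 3-D NIfTI volume as a BetaVolume (values + affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    return BetaVolume(data=np.asarray(data, dtype=float), affine=np.asarray(img.affine))


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    """Write a volume as NIfTI-1 (gzipped if the suffix says so)."""
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    # fixed timestamp-free header → identical bytes for identical content
    nib.save(img, str(path))


def read_atlas(path: str | Path, labels_csv: str | Path) -> LabelAtlas:
    """Load an integer label volume plus its label table CSV.

    The table needs columns ``label,segment,hemisphere``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label volume, got {data.shape}")
    data = np.rint(np.asarray(data)).astype(np.int32)
    table = pd.read_csv(labels_csv)
    return LabelAtlas(data=data, affine=np.asarray(img.affine), table=table)


def read_signal(path: str | Path, fs: Optional[float] = None) -> SampledSeries:
    """Read a 2-column ``time_s,value`` file into a SampledSeries.

    The time column must be a uniform grid; the sampling rate is inferred
    from it unless supplied.
    """
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (time_s,value)")
    t, v = arr[:, 0], arr[:, 1]
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dts = np.diff(t)
    if np.ptp(dts) > 1e-6 * dts.mean():
        raise ValueError(f"{path}: time grid is not uniform")
    inferred = 1.0 / dts.mean()
    return SampledSeries(values=v, fs=fs if fs is not None else float(inferred))


def write_signal(path: str | Path, series: SampledSeries) -> None:
    arr = np.column_stack([series.sample_times, series.values])
    np.savetxt(path, arr, delimiter=",", fmt="%.6f", header="time_s,value", comments="")


@dataclass(frozen=True)
class FixtureTables:
    """Packaged per-subject clinical/performance tables.

    table1: patient clinical characteristics (n = 20) — age, time post
            stroke, lesion side/location, FM (0–66), ARAT (0–57), %NHPT.
    table2: patient glove/EMG performance scores (MM_EMG per condition,
            MM_glove, compliance correlation, movement counts).
    table3: the same performance scores for the 15 controls.

    Missing cells (equipment failure) are NaN.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame


def _fixture_bytes(name: str) -> bytes:
    ref = resources.files("hemiscope.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise ValueError(
            f"fixture {name} failed its checksum; the packaged tables are "
            "part of the validated surface and must not be edited"
        )
    return raw


def load_fixtures() -> FixtureTables:
    """Load and checksum-validate the packaged fixture tables."""
    import io as _io

    frames = {}
    for name in ("table1.csv", "table2.csv", "table3.csv"):
        frames[name] = pd.read_csv(_io.BytesIO(_fixture_bytes(name)))
    t1, t2, t3 = frames["table1.csv"], frames["table2.csv"], frames["table3.csv"]
    if len(t1) != 20 or len(t2) != 20 or len(t3) != 15:
        raise ValueError("fixture tables have unexpected row counts")
    return FixtureTables(table1=t1, table2=t2, table3=t3)
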