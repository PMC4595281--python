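"""Synthetic generator for every input the pipeline consumes.

The generator emulates the study conditions: a 20 s-on / 20 s-off block
task lasting 6 minutes; ~0.5 Hz finger flexion–extension glove traces with
sensor drift and optional mirror leakage into the inactive hand; surface
EMG with scanner gradient artifacts at 45/90 Hz plus task-locked bursts of
controllable %MVE; mirror-symmetric 6-segment label atlases; and bilateral
beta volumes with controllable lateralization.  Every draw is a pure
function of an explicit seed, so recovery tests can estimate the ground
truth back.

Defaults (the study conditions):

* blocks 20 s, total 360 s, starting with rest;
* glove sampled at 100 Hz; movement cycle 2 s (the visual cue cycled at
  1 Hz but counted movements land near 90 per task);
* amplitude varied over three levels per movement block (30/60/90 deg);
* EMG sampled at 1000 Hz with a 20–120 Hz burst carrier.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import HEMISPHERES, MOTOR_SEGMENTS, BetaVolume, LabelAtlas, SampledSeries, TaskBoxcar

__all__ = [
    "GroundTruth",
    "make_task_boxcar",
    "simulate_glove_trace",
    "simulate_emg_trace",
    "make_label_atlas",
    "simulate_beta_volume",
    "simulate_cohort_table",
    "simulate_cohort",
]

GLOVE_FS = 100.0
EMG_FS = 1000.0
EMG_CARRIER_BAND = (20.0, 120.0)
DEFAULT_AMPLITUDE_LEVELS = (30.0, 60.0, 90.0)


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters the recovery tests estimate back.

    mirror_gain      : leakage of the active-hand movement into the
                       inactive-hand glove trace (dimensionless).
    target_pct_mve   : contraction amplitude during movement blocks as a
                       percentage of the MVE recording amplitude.
    li_true          : target laterality index in [-1, 1] (scalar applied
                       to every segment pair).
    movement_rate    : flexion–extension cycles per second.
    seed             : fully determines all random draws.
    """

    mirror_gain: float = 0.0
    target_pct_mve: float = 2.0
    li_true: float = 0.0
    movement_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.li_true <= 1.0:
            raise ValueError("li_true must lie in [-1, 1]")
        if self.target_pct_mve < 0:
            raise ValueError("target_pct_mve must be >= 0")
        if self.movement_rate <= 0:
            raise ValueError("movement_rate must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def make_task_boxcar(
    block_s: float = 20.0, total_s: float = 360.0, dt: float = 0.5
) -> TaskBoxcar:
    """Binary move/rest indicator: alternating equal blocks, rest first.

    ``total_s`` must be an integer multiple of one rest+move pair
    (2×block_s) and ``dt`` must divide ``block_s`` exactly.
    """
    if block_s <= 0 or total_s <= 0 or dt <= 0:
        raise ValueError("durations must be positive")
    pairs = total_s / (2.0 * block_s)
    if abs(pairs - round(pairs)) > 1e-9 or round(pairs) < 1:
        raise ValueError(
            f"total_s={total_s} is not an integer multiple of a rest+move "
            f"pair (2 x {block_s} s)"
        )
    per_block = block_s / dt
    if abs(per_block - round(per_block)) > 1e-9:
        raise ValueError(
            f"dt={dt} s does not divide the block length {block_s} s "
            f"({block_s}/{dt} = {per_block:.4f} is not an integer)"
        )
    n = int(round(total_s / dt))
    times = np.arange(n) * dt
    values = np.where((times % (2.0 * block_s)) >= block_s, 1, 0).astype(np.int8)
    return TaskBoxcar(block_s=block_s, total_s=total_s, dt=dt, values=values)


def _movement_component(
    times: np.ndarray,
    boxcar: TaskBoxcar,
    rate: float,
    amplitude_schedule: Sequence[float],
) -> np.ndarray:
    """Pure movement signal: sinusoid at ``rate`` Hz inside move blocks.

    The amplitude cycles through the schedule across successive movement
    blocks (the three requested extension levels).  The sinusoid starts at
    phase 0 at each block onset, so it joins the rest baseline continuously.
    """
    out = np.zeros_like(times)
    pair = 2.0 * boxcar.block_s
    block_index = np.floor(times / pair).astype(int)
    in_move = boxcar.sample(times) > 0.5
    t_local = times - (block_index * pair + boxcar.block_s)
    amps = np.asarray(amplitude_schedule, dtype=float)
    level = amps[block_index % len(amps)]
    out[in_move] = 0.5 * level[in_move] * np.sin(
        2.0 * np.pi * rate * t_local[in_move]
    )
    return out


def simulate_glove_trace(
    boxcar: TaskBoxcar,
    truth: GroundTruth,
    amplitude_schedule: Sequence[float] = DEFAULT_AMPLITUDE_LEVELS,
    noise_sd: float = 0.25,
    drift_amp: float = 5.0,
    fs: float = GLOVE_FS,
    rng: Optional[np.random.Generator] = None,
) -> tuple[SampledSeries, SampledSeries]:
    """Glove angle traces for the instructed and the inactive hand.

    Returns ``(active, inactive)``.  The inactive hand receives
    ``mirror_gain`` times the active movement component plus its own drift
    and noise; with mirror_gain = 0 it carries no task information.
    """
    amps = np.asarray(amplitude_schedule, dtype=float)
    if np.any(amps <= 0) or np.any(amps > 90):
        raise ValueError("amplitude levels must lie in (0, 90] degrees")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if drift_amp < 0:
        raise ValueError("drift_amp must be non-negative")
    rng = truth.rng(1) if rng is None else rng
    n = int(round(boxcar.total_s * fs))
    times = np.arange(n) / fs
    movement = _movement_component(times, boxcar, truth.movement_rate, amps)

    def drift():
        f = rng.uniform(0.005, 0.02)
        phase = rng.uniform(0, 2 * np.pi)
        return drift_amp * np.sin(2 * np.pi * f * times + phase)

    active = movement + drift() + rng.normal(0.0, noise_sd, n)
    inactive = (
        truth.mirror_gain * movement + drift() + rng.normal(0.0, noise_sd, n)
    )
    return SampledSeries(active, fs), SampledSeries(inactive, fs)


def _band_limited_carrier(
    n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS broadband EMG carrier confined to the 20–120 Hz band."""
    sos = sps.butter(4, EMG_CARRIER_BAND, "bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_emg_trace(
    boxcar: TaskBoxcar,
    truth: GroundTruth,
    fs: float = EMG_FS,
    artifact_amps: tuple[float, float] = (0.5, 0.5),
    mve_amp: float = 1.0,
    mve_duration_s: float = 5.0,
    baseline_pct: float = 2.0,
    drift_amp: float = 0.2,
    rng: Optional[np.random.Generator] = None,
) -> tuple[SampledSeries, SampledSeries]:
    """EMG of the contralateral hand plus a maximal-voluntary-extension burst.

    The task recording is a rectified-Gaussian broadband carrier whose
    amplitude is modulated by the boxcar: ``target_pct_mve`` percent of the
    MVE amplitude during movement blocks, a small resting tone
    (``baseline_pct``) elsewhere.  Sinusoidal gradient artifacts at exactly
    45 and 90 Hz and a sub-10 Hz motion drift are superimposed — the
    components the preprocessing chain is built to remove.
    """
    if fs < 260.0:
        raise ValueError(
            f"fs={fs} Hz violates the Nyquist constraint: the 130 Hz band "
            "edge of the preprocessing chain requires fs >= 260 Hz"
        )
    rng = truth.rng(2) if rng is None else rng
    n = int(round(boxcar.total_s * fs))
    times = np.arange(n) / fs
    carrier = _band_limited_carrier(n, fs, rng)
    move = boxcar.sample(times)
    sigma_rest = (baseline_pct / 100.0) * mve_amp
    sigma_move = max(sigma_rest, (truth.target_pct_mve / 100.0) * mve_amp)
    sigma = np.where(move > 0.5, sigma_move, sigma_rest)
    a45, a90 = artifact_amps
    task = (
        sigma * carrier
        + a45 * np.sin(2 * np.pi * 45.0 * times)
        + a90 * np.sin(2 * np.pi * 90.0 * times)
        + drift_amp * np.sin(2 * np.pi * 0.4 * times + rng.uniform(0, 2 * np.pi))
    )
    n_mve = int(round(mve_duration_s * fs))
    mve = mve_amp * _band_limited_carrier(n_mve, fs, rng)
    return SampledSeries(task, fs), SampledSeries(mve, fs)


def make_label_atlas(
    shape: tuple[int, int, int] = (24, 24, 24),
    segments: Sequence[str] = MOTOR_SEGMENTS,
    voxel_size_mm: float = 4.0,
) -> LabelAtlas:
    """Mirror-symmetric integer atlas: 6 segments × 2 hemispheres.

    The first voxel axis is left–right (RAS affine, low index = left); the
    mid-sagittal plane sits between the two halves, so the first-axis
    length must be even.  Within each hemisphere the segments tile a 2×3
    grid in the coronal/axial plane with a one-voxel background margin.
    """
    nx, ny, nz = shape
    if nx % 2:
        raise ValueError(f"first (left-right) axis must be even, got {nx}")
    if len(segments) != 6:
        raise ValueError("exactly 6 segments expected")
    data = np.zeros(shape, dtype=np.int16)
    half = nx // 2
    x_left = np.arange(1, half)  # margin at the outer edge
    y_edges = np.linspace(1, ny - 1, 3).round().astype(int)
    z_edges = np.linspace(1, nz - 1, 4).round().astype(int)
    rows = []
    seg_idx = 0
    for yi in range(2):
        for zi in range(3):
            seg = segments[seg_idx]
            ys = slice(y_edges[yi], y_edges[yi + 1])
            zs = slice(z_edges[zi], z_edges[zi + 1])
            label_l, label_r = 2 * seg_idx + 1, 2 * seg_idx + 2
            data[x_left, ys, zs] = label_l
            data[nx - 1 - x_left, ys, zs] = label_r
            rows.append({"label": label_l, "segment": seg, "hemisphere": "L"})
            rows.append({"label": label_r, "segment": seg, "hemisphere": "R"})
            seg_idx += 1
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.array(shape) - 1) / 2.0
    return LabelAtlas(data=data, affine=affine, table=pd.DataFrame(rows))


def simulate_beta_volume(
    atlas: LabelAtlas,
    truth: GroundTruth,
    effect: float = 2.0,
    noise_sd: float = 0.2,
    lesion_side: str = "L",
    fraction: float = 0.15,
    rng: Optional[np.random.Generator] = None,
) -> BetaVolume:
    """Beta volume whose expected laterality index equals ``truth.li_true``.

    In each segment pair, the pooled top-``fraction`` voxel budget ``k`` is
    split between hemispheres as k·(1±li)/2; those "active" voxels receive
    beta ≈ ``effect`` and everything else pure noise.  With noise_sd = 0 the
    recovered LI is exact up to the ±1/k rounding of the split.
    """
    if not np.isfinite(effect):
        raise ValueError("effect must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if lesion_side not in HEMISPHERES:
        raise ValueError("lesion_side must be 'L' or 'R'")
    rng = truth.rng(3) if rng is None else rng
    data = rng.normal(0.0, noise_sd, atlas.data.shape) if noise_sd > 0 else np.zeros(
        atlas.data.shape
    )
    ipsi, contra = lesion_side, ("R" if lesion_side == "L" else "L")
    for seg in atlas.segments:
        idx_i = np.flatnonzero(atlas.data == atlas.label_of(seg, ipsi))
        idx_c = np.flatnonzero(atlas.data == atlas.label_of(seg, contra))
        k = max(1, int(np.floor(fraction * (idx_i.size + idx_c.size))))
        n_i = int(np.clip(round(k * (1.0 + truth.li_true) / 2.0), 0, k))
        n_c = k - n_i
        hot_i = rng.choice(idx_i, size=min(n_i, idx_i.size), replace=False)
        hot_c = rng.choice(idx_c, size=min(n_c, idx_c.size), replace=False)
        flat = data.reshape(-1)
        flat[hot_i] += effect
        flat[hot_c] += effect
    return BetaVolume(data=data, affine=atlas.affine.copy())


# ---------------------------------------------------------------------------
# Cohort-level generation


def _clinical_scores(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinical score draws emulating a moderately-to-well recovered cohort.

    FM-arm ~ N(60.5, 5.6) clipped to [0, 66]; ARAT at its ceiling of 57 for
    about three quarters of patients, a handful of points below otherwise;
    %NHPT ~ N(69, 22.5) truncated positive.
    """
    fm = np.clip(np.round(rng.normal(60.5, 5.6, n)), 0, 66).astype(int)
    deficit = np.where(
        rng.random(n) < 0.75, 0, 1 + rng.poisson(3.0, n)
    )
    arat = np.clip(57 - deficit, 0, 57).astype(int)
    nhpt = np.clip(np.round(rng.normal(69.0, 22.5, n), 1), 5.0, None)
    return pd.DataFrame({"fm": fm, "arat": arat, "nhpt_pct": nhpt})


def simulate_cohort_table(
    n_patients: int = 20,
    n_controls: int = 15,
    seed: int = 0,
    n_rois: int = 12,
    roi_effect_mean: float = 1.0,
    roi_effect_sd: float = 0.15,
    subject_gain_sd: float = 0.25,
    fm_slope: float = 0.0,
    fm_roi: int = 0,
    group_roi_shift: float = 0.0,
) -> pd.DataFrame:
    """In-memory cohort table: groups, lesion sides, clinical scores, ROI betas.

    Each subject's ROI activations share a global activation gain
    (``subject_gain_sd``) on top of independent per-ROI variation
    (``roi_effect_sd``): ROI means are strongly correlated across subjects,
    as they are in real task-fMRI data — global signal variation is exactly
    what the proportional ROI threshold is there to absorb.

    ``fm_slope`` injects a linear dependence of the FM score on one ROI's
    activation (for brain–behavior power checks); ``group_roi_shift`` adds a
    group difference to every ROI (zero = the null regime).  Lesion sides
    alternate L/R so hemisphere flipping is exercised.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    groups = ["patient"] * n_patients + ["control"] * n_controls
    n = len(groups)
    roi_cols = [f"roi_{i:02d}" for i in range(n_rois)]
    gain = rng.normal(0.0, subject_gain_sd, (n, 1))
    betas = gain + rng.normal(roi_effect_mean, roi_effect_sd, (n, n_rois))
    betas[: n_patients] += group_roi_shift
    rows = pd.DataFrame(betas, columns=roi_cols)
    rows.insert(0, "subject", [f"S{i + 1:02d}" for i in range(n)])
    rows.insert(1, "group", groups)
    rows.insert(
        2,
        "lesion_side",
        [HEMISPHERES[i % 2] for i in range(n_patients)]
        + [HEMISPHERES[i % 2] for i in range(n_controls)],
    )
    clin = _clinical_scores(rng, n_patients)
    for col in ("fm", "arat", "nhpt_pct"):
        rows[col] = np.nan
        rows.loc[: n_patients - 1, col] = clin[col].to_numpy()
    if fm_slope != 0.0:
        fm = (
            60.5
            + fm_slope * (betas[:n_patients, fm_roi] - roi_effect_mean)
            + rng.normal(0.0, 2.0, n_patients)
        )
        rows.loc[: n_patients - 1, "fm"] = np.clip(np.round(fm), 0, 66)
    return rows


def simulate_cohort(
    out_dir: str | Path,
    n_patients: int = 20,
    n_controls: int = 15,
    seed: int = 0,
    truth: Optional[GroundTruth] = None,
    total_s: float = 360.0,
    block_s: float = 20.0,
    atlas_shape: tuple[int, int, int] = (24, 24, 24),
    overwrite: bool = False,
) -> Path:
    """Write a full synthetic cohort to disk and return its root directory.

    Layout::

        out_dir/
          cohort.csv                subject,group,lesion_side,fm,arat,nhpt_pct
          boxcar.json               task timing sidecar
          atlas.nii + labels.csv    shared label atlas
          <subject>/
            glove_active.csv        time_s,angle_deg (instructed hand)
            glove_inactive.csv      time_s,angle_deg (other hand)
            emg_task.csv            time_s,amplitude
            emg_mve.csv             time_s,amplitude
            beta_amp.nii            first-level beta volume (amplitude task)
            truth.json              ground-truth sidecar

    Fully reproducible from ``seed``: the same call produces byte-identical
    files.  Volumes are written uncompressed so the bytes do not depend on
    compression timestamps.
    """
    from . import io as hio  # local import to avoid a cycle

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out_dir} exists and is not empty; pass overwrite=True"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    base = truth or GroundTruth(seed=seed)
    boxcar = make_task_boxcar(block_s=block_s, total_s=total_s)
    atlas = make_label_atlas(shape=atlas_shape)
    hio.write_nifti(out_dir / "atlas.nii", atlas.data, atlas.affine)
    atlas.table.to_csv(out_dir / "labels.csv", index=False)
    (out_dir / "boxcar.json").write_text(
        json.dumps(
            {"block_s": block_s, "total_s": total_s, "dt": boxcar.dt}, indent=2
        )
    )
    table = simulate_cohort_table(n_patients, n_controls, seed=seed)
    table[["subject", "group", "lesion_side", "fm", "arat", "nhpt_pct"]].to_csv(
        out_dir / "cohort.csv", index=False, float_format="%.1f"
    )
    seq = np.random.SeedSequence([seed, 99])
    children = seq.spawn(len(table))
    for (_, row), child in zip(table.iterrows(), children):
        sdir = out_dir / row["subject"]
        sdir.mkdir()
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        truth_s = GroundTruth(
            mirror_gain=base.mirror_gain,
            target_pct_mve=base.target_pct_mve,
            li_true=base.li_true,
            movement_rate=base.movement_rate,
            seed=sub_seed,
        )
        active, inactive = simulate_glove_trace(boxcar, truth_s)
        hio.write_signal(sdir / "glove_active.csv", active)
        hio.write_signal(sdir / "glove_inactive.csv", inactive)
        task, mve = simulate_emg_trace(boxcar, truth_s)
        hio.write_signal(sdir / "emg_task.csv", task)
        hio.write_signal(sdir / "emg_mve.csv", mve)
        # moderate effect/noise ratio so proportional selections (and hence
        # LI) vary between subjects, as they do in real cohorts
        beta = simulate_beta_volume(
            atlas, truth_s, effect=1.0, noise_sd=0.5, lesion_side=row["lesion_side"]
        )
        hio.write_nifti(sdir / "beta_amp.nii", beta.data.astype(np.float32), beta.affine)
        (sdir / "truth.json").write_text(json.dumps(asdict(truth_s), indent=2))
    return out_dir
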