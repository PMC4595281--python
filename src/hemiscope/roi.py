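"""ROI analysis: proportional thresholding, mean betas, laterality, GLM.

Activity in each anatomical motor segment is summarized by the mean beta
over the 15% most active voxels of that segment (a *proportional*
threshold, so a global rescaling of a subject's betas changes nothing).
Lateralization is quantified per bilateral segment pair by pooling both
hemispheres, selecting the top 15% of the pooled voxels and counting them
per side:

    LI = (vox_i - vox_c) / (vox_i + vox_c)

with vox_i / vox_c the counts ipsilesional / contralesional to the stroke;
LI = 1 means all selected voxels sit in the ipsilesional hemisphere.

A simplified first-level block GLM is included to regenerate beta volumes
from voxel time series: discrete-cosine high-pass (128 s cutoff), optional
AR(1) prewhitening, raw boxcar regressor.  It emulates the structure of a
standard first-level analysis; it does not reproduce any particular
package's output.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import BetaVolume, LabelAtlas, RoiSummary, TaskBoxcar

__all__ = [
    "fit_block_glm",
    "select_top_voxels",
    "roi_mean_beta",
    "laterality_index",
    "flip_hemispheres",
    "smooth_volume",
    "summarize_rois",
    "DEFAULT_FRACTION",
]

DEFAULT_FRACTION = 0.15
DEFAULT_HP_CUTOFF_S = 128.0


def _dct_highpass_basis(n: int, dt: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis: all components slower than 1/cutoff Hz."""
    order = int(np.floor(2.0 * (n * dt) / cutoff_s + 1.0))
    k = np.arange(1, max(order, 1))
    t = np.arange(n)
    basis = np.cos(np.pi * np.outer(t + 0.5, k) / n)
    return basis


def fit_block_glm(
    ts: np.ndarray,
    boxcar: TaskBoxcar,
    hp_cutoff_s: float = DEFAULT_HP_CUTOFF_S,
    ar1: bool = False,
    affine: Optional[np.ndarray] = None,
) -> BetaVolume:
    """Per-voxel block-design GLM; returns the boxcar coefficient volume.

    ``ts`` is a 4-D array (x, y, z, t) whose last axis matches the boxcar
    grid.  The design is [boxcar, intercept, DCT drift terms]; with
    ``ar1=True`` a per-voxel lag-1 autoregressive coefficient is estimated
    from OLS residuals and both sides are prewhitened before refitting.
    Constant time series get beta 0 and are reported in a warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 4:
        raise ValueError(f"expected 4-D time-series array, got shape {ts.shape}")
    n_t = ts.shape[-1]
    if n_t != boxcar.n_samples:
        raise ValueError(
            f"time axis ({n_t}) does not match boxcar ({boxcar.n_samples})"
        )
    shape = ts.shape[:3]
    Y = ts.reshape(-1, n_t)
    flat_var = Y.var(axis=1)
    constant = flat_var == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant time series; their beta is set to 0"
        )
    reg = boxcar.values.astype(float)
    drift = _dct_highpass_basis(n_t, boxcar.dt, hp_cutoff_s)
    X = np.column_stack([reg, np.ones(n_t), drift])
    beta_full, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    betas = beta_full[0].copy()
    if ar1:
        resid = Y.T - X @ beta_full  # (t, v)
        num = np.sum(resid[1:] * resid[:-1], axis=0)
        den = np.sum(resid[:-1] ** 2, axis=0)
        rho = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        rho = np.clip(rho, -0.99, 0.99)
        # prewhiten: y'_t = y_t - rho y_{t-1}, same transform on the design
        Yw = Y[:, 1:] - rho[:, None] * Y[:, :-1]          # (v, t-1)
        Xw = X[None, 1:, :] - rho[:, None, None] * X[None, :-1, :]  # (v, t-1, p)
        xtx = np.einsum("vtp,vtq->vpq", Xw, Xw)
        xty = np.einsum("vtp,vt->vp", Xw, Yw)
        betas = np.linalg.solve(xtx, xty[..., None])[:, 0, 0]
    betas[constant] = 0.0
    if affine is None:
        affine = np.eye(4)
    return BetaVolume(data=betas.reshape(shape), affine=np.asarray(affine, float))


def _top_k_indices(beta_flat: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Flat indices of the k highest betas among ``candidates``.

    Ties at the threshold are broken by the lowest linear voxel index
    (stable sort on descending beta), so selections are deterministic
    across runs and platforms.
    """
    order = np.argsort(-beta_flat[candidates], kind="stable")
    return candidates[order[:k]]


def select_top_voxels(
    beta: BetaVolume,
    atlas: LabelAtlas,
    segment: str,
    hemisphere: str,
    fraction: float = DEFAULT_FRACTION,
) -> np.ndarray:
    """Flat indices of the top-``fraction`` most active voxels of one ROI.

    k = floor(fraction x N), with a minimum of one voxel so the ROI summary
    is always defined; an empty (segment, hemisphere) label is an error.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if beta.data.shape != atlas.data.shape:
        raise ValueError(
            f"beta grid {beta.data.shape} does not match atlas {atlas.data.shape}"
        )
    label = atlas.label_of(segment, hemisphere)
    candidates = np.flatnonzero(atlas.data == label)
    if candidates.size == 0:
        raise ValueError(f"segment '{segment}' ({hemisphere}) has no voxels")
    k = max(1, int(np.floor(fraction * candidates.size)))
    return _top_k_indices(beta.data.reshape(-1), candidates, k)


def roi_mean_beta(beta: BetaVolume, selection: np.ndarray) -> float:
    """Arithmetic mean beta over a selected voxel set."""
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty voxel selection")
    return float(beta.data.reshape(-1)[selection].mean())


def laterality_index(
    beta: BetaVolume,
    atlas: LabelAtlas,
    segment: str,
    lesion_side: str,
    fraction: float = DEFAULT_FRACTION,
) -> float:
    """LI over the pooled bilateral segment's top-``fraction`` voxels.

    Both hemispheres are pooled before thresholding ("combined left and
    right"), then the selected voxels are counted per side.
    """
    if lesion_side not in ("L", "R"):
        raise ValueError("lesion_side must be 'L' or 'R'")
    lab_l = atlas.label_of(segment, "L")
    lab_r = atlas.label_of(segment, "R")
    candidates = np.flatnonzero((atlas.data == lab_l) | (atlas.data == lab_r))
    if candidates.size == 0:
        raise ValueError(f"segment '{segment}' has no voxels")
    k = max(1, int(np.floor(fraction * candidates.size)))
    selected = _top_k_indices(beta.data.reshape(-1), candidates, k)
    sel_labels = atlas.data.reshape(-1)[selected]
    n_left = int(np.sum(sel_labels == lab_l))
    n_right = int(np.sum(sel_labels == lab_r))
    vox_i = n_left if lesion_side == "L" else n_right
    vox_c = n_right if lesion_side == "L" else n_left
    return (vox_i - vox_c) / (vox_i + vox_c)


def _lr_axis(affine: np.ndarray) -> int:
    """Voxel axis carrying the world left-right direction.

    The axis whose column dominates the first (x) row of the affine; an
    ambiguous (oblique) affine is rejected rather than guessed.
    """
    row = np.abs(affine[0, :3])
    axis = int(np.argmax(row))
    if row[axis] < 2.0 * (row.sum() - row[axis]) or row[axis] == 0:
        raise ValueError(
            "left-right axis is ambiguous from the affine; supply a volume "
            "with a dominant x-direction axis"
        )
    return axis


def flip_hemispheres(volume):
    """Mirror a volume over the mid-sagittal plane.

    For a :class:`BetaVolume` the grid is reversed along the left-right
    axis (the affine is kept, so the *content* is mirrored in world space —
    the operation used to map all lesions onto a common hemisphere).  For a
    :class:`LabelAtlas` the hemisphere column of the label table is swapped
    as well, so (segment, hemisphere) lookups stay anatomically correct.
    Applying the function twice is the identity.
    """
    axis = _lr_axis(volume.affine)
    flipped = np.flip(volume.data, axis=axis).copy()
    if isinstance(volume, LabelAtlas):
        table = volume.table.copy()
        table["hemisphere"] = table["hemisphere"].map({"L": "R", "R": "L"})
        return LabelAtlas(data=flipped, affine=volume.affine.copy(), table=table)
    if isinstance(volume, BetaVolume):
        return BetaVolume(
            data=flipped,
            affine=volume.affine.copy(),
            subject=volume.subject,
            condition=volume.condition,
        )
    raise TypeError(f"cannot flip object of type {type(volume).__name__}")


def smooth_volume(beta: BetaVolume, fwhm_mm: float = 8.0) -> BetaVolume:
    """Gaussian smoothing with the given full-width-at-half-maximum in mm.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxels via the
    affine's voxel sizes.  fwhm = 0 returns the input unchanged.  The ROI
    path runs on unsmoothed data; smoothing is for voxelwise group maps.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return BetaVolume(
            data=beta.data.copy(), affine=beta.affine.copy(),
            subject=beta.subject, condition=beta.condition,
        )
    voxel_sizes = np.sqrt((beta.affine[:3, :3] ** 2).sum(axis=0))
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / voxel_sizes
    smoothed = ndimage.gaussian_filter(beta.data, sigma=sigma_vox)
    return BetaVolume(
        data=smoothed, affine=beta.affine.copy(),
        subject=beta.subject, condition=beta.condition,
    )


def summarize_rois(
    beta: BetaVolume,
    atlas: LabelAtlas,
    lesion_side: str,
    fraction: float = DEFAULT_FRACTION,
) -> list[RoiSummary]:
    """Per-(segment, hemisphere) mean betas plus the pair-level LI."""
    out = []
    for seg in atlas.segments:
        li = laterality_index(beta, atlas, seg, lesion_side, fraction)
        for hemi in ("L", "R"):
            sel = select_top_voxels(beta, atlas, seg, hemi, fraction)
            out.append(
                RoiSummary(
                    segment=seg,
                    hemisphere=hemi,
                    n_selected=sel.size,
                    mean_beta=roi_mean_beta(beta, sel),
                    li=li,
                )
            )
    return out
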