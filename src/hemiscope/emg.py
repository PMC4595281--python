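"""Surface-EMG processing: artifact removal, %MVE normalization, MM_EMG.

The EMG is recorded over the extensor digitorum communis of the hand
*contralateral* to the instructed hand, to detect task-locked isometric
mirror contractions.  The chain is:

1. notch filters at 45 and 90 Hz (scanner gradient artifacts),
2. 10 Hz high-pass (movement artifacts),
3. full-wave rectification (regains low-frequency burst content),
4. 2–130 Hz band-pass.

From the preprocessed signal two quantities are derived:

* ``%MVE`` — mean task amplitude as a percentage of the amplitude during a
  maximal voluntary extension (MVE) recording.  Normalizing by each
  subject's own MVE cancels gain factors (skin conductivity, electrode
  placement, muscle volume).
* ``MM_EMG = r(T, E_EMG) * %MVE`` — Pearson correlation of the EMG
  envelope with the task boxcar, weighted by %MVE.  A contraction has to be
  both task-locked *and* non-negligible in amplitude to score high.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .core import EnvelopeSeries, MirrorEmgResult, SampledSeries, TaskBoxcar

__all__ = [
    "preprocess_emg",
    "compute_envelope",
    "percent_mve",
    "mirror_emg_score",
    "safe_pearson",
]

#: Band edges of the preprocessing chain (Hz).
NOTCH_FREQS = (45.0, 90.0)
NOTCH_Q = 30.0
HIGHPASS_HZ = 10.0
BANDPASS_HZ = (2.0, 130.0)
FILTER_ORDER = 4
#: Envelope smoothing window (seconds), shared with the glove module.
ENVELOPE_SMOOTH_S = 0.5


def safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r that returns 0 (with a warning) for zero-variance input.

    Degenerate inputs (flat envelope, flat boxcar) would otherwise
    propagate NaN into cohort tables; a zero correlation is the neutral
    value for "no task-locked structure".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance input to correlation; returning r = 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def preprocess_emg(raw: SampledSeries) -> SampledSeries:
    """Apply the EMG artifact-removal chain, in the stated order.

    All filters are zero-phase (forward–backward) so envelope timing is
    unbiased.  Requires ``fs >= 260`` Hz so the 130 Hz band edge is below
    Nyquist.
    """
    fs = raw.fs
    if fs < 2 * BANDPASS_HZ[1]:
        raise ValueError(
            f"sampling rate {fs} Hz violates the Nyquist constraint for the "
            f"{BANDPASS_HZ[1]} Hz band edge; need fs >= {2 * BANDPASS_HZ[1]} Hz"
        )
    x = raw.values
    for f0 in NOTCH_FREQS:
        b, a = sps.iirnotch(f0, NOTCH_Q, fs=fs)
        x = sps.filtfilt(b, a, x)
    sos_hp = sps.butter(FILTER_ORDER, HIGHPASS_HZ, "highpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, x)
    x = np.abs(x)  # full-wave rectification
    sos_bp = sps.butter(FILTER_ORDER, BANDPASS_HZ, "bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos_bp, x)
    return SampledSeries(values=x, fs=fs)


def compute_envelope(
    series: SampledSeries, smooth_s: float = ENVELOPE_SMOOTH_S, source: str = "emg"
) -> EnvelopeSeries:
    """Amplitude envelope: |analytic signal|, moving-average smoothed.

    The magnitude of the Hilbert analytic signal tracks instantaneous
    amplitude; the moving average (default 0.5 s) suppresses carrier-rate
    ripple so the envelope follows the block structure.
    """
    if smooth_s < 0:
        raise ValueError("smooth_s must be non-negative")
    env = np.abs(sps.hilbert(series.values))
    width = int(round(smooth_s * series.fs))
    if width > 1:
        from scipy.ndimage import uniform_filter1d

        env = uniform_filter1d(env, size=width, mode="nearest")
    return EnvelopeSeries(values=env, fs=series.fs, source=source)


def percent_mve(
    task_emg: SampledSeries,
    mve_emg: SampledSeries,
    move_mask: np.ndarray,
) -> float:
    """Mean task EMG amplitude as % of the maximal-voluntary-extension mean.

    Both inputs must already be preprocessed.  "Amplitude" is the mean
    absolute value (the band-pass at the end of the chain re-centres the
    rectified signal, so a plain mean would be near zero by construction).
    The task mean is taken over movement-block samples only; the MVE mean
    over the full MVE recording.  Any common gain cancels in the ratio.
    """
    move_mask = np.asarray(move_mask, dtype=bool)
    if move_mask.size != task_emg.n_samples:
        raise ValueError("move_mask length does not match task recording")
    if not move_mask.any():
        raise ValueError("move_mask selects no samples")
    mve_level = float(np.mean(np.abs(mve_emg.values)))
    task_level = float(np.mean(np.abs(task_emg.values[move_mask])))
    if mve_level <= 0 or not np.isfinite(mve_level):
        raise ValueError("mean MVE amplitude is ~0; cannot normalize")
    return 100.0 * task_level / mve_level


def mirror_emg_score(
    envelope: EnvelopeSeries, boxcar: TaskBoxcar, pct: float
) -> MirrorEmgResult:
    """MM_EMG = r(boxcar, EMG envelope) × %MVE.

    The boxcar is sampled onto the envelope's grid.  The identity
    ``mm_score == task_corr * pct`` holds exactly by construction.
    """
    if pct < 0:
        raise ValueError("%MVE must be non-negative")
    t = boxcar.sample(envelope.sample_times)
    r = safe_pearson(t, envelope.values)
    return MirrorEmgResult(pct_mve_mean=pct, task_corr=r, mm_score=r * pct)
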