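"""Data-glove kinematics: movement counting, compliance, glove mirror score.

The glove records the average flexion angle of the fingers (degrees, 0–90
after calibration) of each hand during the amplitude task.  Three
performance measures are derived:

* number of movements — (n_maxima + n_minima) / 2 of the detrended signal;
* compliance correlation — Pearson r between the movement-signal envelope
  and the task boxcar (task adherence of the instructed hand);
* MM_glove — the same correlation computed for the hand that was *not*
  instructed to move (overt mirror movements).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import KinematicsResult, SampledSeries, TaskBoxcar
from .emg import compute_envelope, safe_pearson

__all__ = [
    "detrend_resample",
    "count_movements",
    "compliance_correlation",
    "mirror_glove_score",
    "score_glove_pair",
    "RESAMPLE_DT",
    "DRIFT_HIGHPASS_HZ",
]

#: Target temporal resolution after resampling (seconds).
RESAMPLE_DT = 0.015
#: Drift-removal high-pass cutoff (Hz).  Movement is ~0.5–1 Hz; 0.05 Hz
#: removes slow sensor drift without touching it.
DRIFT_HIGHPASS_HZ = 0.05
_FILTER_ORDER = 4
#: Default peak prominence as a fraction of the robust signal range.
DEFAULT_PROMINENCE_FRAC = 0.05


def detrend_resample(raw: SampledSeries, dt: float = RESAMPLE_DT) -> SampledSeries:
    """High-pass the glove signal against drift and resample to a 15 ms grid.

    Zero-phase 4th-order Butterworth at 0.05 Hz, then linear interpolation
    onto the uniform ``dt`` grid.  The input must span at least two
    high-pass periods for the filter to be meaningful.
    """
    min_dur = 2.0 / DRIFT_HIGHPASS_HZ
    if raw.duration < min_dur:
        raise ValueError(
            f"glove recording of {raw.duration:.1f} s is too short; need at "
            f"least {min_dur:.0f} s (two periods of the {DRIFT_HIGHPASS_HZ} Hz high-pass)"
        )
    sos = sps.butter(
        _FILTER_ORDER, DRIFT_HIGHPASS_HZ, "highpass", fs=raw.fs, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, raw.values, padtype="odd")
    t_new = np.arange(0.0, raw.duration - 0.5 * dt, dt)
    resampled = np.interp(t_new, raw.sample_times, filtered)
    return SampledSeries(values=resampled, fs=1.0 / dt)


def count_movements(trace: SampledSeries, prominence: float | None = None) -> int:
    """Number of movements: (maxima + minima) / 2, floor.

    Extrema with prominence below the threshold are ignored so measurement
    noise does not register as movement.  The default threshold is 5% of
    the 5th–95th percentile range of the trace.
    """
    x = trace.values
    if prominence is None:
        lo, hi = np.percentile(x, [5, 95])
        prominence = DEFAULT_PROMINENCE_FRAC * (hi - lo)
    if prominence <= 0:  # flat signal
        return 0
    n_max = sps.find_peaks(x, prominence=prominence)[0].size
    n_min = sps.find_peaks(-x, prominence=prominence)[0].size
    return int((n_max + n_min) // 2)


def compliance_correlation(trace: SampledSeries, boxcar: TaskBoxcar) -> float:
    """Envelope–boxcar Pearson r of the instructed hand (task adherence)."""
    env = compute_envelope(trace, source="glove")
    t = boxcar.sample(env.sample_times)
    return safe_pearson(t, env.values)


def mirror_glove_score(inactive_trace: SampledSeries, boxcar: TaskBoxcar) -> float:
    """MM_glove: envelope–boxcar r of the hand not instructed to move.

    Identical contract to :func:`compliance_correlation`; a value near 0
    means no overt mirror movement.
    """
    return compliance_correlation(inactive_trace, boxcar)


def score_glove_pair(
    active_raw: SampledSeries,
    inactive_raw: SampledSeries,
    boxcar: TaskBoxcar,
    prominence: float | None = None,
) -> KinematicsResult:
    """Full kinematic scoring of one run: both hands, all three measures."""
    active = detrend_resample(active_raw)
    inactive = detrend_resample(inactive_raw)
    return KinematicsResult(
        n_movements=count_movements(active, prominence),
        compliance_r=compliance_correlation(active, boxcar),
        mirror_r=mirror_glove_score(inactive, boxcar),
    )
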