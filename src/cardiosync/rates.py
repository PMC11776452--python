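"""Peak trains to instantaneous rate (BPM) and wrapped cycle phase.

The correlation family works on instantaneous heart/respiration rate:
60/interval assigned at the completing peak, interpolated at the raw
sampling rate, and decimated (with anti-alias filtering) to the common
20 Hz analysis grid.  The phase family works on the cycle phase angle:
for each inter-peak interval a sinusoid of frequency 1/IBI is fitted so
its maximum falls on the detected peak; the analytic-signal angle of that
piecewise surrogate is, in closed form, a linear ramp from 0 to 2*pi over
the cycle, wrapped to (-pi, pi] — 0 at the peak, +/-pi at mid-cycle.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .features import wrap_angle
from .prep import PLAUSIBLE_INTERVALS_S
from .series import ANALYSIS_FS, PeakSeries, PhaseSeries, RateSeries

__all__ = ["peaks_to_rate", "fit_cycle_phase", "mean_rate_hz", "mean_cycle_s"]


def mean_rate_hz(peaks: PeakSeries) -> float:
    """Participant's mean event frequency (Hz) = 1 / mean interval."""
    return 1.0 / float(np.mean(peaks.intervals_s))


def mean_cycle_s(peaks: PeakSeries) -> float:
    return float(np.mean(peaks.intervals_s))


def peaks_to_rate(
    peaks: PeakSeries,
    fs_out: float = ANALYSIS_FS,
    fs_interp: float = 1000.0,
    anchor: str = "mid",
) -> RateSeries:
    """Instantaneous rate in BPM on the uniform ``fs_out`` grid.

    BPM_k = 60/interval_k is linearly interpolated at ``fs_interp``, held
    constant beyond the first/last anchor, and decimated to ``fs_out``
    through a zero-phase anti-alias FIR.  ``anchor='mid'`` (default) places
    each BPM value at the interval midpoint — 60/interval estimates the
    average rate over the interval, so the midpoint is the unbiased
    placement and keeps stimulus-response lags undistorted.
    ``anchor='end'`` places it at the completing peak (the causal
    convention), which delays the reconstructed series by about half a
    cycle.
    """
    if len(peaks) < 2:
        raise ValueError("need at least two peaks to form an interval")
    intervals = peaks.intervals_s
    bpm = 60.0 / intervals
    if anchor == "mid":
        anchors = (peaks.times_s[:-1] + peaks.times_s[1:]) / 2.0
    elif anchor == "end":
        anchors = peaks.times_s[1:]
    else:
        raise ValueError("anchor must be 'mid' or 'end'")
    n_fine = int(round(peaks.duration_s * fs_interp))
    t_fine = np.arange(n_fine) / fs_interp
    fine = np.interp(t_fine, anchors, bpm)  # edges held constant
    down = int(round(fs_interp / fs_out))
    if abs(fs_interp / fs_out - down) > 1e-9:
        raise ValueError("fs_interp must be an integer multiple of fs_out")
    coarse = sps.resample_poly(fine, 1, down, padtype="line")
    return RateSeries(bpm=coarse, fs_hz=fs_out)


def fit_cycle_phase(
    peaks: PeakSeries,
    signal=None,
    channel: str = "heart",
    fs_out: float = ANALYSIS_FS,
) -> PhaseSeries:
    """Wrapped cycle-phase series on the analysis grid.

    ``signal`` (the detrended, z-scored filtered recording) only sets the
    surrogate's amplitude, which does not enter the angle; the phase is
    evaluated in closed form.  Cycles whose interval falls outside the
    channel's plausibility bounds are masked (NaN), as are samples before
    the first and after the last peak — phase is never fabricated.
    """
    if len(peaks) < 2:
        raise ValueError("need at least two peaks to define a cycle")
    lo, hi = PLAUSIBLE_INTERVALS_S[channel]
    times = peaks.times_s
    intervals = peaks.intervals_s
    n_out = int(round(peaks.duration_s * fs_out))
    t = np.arange(n_out) / fs_out
    idx = np.searchsorted(times, t, side="right") - 1
    valid = (idx >= 0) & (idx < intervals.size)
    safe = np.clip(idx, 0, intervals.size - 1)
    frac = (t - times[safe]) / intervals[safe]
    angle = wrap_angle(2 * np.pi * frac)
    angle[~valid] = np.nan
    angle[valid & ((intervals[safe] < lo) | (intervals[safe] > hi))] = np.nan
    return PhaseSeries(angle_rad=angle, fs_hz=fs_out)
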