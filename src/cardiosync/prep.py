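"""Preprocessing of raw 1000 Hz ECG and respiration-belt recordings.

Stages: short-gap interpolation, channel-specific zero-phase Butterworth
filtering with demeaning, peak detection (QRS complexes; inspiration
maxima), reproducible manual-edit overlays, and per-piece quality
rejection.  Everything downstream works on the resulting
:class:`~cardiosync.series.PeakSeries`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .series import PeakSeries

__all__ = [
    "RawRecording",
    "interpolate_gaps",
    "filter_physio",
    "detect_r_peaks",
    "detect_resp_peaks",
    "apply_peak_overrides",
    "reject_piece",
    "RejectionCriteria",
]

#: refractory period between successive R-peaks (s); guards against T waves
R_REFRACTORY_S = 0.25
#: plausible interval bounds (s) per channel, used for piece rejection
PLAUSIBLE_INTERVALS_S = {"heart": (0.33, 3.0), "resp": (1.0, 20.0)}


@dataclass
class RawRecording:
    """One continuous raw channel for one participant, piece, condition."""

    samples: np.ndarray
    fs_hz: float = 1000.0
    channel: str = "heart"  # heart | resp
    participant_id: str = ""
    concert_id: str = ""
    piece_id: str = ""
    condition: str = ""
    missing_mask: np.ndarray | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel not in ("heart", "resp"):
            raise ValueError("channel must be 'heart' or 'resp'")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.samples.size, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.samples.shape:
                raise ValueError("missing mask must align with samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


def _missing_runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def interpolate_gaps(rec: RawRecording, max_gap_ms: float = 60.0) -> RawRecording:
    """Linearly fill flagged gaps up to ``max_gap_ms``; longer gaps stay
    flagged and are reported in ``flags``."""
    out = rec.samples.copy()
    mask = rec.missing_mask.copy()
    max_n = int(round(max_gap_ms * rec.fs_hz / 1000.0))
    flags = list(rec.flags)
    for start, stop in _missing_runs(rec.missing_mask):
        length = stop - start
        if length <= max_n and start > 0 and stop < out.size:
            lo, hi = out[start - 1], out[stop]
            out[start:stop] = lo + (hi - lo) * np.arange(1, length + 1) / (length + 1)
            mask[start:stop] = False
        else:
            flags.append(("long_gap", start / rec.fs_hz, length / rec.fs_hz))
            warnings.warn(
                f"gap of {length / rec.fs_hz * 1000:.0f} ms exceeds "
                f"{max_gap_ms:.0f} ms; left unfilled",
                stacklevel=2,
            )
    return replace(rec, samples=out, missing_mask=mask, flags=flags)


def filter_physio(rec: RawRecording, order: int = 4) -> RawRecording:
    """Channel filter: respiration low-pass 2 Hz, ECG band-pass 0.6-20 Hz
    (Butterworth, 4th order, zero-phase), then demean."""
    if rec.channel == "resp":
        if rec.fs_hz <= 4:
            raise ValueError("sampling rate too low for a 2 Hz low-pass")
        sos = sps.butter(order, 2.0, btype="lowpass", fs=rec.fs_hz, output="sos")
    else:
        if rec.fs_hz <= 40:
            raise ValueError("sampling rate too low for a 0.6-20 Hz band-pass")
        sos = sps.butter(order, [0.6, 20.0], btype="bandpass", fs=rec.fs_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    filtered = filtered - filtered.mean()
    return replace(rec, samples=filtered)


def detect_r_peaks(rec: RawRecording, refractory_s: float = R_REFRACTORY_S) -> PeakSeries:
    """QRS detection on a filtered ECG channel.

    Derivative-energy detector: the squared first derivative is smoothed
    over 150 ms; energy peaks above an adaptive threshold mark QRS
    complexes, which are then refined to the local signal maximum.  A
    quality gate (energy peak must dominate the background) returns an
    empty series on flat or noise-only input, and the refractory period
    keeps T waves from being picked up as R waves.
    """
    x = rec.samples
    fs = rec.fs_hz
    duration = rec.duration_s
    energy = uniform_filter1d(np.gradient(x) ** 2, size=max(int(0.15 * fs), 1))
    peak_e = float(energy.max())
    background = float(np.median(energy))
    if peak_e <= 0 or (background > 0 and peak_e < 50 * background):
        warnings.warn("no clear QRS energy found; returning empty peak series", stacklevel=2)
        return PeakSeries(np.array([]), duration, source="detected", quality_flag="empty")
    cand, _ = sps.find_peaks(
        energy, height=0.2 * peak_e, distance=max(int(refractory_s * fs), 1)
    )
    half = int(0.05 * fs)
    refined = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, x.size)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    times = np.unique(np.asarray(refined)) / fs
    # enforce the refractory period after refinement, keeping larger peaks
    kept: list[float] = []
    for tpk in times:
        if kept and tpk - kept[-1] < refractory_s:
            if x[int(tpk * fs)] > x[int(kept[-1] * fs)]:
                kept[-1] = tpk
        else:
            kept.append(tpk)
    return PeakSeries(np.asarray(kept), duration, source="detected")


def detect_resp_peaks(
    rec: RawRecording,
    threshold_frac: float = 0.3,
    min_interval_s: float = 1.5,
    range_window_s: float = 60.0,
) -> PeakSeries:
    """Inspiration peaks: local maxima exceeding a threshold defined
    relative to the rolling signal range (robust to amplitude drift),
    separated by at least ``min_interval_s``."""
    x = rec.samples
    fs = rec.fs_hz
    win = max(int(range_window_s * fs), 3)
    roll_max = maximum_filter1d(x, size=win)
    roll_min = minimum_filter1d(x, size=win)
    rng = roll_max - roll_min
    if float(rng.max()) <= 0:
        warnings.warn("constant respiration signal; no peaks", stacklevel=2)
        return PeakSeries(np.array([]), rec.duration_s, quality_flag="empty")
    threshold = roll_min + (0.5 + threshold_frac / 2.0) * rng
    idx, _ = sps.find_peaks(x, distance=max(int(min_interval_s * fs), 1))
    idx = idx[x[idx] >= threshold[idx]]
    return PeakSeries(idx / fs, rec.duration_s, source="detected")


def apply_peak_overrides(
    peaks: PeakSeries, overrides, match_tol_s: float = 0.020
) -> PeakSeries:
    """Apply a reproducible manual-screening edit list.

    ``overrides`` is an iterable of ``(action, time_s)`` with action in
    {"add", "remove"}; removals must match an existing peak within
    ``match_tol_s``.  Per-peak provenance is recorded.
    """
    times = list(peaks.times_s)
    prov = (
        list(peaks.provenance)
        if peaks.provenance is not None
        else ["detected"] * len(times)
    )
    for action, t in overrides:
        t = float(t)
        if not 0 <= t <= peaks.duration_s:
            raise ValueError(f"edit time {t} s outside the piece span")
        if action == "add":
            times.append(t)
            prov.append("added")
        elif action == "remove":
            if not times:
                raise ValueError("cannot remove a peak from an empty series")
            diffs = np.abs(np.asarray(times) - t)
            j = int(np.argmin(diffs))
            if diffs[j] > match_tol_s:
                raise ValueError(f"no peak within {match_tol_s * 1000:.0f} ms of {t} s")
            times.pop(j)
            prov.pop(j)
        else:
            raise ValueError(f"unknown edit action {action!r}")
    order = np.argsort(times)
    return PeakSeries(
        np.asarray(times)[order],
        peaks.duration_s,
        source="manual" if len(overrides) else peaks.source,
        provenance=np.asarray(prov, dtype=object)[order],
    )


@dataclass
class RejectionCriteria:
    """Piece-level quality rule: too many implausible intervals, too many
    long gaps, or too few peaks and the piece is dropped."""

    max_implausible_frac: float = 0.10
    max_long_gaps: int = 0
    min_peaks: int = 2


def reject_piece(
    peaks: PeakSeries,
    channel: str = "heart",
    criteria: RejectionCriteria | None = None,
    n_long_gaps: int = 0,
) -> tuple[bool, str]:
    """Return ``(keep, reason)`` for one participant-piece peak series."""
    criteria = criteria or RejectionCriteria()
    if len(peaks) < criteria.min_peaks:
        return False, f"too few peaks ({len(peaks)} < {criteria.min_peaks})"
    lo, hi = PLAUSIBLE_INTERVALS_S[channel]
    ivals = peaks.intervals_s
    bad = float(np.mean((ivals < lo) | (ivals > hi)))
    if bad > criteria.max_implausible_frac:
        return False, f"{bad:.0%} of intervals outside [{lo}, {hi}] s"
    if n_long_gaps > criteria.max_long_gaps:
        return False, f"{n_long_gaps} unfillable gaps"
    return True, "ok"
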