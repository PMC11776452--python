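"""Stimulus features: spectral flux, audience-frequency sub-bands, flux phase.

Spectral flux — the Euclidean distance between magnitude spectra of
successive short-time frames — tracks acoustic change (note onsets,
dynamics) and is the stimulus feature correlated with audience heart and
respiration rates.  For the phase-coherence family the flux is band-pass
filtered at the audience's own heart/respiration frequency range (the
interquartile range of participants' mean rates) before extracting its
analytic-signal phase.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .series import ANALYSIS_FS, FluxSeries, PhaseSeries

__all__ = [
    "FrequencyBand",
    "spectral_flux",
    "audience_band",
    "subband_phase",
    "flux_similarity",
]

#: IQR fallback half-width (Hz) when an audience has (near-)identical rates
DEGENERATE_BAND_PAD_HZ = 0.05


@dataclass
class FrequencyBand:
    lo_hz: float
    hi_hz: float
    provenance: str = "fixed"

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError("need 0 < lo < hi")


def _resample_to_analysis_fs(x: np.ndarray, native_fs: float) -> np.ndarray:
    ratio = Fraction(ANALYSIS_FS / native_fs).limit_denominator(1000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator, padtype="line")


def spectral_flux(
    audio: np.ndarray,
    fs_hz: float,
    frame_ms: float = 25.0,
    overlap: float = 0.5,
    rectified: bool = False,
) -> FluxSeries:
    """Spectral flux per STFT frame (Hann window, magnitude spectra).

    ``flux[j] = || |S_j| - |S_{j-1}| ||_2`` with ``flux[0] = 0``.  With the
    default 25 ms frames at 50% overlap the native frame rate is 80 Hz; a
    20 Hz resampled copy is attached for the synchrony grid.  Setting
    ``rectified`` keeps only spectral increases before the norm (off by
    default: plain Euclidean distance).
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim == 2:  # downmix
        audio = audio.mean(axis=1)
    nperseg = int(round(fs_hz * frame_ms / 1000.0))
    hop = max(int(round(nperseg * (1.0 - overlap))), 1)
    if audio.size < nperseg + hop:
        raise ValueError("audio shorter than two analysis frames")
    frames = sliding_window_view(audio, nperseg)[::hop]
    spectra = np.abs(np.fft.rfft(frames * sps.windows.hann(nperseg, sym=False), axis=1))
    diff = np.diff(spectra, axis=0)
    if rectified:
        diff = np.clip(diff, 0.0, None)
    flux = np.concatenate(([0.0], np.linalg.norm(diff, axis=1)))
    hop_s = hop / fs_hz
    flux20 = _resample_to_analysis_fs(flux, 1.0 / hop_s)
    return FluxSeries(flux=flux, frame_hop_s=hop_s, band="full", flux_20hz=flux20)


def audience_band(mean_rates_hz, pad_hz: float = DEGENERATE_BAND_PAD_HZ) -> FrequencyBand:
    """[Q1, Q3] of participants' mean rates (Hz), linear-interpolated
    quantiles; a degenerate IQR is widened by ``pad_hz`` on each side."""
    rates = np.asarray(list(mean_rates_hz), dtype=float)
    if rates.size < 4:
        warnings.warn(
            f"audience band estimated from only {rates.size} rates", stacklevel=2
        )
    lo, hi = np.quantile(rates, [0.25, 0.75])
    provenance = "audience_iqr"
    if hi - lo < 1e-9:
        lo, hi = lo - pad_hz, hi + pad_hz
        provenance = "audience_iqr_degenerate_widened"
    return FrequencyBand(float(max(lo, 1e-6)), float(hi), provenance)


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return np.where(out <= -np.pi, out + 2 * np.pi, out)


def subband_phase(flux: FluxSeries, band: FrequencyBand, order: int = 4) -> PhaseSeries:
    """Analytic-signal phase of band-limited spectral flux, on the 20 Hz grid.

    The flux is zero-phase Butterworth band-passed at its native frame rate,
    Hilbert-transformed, and the unwrapped angle interpolated onto the
    analysis grid.  Phase 0 falls on band-limited flux maxima.
    """
    fs = flux.frame_fs_hz
    if band.hi_hz >= fs / 2:
        raise ValueError("band extends to or beyond the flux Nyquist frequency")
    sos = sps.butter(order, [band.lo_hz, band.hi_hz], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, flux.flux)
    analytic = sps.hilbert(filtered)
    unwrapped = np.unwrap(np.angle(analytic))
    t_native = flux.frame_times_s
    t_out = np.arange(0.0, t_native[-1] + 1e-9, 1.0 / ANALYSIS_FS)
    angle = wrap_angle(np.interp(t_out, t_native, unwrapped))
    return PhaseSeries(angle_rad=angle)


def flux_similarity(flux_a: FluxSeries | np.ndarray, flux_b: FluxSeries | np.ndarray) -> float:
    """Pearson correlation of two full-band flux series (truncated to the
    common length); NaN if either series has zero variance."""
    a = flux_a.flux if isinstance(flux_a, FluxSeries) else np.asarray(flux_a, float)
    b = flux_b.flux if isinstance(flux_b, FluxSeries) else np.asarray(flux_b, float)
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance flux: similarity undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
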