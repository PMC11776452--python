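"""Synthetic concert audiences with known ground truth.

Emulates the measurement situation of a two-concert chamber-music study:
each participant contributes a cardiac (R-peak) and a respiratory
(inspiration-peak) event train per piece and presentation condition
(audio-visual AV vs. audio-only AO).  Event trains are produced by an
inhomogeneous point process via time rescaling, so a specified
instantaneous-rate function maps exactly onto inter-beat intervals:

    rate(t) [BPM] = base + coupling_gain * flux_z(t - lag) + orienting(t) + noise(t)

* ``flux_z`` is the z-scored spectral flux of the stimulus — participants'
  rates track acoustic change with a fixed physiological lag,
* ``orienting(t)`` is a deceleration-acceleration waveform at annotated
  section boundaries (two 10-s half-cosine lobes; the deceleration trough
  falls on the boundary, the acceleration peak ~10 s after, matching the
  event-related heart-rate orienting response),
* ``noise(t)`` is smooth (Gaussian-filtered) rate noise.

Base rhythms default to the audience averages of ~1.01 Hz (heart) and
~0.30 Hz (respiration).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter1d

from .series import ANALYSIS_FS, BOUNDARY_COLUMNS, PeakSeries

__all__ = [
    "StimulusSpec",
    "ParticipantSpec",
    "generate_stimulus",
    "generate_audience",
    "render_waveforms",
    "default_stimulus_spec",
    "default_audience_specs",
    "generate_study",
    "StudyData",
]


@dataclass
class StimulusSpec:
    """Blueprint for one synthetic 'piece': tones plus section boundaries."""

    duration_s: float
    boundary_times_s: list[float] = field(default_factory=list)
    tone_schedule: list[tuple[float, float, float]] = field(default_factory=list)
    sample_rate_hz: int = 8000
    piece_id: str = "piece"
    section_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        b = np.asarray(self.boundary_times_s, dtype=float)
        if b.size and (np.any(np.diff(b) <= 0) or b.min() <= 0 or b.max() >= self.duration_s):
            raise ValueError("boundaries must be strictly increasing within (0, duration)")
        onsets = [t for t, _, _ in self.tone_schedule]
        if len(onsets) != len(set(onsets)):
            raise ValueError("overlapping tones with identical onsets")
        if onsets and (min(onsets) < 0 or max(onsets) >= self.duration_s):
            raise ValueError("tone onsets must fall within the piece")


@dataclass
class ParticipantSpec:
    """Ground-truth response parameters for one audience member.

    ``coupling_gain`` is in BPM per standard deviation of normalized flux;
    ``lag_ms`` the stimulus-to-response delay; ``orienting_depth_bpm`` the
    trough depth of the boundary deceleration.  Respiration reuses the
    heart parameters scaled by the ``resp_*`` factors, with its own lag.
    """

    participant_id: str
    concert_id: str = "c1"
    base_heart_hz: float = 1.01
    base_resp_hz: float = 0.30
    coupling_gain: float = 1.5
    lag_ms: float = 600.0
    orienting_depth_bpm: float = 0.5
    noise_sd_bpm: float = 1.0
    seed: int = 0
    resp_lag_ms: float = 1600.0
    resp_coupling_scale: float = 0.4
    resp_orienting_scale: float = 0.4
    resp_noise_sd_bpm: float = 0.5

    def __post_init__(self) -> None:
        if self.base_heart_hz <= self.base_resp_hz:
            raise ValueError("heart rhythm must be faster than respiration")
        if self.lag_ms < 0 or self.lag_ms >= 1000.0 / self.base_heart_hz:
            raise ValueError("heart lag must be within one mean cardiac cycle")
        if self.resp_lag_ms < 0 or self.resp_lag_ms >= 1000.0 / self.base_resp_hz:
            raise ValueError("respiration lag must be within one mean breath cycle")
        for name in ("coupling_gain", "orienting_depth_bpm", "noise_sd_bpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# ---------------------------------------------------------------------------
# Stimulus rendering
# ---------------------------------------------------------------------------

def generate_stimulus(spec: StimulusSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a mono waveform plus its boundary-annotation table.

    Each scheduled tone sounds from its onset until the next onset (or the
    end of the piece), so amplitude/frequency changes happen exactly at the
    scheduled onsets and spectral flux peaks there.
    """
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    wave = np.zeros(n)
    sched = sorted(spec.tone_schedule)
    t = np.arange(n) / fs
    for i, (onset, freq, amp) in enumerate(sched):
        end = sched[i + 1][0] if i + 1 < len(sched) else spec.duration_s
        i0, i1 = int(round(onset * fs)), int(round(end * fs))
        seg_t = t[i0:i1]
        wave[i0:i1] = amp * np.sin(2 * np.pi * freq * seg_t)

    labels = spec.section_labels or [
        f"S{i + 1}" for i in range(len(spec.boundary_times_s) + 1)
    ]
    ann = pd.DataFrame(
        {
            "piece_id": spec.piece_id,
            "boundary_time_s": list(spec.boundary_times_s),
            # label of the section that STARTS at each boundary
            "section_label": labels[1 : len(spec.boundary_times_s) + 1],
        },
        columns=BOUNDARY_COLUMNS,
    )
    return wave, ann


def write_stimulus_wav(path: str | Path, wave: np.ndarray, fs: int) -> None:
    scaled = np.clip(wave, -1, 1)
    wavfile.write(str(path), fs, (scaled * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Rate construction and time rescaling
# ---------------------------------------------------------------------------

#: acceleration-overshoot amplitude relative to the deceleration depth
ORIENTING_OVERSHOOT = 0.4


def orienting_waveform(t_s: np.ndarray, boundaries_s, depth_bpm: float) -> np.ndarray:
    """Deceleration-acceleration rate perturbation around section boundaries.

    Negative half-sine lobe over [b-5, b+5] (trough ``-depth`` at the
    boundary) followed by a milder positive recovery lobe over
    [b+5, b+15] (peak ``+0.4 depth``) — 20 s total span.  The trough sits
    on the salient event, so epoch windows +/-10 s away see higher rate
    than the boundary window, and the shared rate excursion (hence
    inter-subject correlation) is strongest at the boundary itself.
    """
    out = np.zeros_like(t_s, dtype=float)
    for b in np.atleast_1d(np.asarray(boundaries_s, dtype=float)):
        u = t_s - b
        neg = (u >= -5.0) & (u < 5.0)
        pos = (u >= 5.0) & (u <= 15.0)
        out[neg] += -depth_bpm * np.sin(np.pi * (u[neg] + 5.0) / 10.0)
        out[pos] += ORIENTING_OVERSHOOT * depth_bpm * np.sin(np.pi * (u[pos] - 5.0) / 10.0)
    return out


def _normalize_flux(flux: np.ndarray) -> np.ndarray:
    flux = np.asarray(flux, dtype=float)
    sd = flux.std()
    if sd == 0:
        return np.zeros_like(flux)
    return (flux - flux.mean()) / sd


def peaks_from_rate(rate_bpm: np.ndarray, grid_dt_s: float, duration_s: float) -> np.ndarray:
    """Event times of an inhomogeneous point process, by time rescaling.

    A peak is emitted whenever the running integral of rate/60 gains one
    unit; with a constant rate lambda BPM this yields intervals of exactly
    60/lambda seconds.
    """
    if np.any(rate_bpm <= 0):
        raise ValueError("rate function must stay positive everywhere")
    t = np.arange(rate_bpm.size) * grid_dt_s
    cum = cumulative_trapezoid(rate_bpm / 60.0, t, initial=0.0)
    n_peaks = int(np.floor(cum[-1] + 1e-9))
    targets = np.arange(1, n_peaks + 1, dtype=float)
    times = np.interp(targets, cum, t)
    return np.minimum(times, duration_s)


def participant_rate(
    t: np.ndarray,
    spec: ParticipantSpec,
    flux_20hz: np.ndarray | None,
    boundaries_s,
    signal: str,
    orienting_on: bool,
    noise_stream: int = 0,
) -> np.ndarray:
    """Ground-truth instantaneous rate (BPM) on grid ``t`` for one signal.

    ``noise_stream`` decorrelates the smooth rate noise across pieces and
    conditions while staying deterministic in the participant seed.
    """
    if signal == "heart":
        base = spec.base_heart_hz * 60.0
        gain, lag_s = spec.coupling_gain, spec.lag_ms / 1000.0
        depth, noise_sd = spec.orienting_depth_bpm, spec.noise_sd_bpm
    else:
        base = spec.base_resp_hz * 60.0
        gain = spec.coupling_gain * spec.resp_coupling_scale
        lag_s = spec.resp_lag_ms / 1000.0
        depth = spec.orienting_depth_bpm * spec.resp_orienting_scale
        noise_sd = spec.resp_noise_sd_bpm

    rate = np.full_like(t, base, dtype=float)
    if flux_20hz is not None and gain > 0:
        fz = _normalize_flux(flux_20hz)
        flux_t = np.arange(fz.size) / ANALYSIS_FS
        # response at t follows the stimulus at t - lag; before stimulus
        # onset the drive is zero
        shifted = np.interp(t - lag_s, flux_t, fz, left=0.0, right=0.0)
        rate += gain * shifted
    if orienting_on and depth > 0 and len(np.atleast_1d(boundaries_s)):
        rate += orienting_waveform(t, boundaries_s, depth)
    if noise_sd > 0:
        rng = np.random.default_rng(
            [spec.seed, 0 if signal == "heart" else 1, noise_stream]
        )
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        raw = rng.standard_normal(t.size)
        smooth = gaussian_filter1d(raw, sigma=max(2.0 / dt, 1.0))
        sd = smooth.std()
        if sd > 0:
            rate += noise_sd * smooth / sd
    return rate


def generate_audience(
    duration_s: float,
    specs: list[ParticipantSpec],
    condition: str,
    flux_20hz: np.ndarray | None = None,
    boundaries_s=(),
    orienting_conditions: tuple[str, ...] = ("AV",),
    grid_fs_hz: float = 50.0,
    noise_stream: int = 0,
) -> tuple[list[dict], pd.DataFrame]:
    """Generate heart/respiration peak trains for one piece and condition.

    Returns ``(records, manifest)`` where each record holds the participant
    spec plus ``heart`` and ``resp`` :class:`PeakSeries`, and the manifest
    is the ground-truth table (one row per participant and signal).
    """
    if len(specs) < 2:
        raise ValueError("an audience needs at least two participants")
    t = np.arange(0.0, duration_s + 1e-9, 1.0 / grid_fs_hz)
    orienting_on = condition in orienting_conditions
    records, manifest_rows = [], []
    for spec in specs:
        rec = {"spec": spec}
        for signal in ("heart", "resp"):
            rate = participant_rate(
                t, spec, flux_20hz, boundaries_s, signal, orienting_on, noise_stream
            )
            times = peaks_from_rate(rate, 1.0 / grid_fs_hz, duration_s)
            rec[signal] = PeakSeries(times, duration_s, source="synthetic")
            manifest_rows.append(
                {
                    "participant_id": spec.participant_id,
                    "concert_id": spec.concert_id,
                    "condition": condition,
                    "signal": signal,
                    "lag_ms": spec.lag_ms if signal == "heart" else spec.resp_lag_ms,
                    "coupling_gain": spec.coupling_gain
                    if signal == "heart"
                    else spec.coupling_gain * spec.resp_coupling_scale,
                    "orienting_depth_bpm": (
                        spec.orienting_depth_bpm
                        if signal == "heart"
                        else spec.orienting_depth_bpm * spec.resp_orienting_scale
                    )
                    * (1.0 if orienting_on else 0.0),
                    "orienting_enabled": orienting_on,
                    "n_peaks": len(rec[signal]),
                    "seed": spec.seed,
                }
            )
        records.append(rec)
    return records, pd.DataFrame(manifest_rows)


# ---------------------------------------------------------------------------
# Continuous-waveform rendering (exercises the preprocessing stage)
# ---------------------------------------------------------------------------

def _ecg_template(fs: float) -> tuple[np.ndarray, int]:
    """QRS-like spike plus a smaller, wider T-like bump 250 ms later."""
    t = np.arange(-0.1, 0.45, 1.0 / fs)
    qrs = np.exp(-0.5 * (t / 0.008) ** 2)
    twave = 0.2 * np.exp(-0.5 * ((t - 0.25) / 0.04) ** 2)
    center = int(round(0.1 * fs))
    return qrs + twave, center


def render_waveforms(
    heart_peaks: PeakSeries,
    resp_peaks: PeakSeries,
    fs_hz: float = 1000.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render ECG-like and respiration-belt-like continuous signals.

    The ECG places a spike template at each cardiac peak over baseline
    noise; the respiration trace is a piecewise sinusoid attaining its
    maxima exactly at the inspiration peaks.
    """
    if fs_hz < 100:
        raise ValueError("sampling rate too low for the QRS template bandwidth")
    duration = heart_peaks.duration_s
    n = int(round(duration * fs_hz))
    rng = np.random.default_rng(seed)

    ecg = rng.standard_normal(n) * noise_sd
    template, center = _ecg_template(fs_hz)
    for pt in heart_peaks.times_s:
        i0 = int(round(pt * fs_hz)) - center
        lo, hi = max(i0, 0), min(i0 + template.size, n)
        ecg[lo:hi] += template[lo - i0 : hi - i0]

    resp = np.zeros(n)
    times = resp_peaks.times_s
    grid_t = np.arange(n) / fs_hz
    if times.size >= 2:
        mean_cycle = float(np.mean(np.diff(times)))
        # phase ramps 0 -> 2pi between consecutive inspiration peaks;
        # cos(phase) then peaks at every inspiration peak
        anchors = np.concatenate(([times[0] - mean_cycle], times, [times[-1] + mean_cycle]))
        cyc = np.interp(grid_t, anchors, np.arange(anchors.size, dtype=float))
        resp = np.cos(2 * np.pi * cyc)
    resp += rng.standard_normal(n) * noise_sd * 0.5
    return ecg, resp


# ---------------------------------------------------------------------------
# Default study layout
# ---------------------------------------------------------------------------

#: smallest layout exercising every grouping factor
DEFAULT_N_CONCERTS = 2
DEFAULT_N_PER_CONCERT = 8
DEFAULT_PIECE_SECONDS = 180.0
DEFAULT_SECTION_COUNTS = (7, 9, 9)
CONDITIONS = ("AV", "AO")


def default_stimulus_spec(
    piece_id: str,
    seed: int,
    duration_s: float = DEFAULT_PIECE_SECONDS,
    n_sections: int = 7,
    tone_step_s: float = 0.25,
) -> StimulusSpec:
    """A synthetic 'piece': tones re-struck every 250 ms with smoothly
    wandering amplitude, so spectral flux carries power in the heart- and
    respiration-frequency range; boundaries tile the piece evenly."""
    rng = np.random.default_rng(seed)
    n_bound = n_sections - 1
    boundaries = [duration_s * (i + 1) / n_sections for i in range(n_bound)]
    onsets = np.arange(0.0, duration_s - tone_step_s / 2, tone_step_s)
    amp_walk = gaussian_filter1d(rng.standard_normal(onsets.size), sigma=2.0)
    amp = 0.5 + 0.35 * amp_walk / max(amp_walk.std(), 1e-12)
    amp = np.clip(amp, 0.05, 1.0)
    freqs = 220.0 * 2 ** (rng.integers(0, 13, onsets.size) / 12.0)
    sched = [(float(o), float(f), float(a)) for o, f, a in zip(onsets, freqs, amp)]
    return StimulusSpec(
        duration_s=duration_s,
        boundary_times_s=boundaries,
        tone_schedule=sched,
        piece_id=piece_id,
    )


def default_audience_specs(
    seed: int,
    n_concerts: int = DEFAULT_N_CONCERTS,
    n_per_concert: int = DEFAULT_N_PER_CONCERT,
    **overrides,
) -> list[ParticipantSpec]:
    """Participant specs with base rhythms jittered around the audience
    averages (heart ~1.01 Hz, respiration ~0.30 Hz)."""
    rng = np.random.default_rng(seed)
    specs = []
    for c in range(n_concerts):
        for p in range(n_per_concert):
            idx = c * n_per_concert + p
            specs.append(
                ParticipantSpec(
                    participant_id=f"p{idx + 1:02d}",
                    concert_id=f"concert{c + 1}",
                    base_heart_hz=float(np.clip(rng.normal(1.01, 0.05), 0.85, 1.2)),
                    base_resp_hz=float(np.clip(rng.normal(0.30, 0.02), 0.22, 0.4)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    **overrides,
                )
            )
    return specs


@dataclass
class StudyData:
    """A full synthetic study: stimuli, flux drives, peak trains, truth."""

    stimuli: dict
    boundaries: pd.DataFrame
    peaks: pd.DataFrame
    manifest: pd.DataFrame
    specs: list[ParticipantSpec]
    flux: dict

    def peak_series(self, participant_id, piece_id, condition, signal) -> PeakSeries:
        df = self.peaks
        sel = df[
            (df.participant_id == participant_id)
            & (df.piece_id == piece_id)
            & (df.condition == condition)
            & (df.signal == signal)
        ]
        dur = float(self.stimuli[piece_id].duration_s)
        return PeakSeries(sel.peak_time_s.to_numpy(), dur, source="synthetic")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peaks.to_csv(outdir / "peaks.csv", index=False)
        self.boundaries.to_csv(outdir / "boundaries.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.manifest.to_dict(orient="records"), fh, indent=1)
        for piece_id, spec in self.stimuli.items():
            wave, _ = generate_stimulus(spec)
            write_stimulus_wav(outdir / f"{piece_id}.wav", wave, spec.sample_rate_hz)


def generate_study(
    seed: int = 0,
    n_concerts: int = DEFAULT_N_CONCERTS,
    n_per_concert: int = DEFAULT_N_PER_CONCERT,
    piece_seconds: float = DEFAULT_PIECE_SECONDS,
    section_counts: tuple[int, ...] = DEFAULT_SECTION_COUNTS,
    conditions: tuple[str, ...] = CONDITIONS,
    **participant_overrides,
) -> StudyData:
    """Generate the default synthetic study layout end to end."""
    from .features import spectral_flux  # deferred: avoid import cycle

    rng = np.random.default_rng(seed)
    specs = default_audience_specs(
        int(rng.integers(0, 2**31 - 1)), n_concerts, n_per_concert, **participant_overrides
    )
    stimuli, flux_map, bound_frames, peak_rows, manifest_frames = {}, {}, [], [], []
    for i, n_sec in enumerate(section_counts):
        piece_id = f"piece{i + 1}"
        sspec = default_stimulus_spec(
            piece_id, int(rng.integers(0, 2**31 - 1)), piece_seconds, n_sec
        )
        stimuli[piece_id] = sspec
        wave, ann = generate_stimulus(sspec)
        bound_frames.append(ann)
        flux = spectral_flux(wave, sspec.sample_rate_hz)
        flux_map[piece_id] = flux
        for j, condition in enumerate(conditions):
            records, manifest = generate_audience(
                sspec.duration_s,
                specs,
                condition,
                flux_20hz=flux.flux_20hz,
                boundaries_s=sspec.boundary_times_s,
                noise_stream=i * len(conditions) + j,
            )
            manifest["piece_id"] = piece_id
            manifest_frames.append(manifest)
            for rec in records:
                for signal in ("heart", "resp"):
                    ps = rec[signal]
                    peak_rows.append(
                        pd.DataFrame(
                            {
                                "participant_id": rec["spec"].participant_id,
                                "concert_id": rec["spec"].concert_id,
                                "piece_id": piece_id,
                                "condition": condition,
                                "signal": signal,
                                "peak_time_s": ps.times_s,
                            }
                        )
                    )
    return StudyData(
        stimuli=stimuli,
        boundaries=pd.concat(bound_frames, ignore_index=True),
        peaks=pd.concat(peak_rows, ignore_index=True),
        manifest=pd.concat(manifest_frames, ignore_index=True),
        specs=specs,
        flux=flux_map,
    )
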