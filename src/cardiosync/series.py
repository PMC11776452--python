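"""Core time-series containers shared across the pipeline.

All synchrony analysis happens on a common 20 Hz grid so that stimulus
features (spectral flux) and physiological responses (instantaneous rate,
cycle phase) align sample-for-sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: common analysis sampling rate (Hz) for rates, phases and resampled flux
ANALYSIS_FS = 20.0


@dataclass
class PeakSeries:
    """Strictly increasing event times (s) of R-peaks or inspiration peaks.

    Times are relative to piece onset; ``duration_s`` is the piece span and
    bounds every peak.
    """

    times_s: np.ndarray
    duration_s: float
    source: str = "detected"
    quality_flag: str = "ok"
    provenance: np.ndarray | None = None  # per-peak: detected|added|manual

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape != self.times_s.shape:
                raise ValueError("provenance must align with peak times")
        if self.times_s.ndim != 1:
            raise ValueError("peak times must be one-dimensional")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if self.times_s.size and (
            self.times_s[0] < 0 or self.times_s[-1] > self.duration_s
        ):
            raise ValueError("peak times must lie within [0, duration_s]")

    def __len__(self) -> int:
        return int(self.times_s.size)

    @property
    def intervals_s(self) -> np.ndarray:
        """Consecutive inter-event intervals (IBI / IBrI), in seconds."""
        return np.diff(self.times_s)

    def shifted(self, offset_s: float) -> "PeakSeries":
        """Circularly shift peaks by ``offset_s`` modulo the piece length.

        Used to build time-"unlocked" surrogate data that preserves each
        train's interval structure while destroying stimulus locking.
        """
        t = np.sort(np.mod(self.times_s + offset_s, self.duration_s))
        t = np.unique(t)
        return replace(self, times_s=t, source="shifted", provenance=None)


@dataclass
class RateSeries:
    """Instantaneous rate in BPM on the uniform 20 Hz analysis grid."""

    bpm: np.ndarray
    fs_hz: float = ANALYSIS_FS
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.bpm = np.asarray(self.bpm, dtype=float)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.bpm.size) / self.fs_hz


@dataclass
class PhaseSeries:
    """Wrapped cycle phase in (-pi, pi] on the uniform analysis grid.

    Convention: 0 at the cycle peak (R wave / inspiration peak), +/-pi at
    the cycle midpoint.  Samples outside valid cycles are NaN (masked).
    """

    angle_rad: np.ndarray
    fs_hz: float = ANALYSIS_FS
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.angle_rad = np.asarray(self.angle_rad, dtype=float)
        finite = self.angle_rad[np.isfinite(self.angle_rad)]
        if finite.size and (finite.min() <= -np.pi - 1e-9 or finite.max() > np.pi + 1e-9):
            raise ValueError("phase angles must be wrapped to (-pi, pi]")

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.angle_rad.size) / self.fs_hz


@dataclass
class FluxSeries:
    """Spectral flux magnitude per STFT frame, plus a 20 Hz resampled copy."""

    flux: np.ndarray
    frame_hop_s: float
    band: str = "full"
    flux_20hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.flux = np.asarray(self.flux, dtype=float)

    @property
    def frame_fs_hz(self) -> float:
        return 1.0 / self.frame_hop_s

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.flux.size) * self.frame_hop_s

    @property
    def times_20hz_s(self) -> np.ndarray:
        if self.flux_20hz is None:
            raise ValueError("no 20 Hz copy attached")
        return np.arange(self.flux_20hz.size) / ANALYSIS_FS


@dataclass
class SyncSeries:
    """One synchrony value per sliding window.

    Correlation measures live in [-1, 1]; coherence measures in [0, 1].
    Masked (undefined) windows are NaN.
    """

    values: np.ndarray
    center_times_s: np.ndarray
    measure: str
    window_len_s: float = 10.0
    hop_s: float = 1.0
    n_pairs: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center_times_s = np.asarray(self.center_times_s, dtype=float)
        if self.values.shape != self.center_times_s.shape:
            raise ValueError("values and center times must align")
        v = self.values[np.isfinite(self.values)]
        if self.measure.upper().startswith(("SRC", "ISC")):
            if v.size and (v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("correlation values outside [-1, 1]")
        else:
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("coherence values outside [0, 1]")

    def time_average(self) -> float:
        return float(np.nanmean(self.values))

    def to_frame(self, **keys) -> pd.DataFrame:
        df = pd.DataFrame(
            {"window_center_s": self.center_times_s, "value": self.values}
        )
        df["measure"] = self.measure
        df["n_pairs"] = self.n_pairs
        for k, v in keys.items():
            df[k] = v
        return df


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

PEAK_COLUMNS = [
    "participant_id",
    "concert_id",
    "piece_id",
    "condition",
    "signal",
    "peak_time_s",
]

BOUNDARY_COLUMNS = ["piece_id", "boundary_time_s", "section_label"]


def write_peak_table(path: str | Path, rows: pd.DataFrame) -> None:
    rows.loc[:, PEAK_COLUMNS].to_csv(path, index=False)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def write_boundaries(path: str | Path, rows: pd.DataFrame) -> None:
    rows.loc[:, BOUNDARY_COLUMNS].to_csv(path, index=False)


def read_boundaries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BOUNDARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"boundary table missing columns: {sorted(missing)}")
    return df
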