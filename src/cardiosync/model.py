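"""Top-level model/results interface for an audience-synchrony analysis.

:class:`ConcertSynchrony` is built from a dataset (peak trains per
participant, piece and condition, plus per-piece stimulus flux and
section boundaries); :meth:`ConcertSynchrony.fit` runs the requested
synchrony measures, the circular-shift significance tests, and the
AV-vs-AO contrasts, returning a :class:`ConcertSynchronyResults` whose
``summary()`` collects the headline tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference, sync
from .features import FrequencyBand, audience_band, subband_phase
from .rates import fit_cycle_phase, mean_cycle_s, mean_rate_hz, peaks_to_rate
from .series import PeakSeries
from .synth import StudyData

__all__ = ["ConcertSynchrony", "ConcertSynchronyResults"]

CORRELATION_MEASURES = ("SRC-HR", "SRC-RR", "ISC-HR", "ISC-RR")
PHASE_MEASURES = ("SRPC-heart", "SRPC-resp", "ISPC-heart", "ISPC-resp")
_SIGNAL_OF = {
    "SRC-HR": "heart",
    "SRC-RR": "resp",
    "ISC-HR": "heart",
    "ISC-RR": "resp",
    "SRPC-heart": "heart",
    "SRPC-resp": "resp",
    "ISPC-heart": "heart",
    "ISPC-resp": "resp",
}


@dataclass
class ConcertSynchronyResults:
    """Estimates and diagnostics from a fitted audience-synchrony model."""

    lags_ms: dict
    time_averaged: pd.DataFrame
    permutation: pd.DataFrame
    modality_fits: dict
    paired_tests: dict
    epoch_tables: dict
    epoch_contrasts: dict
    rate_profiles: dict
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Audience cardiorespiratory synchrony", "=" * 38]
        if self.lags_ms:
            lines.append("Group stimulus-response lags (ms):")
            for m, v in self.lags_ms.items():
                lines.append(f"  {m:12s} {v:7.0f}")
        if len(self.permutation):
            lines.append("\nCircular-shift significance (time-averaged):")
            lines.append(
                self.permutation.to_string(
                    index=False, float_format=lambda v: f"{v: .4f}"
                )
            )
        for m, fit in self.modality_fits.items():
            lines.append(f"\nAV vs AO, time-averaged {m}:")
            lines.append(fit.summary())
            t = self.paired_tests.get(m)
            if t is not None:
                lines.append(
                    f"  paired sanity check ({t.test_name}): stat={t.statistic:.3f}, "
                    f"p={t.p_value:.3f}, n={t.n}"
                )
        for m, fit in self.rate_profiles.items():
            lines.append(f"\nBoundary-epoched raw {m} (window 0 = boundary):")
            lines.append(fit[1].summary())
        return "\n".join(lines)

    def plot_epochs(self, measure: str, ax=None):
        """Mean synchrony per epoch window and condition (orienting view)."""
        import matplotlib.pyplot as plt

        table = self.epoch_tables[measure]
        if ax is None:
            _, ax = plt.subplots()
        for cond, sub in table.groupby("condition"):
            prof = sub.groupby("window")["value"].mean()
            ax.plot(prof.index, prof.values, marker="o", label=cond)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("window relative to section boundary (s)")
        ax.set_ylabel(measure)
        ax.legend()
        return ax


class ConcertSynchrony:
    """Audience-synchrony model over a set of concert recordings.

    Parameters
    ----------
    peaks : DataFrame with columns participant_id, concert_id, piece_id,
        condition, signal (heart|resp), peak_time_s.
    boundaries : DataFrame with piece_id, boundary_time_s.
    durations_s : mapping piece_id -> piece length (s).
    flux_20hz : mapping piece_id -> full-band spectral flux on the 20 Hz
        grid (used by the correlation family and as the coupling drive).
    flux_native : optional mapping piece_id -> FluxSeries (needed for the
        phase family's sub-band flux phase).
    """

    def __init__(self, peaks, boundaries, durations_s, flux_20hz, flux_native=None):
        self.peaks = peaks
        self.boundaries = boundaries
        self.durations_s = dict(durations_s)
        self.flux_20hz = {k: np.asarray(v, float) for k, v in flux_20hz.items()}
        self.flux_native = flux_native or {}
        self.pieces = sorted(self.durations_s)
        self.conditions = sorted(peaks["condition"].unique())
        self.concerts = sorted(peaks["concert_id"].unique())

    @classmethod
    def from_study(cls, study: StudyData) -> "ConcertSynchrony":
        durations = {pid: s.duration_s for pid, s in study.stimuli.items()}
        return cls(
            peaks=study.peaks,
            boundaries=study.boundaries,
            durations_s=durations,
            flux_20hz={pid: f.flux_20hz for pid, f in study.flux.items()},
            flux_native=study.flux,
        )

    # -- data access --------------------------------------------------------

    def _participants(self, concert_id: str) -> list[str]:
        sel = self.peaks[self.peaks.concert_id == concert_id]
        return sorted(sel.participant_id.unique())

    def peak_series(self, participant_id, piece_id, condition, signal) -> PeakSeries:
        df = self.peaks
        sel = df[
            (df.participant_id == participant_id)
            & (df.piece_id == piece_id)
            & (df.condition == condition)
            & (df.signal == signal)
        ]
        return PeakSeries(sel.peak_time_s.to_numpy(), self.durations_s[piece_id])

    def piece_boundaries(self, piece_id) -> np.ndarray:
        sel = self.boundaries[self.boundaries.piece_id == piece_id]
        return sel.boundary_time_s.to_numpy(dtype=float)

    # -- fitting ------------------------------------------------------------

    def estimate_lags(self, measures=("SRC-HR", "SRC-RR")) -> dict:
        """Group lag per stimulus-response measure: per-participant optima
        pooled over pieces and conditions, then averaged."""
        lags = {}
        for measure in measures:
            signal = _SIGNAL_OF[measure]
            optima = []
            for piece_id in self.pieces:
                stim = self.flux_20hz[piece_id]
                for condition in self.conditions:
                    responses, bounds = [], []
                    for concert in self.concerts:
                        for pid in self._participants(concert):
                            ps = self.peak_series(pid, piece_id, condition, signal)
                            if len(ps) < 2:
                                continue
                            responses.append(peaks_to_rate(ps).bpm)
                            bounds.append(mean_cycle_s(ps))
                    est = sync.estimate_group_lag(
                        responses, stim, bounds, "correlation", measure=measure
                    )
                    optima.extend(est.per_participant_ms)
            lags[measure] = float(np.mean(optima)) if optima else 0.0
        return lags

    def _phase_band(self, signal: str) -> FrequencyBand:
        rates = []
        for concert in self.concerts:
            for pid in self._participants(concert):
                for piece_id in self.pieces:
                    for condition in self.conditions:
                        ps = self.peak_series(pid, piece_id, condition, signal)
                        if len(ps) >= 2:
                            rates.append(mean_rate_hz(ps))
        return audience_band(rates)

    def _measure_observations(
        self,
        measure: str,
        piece_id: str,
        condition: str,
        peak_map: dict,
        lag_ms: float,
        hop_s: float,
        flux_phase=None,
    ) -> pd.DataFrame:
        """Per-participant section-averaged observations for one measure on
        one piece x condition.  ``peak_map``: concert -> {pid -> PeakSeries}."""
        duration = self.durations_s[piece_id]
        bounds = self.piece_boundaries(piece_id)
        rows = []
        for concert, per_pid in peak_map.items():
            series_map = {}
            if measure.startswith("SRC"):
                for pid, ps in per_pid.items():
                    series_map[pid] = sync.src(
                        peaks_to_rate(ps),
                        self.flux_20hz[piece_id],
                        lag_ms,
                        hop_s=hop_s,
                        measure=measure,
                    )
            elif measure.startswith("ISC"):
                pids = list(per_pid)
                if len(pids) < 2:
                    continue
                rates = [peaks_to_rate(per_pid[p]) for p in pids]
                series = sync.isc_per_participant(rates, hop_s=hop_s, measure=measure)
                series_map = dict(zip(pids, series))
            elif measure.startswith("SRPC"):
                for pid, ps in per_pid.items():
                    phase = fit_cycle_phase(ps, channel=_SIGNAL_OF[measure])
                    series_map[pid] = sync.srpc(
                        phase, flux_phase, lag_ms, hop_s=hop_s, measure=measure
                    )
            elif measure.startswith("ISPC"):
                pids = list(per_pid)
                if len(pids) < 2:
                    continue
                phases = {
                    p: fit_cycle_phase(per_pid[p], channel=_SIGNAL_OF[measure])
                    for p in pids
                }
                for pid in pids:
                    partner_vals = [
                        sync.srpc(
                            phases[pid],
                            phases[other],
                            0.0,
                            hop_s=hop_s,
                            measure=measure,
                        )
                        for other in pids
                        if other != pid
                    ]
                    stacked = np.vstack([s.values for s in partner_vals])
                    proto = partner_vals[0]
                    series_map[pid] = sync.SyncSeries(
                        np.nanmean(stacked, axis=0),
                        proto.center_times_s,
                        measure,
                        proto.window_len_s,
                        proto.hop_s,
                        n_pairs=len(partner_vals),
                    )
            else:
                raise ValueError(f"unknown measure {measure}")
            for pid, s in series_map.items():
                agg = inference.aggregate_time_averaged(s, bounds, duration)
                agg["participant_id"] = pid
                agg["concert_id"] = concert
                rows.append(agg)
        if not rows:
            return pd.DataFrame()
        out = pd.concat(rows, ignore_index=True)
        out["piece_id"] = piece_id
        out["condition"] = condition
        out["measure"] = measure
        return out

    def _peak_map(self, piece_id, condition, signal) -> dict:
        out = {}
        for concert in self.concerts:
            per_pid = {}
            for pid in self._participants(concert):
                ps = self.peak_series(pid, piece_id, condition, signal)
                if len(ps) >= 2:
                    per_pid[pid] = ps
            out[concert] = per_pid
        return out

    def fit(
        self,
        measures=("SRC-HR", "ISC-HR", "ISC-RR"),
        lag_mode: str = "estimate",
        fixed_lags_ms: dict | None = None,
        n_perm: int = 200,
        seed: int = 0,
        hop_s: float = 1.0,
        run_permutations: bool = True,
        run_epochs: bool = True,
    ) -> ConcertSynchronyResults:
        """Run the synchrony pipeline and group inference.

        ``lag_mode='estimate'`` recovers group lags from the data;
        ``'fixed'`` uses ``fixed_lags_ms`` (falling back to the documented
        study constants in :data:`cardiosync.sync.STUDY_LAGS_MS`).
        """
        measures = list(measures)
        src_measures = [m for m in measures if m.startswith(("SRC", "SRPC"))]
        if lag_mode == "estimate":
            lags = self.estimate_lags([m for m in src_measures if m.startswith("SRC")])
            for m in src_measures:
                if m not in lags:
                    lags[m] = sync.STUDY_LAGS_MS.get(m, 0.0)
        elif lag_mode == "fixed":
            lags = {m: (fixed_lags_ms or sync.STUDY_LAGS_MS)[m] for m in src_measures}
        else:
            raise ValueError("lag_mode must be 'estimate' or 'fixed'")

        flux_phases = {}
        for m in measures:
            if m.startswith(("SRPC", "ISPC")) and m not in flux_phases:
                band = self._phase_band(_SIGNAL_OF[m])
                flux_phases[m] = {
                    pid: subband_phase(self.flux_native[pid], band)
                    for pid in self.pieces
                }

        # time-averaged observations
        ta_frames = []
        for measure in measures:
            signal = _SIGNAL_OF[measure]
            for piece_id in self.pieces:
                for condition in self.conditions:
                    peak_map = self._peak_map(piece_id, condition, signal)
                    ta_frames.append(
                        self._measure_observations(
                            measure,
                            piece_id,
                            condition,
                            peak_map,
                            lags.get(measure, 0.0),
                            hop_s,
                            flux_phase=flux_phases.get(measure, {}).get(piece_id),
                        )
                    )
        time_averaged = pd.concat(
            [f for f in ta_frames if len(f)], ignore_index=True
        )

        # circular-shift significance
        perm_rows = []
        results_by_measure = {}
        if run_permutations:
            rng = np.random.default_rng(seed)
            for measure in measures:
                res = self._permute_measure(
                    measure,
                    lags.get(measure, 0.0),
                    hop_s,
                    n_perm,
                    int(rng.integers(0, 2**31 - 1)),
                    flux_phases.get(measure),
                )
                results_by_measure[measure] = res
                perm_rows.append(
                    {
                        "measure": measure,
                        "observed_t": res.observed_stat,
                        "p": res.p_value,
                    }
                )
            perm = pd.DataFrame(perm_rows)
            if len(perm):
                perm["q"] = inference.fdr_adjust(perm["p"])
                for row in perm.itertuples():
                    results_by_measure[row.measure].q_value = row.q
        else:
            perm = pd.DataFrame(columns=["measure", "observed_t", "p", "q"])

        # AV vs AO: time-averaged mixed models + paired sanity checks
        modality_fits, paired = {}, {}
        if len(self.conditions) == 2:
            for measure in measures:
                sub = time_averaged[time_averaged.measure == measure]
                modality_fits[measure] = inference.fit_modality_models(sub)
                per = (
                    sub.groupby(["participant_id", "condition"])["value"]
                    .mean()
                    .unstack("condition")
                    .dropna()
                )
                if len(per) >= 3:
                    paired[measure] = inference.sanity_paired_test(
                        per[self.conditions[0]], per[self.conditions[1]]
                    )

        # boundary-epoched synchrony and raw-rate orienting profiles
        epoch_tables, epoch_contrasts, rate_profiles = {}, {}, {}
        if run_epochs:
            for measure in measures:
                epoch_tables[measure] = self._epoch_measure(
                    measure, lags.get(measure, 0.0), hop_s, flux_phases.get(measure)
                )
                tab = epoch_tables[measure]
                if len(tab) and tab["value"].notna().sum() > 20:
                    epoch_contrasts[measure] = inference.window_contrasts(tab)
            for signal, label in (("heart", "HR"), ("resp", "RR")):
                tab = self._epoch_rates(signal)
                if len(tab):
                    rate_profiles[label] = inference.boundary_rate_profile(tab)

        return ConcertSynchronyResults(
            lags_ms=lags,
            time_averaged=time_averaged,
            permutation=perm,
            modality_fits=modality_fits,
            paired_tests=paired,
            epoch_tables=epoch_tables,
            epoch_contrasts=epoch_contrasts,
            rate_profiles=rate_profiles,
            config={
                "measures": measures,
                "lag_mode": lag_mode,
                "n_perm": n_perm,
                "seed": seed,
                "hop_s": hop_s,
            },
        )

    # -- helpers ------------------------------------------------------------

    def _permute_measure(
        self, measure, lag_ms, hop_s, n_perm, seed, flux_phase_map
    ) -> inference.PermutationResult:
        """Circular-shift test pooling observations over pieces/conditions."""
        signal = _SIGNAL_OF[measure]
        layout = []  # (piece, condition, concert, [pids]) with flat indexing
        flat: list[PeakSeries] = []
        for piece_id in self.pieces:
            for condition in self.conditions:
                peak_map = self._peak_map(piece_id, condition, signal)
                for concert, per_pid in peak_map.items():
                    pids = list(per_pid)
                    idx = []
                    for pid in pids:
                        idx.append(len(flat))
                        flat.append(per_pid[pid])
                    layout.append((piece_id, condition, concert, pids, idx))

        def measure_fn(peak_sets: list[PeakSeries]) -> np.ndarray:
            obs = []
            for piece_id, condition, concert, pids, idx in layout:
                peak_map = {concert: {p: peak_sets[i] for p, i in zip(pids, idx)}}
                df = self._measure_observations(
                    measure,
                    piece_id,
                    condition,
                    peak_map,
                    lag_ms,
                    hop_s,
                    flux_phase=(flux_phase_map or {}).get(piece_id),
                )
                if len(df):
                    obs.append(df["value"].to_numpy())
            return np.concatenate(obs) if obs else np.array([])

        return inference.circular_null_test(
            flat, measure_fn, n_perm=n_perm, seed=seed, measure=measure
        )

    def _epoch_measure(self, measure, lag_ms, hop_s, flux_phase_map) -> pd.DataFrame:
        signal = _SIGNAL_OF[measure]
        frames = []
        for piece_id in self.pieces:
            duration = self.durations_s[piece_id]
            bounds = self.piece_boundaries(piece_id)
            if not len(bounds):
                continue
            for condition in self.conditions:
                peak_map = self._peak_map(piece_id, condition, signal)
                for concert, per_pid in peak_map.items():
                    series_map = self._series_for_epochs(
                        measure,
                        piece_id,
                        per_pid,
                        lag_ms,
                        hop_s,
                        flux_phase_map,
                    )
                    for pid, s in series_map.items():
                        tab = inference.epoch_around_boundaries(s, bounds, duration)
                        tab["participant_id"] = pid
                        tab["concert_id"] = concert
                        tab["piece_id"] = piece_id
                        tab["condition"] = condition
                        tab["measure"] = measure
                        frames.append(tab)
        return (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )

    def _series_for_epochs(
        self, measure, piece_id, per_pid, lag_ms, hop_s, flux_phase_map
    ) -> dict:
        series_map = {}
        if measure.startswith("SRC"):
            for pid, ps in per_pid.items():
                series_map[pid] = sync.src(
                    peaks_to_rate(ps),
                    self.flux_20hz[piece_id],
                    lag_ms,
                    hop_s=hop_s,
                    measure=measure,
                )
        elif measure.startswith("ISC"):
            pids = list(per_pid)
            if len(pids) >= 2:
                rates = [peaks_to_rate(per_pid[p]) for p in pids]
                series = sync.isc_per_participant(rates, hop_s=hop_s, measure=measure)
                series_map = dict(zip(pids, series))
        elif measure.startswith("SRPC"):
            fp = (flux_phase_map or {}).get(piece_id)
            for pid, ps in per_pid.items():
                phase = fit_cycle_phase(ps, channel=_SIGNAL_OF[measure])
                series_map[pid] = sync.srpc(
                    phase, fp, lag_ms, hop_s=hop_s, measure=measure
                )
        elif measure.startswith("ISPC"):
            pids = list(per_pid)
            if len(pids) >= 2:
                phases = [
                    fit_cycle_phase(per_pid[p], channel=_SIGNAL_OF[measure])
                    for p in pids
                ]
                combined = sync.ispc(phases, hop_s=hop_s, measure=measure)
                series_map = {pid: combined for pid in pids[:1]}
        return series_map

    def _epoch_rates(self, signal: str) -> pd.DataFrame:
        frames = []
        for piece_id in self.pieces:
            duration = self.durations_s[piece_id]
            bounds = self.piece_boundaries(piece_id)
            if not len(bounds):
                continue
            for condition in self.conditions:
                for concert in self.concerts:
                    for pid in self._participants(concert):
                        ps = self.peak_series(pid, piece_id, condition, signal)
                        if len(ps) < 2:
                            continue
                        tab = inference.epoch_rate_around_boundaries(
                            peaks_to_rate(ps), bounds, duration
                        )
                        tab["participant_id"] = pid
                        tab["concert_id"] = concert
                        tab["piece_id"] = piece_id
                        tab["condition"] = condition
                        frames.append(tab)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
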