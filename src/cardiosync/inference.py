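"""Group-level inference: permutation significance, aggregation, epoching,
and modality (AV vs. AO) contrasts.

Significance of each synchrony measure is assessed against circular-shift
surrogates: every participant's peak train is rotated modulo the piece
length (preserving interval structure, destroying time locking), the full
measure pipeline is recomputed, and the one-sample t statistic of the
time-averaged observations forms the null distribution.

Condition contrasts use linear mixed models with random intercepts for
concert, piece, and participant (participants nested in concerts; piece
crossed) plus a participant modality slope, simplified in a declared
order when the maximal structure is singular or fails to converge.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .series import PeakSeries, RateSeries, SyncSeries

__all__ = [
    "PermutationResult",
    "circular_null_test",
    "fdr_adjust",
    "sections_from_boundaries",
    "aggregate_time_averaged",
    "epoch_around_boundaries",
    "epoch_rate_around_boundaries",
    "MixedModelFit",
    "fit_modality_models",
    "window_contrasts",
    "sanity_paired_test",
    "boundary_rate_profile",
    "WINDOW_LABELS",
]

#: 6-s partitions of the +/-15 s epoch, labeled as conventionally printed
#: (labels are names; the partition edges fix the geometry)
EPOCH_EDGES_S = (-15.0, -9.0, -3.0, 3.0, 9.0, 15.0)
WINDOW_LABELS = (-10, -5, 0, 5, 10)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    measure: str
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("permutation p-value must lie in (0, 1]")


def _one_sample_t(obs: np.ndarray) -> float:
    obs = np.asarray(obs, float)
    obs = obs[np.isfinite(obs)]
    if obs.size < 2:
        return np.nan
    sd = obs.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(obs.mean() / (sd / np.sqrt(obs.size)))


def circular_null_test(
    peak_sets: list[PeakSeries],
    measure_fn,
    n_perm: int = 1000,
    seed: int = 0,
    measure: str = "SRC-HR",
    shift_sampler=None,
) -> PermutationResult:
    """Permutation test of time-locked synchrony against circular shifts.

    ``measure_fn(list[PeakSeries]) -> array`` runs the full pipeline for
    one measure and returns its time-averaged observations (e.g. one value
    per participant and section).  Each permutation independently rotates
    every participant's peak train by a uniform offset over the piece
    length and recomputes the observations; the statistic is the pooled
    one-sample t against zero, and

        p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives coarse p-value resolution", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    if shift_sampler is None:
        shift_sampler = lambda rng, duration: rng.uniform(0.0, duration)  # noqa: E731
    t_obs = _one_sample_t(measure_fn(peak_sets))
    null = np.empty(n_perm)
    for k in range(n_perm):
        shifted = [
            ps.shifted(shift_sampler(rng, ps.duration_s)) for ps in peak_sets
        ]
        null[k] = _one_sample_t(measure_fn(shifted))
    n_ge = int(np.sum(null[np.isfinite(null)] >= t_obs))
    p = (1 + n_ge) / (1 + n_perm)
    return PermutationResult(measure, t_obs, null, p, n_perm, seed)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Aggregation and epoching
# ---------------------------------------------------------------------------


def sections_from_boundaries(boundaries_s, duration_s: float) -> list[tuple[float, float]]:
    """Sections tiling [0, duration]: consecutive (lo, hi) spans."""
    edges = [0.0, *(float(b) for b in np.atleast_1d(boundaries_s)), float(duration_s)]
    if any(e1 <= e0 for e0, e1 in zip(edges, edges[1:])):
        raise ValueError("boundaries must be strictly increasing inside the piece")
    return list(zip(edges[:-1], edges[1:]))


def aggregate_time_averaged(
    sync: SyncSeries,
    boundaries_s,
    duration_s: float,
    mode: str = "sections",
    bin_s: float = 30.0,
) -> pd.DataFrame:
    """Mean synchrony per section (or per 30-s bin) for one piece.

    Window values are assigned to the section containing their center.
    Sections holding no window center yield a masked (NaN) row.
    """
    if mode == "sections":
        spans = sections_from_boundaries(boundaries_s, duration_s)
    elif mode == "bins30s":
        edges = np.arange(0.0, duration_s + 1e-9, bin_s)
        if edges[-1] < duration_s:
            edges = np.append(edges, duration_s)
        spans = list(zip(edges[:-1], edges[1:]))
    else:
        raise ValueError("mode must be 'sections' or 'bins30s'")
    rows = []
    for i, (lo, hi) in enumerate(spans):
        inside = (sync.center_times_s >= lo) & (sync.center_times_s < hi)
        vals = sync.values[inside]
        finite = vals[np.isfinite(vals)]
        rows.append(
            {
                "section_index": i,
                "t_lo_s": lo,
                "t_hi_s": hi,
                "value": float(finite.mean()) if finite.size else np.nan,
                "n_windows": int(finite.size),
            }
        )
    return pd.DataFrame(rows)


def _epoch_windows(
    times: np.ndarray,
    values: np.ndarray,
    boundaries_s,
    duration_s: float,
    half_width_s: float = 15.0,
) -> pd.DataFrame:
    scale = half_width_s / 15.0
    edges = np.asarray(EPOCH_EDGES_S) * scale
    rows = []
    for b_idx, b in enumerate(np.atleast_1d(np.asarray(boundaries_s, float))):
        if b - half_width_s < 0 or b + half_width_s > duration_s:
            continue  # epoch would leave the piece: dropped
        rel = times - b
        for label, lo, hi in zip(WINDOW_LABELS, edges[:-1], edges[1:]):
            inside = (rel >= lo) & (rel < hi)
            vals = values[inside]
            finite = vals[np.isfinite(vals)]
            rows.append(
                {
                    "boundary_index": b_idx,
                    "boundary_time_s": float(b),
                    "window": int(label),
                    "value": float(finite.mean()) if finite.size else np.nan,
                    "n_values": int(finite.size),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["boundary_index", "boundary_time_s", "window", "value", "n_values"],
    )


def epoch_around_boundaries(
    sync: SyncSeries,
    boundaries_s,
    duration_s: float,
    half_width_s: float = 15.0,
) -> pd.DataFrame:
    """Partition +/-15 s epochs around each boundary into five 6-s windows
    (labels -10, -5, 0, 5, 10) and average the synchrony values whose
    window centers fall inside each partition.  Boundaries closer than
    15 s to a piece edge are dropped."""
    return _epoch_windows(
        sync.center_times_s, sync.values, boundaries_s, duration_s, half_width_s
    )


def epoch_rate_around_boundaries(
    rate: RateSeries,
    boundaries_s,
    duration_s: float,
    half_width_s: float = 15.0,
) -> pd.DataFrame:
    """Same epoch partition applied to raw BPM samples (orienting check)."""
    return _epoch_windows(
        rate.times_s, rate.bpm, boundaries_s, duration_s, half_width_s
    )


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------


MAXIMAL_VC = {
    "participant_slope": "0 + C(participant_id):C(condition)",
    "participant": "0 + C(participant_id)",
    "piece": "0 + C(piece_id)",
    "concert": "0 + C(concert_id)",
}

#: declared simplification order on convergence/singularity failure
SIMPLIFY_ORDER = ("participant_slope", "concert", "piece", "participant")


@dataclass
class MixedModelFit:
    """Fixed-effect estimates plus fit diagnostics from a (possibly
    simplified) linear mixed model."""

    params: pd.DataFrame
    vc_variances: dict
    resid_variance: float
    marginal_r2: float
    conditional_r2: float
    simplification_path: list[str] = field(default_factory=list)
    converged: bool = True
    formula: str = ""
    result: object | None = None

    def summary(self) -> str:
        lines = [f"Mixed model: {self.formula}"]
        if self.simplification_path:
            lines.append(f"simplified: dropped {', '.join(self.simplification_path)}")
        lines.append(self.params.to_string(float_format=lambda v: f"{v: .4f}"))
        lines.append(
            f"marginal R2 = {self.marginal_r2:.3f}, "
            f"conditional R2 = {self.conditional_r2:.3f}"
        )
        return "\n".join(lines)


def _fit_mixedlm_once(formula: str, data: pd.DataFrame, vc: dict):
    """One mixed-model (or, with no random terms left, OLS) fit attempt.

    Returns ``(result, troubled, singular)``; ``result`` is None when the
    optimizer failed outright.
    """
    import statsmodels.formula.api as smf

    if not vc:  # fully simplified: plain fixed-effects regression
        result = smf.ols(formula, data).fit()
        return result, False, False
    data = data.copy()
    data["_one"] = 1
    model = smf.mixedlm(formula, data, groups="_one", vc_formula=vc)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = model.fit(reml=True, method=["lbfgs", "cg"])
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        return None, True, True
    msgs = " ".join(str(c.message) for c in caught)
    troubled = (not result.converged) or ("converge" in msgs.lower())
    resid = max(result.scale, 1e-12)
    vcomp = np.asarray(result.vcomp, float)
    singular = bool(np.any(vcomp < 1e-8 * resid))
    return result, troubled, singular


def fit_modality_models(
    table: pd.DataFrame,
    outcome: str = "value",
    fixed: str = "C(condition, Treatment('AO'))",
    vc: dict | None = None,
    simplify: bool = True,
    allow_singular: bool = True,
) -> MixedModelFit:
    """Linear mixed model for a long observation table.

    The default structure is maximal: random intercepts for concert,
    piece, and participant, plus an (uncorrelated) participant-by-modality
    slope, emulated through variance components on a single grouping
    level.  On convergence failure or a singular component the structure
    is simplified in the declared order (slope first, then the
    smallest-variance intercepts) and the path is reported.
    """
    data = table.dropna(subset=[outcome]).reset_index(drop=True).copy()
    if vc is None:
        vc = {
            k: v
            for k, v in MAXIMAL_VC.items()
            if all(col in data.columns for col in _vc_columns(v))
        }
    formula = f"{outcome} ~ {fixed}"
    path: list[str] = []
    current = dict(vc)
    while True:
        result, troubled, singular = _fit_mixedlm_once(formula, data, current)
        ok = not troubled and not (singular and not allow_singular)
        if ok or not simplify or not current:
            break
        dropped = None
        for name in SIMPLIFY_ORDER:
            if name in current:
                dropped = name
                break
        if dropped is None:  # drop smallest-variance remaining component
            if result is not None:
                vcomp = dict(zip(current, np.asarray(result.vcomp, float)))
                dropped = min(vcomp, key=vcomp.get)
            else:
                dropped = next(iter(current))
        current.pop(dropped)
        path.append(dropped)
    if result is None:
        raise RuntimeError(
            f"mixed model unidentifiable even after simplification ({path})"
        )
    return _wrap_fit(result, formula, current, path, data, outcome)


def _vc_columns(vc_formula: str) -> list[str]:
    import re

    return re.findall(r"C\((\w+)\)", vc_formula)


def _wrap_fit(result, formula, vc, path, data, outcome) -> MixedModelFit:
    fe = getattr(result, "fe_params", result.params)
    k_fe = len(fe)
    beta = np.asarray(fe)
    se = np.asarray(result.bse[:k_fe])
    ci = result.conf_int().iloc[:k_fe]
    pvals = np.asarray(result.pvalues[:k_fe])
    params = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
            "p": pvals,
        },
        index=fe.index,
    )
    vcomp = np.asarray(getattr(result, "vcomp", []), float)
    vc_var = dict(zip(vc.keys(), vcomp)) if vc else {}
    var_f = float(np.var(result.model.exog @ beta))
    var_r = float(sum(vc_var.values()))
    var_e = float(result.scale)
    total = var_f + var_r + var_e
    return MixedModelFit(
        params=params,
        vc_variances=vc_var,
        resid_variance=var_e,
        marginal_r2=var_f / total if total > 0 else np.nan,
        conditional_r2=(var_f + var_r) / total if total > 0 else np.nan,
        simplification_path=path,
        converged=bool(getattr(result, "converged", True)),
        formula=formula,
        result=result,
    )


# ---------------------------------------------------------------------------
# Epoched contrasts (estimated-marginal-means style)
# ---------------------------------------------------------------------------


def _emm_design(result, ref: pd.DataFrame) -> np.ndarray:
    from patsy import build_design_matrices

    design_info = result.model.data.design_info
    return np.asarray(build_design_matrices([design_info], ref)[0])


def window_contrasts(
    epochs: pd.DataFrame,
    outcome: str = "value",
    vc: dict | None = None,
    adjust_m: int | None = None,
) -> pd.DataFrame:
    """Pairwise AO-AV contrasts per epoch window, and window-vs-window-0
    contrasts within each modality, from a window x modality mixed model.

    Estimated marginal means are linear combinations of the fixed effects;
    contrast p-values use the normal approximation on the fixed-effect
    covariance and are Bonferroni-adjusted (x5 across windows for the
    modality contrasts; x4 across non-zero windows for the window
    contrasts).
    """
    windows = sorted(epochs["window"].unique())
    if set(windows) - set(WINDOW_LABELS):
        raise ValueError("unexpected window labels")
    conditions = sorted(epochs["condition"].unique())
    fixed = "C(condition) * C(window)" if len(conditions) > 1 else "C(window)"
    fit = fit_modality_models(epochs, outcome=outcome, fixed=fixed, vc=vc)
    result = fit.result
    k_fe = len(fit.params)
    cov = np.asarray(result.cov_params())[:k_fe, :k_fe]
    beta = fit.params["estimate"].to_numpy()

    def emm_row(condition, window):
        ref = pd.DataFrame({"condition": [condition], "window": [window]})
        return _emm_design(result, ref)[0]

    rows = []
    if len(conditions) == 2:
        a, b = conditions  # alphabetical: AO, AV
        m = adjust_m or len(windows)
        for w in windows:
            cvec = emm_row(a, w) - emm_row(b, w)
            est = float(cvec @ beta)
            se = float(np.sqrt(cvec @ cov @ cvec))
            z = est / se if se > 0 else np.nan
            p = 2 * sst.norm.sf(abs(z))
            rows.append(
                {
                    "contrast": f"{a}-{b}",
                    "window": w,
                    "estimate": est,
                    "se": se,
                    "stat": z,
                    "p_adj": min(p * m, 1.0),
                }
            )
    m_w = adjust_m or max(len(windows) - 1, 1)
    for cond in conditions:
        for w in windows:
            if w == 0:
                continue
            cvec = emm_row(cond, w) - emm_row(cond, 0)
            est = float(cvec @ beta)
            se = float(np.sqrt(cvec @ cov @ cvec))
            z = est / se if se > 0 else np.nan
            p = 2 * sst.norm.sf(abs(z))
            rows.append(
                {
                    "contrast": f"{cond}: win{w:+d} - win0",
                    "window": w,
                    "estimate": est,
                    "se": se,
                    "stat": z,
                    "p_adj": min(p * m_w, 1.0),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    test_name: str
    shapiro_p: float
    n: int


def sanity_paired_test(ao_values, av_values, alpha_normal: float = 0.05) -> PairedTestResult:
    """Conventional check on per-participant AO-AV differences: Shapiro
    normality gate, then one-sample t-test or Wilcoxon signed-rank."""
    ao = np.asarray(list(ao_values), float)
    av = np.asarray(list(av_values), float)
    if ao.shape != av.shape or ao.size < 3:
        raise ValueError("need at least three matched AO/AV pairs")
    diff = ao - av
    if np.allclose(diff, diff[0]):
        shapiro_p = 1.0  # constant differences: the t branch applies
    else:
        shapiro_p = float(sst.shapiro(diff).pvalue)
    if shapiro_p >= alpha_normal:
        if np.all(diff == 0):
            return PairedTestResult(0.0, 1.0, "t", shapiro_p, diff.size)
        stat, p = sst.ttest_1samp(diff, 0.0)
        return PairedTestResult(float(stat), float(p), "t", shapiro_p, diff.size)
    stat, p = sst.wilcoxon(diff)
    return PairedTestResult(float(stat), float(p), "wilcoxon", shapiro_p, diff.size)


def boundary_rate_profile(
    rate_table: pd.DataFrame,
    vc: dict | None = None,
) -> tuple[pd.DataFrame, MixedModelFit]:
    """Per-window mean BPM plus a window-effect mixed model (window 0 as
    the reference level), applied to raw epoch-averaged HR or RR.

    ``rate_table`` needs columns participant_id, window, value (and any
    grouping columns the random structure uses).
    """
    means = (
        rate_table.groupby("window", as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean_bpm"})
    )
    fit = fit_modality_models(
        rate_table,
        outcome="value",
        fixed="C(window, Treatment(0))",
        vc=vc,
    )
    return means, fit
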