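"""Group inference: permutation machinery, FDR, aggregation geometry,
mixed models, and paired sanity tests."""
import numpy as np
import pandas as pd
import pytest

from cardiosync.inference import (
    aggregate_time_averaged,
    boundary_rate_profile,
    circular_null_test,
    epoch_around_boundaries,
    fdr_adjust,
    fit_modality_models,
    sanity_paired_test,
    sections_from_boundaries,
    window_contrasts,
)
from cardiosync.series import PeakSeries, RateSeries, SyncSeries


def make_sync(values, hop_s=1.0, t0=5.0):
    values = np.asarray(values, float)
    centers = t0 + np.arange(values.size) * hop_s
    return SyncSeries(values, centers, "SRC-HR", 10.0, hop_s)


class TestPermutation:
    def test_zero_shift_null_equals_observed(self, quiet_audience):
        peaks = [r["heart"] for r in quiet_audience[:2]]

        def measure_fn(peak_sets):
            return np.array([len(ps) / 10.0 for ps in peak_sets] + [1.0, 2.0])

        res = circular_null_test(
            peaks, measure_fn, n_perm=100, seed=0, shift_sampler=lambda rng, d: 0.0
        )
        assert np.allclose(res.null_stats, res.observed_stat)
        assert res.p_value == 1.0

    def test_p_value_definition(self):
        peaks = [PeakSeries(np.arange(1.0, 50.0), 50.0)] * 2
        rng_obs = np.random.default_rng(1)

        def measure_fn(peak_sets):
            return rng_obs.normal(size=8)

        res = circular_null_test(peaks, measure_fn, n_perm=100, seed=2)
        n_ge = int(np.sum(res.null_stats >= res.observed_stat))
        assert res.p_value == (1 + n_ge) / 101

    def test_low_n_perm_warns(self):
        peaks = [PeakSeries(np.arange(1.0, 20.0), 20.0)] * 2
        with pytest.warns(UserWarning, match="resolution"):
            circular_null_test(peaks, lambda p: np.array([1.0, 2.0, 3.0]), n_perm=10)


class TestFDR:
    def test_worked_example(self):
        q = fdr_adjust([0.001, 0.01, 0.02, 0.04, 0.05])
        assert np.allclose(q, [0.005, 0.025, 1 / 30, 0.05, 0.05])

    def test_matches_brute_force(self):
        # brute-force BH: q_(i) = min_{j>=i} p_(j) * m / j
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 30))
            order = np.argsort(p)
            m = p.size
            brute = np.empty(m)
            stepup = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            brute[order] = np.minimum(stepup, 1.0)
            assert np.max(np.abs(fdr_adjust(p) - brute)) < 1e-12

    def test_single_and_equal_values(self):
        assert fdr_adjust([0.037]) == pytest.approx([0.037])
        assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_empty_input(self):
        assert fdr_adjust([]).size == 0


class TestAggregation:
    def test_constant_series_aggregates_to_constant(self):
        s = make_sync(np.full(170, 0.42))
        out = aggregate_time_averaged(s, [60.0, 120.0], 180.0)
        assert np.allclose(out["value"], 0.42)
        assert len(out) == 3

    def test_30s_bins_of_180s_piece(self):
        s = make_sync(np.full(170, 1.0))
        out = aggregate_time_averaged(s, [], 180.0, mode="bins30s")
        assert len(out) == 6

    def test_empty_section_is_masked(self):
        s = make_sync(np.full(20, 1.0))  # centers 5..24 s only
        out = aggregate_time_averaged(s, [30.0], 60.0)
        assert np.isnan(out["value"].iloc[1])
        assert out["n_windows"].iloc[1] == 0

    def test_section_tiling_validates(self):
        with pytest.raises(ValueError, match="increasing"):
            sections_from_boundaries([50.0, 40.0], 60.0)


class TestEpochs:
    def test_five_windows_of_six_values(self):
        s = make_sync(np.full(51, 0.5))  # 60-s piece, centers 5..55
        out = epoch_around_boundaries(s, [30.0], 60.0)
        assert len(out) == 5
        assert list(out["window"]) == [-10, -5, 0, 5, 10]
        assert (out["n_values"] == 6).all()

    def test_boundary_near_edge_dropped(self):
        s = make_sync(np.full(51, 0.5))
        out = epoch_around_boundaries(s, [10.0], 60.0)
        assert len(out) == 0

    def test_row_count_scales_with_retained_boundaries(self):
        s = make_sync(np.full(170, 0.5))
        out = epoch_around_boundaries(s, [40.0, 90.0, 140.0, 174.0], 180.0)
        assert len(out) == 5 * 3  # last boundary within 15 s of the edge


class TestMixedModels:
    @staticmethod
    def make_table(rs, offset=0.02, n_per_concert=8):
        rows = []
        for c in range(2):
            for p in range(n_per_concert):
                pid_eff = rs.normal(0, 0.01)
                for piece in range(3):
                    for sec in range(8):
                        for cond, off in (("AO", 0.0), ("AV", offset)):
                            rows.append(
                                {
                                    "participant_id": f"p{c}{p}",
                                    "concert_id": f"c{c}",
                                    "piece_id": f"m{piece}",
                                    "condition": cond,
                                    "value": 0.05 + off + pid_eff + rs.normal(0, 0.03),
                                }
                            )
        return pd.DataFrame(rows)

    def test_injected_offset_recovered(self):
        fit = fit_modality_models(self.make_table(np.random.default_rng(0)))
        term = "C(condition, Treatment('AO'))[T.AV]"
        assert fit.params.loc[term, "ci_low"] <= 0.02 <= fit.params.loc[term, "ci_high"]
        assert fit.params.loc[term, "p"] < 0.01

    def test_zero_effect_not_significant(self):
        hits = 0
        for i in range(10):
            fit = fit_modality_models(
                self.make_table(np.random.default_rng(100 + i), offset=0.0),
                vc={"participant": "0 + C(participant_id)"},
                simplify=False,
            )
            term = "C(condition, Treatment('AO'))[T.AV]"
            est, se = fit.params.loc[term, ["estimate", "se"]]
            hits += abs(est) < 2 * se
        assert hits >= 9

    def test_singular_structure_simplifies_without_error(self):
        # one concert only: the concert variance component is unidentified
        table = self.make_table(np.random.default_rng(5))
        table["concert_id"] = "c0"
        fit = fit_modality_models(table, allow_singular=False)
        assert fit.converged
        assert len(fit.simplification_path) >= 1

    def test_r2_decomposition_is_sane(self):
        fit = fit_modality_models(
            self.make_table(np.random.default_rng(2)),
            vc={"participant": "0 + C(participant_id)"},
            simplify=False,
        )
        assert 0 <= fit.marginal_r2 <= fit.conditional_r2 <= 1


class TestWindowContrasts:
    @staticmethod
    def epoch_table(rs, av_dip=0.03):
        rows = []
        for p in range(8):
            for b in range(5):
                for cond in ("AO", "AV"):
                    for w in (-10, -5, 0, 5, 10):
                        bump = av_dip if (cond == "AV" and w == 0) else 0.0
                        rows.append(
                            {
                                "participant_id": f"p{p}",
                                "concert_id": "c1",
                                "piece_id": "m1",
                                "condition": cond,
                                "window": w,
                                "value": 0.02 + bump + rs.normal(0, 0.02),
                            }
                        )
        return pd.DataFrame(rows)

    def test_bonferroni_scaling(self):
        out = window_contrasts(
            self.epoch_table(np.random.default_rng(0)),
            vc={"participant": "0 + C(participant_id)"},
        )
        ao_av = out[out.contrast == "AO-AV"]
        assert len(ao_av) == 5
        # the AV window-0 elevation shows up as the most negative AO-AV
        assert ao_av.loc[ao_av.estimate.idxmin(), "window"] == 0

    def test_null_table_rarely_significant(self):
        out = window_contrasts(
            self.epoch_table(np.random.default_rng(3), av_dip=0.0),
            vc={"participant": "0 + C(participant_id)"},
        )
        assert (out[out.contrast == "AO-AV"]["p_adj"] > 0.05).all()


class TestPairedSanity:
    def test_identical_conditions(self):
        res = sanity_paired_test(np.ones(10), np.ones(10))
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.test_name == "t"

    def test_constant_positive_shift_detected(self):
        rng = np.random.default_rng(0)
        av = rng.normal(0.05, 0.005, 16)
        ao = av - 0.02
        res = sanity_paired_test(ao, av)
        assert res.p_value < 0.01

    def test_heavy_tails_switch_to_wilcoxon(self):
        rng = np.random.default_rng(1)
        diff = rng.standard_cauchy(40)
        res = sanity_paired_test(diff, np.zeros(40))
        assert res.test_name == "wilcoxon"

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="three"):
            sanity_paired_test([1.0, 2.0], [1.0, 2.0])


class TestBoundaryRateProfile:
    def test_constant_rate_has_equal_window_means(self):
        rows = []
        for p in range(4):
            for b in range(3):
                for w in (-10, -5, 0, 5, 10):
                    rows.append(
                        {
                            "participant_id": f"p{p}",
                            "window": w,
                            "value": 61.0,
                            "concert_id": "c1",
                            "piece_id": "m1",
                        }
                    )
        means, fit = boundary_rate_profile(
            pd.DataFrame(rows), vc={"participant": "0 + C(participant_id)"}
        )
        assert np.allclose(means["mean_bpm"], 61.0)
        window_terms = [i for i in fit.params.index if "Treatment" in i]
        assert np.allclose(fit.params.loc[window_terms, "estimate"], 0.0, atol=1e-8)
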