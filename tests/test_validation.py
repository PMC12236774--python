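import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from markermatch.cnv_io import Callset, CNVCall
from markermatch.matcher import DEFAULT_DMAX_GRID, MatchParams
from markermatch.synthetic import CallsetSimConfig, simulate_callset_pair
from markermatch.validation import (
    ConfusionCounts,
    OverlapRule,
    build_metric_curves,
    classify_calls,
    compute_metrics,
    evaluate_stratified,
    fp_attribution,
    samplewise_ppv,
    select_dmax,
    threshold_curve,
)
from tests._oracles import naive_classify


def call(sample="S1", chrom="1", start=1000, end=2000, cn=1):
    return CNVCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   copy_number=cn, num_snps=10, confidence=10.0)


class TestClassify:
    def test_identical_callsets_are_all_tp(self):
        cs = Callset("x", [call(start=1, end=100), call(start=5000, end=6000)])
        cc, labels = classify_calls(cs, cs)
        assert (cc.tp, cc.fp, cc.fn) == (2, 0, 0)
        assert (labels["label"] == "TP").all()

    def test_empty_test_gives_all_fn(self):
        truth = Callset("t", [call(start=i * 10_000 + 1, end=i * 10_000 + 100)
                              for i in range(5)])
        cc, _ = classify_calls(Callset("e", []), truth)
        assert (cc.tp, cc.fp, cc.fn) == (0, 0, 5)

    def test_type_identity_required_by_default(self):
        test = Callset("t", [call(start=1000, end=2000, cn=1)])
        truth = Callset("g", [call(start=1500, end=2500, cn=1),
                              call(start=1000, end=2000, cn=3)])
        cc, _ = classify_calls(test, truth)
        assert (cc.tp, cc.fp, cc.fn) == (1, 0, 1)
        cc2, _ = classify_calls(test, truth, OverlapRule(same_type=False))
        assert (cc2.tp, cc2.fn) == (1, 0)

    def test_sample_absent_from_truth_counts_fp(self):
        test = Callset("t", [call(sample="ghost")])
        truth = Callset("g", [call(sample="S1")])
        cc, _ = classify_calls(test, truth)
        assert (cc.tp, cc.fp, cc.fn) == (0, 1, 1)

    def test_min_fraction_requires_single_covering_truth_call(self):
        test = Callset("t", [call(start=1000, end=1999)])  # length 1000
        truth = Callset("g", [call(start=1500, end=2500)])  # covers 500/1000
        assert classify_calls(test, truth, OverlapRule(min_fraction=0.5))[0].tp == 1
        assert classify_calls(test, truth, OverlapRule(min_fraction=0.51))[0].tp == 0

    def test_raising_min_fraction_never_increases_tp(self):
        truth, test, _ = simulate_callset_pair(
            CallsetSimConfig(n_samples=40, boundary_jitter_sd_bp=5000, seed=11))
        tps = [classify_calls(test, truth, OverlapRule(min_fraction=f))[0].tp
               for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert tps == sorted(tps, reverse=True)

    def test_matches_all_pairs_oracle_on_random_instances(self):
        rng = np.random.default_rng(13)
        for trial in range(8):
            truth, test, _ = simulate_callset_pair(CallsetSimConfig(
                n_samples=6, cnv_rate_per_sample=8, fp_rate_per_sample=4,
                boundary_jitter_sd_bp=float(rng.integers(0, 20_000)),
                seed=int(rng.integers(2**31)),
            ))
            for rule in (OverlapRule(), OverlapRule(same_type=False),
                         OverlapRule(min_fraction=0.5)):
                cc, _ = classify_calls(test, truth, rule)
                assert (cc.tp, cc.fp, cc.fn) == naive_classify(
                    test, truth, rule.same_sample, rule.same_type, rule.min_fraction)

    def test_conservation_tp_plus_fp_is_test_count(self):
        truth, test, _ = simulate_callset_pair(CallsetSimConfig(n_samples=30, seed=14))
        cc, labels = classify_calls(test, truth)
        assert cc.tp + cc.fp == len(test) == len(labels)


class TestMetrics:
    def test_worked_example_to_four_decimals(self):
        m = compute_metrics(ConfusionCounts(tp=9, fp=1, fn=3))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.ppv == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.8182, abs=5e-5)
        assert m.fmi == pytest.approx(0.8216, abs=5e-5)
        assert m.ji == pytest.approx(0.6923, abs=5e-5)

    def test_perfect_agreement(self):
        m = compute_metrics(ConfusionCounts(5, 0, 0))
        assert all(v == 1.0 for k, v in m.to_dict().items() if k not in ("fnr", "fdr"))
        assert m.fnr == m.fdr == 0.0

    def test_all_zero_counts_give_missing_not_zero(self):
        m = compute_metrics(ConfusionCounts(0, 0, 0))
        assert all(math.isnan(v) for v in m.to_dict().values())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    def test_metric_identities(self, tp, fp, fn):
        m = compute_metrics(ConfusionCounts(tp, fp, fn))
        if not math.isnan(m.sensitivity):
            assert m.fnr == pytest.approx(1 - m.sensitivity, abs=1e-12)
        if not math.isnan(m.ppv):
            assert m.fdr == pytest.approx(1 - m.ppv, abs=1e-12)
        if not any(math.isnan(v) for v in (m.f1, m.ji, m.fmi)):
            assert m.f1 == pytest.approx(2 * m.ji / (1 + m.ji), abs=1e-12)
            assert m.fmi >= m.f1 - 1e-12
            assert m.f1 >= m.ji - 1e-12


class TestStratified:
    def test_all_stratum_equals_global(self):
        truth, test, _ = simulate_callset_pair(CallsetSimConfig(n_samples=20, seed=21))
        table = evaluate_stratified(test, truth).set_index("stratum")
        cc, _ = classify_calls(test, truth)
        assert tuple(table.loc["all", ["tp", "fp", "fn"]]) == (cc.tp, cc.fp, cc.fn)

    def test_deletions_only_pair_leaves_duplication_stratum_empty(self):
        cs = Callset("x", [call(cn=1)])
        table = evaluate_stratified(cs, cs).set_index("stratum")
        dup = table.loc["duplication"]
        assert (dup["tp"], dup["fp"], dup["fn"]) == (0, 0, 0)
        assert math.isnan(dup["ppv"])

    def test_size_bins_match_oracle_per_bin(self):
        bins = [(0, 100_000), (100_000, 500_000), (500_000, math.inf)]
        truth, test, _ = simulate_callset_pair(CallsetSimConfig(n_samples=15, seed=22))
        table = evaluate_stratified(test, truth, size_bins=bins).set_index("stratum")
        from markermatch.cnv_io import size_bin_label

        for lo, hi in bins:
            t2 = test.filtered(lambda c: lo < c.length_bp <= hi)
            g2 = truth.filtered(lambda c: lo < c.length_bp <= hi)
            exp = naive_classify(t2, g2)
            row = table[(table["stratum_kind"] == "size")
                        & (table.index == size_bin_label(lo, hi))]
            assert tuple(row.iloc[0][["tp", "fp", "fn"]]) == exp

    def test_counts_conserve_within_every_stratum(self):
        truth, test, _ = simulate_callset_pair(CallsetSimConfig(n_samples=20, seed=23))
        table = evaluate_stratified(test, truth)
        for _, row in table.iterrows():
            assert row["tp"] + row["fp"] >= 0
            if row["stratum"] == "all":
                assert row["tp"] + row["fp"] == len(test)


class TestSampleWise:
    def _labels(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                           "cnv_type", "length_bp", "label"])

    def test_single_sample_ppv(self):
        labels = self._labels([("S1", "1", 1, 2, "deletion", 2, l)
                               for l in ["TP"] * 3 + ["FP"]])
        table = samplewise_ppv(labels)
        assert table.loc[0, "ppv"] == 0.75

    def test_per_sample_counts_sum_to_global(self):
        truth, test, _ = simulate_callset_pair(CallsetSimConfig(n_samples=25, seed=31))
        cc, labels = classify_calls(test, truth)
        table = samplewise_ppv(labels)
        assert table["tp"].sum() == cc.tp and table["fp"].sum() == cc.fp

    def test_sorted_descending_by_ppv(self):
        truth, test, _ = simulate_callset_pair(CallsetSimConfig(n_samples=25, seed=32))
        _, labels = classify_calls(test, truth)
        ppv = samplewise_ppv(labels)["ppv"].to_numpy()
        assert (np.diff(ppv) <= 1e-12).all()

    def test_fp_attribution_toy(self):
        table = pd.DataFrame({"sample_id": ["A", "B"], "tp": [0, 9], "fp": [5, 1]})
        table["ppv"] = table["tp"] / (table["tp"] + table["fp"])
        att = fp_attribution(table, 0.1)
        assert att.n_flagged == 1
        assert att.frac_samples_flagged == 0.5
        assert att.frac_fp_attributed == pytest.approx(5 / 6)
        assert (att.retained.tp, att.retained.fp) == (9, 1)

    def test_threshold_zero_flags_nothing(self):
        table = pd.DataFrame({"sample_id": ["A"], "tp": [1], "fp": [3], "ppv": [0.25]})
        att = fp_attribution(table, 0.0)
        assert att.n_flagged == 0 and att.frac_fp_attributed == 0.0

    def test_threshold_one_flags_every_sample_with_an_fp(self):
        table = pd.DataFrame({"sample_id": ["A", "B"], "tp": [3, 5],
                              "fp": [1, 0], "ppv": [0.75, 1.0]})
        att = fp_attribution(table, 1.0)
        assert att.n_flagged == 1 and att.frac_fp_attributed == 1.0

    def test_excluding_below_aggregate_ppv_samples_never_lowers_ppv(self):
        truth, test, _ = simulate_callset_pair(CallsetSimConfig(n_samples=40, seed=33))
        cc, labels = classify_calls(test, truth)
        table = samplewise_ppv(labels)
        agg = cc.tp / (cc.tp + cc.fp)
        for t in (0.1, 0.3, min(0.99, agg)):
            att = fp_attribution(table, t)
            new = att.retained.tp / (att.retained.tp + att.retained.fp)
            assert new >= agg - 1e-12

    def test_threshold_curve_rows(self):
        truth, test, _ = simulate_callset_pair(CallsetSimConfig(n_samples=20, seed=34))
        cc, labels = classify_calls(test, truth)
        curve = threshold_curve(samplewise_ppv(labels), [0.0, 0.5, 1.0], fn=cc.fn)
        assert list(curve["threshold"]) == [0.0, 0.5, 1.0]
        assert curve["ppv"].is_monotonic_increasing


def counts_for_ppv(ppv, n=10_000, fn=200):
    tp = int(round(ppv * n))
    return ConfusionCounts(tp, n - tp, fn)


class TestCurves:
    def _results(self, ppvs, method="distance"):
        return [(MatchParams(d_max=d, method=method), counts_for_ppv(p))
                for d, p in zip(DEFAULT_DMAX_GRID, ppvs)]

    def test_constant_metric_smooths_to_itself(self):
        curves = build_metric_curves(self._results([0.8] * 12), ConfusionCounts(100, 0, 0))
        c = curves["distance"]
        assert np.allclose(c.smoothed["ppv"], 0.8, atol=1e-9)

    def test_full_set_metric_one_means_scaled_equals_smoothed(self):
        curves = build_metric_curves(self._results([0.5] * 12), ConfusionCounts(100, 0, 0))
        c = curves["distance"]
        assert np.allclose(c.scaled["ppv"], c.smoothed["ppv"], equal_nan=True)

    def test_linear_in_log10_reproduced_by_smoother(self):
        x = np.log10(np.array(DEFAULT_DMAX_GRID, float))
        ppvs = 0.3 + 0.1 * (x - x.min())
        curves = build_metric_curves(self._results(ppvs.tolist()), ConfusionCounts(100, 0, 0))
        sm = curves["distance"].smoothed["ppv"].to_numpy()
        assert np.allclose(sm, ppvs, atol=0.01)

    def test_short_grid_passes_raw_through_with_warning(self):
        results = self._results([0.5, 0.6, 0.7])[:3]
        with pytest.warns(UserWarning, match="smoothing skipped"):
            curves = build_metric_curves(results, ConfusionCounts(100, 0, 0))
        assert np.allclose(curves["distance"].smoothed["ppv"],
                           curves["distance"].raw["ppv"])

    def test_ratio_scaling_divides_by_reference(self):
        ref = counts_for_ppv(0.5, fn=0)  # full-set ppv 0.5
        curves = build_metric_curves(self._results([0.4] * 12), ref)
        assert np.allclose(curves["distance"].scaled["ppv"], 0.8, atol=1e-9)


class TestSelectDmax:
    def _curve(self, ppvs):
        results = [(MatchParams(d_max=d, method="distance"), counts_for_ppv(p))
                   for d, p in zip(DEFAULT_DMAX_GRID, ppvs)]
        return build_metric_curves(results, ConfusionCounts(100, 0, 0))["distance"]

    def test_flat_curve_returns_first_grid_point(self):
        assert select_dmax(self._curve([0.7] * 12), metric="ppv") == 10

    def test_saturating_curve_returns_plateau_onset(self):
        ppvs = [0.20, 0.30, 0.45, 0.60, 0.72, 0.82, 0.90, 0.90, 0.90, 0.90, 0.90, 0.90]
        assert select_dmax(self._curve(ppvs), metric="ppv") == 10_000

    def test_single_peak_with_zero_tolerance_returns_peak(self):
        ppvs = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.9, 0.7, 0.6, 0.5, 0.4, 0.3]
        c = self._curve(ppvs)
        peak_idx = int(np.nanargmax(c.scaled["ppv"].to_numpy()))
        assert select_dmax(c, tolerance=0.0, metric="ppv") == int(c.d_max[peak_idx])

    def test_too_few_points_rejected(self):
        c = self._curve([0.5] * 12)
        c.d_max = c.d_max[:1]
        with pytest.raises(ValueError):
            select_dmax(c)
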