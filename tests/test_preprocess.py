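import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import brainmetab as bm
from brainmetab.io_formats import AnalyteTable
from brainmetab.preprocess import (
    PipelineError,
    boxcox_fit_transform,
    classify_levodopa,
    compute_indicators,
    compute_lod,
    filter_below_lod,
    impute_covariates,
    interpolate_zeros,
    plate_normalize,
    quantify_linear,
    standardize_to_controls,
    tukey_fence,
)
from conftest import make_meta


def table_of(values: dict, index=None, method="LC"):
    df = pd.DataFrame(values, index=index)
    if index is None:
        df.index = [f"s{i + 1}" for i in range(len(df))]
    ann = pd.DataFrame({
        "method": method, "analyte_type": "measured", "class_label": "",
    }, index=pd.Index(df.columns, name="analyte_id"))
    return AnalyteTable(df.astype(float), ann)


class TestQuantify:
    def test_sample_at_qc_median_gets_expected_conc(self):
        t = table_of({"A": [1, 2, 3, 2]})
        qc = pd.Series([True, True, True, False], index=t.values.index)
        out, flagged = quantify_linear(t, qc, {"A": 10.0})
        assert out.values.loc["s4", "A"] == pytest.approx(10.0)
        assert not flagged

    def test_linearity(self):
        t = table_of({"A": [1, 2, 3, 4]})
        qc = pd.Series([True, True, True, False], index=t.values.index)
        out, _ = quantify_linear(t, qc, {"A": 10.0})
        assert out.values.loc["s4", "A"] == pytest.approx(20.0)

    def test_zero_qc_median_flags_and_passes_through(self):
        t = table_of({"A": [0, 0, 0, 4]})
        qc = pd.Series([True, True, True, False], index=t.values.index)
        out, flagged = quantify_linear(t, qc, {"A": 10.0})
        assert flagged == ["A"]
        assert out.values.loc["s4", "A"] == 4.0


class TestLod:
    def test_two_times_median(self):
        blanks = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        assert compute_lod(blanks)["A"] == 4.0

    def test_all_zero_blanks(self):
        blanks = pd.DataFrame({"A": [0.0, 0.0, 0.0]})
        assert compute_lod(blanks)["A"] == 0.0

    def test_single_blank(self):
        blanks = pd.DataFrame({"A": [5.0]})
        assert compute_lod(blanks)["A"] == 10.0

    def test_filter_requires_excess_in_every_group(self):
        # 10 samples in each of two groups; analyte A: 60% below LOD in both
        # groups -> removed; B: 60%/40% -> retained; C: exactly 50% -> retained
        groups = ["CTRL"] * 10 + ["PD-D"] * 10
        meta = make_meta(groups)
        lod = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0})
        def col(frac_low_g1, frac_low_g2):
            return [0.5] * frac_low_g1 + [2.0] * (10 - frac_low_g1) + \
                   [0.5] * frac_low_g2 + [2.0] * (10 - frac_low_g2)
        t = table_of({"A": col(6, 6), "B": col(6, 4), "C": col(5, 5)},
                     index=meta.frame.index)
        out, removed = filter_below_lod(t, lod, meta)
        assert removed == ["A"]
        assert out.analyte_ids == ["B", "C"]

    def test_analyte_without_lod_exempt(self):
        meta = make_meta(["CTRL"] * 4)
        t = table_of({"A": [0.1, 0.1, 0.1, 0.1]}, index=meta.frame.index)
        out, removed = filter_below_lod(t, pd.Series(dtype=float), meta)
        assert removed == [] and out.analyte_ids == ["A"]

    def test_sub_lod_values_not_adjusted(self):
        meta = make_meta(["CTRL"] * 4)
        t = table_of({"A": [0.5, 2.0, 2.0, 2.0]}, index=meta.frame.index)
        out, _ = filter_below_lod(t, pd.Series({"A": 1.0}), meta)
        assert out.values.loc["s1", "A"] == 0.5


class TestZeros:
    def test_zero_becomes_half_min_nonzero(self):
        t = table_of({"A": [0.0, 4.0, 8.0]})
        out, flagged = interpolate_zeros(t)
        assert list(out.values["A"]) == [2.0, 4.0, 8.0]
        assert not flagged

    def test_no_zero_unchanged(self):
        t = table_of({"A": [1.0, 2.0, 3.0]})
        out, _ = interpolate_zeros(t)
        assert list(out.values["A"]) == [1.0, 2.0, 3.0]

    def test_all_zero_flagged_missing(self):
        t = table_of({"A": [0.0, 0.0]})
        out, flagged = interpolate_zeros(t)
        assert flagged == ["A"]
        assert out.values["A"].isna().all()


class TestPlateNormalize:
    def oracle(self, x, groups, plates):
        """Direct evaluation of the normalization equations."""
        x = np.asarray(x, float)
        r = np.empty_like(x)
        for g in set(groups):
            m = np.array([gi == g for gi in groups])
            r[m] = x[m] / np.median(x[m])
        q = {p: np.median(r[np.array([pi == p for pi in plates])]) / np.median(r)
             for p in set(plates)}
        y = x / np.array([q[p] for p in plates])
        return y, q

    def test_six_value_instance(self):
        """Two plates, one group, B = 2x A: quotients in ratio 2 and equal
        normalized plate medians."""
        meta = make_meta(["CTRL"] * 6, plates=["A", "A", "A", "B", "B", "B"])
        t = table_of({"m": [2, 4, 6, 4, 8, 12]}, index=meta.frame.index)
        out, rec = plate_normalize(t, meta)
        qa, qb = rec.quotients.loc["m", "A"], rec.quotients.loc["m", "B"]
        assert qb / qa == pytest.approx(2.0, abs=1e-12)
        med_a = out.values["m"].iloc[:3].median()
        med_b = out.values["m"].iloc[3:].median()
        assert med_a == pytest.approx(med_b, abs=1e-12)
        y, q = self.oracle([2, 4, 6, 4, 8, 12], ["g"] * 6, list("AAABBB"))
        np.testing.assert_allclose(out.values["m"].to_numpy(), y, rtol=1e-12)

    def test_single_plate_is_identity(self):
        meta = make_meta(["CTRL", "CTRL", "PD-D", "PD-D"])
        t = table_of({"m": [1.0, 2.0, 3.0, 4.0]}, index=meta.frame.index)
        out, rec = plate_normalize(t, meta)
        np.testing.assert_allclose(rec.quotients["P1"], 1.0, atol=1e-12)
        np.testing.assert_allclose(out.values["m"], t.values["m"], rtol=1e-12)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(9, 30))
            groups = [["CTRL", "PD-D", "QC"][i] for i in rng.integers(0, 3, n)]
            plates = [["A", "B"][i] for i in rng.integers(0, 2, n)]
            x = np.exp(rng.normal(0, 1, n))
            meta = make_meta(groups, plates=plates)
            t = table_of({"m": x}, index=meta.frame.index)
            out, rec = plate_normalize(t, meta)
            y, q = self.oracle(x, groups, plates)
            np.testing.assert_allclose(out.values["m"].to_numpy(), y, rtol=1e-10)
            for p, qp in q.items():
                assert rec.quotients.loc["m", p] == pytest.approx(qp, rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        groups = ["CTRL", "CTRL", "PD-D", "PD-D", "QC", "QC"]
        plates = ["A", "B", "A", "B", "A", "B"]
        x = np.array([1.0, 2.0, 3.0, 4.0, 2.5, 3.5])
        meta = make_meta(groups, plates=plates)
        out1, _ = plate_normalize(table_of({"m": x}, index=meta.frame.index), meta)
        out2, _ = plate_normalize(table_of({"m": c * x}, index=meta.frame.index),
                                  meta)
        np.testing.assert_allclose(out2.values["m"], c * out1.values["m"],
                                   rtol=1e-10)

    def test_zero_group_median_excluded_with_warning(self):
        meta = make_meta(["CTRL", "CTRL", "PD-D", "PD-D"],
                         plates=["A", "B", "A", "B"])
        t = table_of({"m": [0.0, 0.0, 3.0, 4.0]}, index=meta.frame.index)
        out, rec = plate_normalize(t, meta)
        assert any("median is 0" in w for w in rec.warnings)
        assert np.isfinite(out.values["m"]).all()


class TestIndicators:
    def defs(self):
        return [
            bm.IndicatorDef("ratio_AB", "ratio", ["A"], ["B"]),
            bm.IndicatorDef("sum_AB", "sum", ["A", "B"]),
        ]

    def test_ratio_and_sum(self):
        t = table_of({"A": [6.0, 1.0], "B": [3.0, 2.0]})
        ind = compute_indicators(t, self.defs())
        assert ind.values.loc["s1", "ratio_AB"] == 2.0
        assert ind.values.loc["s2", "sum_AB"] == 3.0
        assert (ind.annotations["analyte_type"] == "calculated").all()

    def test_zero_denominator_is_missing(self):
        t = table_of({"A": [6.0], "B": [0.0]})
        ind = compute_indicators(t, self.defs())
        assert np.isnan(ind.values.loc["s1", "ratio_AB"])

    def test_mixed_method_goes_to_fia_stratum(self):
        df = pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["s1"])
        ann = pd.DataFrame({"method": ["LC", "FIA"],
                            "analyte_type": ["measured"] * 2,
                            "class_label": ["", ""]},
                           index=pd.Index(["A", "B"], name="analyte_id"))
        t = AnalyteTable(df, ann)
        ind = compute_indicators(t, [bm.IndicatorDef("s", "sum", ["A", "B"])])
        assert ind.annotations.loc["s", "method"] == "FIA"

    def test_filtered_member_dropped_from_sum(self):
        t = table_of({"A": [1.0, 2.0]})
        ind = compute_indicators(
            t, [bm.IndicatorDef("s", "sum", ["A", "GONE"])])
        assert list(ind.values["s"]) == [1.0, 2.0]

    def test_all_members_filtered_gives_missing(self):
        t = table_of({"A": [1.0]})
        ind = compute_indicators(t, [bm.IndicatorDef("s", "sum", ["GONE"])])
        assert ind.values["s"].isna().all()


class TestBoxCox:
    def grid_oracle(self, x):
        from scipy.stats import boxcox_llf
        grid = np.linspace(-3, 3, 2401)
        return grid[np.argmax([boxcox_llf(l, x) for l in grid])]

    def test_lognormal_gives_lambda_near_zero(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(0, 0.5, 200))
        t, lam = boxcox_fit_transform(x)
        assert abs(lam) < 0.2
        assert lam == pytest.approx(self.grid_oracle(x), abs=5e-3)

    def test_normal_sample_gives_lambda_near_one(self):
        rng = np.random.default_rng(8)
        x = np.clip(rng.normal(20, 6, 200), 0.5, None)
        t, lam = boxcox_fit_transform(x)
        assert abs(lam - 1.0) < 0.4
        assert lam == pytest.approx(self.grid_oracle(x), abs=5e-3)

    def test_nonpositive_value_is_pipeline_error(self):
        with pytest.raises(PipelineError, match="non-positive"):
            boxcox_fit_transform(np.array([1.0, 0.0, 2.0]))

    def test_constant_vector_flagged(self):
        t, lam = boxcox_fit_transform(np.full(20, 3.0))
        assert np.isnan(lam)

    def test_missing_values_preserved(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        t, lam = boxcox_fit_transform(x)
        assert np.isnan(t[1]) and np.isfinite(np.delete(t, 1)).all()


class TestTukey:
    def test_all_equal_unchanged(self):
        v, rec = tukey_fence(np.full(10, 2.0))
        assert (v == 2.0).all() and rec["n_adjusted"] == 0

    def test_zero_iqr_pulls_outlier_to_fence(self):
        x = np.array([0.0] * 9 + [100.0])
        v, rec = tukey_fence(x)
        assert v[-1] == 0.0 and rec["n_adjusted"] == 1

    def test_outlier_maps_to_quantile_fence(self):
        rng = np.random.default_rng(2)
        x = np.append(rng.standard_normal(200), 50.0)
        v, rec = tukey_fence(x, k=3)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        assert v[-1] == pytest.approx(q3 + 3 * (q3 - q1), rel=1e-12)

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=4,
                    max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_expands_range_never_touches_inliers(self, xs):
        x = np.asarray(xs, float)
        v, rec = tukey_fence(x)
        assert v.min() >= x.min() - 1e-9 and v.max() <= x.max() + 1e-9
        inside = (x >= rec["lower"]) & (x <= rec["upper"])
        np.testing.assert_array_equal(v[inside], x[inside])


class TestStandardize:
    def test_control_anchoring(self):
        ctrl = np.array([True, True, True, False])
        z, rec = standardize_to_controls(np.array([1.0, 2.0, 3.0, 2.0]), ctrl)
        assert z[3] == pytest.approx(0.0)
        z, rec = standardize_to_controls(np.array([1.0, 2.0, 3.0, 3.0]), ctrl)
        assert z[3] == pytest.approx(1.0)

    def test_constant_controls_flagged(self):
        z, rec = standardize_to_controls(np.array([2.0, 2.0, 2.0, 5.0]),
                                         np.array([True, True, True, False]))
        assert z is None and rec["flag"] == "zero_control_sd"

    def test_processed_controls_have_unit_moments(self, processed_null):
        for region, pr in processed_null.regions.items():
            ctrl = processed_null.meta.subjects(region)
            ctrl = ctrl[ctrl.group == "CTRL"].index
            vals = pr.table.values.loc[ctrl]
            np.testing.assert_allclose(vals.mean(), 0.0, atol=1e-10)
            np.testing.assert_allclose(vals.std(ddof=1), 1.0, rtol=1e-10)


class TestImpute:
    def meta_with_missing(self):
        return make_meta(
            ["PD-MCI"] * 3 + ["CTRL"] * 2,
            sex=["M", "M", "M", "F", "F"],
            bmi=[24.0, 26.0, np.nan, 22.0, np.nan],
            education=[10.0, 12.0, 14.0, 16.0, 18.0],
        )

    def test_group_sex_conditional_mean(self):
        out = impute_covariates(self.meta_with_missing())
        assert out.frame.loc["s3", "bmi"] == pytest.approx(25.0)
        assert out.frame.loc["s5", "bmi"] == pytest.approx(22.0)

    def test_no_missing_is_identity(self, null_cohort):
        _, meta, _, _ = null_cohort
        once = impute_covariates(meta)
        twice = impute_covariates(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_singleton_cell_falls_back_to_group_mean(self):
        meta = make_meta(["PD-D", "PD-D"], sex=["F", "M"],
                         bmi=[np.nan, 30.0], education=[10.0, 12.0])
        out = impute_covariates(meta)
        assert out.frame.loc["s1", "bmi"] == pytest.approx(30.0)


class TestLevodopa:
    def test_threshold_is_control_quantile_and_ties_go_lminus(self):
        groups = ["CTRL"] * 20 + ["PD-D"] * 2
        meta = make_meta(groups)
        dopa = pd.Series(np.r_[np.arange(1.0, 21.0), [0.0, 0.0]],
                         index=meta.frame.index)
        thr = np.quantile(np.arange(1.0, 21.0), 0.95)
        dopa.iloc[20] = thr        # exactly at threshold -> L-
        dopa.iloc[21] = thr + 0.01
        status = classify_levodopa(dopa, meta)
        assert status.thresholds["cortex"] == pytest.approx(thr)
        assert status.flags.iloc[0] == "L-"
        assert status.flags.iloc[1] == "L+"
        ctrl_above = (dopa.iloc[:20] > thr).mean()
        assert ctrl_above <= 0.05

    def test_region_without_controls_errors(self):
        meta = make_meta(["PD-CN", "PD-CN"] * 6)
        dopa = pd.Series(np.arange(12.0), index=meta.frame.index)
        with pytest.raises(PipelineError, match="no control DOPA"):
            classify_levodopa(dopa, meta)

    def test_agreement_with_generator_truth(self, processed_null, null_cohort):
        _, meta, _, truth = null_cohort
        flags = processed_null.lstatus.flags
        subj = meta.frame.loc[flags.index, "subject_id"]
        agree = np.mean([(flags[s] == "L+") == truth.lplus[subj[s]]
                         for s in flags.index])
        assert agree >= 0.95


class TestPipelineOrdering:
    def test_boxcox_refuses_unhandled_zeros(self):
        """Zeros surviving to the transform stage indicate stage reordering."""
        with pytest.raises(PipelineError):
            boxcox_fit_transform(np.array([0.0, 1.0, 2.0]))

    def test_pipeline_outputs_exclude_qc(self, processed_null, null_cohort):
        _, meta, _, _ = null_cohort
        qc = meta.frame.index[meta.frame.group == "QC"]
        for pr in processed_null.regions.values():
            assert not pr.table.values.index.isin(qc).any()
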