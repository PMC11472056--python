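"""QC filtering, quantile normalization, fold changes, rank-sum statistics."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from seedscreen.expression import (
    DEFAULT_FLAG_CRITERIA,
    ExpressionTable,
    QcCriteria,
    apply_flag_filter,
    compute_fold_changes,
    ddct_fold_change,
    ecdf,
    filter_low_tpm,
    offtarget_report,
    quantile_normalize,
    relative_luc_activity,
    wilcoxon_rank_sum,
)
from seedscreen.seed_match import SeedClassification


def make_table(values: dict, platform="microarray", flags=None, annotation=None):
    df = pd.DataFrame(values)
    sample_cols = tuple(
        c for c in df.columns
        if c not in {"transcript_id", annotation, *(flags or ())}
    )
    return ExpressionTable(
        data=df,
        sample_columns=sample_cols,
        flag_columns=tuple(flags or ()),
        platform=platform,
        annotation_column=annotation,
    )


class TestFlagFilter:
    def toy_table(self):
        n = 6
        data = {"transcript_id": [f"t{i}" for i in range(n)]}
        for col, passing in DEFAULT_FLAG_CRITERIA.items():
            data[col] = [passing] * n
        data["gIsSaturated"] = [0, 1, 0, 1, 0, 0]
        data["mock"] = np.arange(1.0, n + 1)
        data["treated"] = np.arange(1.0, n + 1)
        return make_table(data, flags=DEFAULT_FLAG_CRITERIA)

    def test_saturated_rows_removed(self):
        out = apply_flag_filter(self.toy_table())
        assert len(out.data) == 4
        assert set(out.data["transcript_id"]) == {"t0", "t2", "t4", "t5"}

    def test_all_passing_is_identity(self):
        table = self.toy_table()
        table.data["gIsSaturated"] = 0
        out = apply_flag_filter(table)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_missing_flag_column_named_in_error(self):
        table = make_table(
            {"transcript_id": ["a"], "mock": [1.0], "treated": [1.0]}
        )
        with pytest.raises(ValueError, match="ControlType"):
            apply_flag_filter(table)

    def test_systematic_name_prefix_applied(self):
        table = self.toy_table()
        table.data["gIsSaturated"] = 0
        table.data["SystematicName"] = ["NM_1", "XR_2", "NM_3", "NM_4", "XM_5", "NM_6"]
        table = make_table(
            table.data, flags=DEFAULT_FLAG_CRITERIA, annotation="SystematicName"
        )
        out = apply_flag_filter(table)
        assert len(out.data) == 4

    def test_synthetic_fail_fraction_bookkeeping(self):
        from seedscreen.synthetic import (
            ExpressionSimSpec,
            TranscriptomeSimSpec,
            gen_expression_table,
            gen_utr_set,
        )

        spec = TranscriptomeSimSpec(
            n_transcripts=1000, motif="GUAGCAG", planted_fraction=0.1,
            utr_length_range=(40, 80), seed=30,
        )
        _, truth = gen_utr_set(spec)
        table, _ = gen_expression_table(
            truth, ExpressionSimSpec(fail_fraction=0.1, seed=31)
        )
        out = apply_flag_filter(table)
        assert len(out.data) == 900


class TestTpmFilter:
    def test_threshold_is_strictly_below(self):
        table = make_table(
            {"transcript_id": ["a", "b", "c"], "mock": [5.0, 10.0, 11.0],
             "treated": [1.0, 1.0, 1.0]},
            platform="rnaseq",
        )
        out = filter_low_tpm(table, threshold=10, reference_sample="mock")
        assert list(out.data["transcript_id"]) == ["b", "c"]

    def test_zero_threshold_is_identity(self):
        table = make_table(
            {"transcript_id": ["a", "b"], "mock": [0.0, 3.0], "treated": [1.0, 1.0]},
            platform="rnaseq",
        )
        assert len(filter_low_tpm(table, threshold=0).data) == 2

    def test_matches_naive_loop_oracle(self, rng):
        n = 300
        table = make_table(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "mock": rng.gamma(2.0, 20.0, n),
                "treated": rng.gamma(2.0, 20.0, n),
            },
            platform="rnaseq",
        )
        out = filter_low_tpm(table, threshold=10, reference_sample="mock")
        naive = [
            tid
            for tid, v in zip(table.data["transcript_id"], table.data["mock"])
            if not v < 10
        ]
        assert list(out.data["transcript_id"]) == naive

    def test_wrong_platform_and_unknown_reference_rejected(self):
        micro = make_table({"transcript_id": ["a"], "mock": [1.0], "treated": [1.0]})
        with pytest.raises(ValueError):
            filter_low_tpm(micro)
        rnaseq = make_table(
            {"transcript_id": ["a"], "mock": [1.0], "treated": [1.0]},
            platform="rnaseq",
        )
        with pytest.raises(ValueError, match="reference"):
            filter_low_tpm(rnaseq, reference_sample="nope")


def naive_quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Reference implementation: loop over columns, average tied-rank values."""
    ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    out = df.copy().astype(float)
    for col in df.columns:
        ranks = stats.rankdata(df[col], method="average")
        out[col] = [
            ref[int(r) - 1] if float(r).is_integer()
            else (ref[int(np.floor(r)) - 1] + ref[int(np.ceil(r)) - 1]) / 2
            for r in ranks
        ]
    return out


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_hand_computed_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["a"], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out["b"], [1.5, 3.0, 4.5])

    def test_sorted_multisets_identical_and_rank_order_preserved(self, rng):
        df = pd.DataFrame(rng.gamma(2.0, 50.0, (200, 4)), columns=list("abcd"))
        out = quantile_normalize(df)
        ref = np.sort(out["a"].to_numpy())
        for col in "bcd":
            np.testing.assert_allclose(np.sort(out[col].to_numpy()), ref)
        for col in "abcd":
            assert np.array_equal(
                np.argsort(out[col].to_numpy(), kind="stable"),
                np.argsort(df[col].to_numpy(), kind="stable"),
            )

    def test_matches_naive_reference_with_ties(self, rng):
        vals = rng.integers(0, 15, (60, 3)).astype(float)  # many ties
        df = pd.DataFrame(vals, columns=list("xyz"))
        pd.testing.assert_frame_equal(
            quantile_normalize(df), naive_quantile_normalize(df)
        )

    def test_requires_two_columns(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestFoldChanges:
    def test_equal_columns_give_zero(self):
        table = make_table(
            {"transcript_id": ["a", "b"], "mock": [4.0, 8.0], "treated": [4.0, 8.0]}
        )
        fc = compute_fold_changes(table, "treated", "mock", pseudocount=0.0)
        np.testing.assert_array_equal(fc["log2fc"], 0.0)

    def test_quarter_ratio_gives_minus_two(self):
        table = make_table(
            {"transcript_id": ["a"], "mock": [8.0], "treated": [2.0]}
        )
        fc = compute_fold_changes(table, "treated", "mock", pseudocount=0.0)
        assert fc["log2fc"].iloc[0] == pytest.approx(-2.0)
        assert fc["avg_log_intensity"].iloc[0] == pytest.approx(
            (np.log10(2.0) + np.log10(8.0)) / 2
        )

    def test_zero_values_need_pseudocount(self):
        table = make_table(
            {"transcript_id": ["a"], "mock": [0.0], "treated": [2.0]}
        )
        with pytest.raises(ValueError):
            compute_fold_changes(table, "treated", "mock", pseudocount=0.0)
        fc = compute_fold_changes(table, "treated", "mock", pseudocount=1.0)
        assert fc["log2fc"].iloc[0] == pytest.approx(np.log2(3.0))


class TestWilcoxonRankSum:
    def test_exact_enumeration_of_separated_triples(self):
        cmp = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert cmp.method == "exact"
        assert cmp.p_two_sided == pytest.approx(0.1)
        assert cmp.u_sm == 0 and cmp.u_other == 9

    def test_identical_samples_give_p_one(self):
        cmp = wilcoxon_rank_sum(np.arange(30.0), np.arange(30.0))
        assert cmp.p_two_sided == pytest.approx(1.0, abs=1e-12)

    def test_u_sum_identity_random_samples(self, rng):
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 40))
            b = rng.normal(size=rng.integers(2, 40))
            cmp = wilcoxon_rank_sum(a, b)
            assert cmp.u_sm + cmp.u_other == pytest.approx(len(a) * len(b))

    @pytest.mark.parametrize("n,bound", [(8, 0.011), (10, 0.01)])
    def test_exact_agrees_with_normal_approx_exhaustively(self, n, bound):
        # every achievable U for equal group sizes n; bounds from full
        # enumeration of the null (worst case 0.0109 at n=8, 0.0086 at n=10)
        from seedscreen.expression import _exact_u_sf_cdf
        from scipy.stats import norm
        import math as _math

        mu, var = n * n / 2.0, n * n * (2 * n + 1) / 12.0
        for u in range(n * n + 1):
            cdf, sf = _exact_u_sf_cdf(n, n, u)
            p_exact = min(1.0, 2.0 * min(cdf, sf))
            d = u - mu
            cc = 0.5 * _math.copysign(1.0, d) if d else 0.0
            p_approx = min(1.0, 2.0 * norm.sf(abs((d - cc) / _math.sqrt(var))))
            assert abs(p_exact - p_approx) < bound

    def test_exact_agrees_with_scipy_cross_check(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=6), rng.normal(size=9)
            ours = wilcoxon_rank_sum(a, b, mode="exact").p_two_sided
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approx_with_ties_close_to_scipy(self, rng):
        for _ in range(10):
            a = rng.integers(0, 6, size=30).astype(float)
            b = rng.integers(0, 6, size=40).astype(float)
            ours = wilcoxon_rank_sum(a, b, mode="normal_approx").p_two_sided
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert ours == pytest.approx(ref.pvalue, abs=1e-9)

    @given(
        st.lists(st.integers(-1000, 1000), min_size=12, max_size=25, unique=True),
    )
    def test_invariant_under_monotone_transform(self, pooled):
        a = np.array(pooled[:6], dtype=float)
        b = np.array(pooled[6:], dtype=float)
        base = wilcoxon_rank_sum(a, b)
        mono = wilcoxon_rank_sum(np.exp(a / 50), np.exp(b / 50))
        assert base.u_sm == pytest.approx(mono.u_sm)
        assert base.p_two_sided == pytest.approx(mono.p_two_sided)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestEcdf:
    def test_single_value(self):
        curve = ecdf([5.0])
        np.testing.assert_array_equal(curve.values, [5.0])
        np.testing.assert_array_equal(curve.fractions, [1.0])

    def test_tied_values_collapse(self):
        curve = ecdf([1, 2, 2, 4])
        np.testing.assert_array_equal(curve.values, [1, 2, 4])
        np.testing.assert_allclose(curve.fractions, [0.25, 0.75, 1.0])

    def test_right_continuous_evaluation(self, rng):
        vals = rng.normal(size=50)
        curve = ecdf(vals)
        assert curve(vals.max()) == 1.0
        assert curve(vals.min() - 1) == 0.0
        assert np.all(np.diff(curve.fractions) > 0)


def classification_for(ids, sm_ids):
    return [
        SeedClassification(
            transcript_id=i,
            is_sm=i in sm_ids,
            match_count=1 if i in sm_ids else 0,
            match_offsets=(0,) if i in sm_ids else (),
        )
        for i in ids
    ]


class TestOfftargetReport:
    def make_zero_noise(self, sm_log2fc):
        ids = [f"t{i}" for i in range(20)]
        sm_ids = set(ids[:5])
        mock = np.full(20, 100.0)
        treated = mock * np.where([i in sm_ids for i in ids], 2.0**sm_log2fc, 1.0)
        treated[10] = 25.0  # the on-target transcript, knocked down 4x
        table = make_table(
            {"transcript_id": ids, "mock": mock, "treated": treated}
        )
        return table, classification_for(ids, sm_ids)

    def test_zero_effect_means_equal_group_means(self):
        table, classes = self.make_zero_noise(0.0)
        res = offtarget_report(
            table, classes, "treated", "mock", on_target_ids=["t10"], pseudocount=0.0
        )
        assert res.comparison.mean_log2fc_sm == 0.0
        assert res.comparison.mean_log2fc_other == 0.0

    def test_sm_effect_recovered_exactly(self):
        table, classes = self.make_zero_noise(-0.5)
        res = offtarget_report(
            table, classes, "treated", "mock", on_target_ids=["t10"], pseudocount=0.0
        )
        assert res.comparison.mean_log2fc_sm == pytest.approx(-0.5, abs=1e-12)
        assert res.comparison.mean_log2fc_other == 0.0
        assert res.comparison.n_other == 14  # on-target excluded

    def test_on_target_kept_in_ma_table_but_excluded_from_groups(self):
        table, classes = self.make_zero_noise(-0.5)
        res = offtarget_report(
            table, classes, "treated", "mock", on_target_ids=["t10"], pseudocount=0.0
        )
        assert "t10" in set(res.ma_table["transcript_id"])
        assert res.comparison.n_sm + res.comparison.n_other == 19

    def test_no_sm_transcripts_yields_warning_not_p(self):
        ids = ["a", "b", "c"]
        table = make_table(
            {"transcript_id": ids, "mock": [1.0, 2.0, 3.0], "treated": [1.0, 2.0, 3.0]}
        )
        res = offtarget_report(table, classification_for(ids, set()), "treated", "mock")
        assert res.comparison is None
        assert any("empty" in w for w in res.warnings)

    def test_outputs_written(self, tmp_path):
        table, classes = self.make_zero_noise(-0.5)
        offtarget_report(
            table, classes, "treated", "mock", on_target_ids=["t10"],
            pseudocount=0.0, out_dir=tmp_path,
        )
        for name in ("ma.tsv", "ecdf_sm.tsv", "ecdf_other.tsv", "summary.json"):
            assert (tmp_path / name).exists()
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["comparison"]["mean_log2fc_sm"] == pytest.approx(-0.5)


class TestAssayQuantification:
    def test_relative_activity_equal_and_half_ratio(self):
        assert relative_luc_activity(2.0, 4.0, 0.5) == pytest.approx(100.0)
        assert relative_luc_activity(1.0, 4.0, 0.5) == pytest.approx(50.0)

    def test_vectorized_matches_per_well_loop(self, rng):
        ren = rng.uniform(0.5, 5.0, 24)
        fly = rng.uniform(0.5, 5.0, 24)
        vec = relative_luc_activity(ren, fly, 0.8)
        loop = [relative_luc_activity(r, f, 0.8) for r, f in zip(ren, fly)]
        np.testing.assert_allclose(vec, loop)

    def test_nonpositive_denominators_rejected(self):
        with pytest.raises(ValueError):
            relative_luc_activity(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            relative_luc_activity(1.0, 1.0, 0.0)

    def test_ddct_identities(self):
        assert ddct_fold_change(20.0, 15.0, 20.0, 15.0) == pytest.approx(1.0)
        assert ddct_fold_change(21.0, 15.0, 20.0, 15.0) == pytest.approx(0.5)

    def test_ddct_invariant_to_constant_shift(self, rng):
        cts = rng.uniform(15, 30, 4)
        base = ddct_fold_change(*cts)
        shifted = ddct_fold_change(*(cts + 3.7))
        assert shifted == pytest.approx(base)


class TestEndToEndStatistics:
    def test_power_with_moderate_sm_knockdown(self, big_truth_and_records):
        from seedscreen.seed_match import classify_utr_set
        from seedscreen.synthetic import ExpressionSimSpec, gen_expression_table

        from conftest import GUIDE_21MER

        records, truth = big_truth_and_records
        spec = ExpressionSimSpec(sm_log2fc=-0.5, noise_log2_sd=0.3, seed=500)
        table, _ = gen_expression_table(truth, spec)
        classes, _ = classify_utr_set(records, GUIDE_21MER)
        res = offtarget_report(table, classes, "treated", "mock", pseudocount=0.0)
        assert res.comparison.n_sm == 150
        assert res.comparison.n_other == 5000
        assert res.comparison.p_two_sided < 1e-6

    def test_type_i_error_controlled_under_null(self, big_truth_and_records):
        from seedscreen.synthetic import ExpressionSimSpec, gen_expression_table

        _, truth = big_truth_and_records
        is_sm = truth.df["is_sm"].to_numpy()
        hits = 0
        n_reps = 500
        for rep in range(n_reps):
            spec = ExpressionSimSpec(sm_log2fc=0.0, on_target_log2fc=0.0,
                                     noise_log2_sd=0.3, seed=1000 + rep)
            table, _ = gen_expression_table(truth, spec)
            fc = np.log2(table.data["treated"].to_numpy()
                         / table.data["mock"].to_numpy())
            cmp = wilcoxon_rank_sum(fc[is_sm], fc[~is_sm])
            hits += cmp.p_two_sided < 0.05
        assert 0.025 <= hits / n_reps <= 0.10

    def test_pipeline_row_order_invariance(self, rng):
        ids = [f"t{i}" for i in range(50)]
        table = make_table(
            {
                "transcript_id": ids,
                "mock": rng.gamma(2.0, 50.0, 50),
                "treated": rng.gamma(2.0, 50.0, 50),
            }
        )
        classes = classification_for(ids, set(ids[:10]))
        res1 = offtarget_report(table, classes, "treated", "mock")
        perm = rng.permutation(50)
        shuffled = make_table(
            {
                "transcript_id": [ids[i] for i in perm],
                "mock": table.data["mock"].to_numpy()[perm],
                "treated": table.data["treated"].to_numpy()[perm],
            }
        )
        res2 = offtarget_report(shuffled, classes, "treated", "mock")
        assert res1.comparison == res2.comparison
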