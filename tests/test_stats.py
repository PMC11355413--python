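import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroct.datasets import (
    multi_image_replicates,
    multi_image_summary,
    repeat_run_replicates,
    repeat_run_summary,
)
from fibroct.stats import (
    aggregate_cv,
    anova_mean_squares,
    ecv_fraction,
    icc,
    interpret_r,
    ks_normality,
    paired_t_test,
    pearson,
    read_replicate_csv,
    replicate_stats,
    replicate_table_stats,
    round_half_up,
    sample_size_correlation,
)

finite_floats = st.floats(0.1, 100.0, allow_nan=False)


def test_round_half_up_convention():
    assert round_half_up(0.125, 2) == 0.13  # built-in round would give 0.12
    assert round_half_up(1.005, 2) == 1.01
    assert round_half_up(-0.125, 2) == -0.13


class TestReplicateStats:
    @pytest.mark.parametrize(
        "values, mean, sd, cv",
        [
            ((8.9, 9.2, 8.79), 8.96, 0.21, 1.93),
            ((5.77, 7.57, 6.51), 6.62, 0.90, 11.16),
        ],
    )
    def test_published_rows(self, values, mean, sd, cv):
        out = replicate_stats(values)
        assert out == {"mean": mean, "sd_sample": sd, "cv_percent": cv}

    def test_constant_replicates(self):
        out = replicate_stats((4.2, 4.2, 4.2))
        assert out["sd_sample"] == 0.0 and out["cv_percent"] == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            replicate_stats((-1.0, 1.0))
        with pytest.raises(ValueError):
            replicate_stats((3.0,))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(finite_floats, min_size=2, max_size=8),
           st.floats(0.01, 1000.0))
    def test_cv_scale_invariance(self, values, scale):
        base = replicate_stats(values, ndigits=None)
        scaled = replicate_stats([scale * v for v in values], ndigits=None)
        assert scaled["cv_percent"] == pytest.approx(base["cv_percent"],
                                                     rel=1e-9, abs=1e-9)

    def test_table_stats_shape_and_mean_bounds(self):
        table = multi_image_replicates()
        frame = replicate_table_stats(table, ndigits=None)
        assert len(frame) == 8
        assert np.all(frame["mean"] >= table.min(axis=1))
        assert np.all(frame["mean"] <= table.max(axis=1))


class TestAggregateCV:
    def test_published_cohort_summary(self):
        cvs = repeat_run_summary()["cv_percent"].to_numpy()
        out = aggregate_cv(cvs)
        assert round_half_up(out["summary"]) == 1.52
        assert round_half_up(out["sd_of_cvs"]) == 1.65

    def test_single_element_both_methods(self):
        for method in ("arithmetic", "rms"):
            out = aggregate_cv([3.7], method=method)
            assert out["summary"] == pytest.approx(3.7)

    def test_equal_cvs_arithmetic_equals_rms(self):
        out = aggregate_cv([2.5, 2.5, 2.5])
        assert out["arithmetic_mean"] == pytest.approx(out["rms"])

    def test_rms_exceeds_mean_for_spread_values(self):
        out = aggregate_cv([1.0, 5.0], method="rms")
        assert out["rms"] > out["arithmetic_mean"]


def _oracle_icc_a1(matrix):
    """Independent variance-components oracle from explicit sums of squares."""
    x = np.asarray(matrix, float)
    n, k = x.shape
    grand = x.mean()
    ssr = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ssc = n * ((x.mean(axis=0) - grand) ** 2).sum()
    sse = ((x - grand) ** 2).sum() - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        base = np.array([[1.0], [5.0], [9.0], [2.0]])
        res = icc(np.hstack([base, base, base]))
        assert res.estimate == 1.0
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_published_repeat_run_table(self):
        res = icc(repeat_run_replicates())
        assert res.estimate >= 0.99
        assert round_half_up(res.estimate) == 1.00
        assert res.p_value < 0.001
        assert res.ci_low >= 0.98

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.normal(5.0, 2.0, size=(4, 3))
        res = icc(matrix)
        assert res.estimate == pytest.approx(_oracle_icc_a1(matrix), abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        matrix = multi_image_replicates()
        frame = (pd.DataFrame(matrix, columns=["a", "b", "c"])
                 .reset_index(names="subject")
                 .melt(id_vars="subject", var_name="rater", value_name="y"))
        ref = pg.intraclass_corr(frame, targets="subject", raters="rater",
                                 ratings="y").set_index("Type")
        mine = icc(matrix)
        assert mine.estimate == pytest.approx(ref.loc["ICC(A,1)", "ICC"],
                                              abs=1e-10)
        assert mine.p_value == pytest.approx(ref.loc["ICC(A,1)", "pval"],
                                             rel=1e-6)
        cons = icc(matrix, model="consistency")
        assert cons.estimate == pytest.approx(ref.loc["ICC(C,1)", "ICC"],
                                              abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0), st.floats(-50, 50))
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        matrix = rng.normal(5.0, 2.0, size=(5, 3))
        r1 = icc(matrix)
        r2 = icc(a * matrix + b)
        assert r2.estimate == pytest.approx(r1.estimate, rel=1e-8, abs=1e-8)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc(np.full((4, 3), 2.0))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, 2.0]]))

    def test_anova_mean_squares_decomposition(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 4))
        msr, msc, mse, n, k = anova_mean_squares(x)
        ss_total = ((x - x.mean()) ** 2).sum()
        assert (msr * (n - 1) + msc * (k - 1) + mse * (n - 1) * (k - 1)
                == pytest.approx(ss_total))


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.band == "very high" and res.sign == "positive"

    def test_hand_computed_three_points(self):
        # product-moment formula evaluated by hand on (1,2,4) vs (2,1,5)
        res = pearson([1.0, 2.0, 4.0], [2.0, 1.0, 5.0])
        assert res.r == pytest.approx(0.8386278693775348, abs=1e-12)
        assert res.p_value == pytest.approx(0.366716573320923, abs=1e-9)

    @pytest.mark.parametrize(
        "r, band",
        [(0.81, "very high"), (-0.77, "very high"), (0.71, "very high"),
         (0.7, "high"), (0.59, "high"), (0.5, "high"), (0.49, "medium"),
         (0.3, "medium"), (0.29, "low"), (0.1, "low"), (0.05, "none"),
         (-0.05, "none")],
    )
    def test_interpretation_bands(self, r, band):
        assert interpret_r(r) == band

    def test_interpret_r_domain(self):
        with pytest.raises(ValueError):
            interpret_r(1.2)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 20))
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r)
        assert pearson(3 * x + 2, y).r == pytest.approx(pearson(x, y).r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_identical_inputs(self):
        out = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out == {"t": 0.0, "p": 1.0}

    def test_hand_computed_three_pairs(self):
        # t = mean(d) / (sd(d)/sqrt(n)) on d = (-0.5, 0, 0.1)
        out = paired_t_test([1.0, 2.0, 3.0], [1.5, 2.0, 2.9])
        assert out["t"] == pytest.approx(-0.7184212081070993, abs=1e-12)
        assert out["p"] == pytest.approx(0.5470891863421619, abs=1e-9)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 3.5], [1.5, 2.0, 2.9]
        fwd, rev = paired_t_test(a, b), paired_t_test(b, a)
        assert fwd["t"] == pytest.approx(-rev["t"])
        assert fwd["p"] == pytest.approx(rev["p"])

    def test_constant_nonzero_shift_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestKSNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(123)
        out = ks_normality(rng.normal(size=200))
        assert out["p"] > 0.05
        assert 0.0 <= out["statistic"] <= 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        shuffled = x.copy()
        rng.shuffle(shuffled)
        assert ks_normality(x) == ks_normality(shuffled)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([2.0, 2.0, 2.0])


class TestECV:
    def test_no_myocardial_change_gives_zero(self):
        assert ecv_fraction(0.42, 1114, 1114, 1600, 300) == 0.0

    def test_direct_formula_evaluation(self):
        # (1-0.42) * [(1/500 - 1/1114) / (1/300 - 1/1600)] * 100
        assert ecv_fraction(0.42, 1114, 500, 1600, 300) == pytest.approx(
            23.606905123601717, abs=1e-9)

    def test_linear_in_plasma_fraction(self):
        e1 = ecv_fraction(0.40, 1114, 500, 1600, 300)
        e2 = ecv_fraction(0.70, 1114, 500, 1600, 300)
        assert e2 / e1 == pytest.approx(0.30 / 0.60)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ecv_fraction(1.2, 1114, 500, 1600, 300)
        with pytest.raises(ValueError):
            ecv_fraction(0.42, 1114, 500, 1600, 1600)
        with pytest.raises(ValueError):
            ecv_fraction(0.42, -5, 500, 1600, 300)


class TestSampleSize:
    def test_reference_design_point(self):
        assert sample_size_correlation(0.35, alpha=0.05, power=0.80) == 62

    def test_monotone_in_effect_size(self):
        sizes = [sample_size_correlation(r) for r in (0.2, 0.35, 0.5, 0.8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_limit_large_r(self):
        assert sample_size_correlation(0.999999) == 4

    def test_invalid_r_rejected(self):
        for bad in (0.0, 1.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                sample_size_correlation(bad)


def test_read_replicate_csv_with_and_without_labels(tmp_path):
    p1 = tmp_path / "bare.csv"
    p1.write_text("r1,r2,r3\n8.9,9.2,8.79\n5.77,7.57,6.51\n")
    m1 = read_replicate_csv(p1)
    assert m1.shape == (2, 3)
    p2 = tmp_path / "labelled.csv"
    p2.write_text("patient,r1,r2,r3\nP1,8.9,9.2,8.79\nP2,5.77,7.57,6.51\n")
    assert np.array_equal(read_replicate_csv(p2), m1)


def test_dataset_tables_are_consistent():
    assert multi_image_replicates().shape == (8, 3)
    assert repeat_run_replicates().shape == (8, 3)
    assert len(multi_image_summary()) == len(repeat_run_summary()) == 8
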