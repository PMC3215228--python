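"""Cohort statistics: summaries, sex comparisons, correlations, variability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from menmorph.cohort import cohort_config, sample_cohort
from menmorph.segio import ValidationError
from menmorph.stats import (build_comparison_table, comparison_to_frame,
                            correlation_matrix, format_comparison_table,
                            format_p, group_summary, pearson_correlation,
                            percent_difference, t_test_from_summary,
                            unpaired_t_test, variability_comparison)


def two_values(mean, sd):
    """Smallest sample with exactly the given mean and sample SD."""
    d = sd / math.sqrt(2)
    return [mean - d, mean + d]


class TestGroupSummary:
    @pytest.mark.parametrize("mean,sd,cv_int", [
        (1774, 276, 16),        # absolute meniscus surface area, men medial
        (1.52, 0.161, 11),      # normalized size ratio, men medial
        (1480, 178, 12),        # women medial
        (1.56, 0.143, 9),
        (1848, 260, 14),        # men lateral
        (1.68, 0.201, 12),
        (1463, 174, 12),        # women lateral
        (1.70, 0.134, 8),
    ])
    def test_cv_reproduces_published_integers(self, mean, sd, cv_int):
        g = group_summary(two_values(mean, sd))
        assert round(g.cv_percent) == cv_int
        assert g.sd == pytest.approx(sd, rel=1e-9)

    def test_constant_vector(self):
        g = group_summary([5.0, 5.0, 5.0])
        assert g.sd == 0.0 and g.cv_percent == 0.0

    def test_zero_mean_flagged(self):
        g = group_summary([-1.0, 1.0])
        assert not g.cv_defined and math.isnan(g.cv_percent)

    def test_needs_two_values(self):
        with pytest.raises(ValidationError):
            group_summary([1.0])


class TestPercentDifference:
    def test_published_total_area_row(self):
        assert percent_difference(1774, 1480) == pytest.approx(19.9, abs=0.05)

    def test_published_negative_row_with_rounded_inputs(self):
        # printed -18.2 was computed from unrounded means; from the rounded
        # means the value is -18.0
        assert percent_difference(10.0, 12.2) == pytest.approx(-18.03, abs=0.01)

    def test_equal_means(self):
        assert percent_difference(7.0, 7.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            percent_difference(1.0, 0.0)


class TestTTests:
    def test_identical_groups(self):
        g = np.arange(10.0)
        t, df, p = unpaired_t_test(g, g)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)
        assert df == 18

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        t1, _, p1 = unpaired_t_test(a, b)
        t2, _, p2 = unpaired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_summary_matches_raw(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1.2, 18)
        for variant in ("pooled", "welch"):
            t1, df1, p1 = unpaired_t_test(a, b, variant)
            t2, df2, p2 = t_test_from_summary(a.mean(), a.std(ddof=1), 15,
                                              b.mean(), b.std(ddof=1), 18, variant)
            assert t1 == pytest.approx(t2)
            assert df1 == pytest.approx(df2)
            assert p1 == pytest.approx(p2)

    def test_published_medial_extrusion_row(self):
        """Mean medial extrusion 1.24 +/- 1.18 (40 men) vs 1.83 +/- 1.06
        (62 women): pooled two-tailed p ~= 0.010, printed as 0.011."""
        _, df, p = t_test_from_summary(1.24, 1.18, 40, 1.83, 1.06, 62)
        assert df == 100
        assert 0.008 <= p <= 0.013

    def test_published_plateau_area_row(self):
        _, _, p = t_test_from_summary(1169, 122, 40, 952, 85.7, 62)
        assert p < 0.001

    def test_equal_means_p_one(self):
        _, _, p = t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert p == pytest.approx(1.0)

    def test_p_monotone_in_mean_difference(self):
        ps = [t_test_from_summary(d, 1.0, 20, 0.0, 1.0, 20)[2]
              for d in (0.1, 0.3, 0.6, 1.0, 1.5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_unknown_variant(self):
        with pytest.raises(ValidationError):
            unpaired_t_test([1, 2, 3], [1, 2, 3], "bootstrap")


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_correlation(x, -3 * x + 5).r == pytest.approx(-1.0)

    def test_constant_flagged(self):
        c = pearson_correlation(np.ones(5), np.arange(5.0))
        assert not c.defined and c.band == "undefined"

    @settings(max_examples=40, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0 = pearson_correlation(x, y).r
        assert pearson_correlation(a * x + b, y).r == pytest.approx(r0, abs=1e-9)
        assert pearson_correlation(-a * x + b, y).r == pytest.approx(-r0, abs=1e-9)

    def test_significance_bands(self):
        x = np.arange(50.0)
        strong = pearson_correlation(x, x + np.random.default_rng(2).normal(0, 1, 50))
        assert strong.band == "**"


class TestCorrelationMatrix:
    def test_two_variables_single_cell(self):
        df = sample_cohort(cohort_config("medial", seed=0))
        cells = correlation_matrix(df, ["V", "TOT_A"])
        men = cells["M"][("V", "TOT_A")]
        ref = pearson_correlation(df[df.sex == "M"].V, df[df.sex == "M"].TOT_A)
        assert men.r == pytest.approx(ref.r)
        assert men.n == 40

    def test_constant_variable_flagged(self):
        df = sample_cohort(cohort_config("medial", seed=0))
        df["const"] = 1.0
        cells = correlation_matrix(df, ["V", "const"])
        assert not cells["M"][("V", "const")].defined

    def test_phantom_derived_cohort_size_coupling(self):
        """Scaled copies of one shape: volume and total area co-vary strongly,
        mirroring the published .97/.96 volume-area correlations."""
        from menmorph.phantom import analytic_morphometry, preset_params

        import pandas as pd

        base = preset_params("F", "medial")
        rng = np.random.default_rng(3)
        rows = []
        for s in rng.normal(1.0, 0.08, 60):
            gt = analytic_morphometry(base.scaled(abs(s)))
            rows.append({"sex": "F", "V": gt.V, "TOT_A": gt.TOT_A})
        df = pd.DataFrame(rows)
        r = correlation_matrix(df, ["V", "TOT_A"])["F"][("V", "TOT_A")].r
        assert r > 0.9


class TestComparisonTable:
    def test_single_measure_row(self):
        df = sample_cohort(cohort_config("medial", seed=1))
        rows = build_comparison_table(df, ["TOT_A"])
        assert len(rows) == 1
        row = rows[0]
        assert row.men.n == 40 and row.women.n == 62
        assert row.diff_percent == pytest.approx(
            percent_difference(row.men.mean, row.women.mean))
        frame = comparison_to_frame(rows)
        assert {"men_mean", "women_sd", "diff_pct", "p"} <= set(frame.columns)

    def test_empty_cohort_rejected(self):
        import pandas as pd

        with pytest.raises(ValidationError):
            build_comparison_table(pd.DataFrame(), ["TOT_A"])

    def test_formatting_floor_and_idempotence(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.221) == "0.221"
        df = sample_cohort(cohort_config("medial", seed=1))
        text = format_comparison_table(build_comparison_table(df, ["TOT_A", "Ex_Me"]))
        assert text == format_comparison_table(build_comparison_table(df, ["TOT_A", "Ex_Me"]))
        assert "TOT_A" in text


class TestVariability:
    def test_exact_proportionality_gives_zero_ratio_cv(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        ac = rng.normal(1000, 100, 50)
        df = pd.DataFrame({"sex": "M", "ACdAB": ac, "TOT_A": 1.5 * ac,
                           "TOTA_over_ACdAB": 1.5})
        rep = variability_comparison(df)
        assert rep["M"]["cv_ratio_pct"] == pytest.approx(0.0, abs=1e-9)
        assert rep["M"]["normalization_reduces_cv"]

    def test_calibrated_cohort_normalization_reduces_cv(self):
        df = sample_cohort(cohort_config("medial", seed=12))
        rep = variability_comparison(df)
        for sex in ("M", "F"):
            assert rep[sex]["normalization_reduces_cv"], sex

    def test_uncorrelated_control_reported_not_asserted(self):
        cfg = cohort_config("medial", seed=2)
        for s in ("M", "F"):
            cfg.corr[s] = {}        # no size coupling
        df = sample_cohort(cfg)
        rep = variability_comparison(df)
        assert set(rep) == {"F", "M"}
        for sex in ("M", "F"):
            assert isinstance(rep[sex]["normalization_reduces_cv"], bool)
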