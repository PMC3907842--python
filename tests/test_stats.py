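"""Normalization and the exact tag-count test."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mirtally._util import MirtallyError
from mirtally.stats import (
    NormalizationError,
    audic_claverie_p,
    call_de,
    classify_call,
    size_factors,
)

from oracles import ac_two_sided_exact, ac_upper_tail_exact, median_of_ratios


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        df = pd.DataFrame({"count_ck": [3, 50, 700], "count_tr": [3, 50, 700]})
        sf = size_factors(df)
        assert sf.s_ck == pytest.approx(1.0)
        assert sf.s_tr == pytest.approx(1.0)
        assert sf.n_tags_used == 3

    def test_uniform_doubling_doubles_one_factor(self):
        df = pd.DataFrame({"count_ck": [10, 40, 90], "count_tr": [20, 80, 180]})
        sf = size_factors(df)
        assert sf.s_tr / sf.s_ck == pytest.approx(2.0)

    def test_hand_computed_three_tag_table(self):
        # g = (sqrt(200), sqrt(5000), 2000); medians worked out by hand
        df = pd.DataFrame({"count_ck": [10, 100, 1000], "count_tr": [20, 50, 4000]})
        sf = size_factors(df)
        assert sf.s_ck == pytest.approx(1 / math.sqrt(2))
        assert sf.s_tr == pytest.approx(math.sqrt(2))
        s1, s2 = median_of_ratios([(10, 20), (100, 50), (1000, 4000)])
        assert sf.s_ck == pytest.approx(s1) and sf.s_tr == pytest.approx(s2)

    def test_zero_containing_tags_excluded(self):
        df = pd.DataFrame({"count_ck": [10, 0, 30], "count_tr": [10, 99, 30]})
        assert size_factors(df).n_tags_used == 2

    def test_all_zero_rows_raise_normalization_error(self):
        df = pd.DataFrame({"count_ck": [0, 5], "count_tr": [9, 0]})
        with pytest.raises(NormalizationError):
            size_factors(df)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(1, 1000), st.integers(1, 1000)),
            min_size=1,
            max_size=20,
        ),
        st.floats(0.1, 10.0),
    )
    def test_scale_equivariance_of_factor_ratio(self, counts, c):
        """Scaling one library scales the between-library factor ratio by c
        (factors themselves are defined only up to a common scalar)."""
        df = pd.DataFrame(counts, columns=["count_ck", "count_tr"])
        base = size_factors(df)
        scaled = size_factors(df.assign(count_tr=df.count_tr * c))
        assert scaled.s_tr / scaled.s_ck == pytest.approx(
            c * base.s_tr / base.s_ck, rel=1e-9
        )


class TestAudicClaverie:
    def test_closed_form_at_zero_counts(self):
        # p(0|0) = 1/2 per outcome; doubling the half tail gives 1
        assert audic_claverie_p(0, 0, 1000, 1000) == pytest.approx(1.0)

    def test_exchangeable_under_library_swap(self):
        for x, y, n1, n2 in [(3, 9, 100, 200), (50, 5, 1e6, 2e6), (0, 7, 500, 500)]:
            assert audic_claverie_p(x, y, n1, n2) == pytest.approx(
                audic_claverie_p(y, x, n2, n1), rel=1e-12
            )

    def test_matches_exact_rational_oracle_spot_checks(self):
        for x, y, n1, n2 in [(5, 25, 10**6, 10**6), (0, 40, 1000, 2000), (33, 21, 777, 500)]:
            exact = float(ac_two_sided_exact(x, y, n1, n2))
            assert audic_claverie_p(x, y, n1, n2) == pytest.approx(exact, rel=1e-10)

    def test_upper_tail_summation_matches_exact_complement(self):
        for x, y in [(5, 25), (40, 10), (0, 0)]:
            exact = float(ac_upper_tail_exact(y, x, 1000, 3000))
            got = audic_claverie_p(x, y, 1000, 3000, sided="upper")
            assert got == pytest.approx(exact, rel=1e-10)

    def test_per_outcome_probability_is_negative_binomial(self):
        # independent route: the per-outcome law is NB(x+1, N1/(N1+N2))
        x, n1, n2 = 12, 1500, 4500
        lower = audic_claverie_p(x, 30, n1, n2, sided="lower")
        assert lower == pytest.approx(sps.nbinom.cdf(30, x + 1, n1 / (n1 + n2)), rel=1e-12)

    def test_large_counts_remain_finite(self):
        p = audic_claverie_p(10**6, 10**6 + 1000, 10**7, 10**7)
        assert 0.0 <= p <= 1.0 and np.isfinite(p)

    def test_domain_errors(self):
        with pytest.raises(MirtallyError):
            audic_claverie_p(-1, 0, 10, 10)
        with pytest.raises(MirtallyError):
            audic_claverie_p(0, 0, 0, 10)


class TestCalling:
    def test_strict_thresholds(self):
        assert classify_call(-1.18, 2.72e-52) == "down"
        assert classify_call(0.99, 1e-10) == "none"  # fails strict lfc cut
        assert classify_call(1.01, 0.05) == "none"  # fails strict alpha
        assert classify_call(1.91, 1.04e-43) == "up"

    def test_call_de_applies_length_and_abundance_filters(self):
        from mirtally.stats import SizeFactors

        profiles = pd.DataFrame(
            {
                "name": ["short", "low", "kept"],
                "sequence": ["A" * 17, "C" * 21, "G" * 21],
                "count_ck": [500, 10, 400],
                "count_tr": [500, 8, 100],
            }
        )
        de = call_de(profiles, SizeFactors(1.0, 1.0, 3), 10000, 10000)
        assert list(de.name) == ["kept"]
        assert de.call.iloc[0] == "down"

    def test_zero_count_side_gets_pseudocount_for_reporting_only(self):
        from mirtally.stats import SizeFactors

        profiles = pd.DataFrame(
            {"name": ["m"], "sequence": ["A" * 21], "count_ck": [64], "count_tr": [0]}
        )
        de = call_de(profiles, SizeFactors(1.0, 1.0, 1), 10000, 10000)
        assert de.log2fc.iloc[0] == pytest.approx(math.log2(0.5 / 64))
        # the p-value uses the raw zero, not the pseudo-count
        assert de.pvalue.iloc[0] == pytest.approx(
            audic_claverie_p(64, 0, 10000, 10000)
        )

    def test_scale_invariance_of_calls(self):
        """Scaling one library's counts changes its size factor, not the calls."""
        from mirtally.stats import SizeFactors

        rng = np.random.default_rng(11)
        n = 30
        base = rng.integers(20, 2000, size=n)
        profiles = pd.DataFrame(
            {
                "name": [f"m{i:02d}" for i in range(n)],
                "sequence": ["A" * 21] * n,
                "count_ck": base,
                "count_tr": (base * rng.choice([1.0, 1.0, 4.0], size=n)).astype(int),
            }
        )
        sf1 = size_factors(profiles)
        de1 = call_de(profiles, sf1, 10**5, 10**5)
        scaled = profiles.assign(count_tr=profiles.count_tr * 3)
        sf2 = size_factors(scaled)
        assert sf2.s_tr / sf2.s_ck == pytest.approx(3 * sf1.s_tr / sf1.s_ck, rel=1e-9)
        de2 = call_de(scaled, sf2, 10**5, 3 * 10**5)
        np.testing.assert_allclose(de1.log2fc, de2.log2fc, rtol=1e-9)
        assert list(de1.call) == list(de2.call)
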