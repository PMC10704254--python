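import math
import warnings
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lscikit import (
    CorrelationTruncationWarning,
    WindowSpec,
    beta_uncorrected,
    coefficient_table,
    contrast_curve,
    correlation_factor,
    outsider_count,
    pair_multiplicities,
    spatial_contrast,
    spatial_contrast_sq,
    window_statistics_oracle,
)

M_REF = 0.0338


def enumerate_pairs(L: int, p: int):
    """Brute-force classification of all L^4 ordered pixel pairs by offset."""
    counts = {"central": 0, "lateral": {}, "diagonal": {}, "knight": {}, "outsiders": 0}
    for r1 in range(L):
        for c1 in range(L):
            for r2 in range(L):
                for c2 in range(L):
                    de, dx = abs(r1 - r2), abs(c1 - c2)
                    eta, xi = max(de, dx), min(de, dx)
                    if eta > p:
                        counts["outsiders"] += 1
                    elif eta == 0:
                        counts["central"] += 1
                    elif xi == 0:
                        counts["lateral"][eta] = counts["lateral"].get(eta, 0) + 1
                    elif xi == eta:
                        counts["diagonal"][eta] = counts["diagonal"].get(eta, 0) + 1
                    else:
                        counts["knight"][(eta, xi)] = counts["knight"].get((eta, xi), 0) + 1
    return counts


class TestWindowSpec:
    def test_even_side_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(side=4, p=1)

    def test_oversized_subregion_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(side=3, p=2)

    def test_full_default(self):
        assert WindowSpec.full(7) == WindowSpec(side=7, p=3)


class TestPairMultiplicities:
    @pytest.mark.parametrize(
        "L,p", [(1, 0), (3, 0), (3, 1), (5, 1), (5, 2), (7, 2), (7, 3), (9, 4)]
    )
    def test_exact_against_enumeration(self, L, p):
        t = pair_multiplicities(WindowSpec(L, p))
        ref = enumerate_pairs(L, p)
        assert t.central == ref["central"]
        assert t.lateral == ref["lateral"]
        assert t.diagonal == ref["diagonal"]
        assert t.knight == ref["knight"]
        assert t.outsiders == ref["outsiders"]

    def test_example_3_1(self):
        t = pair_multiplicities(WindowSpec(3, 1))
        assert (t.central, t.lateral[1], t.diagonal[1], t.knight, t.outsiders) == (
            9, 24, 16, {}, 32,
        )

    def test_example_5_2(self):
        t = pair_multiplicities(WindowSpec(5, 2))
        assert t.total - t.outsiders == 361
        assert t.outsiders == 264

    def test_p0_only_self_pairs(self):
        for L in (3, 5, 7):
            t = pair_multiplicities(WindowSpec(L, 0))
            assert t.central == L * L
            assert t.outsiders == L**4 - L * L

    @given(st.sampled_from([(3, 1), (5, 2), (7, 1), (7, 3), (9, 2), (9, 4)]))
    @settings(max_examples=10, deadline=None)
    def test_total_is_L4(self, lp):
        L, p = lp
        assert pair_multiplicities(WindowSpec(L, p)).total == L**4


class TestOutsiderCount:
    @pytest.mark.parametrize("L,p", [(3, 1), (5, 1), (5, 2), (7, 3), (9, 0), (9, 4)])
    def test_closed_form_matches_enumeration(self, L, p):
        assert outsider_count(WindowSpec(L, p)) == enumerate_pairs(L, p)["outsiders"]

    def test_examples(self):
        assert outsider_count(WindowSpec(3, 1)) == 32
        assert outsider_count(WindowSpec(7, 3)) == 2401 - (7 * 7 - 12) ** 2
        assert outsider_count(WindowSpec(7, 3)) == 1032


class TestCoefficientTable:
    def test_table_row_3_1(self):
        assert coefficient_table(WindowSpec(3, 1)) == {
            (1, 0): Fraction(-1, 3),
            (1, 1): Fraction(-2, 9),
        }

    def test_table_row_5_2(self):
        assert coefficient_table(WindowSpec(5, 2)) == {
            (1, 0): Fraction(-2, 15),
            (2, 0): Fraction(-1, 10),
            (1, 1): Fraction(-8, 75),
            (2, 2): Fraction(-3, 50),
            (2, 1): Fraction(-4, 25),
        }

    def test_table_row_7_3(self):
        t = coefficient_table(WindowSpec(7, 3))
        assert t[(1, 0)] == Fraction(-1, 14)
        assert t[(2, 0)] == Fraction(-5, 84)
        assert t[(3, 0)] == Fraction(-1, 21)
        assert t[(1, 1)] == Fraction(-3, 49)
        assert t[(2, 2)] == Fraction(-25, 588)
        assert t[(3, 3)] == Fraction(-4, 147)
        assert t[(2, 1)] == Fraction(-5, 49)
        assert t[(3, 1)] == Fraction(-4, 49)
        assert t[(3, 2)] == Fraction(-10, 147)

    def test_p0_empty(self):
        assert coefficient_table(WindowSpec(5, 0)) == {}

    def test_coefficients_sum_with_central_weight(self):
        # sum of all pair weights (central + classes) equals 1/(L^2-1) * ...
        # sanity: subtracted mass is bounded by 1
        for L, p in [(3, 1), (5, 2), (7, 3), (9, 4)]:
            total = -sum(coefficient_table(WindowSpec(L, p)).values())
            assert 0 < total < 1


class TestSpatialContrast:
    def test_reference_correction_factors(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CorrelationTruncationWarning)
            assert spatial_contrast(WindowSpec(1, 0), M_REF) == pytest.approx(0.9827, abs=1e-4)
            assert spatial_contrast(WindowSpec(3, 1), M_REF) == pytest.approx(0.7073, abs=1e-4)
            assert spatial_contrast(WindowSpec(7, 3), M_REF) == pytest.approx(0.8198, abs=1e-4)

    def test_sq_value_3_1(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CorrelationTruncationWarning)
            assert spatial_contrast_sq(WindowSpec(3, 1), M_REF) == pytest.approx(0.5003, abs=2e-4)

    def test_p0_equals_central_factor(self):
        for L in (1, 3, 7):
            for m in (0.05, 1.0, 4.0):
                assert spatial_contrast_sq(WindowSpec(L, 0), m) == pytest.approx(
                    correlation_factor(0, 0, m), rel=1e-14
                )

    def test_full_correlation_limit_of_model(self):
        # With all factors -> 1 the model tends to 1 - (C - L^2)/(L^2 (L^2-1))
        # where C = (L(2p+1) - p(p+1))^2 is the number of correlated ordered
        # pairs: outsider pairs keep the limit strictly positive.  (The naive
        # expectation "whole window is one speckle => K -> 0" holds only for
        # the untruncated pair enumeration, tested below.)
        for L in (3, 5, 7):
            w = WindowSpec.full(L)
            C = (L * (2 * w.p + 1) - w.p * (w.p + 1)) ** 2
            limit = 1.0 - (C - L * L) / (L * L * (L * L - 1))
            assert spatial_contrast_sq(w, 1e-8) == pytest.approx(limit, abs=1e-6)

    def test_vanishing_limit_untruncated_expectation(self):
        for L in (3, 5, 7):
            full = window_statistics_oracle(WindowSpec.full(L), 1e-8, truncate_outsiders=False)
            assert math.sqrt(max(full, 0.0)) <= 1e-3

    def test_upper_bound_beta(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CorrelationTruncationWarning)
            for L, p in [(3, 1), (5, 2), (7, 3), (9, 4), (5, 0)]:
                for m in (0.0338, 0.3, 1.0, 5.0):
                    assert spatial_contrast(WindowSpec(L, p), m) <= beta_uncorrected(m) + 1e-12

    def test_ordering_at_small_M(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CorrelationTruncationWarning)
            k3 = spatial_contrast(WindowSpec(3, 1), M_REF)
            k7 = spatial_contrast(WindowSpec(7, 3), M_REF)
        assert k3 < k7

    def test_truncation_warning_emitted(self):
        with pytest.warns(CorrelationTruncationWarning):
            spatial_contrast_sq(WindowSpec(7, 1), 0.05)

    def test_no_warning_when_subregion_fills_window(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error", CorrelationTruncationWarning)
            spatial_contrast_sq(WindowSpec(3, 1), 0.05)


class TestBetaUncorrected:
    def test_reference_value(self):
        assert beta_uncorrected(M_REF) == pytest.approx(0.9827, abs=5e-5)

    def test_limit_to_one(self):
        assert beta_uncorrected(1e-8) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_decreasing(self):
        grid = np.geomspace(1e-3, 100, 80)
        vals = [beta_uncorrected(m) for m in grid]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("L,p", [(3, 1), (5, 1), (5, 2), (7, 2), (7, 3), (9, 4)])
    @pytest.mark.parametrize("m", [0.0338, 0.1, 0.5, 1.0, 2.0, 5.0])
    def test_model_matches_pair_enumeration(self, L, p, m):
        w = WindowSpec(L, p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CorrelationTruncationWarning)
            model = spatial_contrast_sq(w, m)
        oracle = window_statistics_oracle(w, m)
        assert model == pytest.approx(oracle, rel=1e-12)

    def test_oracle_p0(self):
        for L in (3, 5):
            assert window_statistics_oracle(WindowSpec(L, 0), 0.7) == pytest.approx(
                correlation_factor(0, 0, 0.7), rel=1e-12
            )

    def test_oracle_refuses_large_side(self):
        with pytest.raises(ValueError):
            window_statistics_oracle(WindowSpec(11, 1), 0.5)

    def test_untruncated_oracle_below_model_at_small_M(self):
        # keeping the outsider correlations lowers the expected contrast
        w = WindowSpec(3, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CorrelationTruncationWarning)
            model = spatial_contrast_sq(w, 0.03)
        full = window_statistics_oracle(w, 0.03, truncate_outsiders=False)
        assert full < model


class TestContrastCurve:
    def test_interior_maximum_3_1(self):
        grid = np.geomspace(0.01, 10, 120)
        cc = contrast_curve(WindowSpec(3, 1), grid)
        i = int(np.argmax(cc.K_values))
        assert 0 < i < len(grid) - 1
        # single interior maximum: rises before, falls after
        assert np.all(np.diff(cc.K_values[: i + 1]) >= -1e-12)
        assert np.all(np.diff(cc.K_values[i:]) <= 1e-12)

    def test_p0_monotone_decreasing(self):
        grid = np.geomspace(0.01, 10, 60)
        cc = contrast_curve(WindowSpec(5, 0), grid)
        assert np.all(np.diff(cc.K_values) <= 1e-14)

    def test_curves_converge_at_large_M_diverge_at_small(self):
        # G_1(M) decays only like 1/(2 pi M), so "overlap when M >= 1" is a
        # plot-scale statement: 2% relative at M=5, sub-percent at M=50.
        for w in (WindowSpec(3, 1), WindowSpec(7, 3)):
            cc = contrast_curve(w, [M_REF, 5.0, 50.0])
            assert cc.K_values[1] == pytest.approx(beta_uncorrected(5.0), rel=0.02)
            assert cc.K_values[2] == pytest.approx(beta_uncorrected(50.0), rel=0.005)
            assert abs(cc.K_values[0] - beta_uncorrected(M_REF)) > 0.1

    def test_k_in_unit_interval(self):
        cc = contrast_curve(WindowSpec(5, 2), np.geomspace(1e-3, 50, 40))
        assert np.all(cc.K_values >= 0) and np.all(cc.K_values <= 1)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            contrast_curve(WindowSpec(3, 1), [])
        with pytest.raises(ValueError):
            contrast_curve(WindowSpec(3, 1), [1.0, 0.5])

    def test_csv_export(self, tmp_path):
        cc = contrast_curve(WindowSpec(3, 1), [0.1, 1.0])
        out = tmp_path / "curve.csv"
        cc.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "M,K,K_sq"
        assert len(lines) == 3
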