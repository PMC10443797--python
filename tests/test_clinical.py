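"""Clinical change metrics, correlation statistics and descending overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import stats

from dmrescue.clinical import (
    DegenerateCorrelationError,
    average_1rm_change,
    build_clinical_table,
    correlate_rescue_with_clinical,
    grouped_descending_overlap,
    mdc,
    meaningful_change,
    partial_spearman,
    percent_change,
    semt,
    spearman,
)
from dmrescue.io_model import ClinicalRaw, ValidationError


class TestChangeMetrics:
    @pytest.mark.parametrize("pre,post,expected", [
        (100, 133, 33.0), (50, 50, 0.0), (50, 127, 154.0), (80, 40, -50.0),
    ])
    def test_percent_change(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected)

    def test_percent_change_zero_pre_undefined(self):
        with pytest.raises(ValidationError):
            percent_change(0, 10)

    @pytest.mark.parametrize("sd,icc,variant,expected", [
        (1.0, 0.75, "sqrt", 0.5),
        (1.0, 1.0, "sqrt", 0.0), (1.0, 1.0, "linear", 0.0),
        (2.5, 0.0, "sqrt", 2.5), (2.5, 0.0, "linear", 2.5),
        (2.0, 0.75, "linear", 0.5),
    ])
    def test_semt_both_variants(self, sd, icc, variant, expected):
        assert semt(sd, icc, variant) == pytest.approx(expected)

    def test_semt_icc_out_of_range(self):
        with pytest.raises(ValidationError):
            semt(1.0, 1.5)

    @pytest.mark.parametrize("s", [0.0, 0.41, 3.77, 1.0])
    def test_mdc_closed_form(self, s):
        assert mdc(s) == pytest.approx(1.96 * s * math.sqrt(2), rel=1e-15)

    def test_meaningful_change_strict_boundary(self):
        m = mdc(0.41)
        assert not meaningful_change(0.0, m, m)  # change exactly MDC: no
        assert not meaningful_change(10.0, 10.0, m)
        assert meaningful_change(0.0, m + 1e-9, m)
        assert meaningful_change(5.0, 5.1, 0.0)  # zero MDC, any change

    @pytest.mark.parametrize("vals,expected", [
        ((10, 20, 30, 40), 25.0), ((7, 7, 7, 7), 7.0), ((0, 0, 0, 100), 25.0),
    ])
    def test_average_1rm(self, vals, expected):
        changes = dict(zip(("leg_extension", "leg_press", "hip_abduction",
                            "squat"), vals))
        assert average_1rm_change(changes) == pytest.approx(expected)

    def test_average_1rm_missing_test_named(self):
        with pytest.raises(ValidationError, match="squat"):
            average_1rm_change({"leg_extension": 1, "leg_press": 2,
                                "hip_abduction": 3})


class TestClinicalTable:
    def _rows(self):
        return [ClinicalRaw(s, t, pre, pre * 1.2)
                for s, pre in (("p1", 10.0), ("p2", 12.0), ("p3", 15.0))
                for t, _ in (("squat", 0),)] + \
               [ClinicalRaw(s, "thirty_sec_sts", v, v + 3)
                for s, v in (("p1", 8.0), ("p2", 10.0), ("p3", 12.0))]

    def test_semt_uses_cohort_baseline_sd(self):
        table = build_clinical_table(self._rows(), {"thirty_sec_sts": 0.75})
        sts = table[table["test_name"] == "thirty_sec_sts"]
        sd = np.std([8.0, 10.0, 12.0], ddof=1)
        assert sts["semt"].iloc[0] == pytest.approx(sd * 0.5)
        assert sts["mdc"].iloc[0] == pytest.approx(1.96 * sd * 0.5 * math.sqrt(2))
        assert sts["meaningful"].all()  # change of 3 units exceeds MDC (~2.77)

    def test_tests_without_icc_have_no_mdc_screen(self):
        table = build_clinical_table(self._rows(), {"thirty_sec_sts": 0.75})
        squat = table[table["test_name"] == "squat"]
        assert squat["semt"].isna().all()
        assert squat["percent_change"].iloc[0] == pytest.approx(20.0)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [1, 2, 3]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_hand_value_four_points(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (0,1,1,0): 1 - 12/60 = 0.8
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8, abs=1e-15)

    def test_matches_scipy_including_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 6, 12).astype(float)  # ties likely
            y = rng.normal(size=12)
            if len(set(x)) < 2:
                continue
            res = spearman(x, y)
            ref_rho, ref_p = stats.spearmanr(x, y)
            assert res.rho == pytest.approx(ref_rho, abs=1e-12)
            assert res.p_value == pytest.approx(ref_p, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=15,
                    unique=True),
           st.lists(st.floats(-100, 100), min_size=15, max_size=15,
                    unique=True))
    def test_invariant_under_monotone_transform(self, x, y):
        y = y[:len(x)]
        transformed = np.exp(np.asarray(x) / 100)
        assume(len(set(transformed)) == len(x))  # no collapse to ties
        r1 = spearman(x, y).rho
        r2 = spearman(transformed, y).rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_exact_permutation_p(self):
        res = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4],
                       p_mode="permutation")
        # p is the exact share of permutations with |rho| >= observed
        assert 0 < res.p_value < 1
        ref = stats.spearmanr([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert res.rho == pytest.approx(ref.statistic)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])


def oracle_partial(x, y, z):
    """Recursion formula evaluated independently on scipy rank transforms."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = stats.rankdata(z)
    rxy = stats.pearsonr(rx, ry).statistic
    rxz = stats.pearsonr(rx, rz).statistic
    ryz = stats.pearsonr(ry, rz).statistic
    return (rxy - rxz * ryz) / math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))


class TestPartialSpearman:
    def test_independent_control_equals_plain_spearman(self):
        # z's ranks are exactly orthogonal to both x's and y's ranks, so the
        # partial correlation reduces to the plain Spearman correlation
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        y = [7.0, 4.0, 8.0, 1.0, 6.0, 5.0, 2.0, 3.0]
        z = [3.0, 5.0, 6.0, 4.0, 2.0, 8.0, 7.0, 1.0]
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        assert abs(stats.pearsonr(rx, rz).statistic) < 1e-12
        assert abs(stats.pearsonr(ry, rz).statistic) < 1e-12
        assert partial_spearman(x, y, z).rho == \
            pytest.approx(spearman(x, y).rho, abs=1e-12)

    def test_matches_recursion_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, y, z = rng.normal(size=(3, 8))
            assert partial_spearman(x, y, z).rho == \
                pytest.approx(oracle_partial(x, y, z), abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        x, y, z = rng.normal(size=(3, 12))
        res = partial_spearman(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            abs=1e-9)

    def test_self_correlation_is_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        z = [2.0, 7.0, 1.0, 8.0, 2.8]
        assert partial_spearman(x, x, z).rho == pytest.approx(1.0)

    def test_constant_shift_of_control_is_invariant(self):
        rng = np.random.default_rng(2)
        x, y, z = rng.normal(size=(3, 9))
        r1 = partial_spearman(x, y, z).rho
        r2 = partial_spearman(x, y, z + 100.0).rho
        assert r1 == pytest.approx(r2, abs=1e-15)

    def test_degenerate_control_rejected(self):
        x = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(DegenerateCorrelationError):
            partial_spearman(x, [4.0, 3.0, 2.0, 1.0], x)
        with pytest.raises(DegenerateCorrelationError):
            partial_spearman(x, [2.0, 1.0, 4.0, 3.0], [1.0, 1.0, 1.0, 1.0])


class TestCorrelateRescueWithClinical:
    def test_permuting_labels_destroys_link(self):
        subjects = [f"s{i}" for i in range(8)]
        pct = {s: 10.0 * i for i, s in enumerate(subjects)}
        gains = {s: 5.0 * i + 1 for i, s in enumerate(subjects)}
        res = correlate_rescue_with_clinical(pct, gains)
        assert res["spearman"].rho == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(50):
            perm = rng.permutation(list(gains.values()))
            shuffled = dict(zip(subjects, perm))
            rhos.append(correlate_rescue_with_clinical(pct, shuffled)
                        ["spearman"].rho)
        assert abs(np.mean(rhos)) < 0.2

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            correlate_rescue_with_clinical({"a": 1, "b": 2, "c": 3},
                                           {"a": 1, "b": 2, "c": 3})


class TestGroupedDescendingOverlap:
    def test_enumeration_example(self):
        sets = {"A": {"g1", "g2", "g3"}, "B": {"g2", "g3"}, "C": {"g4"}}
        out = grouped_descending_overlap(["A", "B", "C"], sets)
        assert out["steps"] == [{"g2", "g3"}, set()]
        assert out["terminal"] == {"g2", "g3"} and out["depth"] == 2

    def test_identical_sets_full_depth(self):
        sets = {s: {"x", "y"} for s in "ABC"}
        out = grouped_descending_overlap(["A", "B", "C"], sets)
        assert out["terminal"] == {"x", "y"} and out["depth"] == 3

    def test_disjoint_top_two(self):
        sets = {"A": {"a"}, "B": {"b"}}
        out = grouped_descending_overlap(["A", "B"], sets)
        assert out["terminal"] == {"a"} and out["depth"] == 1

    def test_empty_first_set(self):
        out = grouped_descending_overlap(["A", "B"], {"A": set(), "B": {"x"}})
        assert out["terminal"] == set() and out["depth"] == 0

    def test_steps_monotone_non_increasing(self):
        rng = np.random.default_rng(4)
        events = [f"g{i}" for i in range(30)]
        sets = {f"S{i}": {e for e in events if rng.random() < 0.5}
                for i in range(6)}
        out = grouped_descending_overlap(sorted(sets), sets)
        chain = out["steps"]
        for a, b in zip(chain, chain[1:]):
            assert b <= a
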