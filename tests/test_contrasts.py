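"""Contrast estimation, significance surrogate and threshold filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dmrescue.contrasts import (
    PRESETS,
    Thresholds,
    apply_support_filter,
    attach_significance,
    benjamini_hochberg,
    delta_log2fc,
    delta_psi_contrast,
    estimate_log2fc,
    estimate_psi,
    filter_low_counts,
    filter_significant,
    get_thresholds,
)
from dmrescue.io_model import ContrastTable, CountMatrix, PsiMatrix, ValidationError


def make_table(units, effects, p=None, fdr=None, label="t"):
    n = len(units)
    return ContrastTable(pd.DataFrame({
        "unit_id": units, "effect": effects,
        "p_value": p if p is not None else [np.nan] * n,
        "fdr": fdr if fdr is not None else [np.nan] * n,
        "contrast_label": label}))


class TestEstimatePsi:
    @pytest.mark.parametrize("inc,skp,li,ls,expected", [
        (10, 5, 2, 1, 0.5),     # length normalization: (10/2)/(10/2+5/1)
        (7, 0, 2, 1, 1.0),      # no skipping reads
        (0, 3, 2, 1, 0.0),      # no inclusion reads
        (3, 3, 1, 1, 0.5),
    ])
    def test_formula(self, inc, skp, li, ls, expected):
        assert estimate_psi(inc, skp, li, ls) == pytest.approx(expected)

    def test_no_reads_is_missing_not_zero(self):
        assert np.isnan(estimate_psi(0, 0, 2, 1))

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            estimate_psi(1, 1, 0, 1)
        with pytest.raises(ValidationError):
            estimate_psi(-1, 1, 1, 1)


class TestEstimateLog2fc:
    def _counts(self, a_gene, a_rest, b_gene, b_rest):
        df = pd.DataFrame({"a1": [a_gene, a_rest], "b1": [b_gene, b_rest]},
                          index=["g1", "filler"])
        return CountMatrix(df)

    def test_identical_groups_zero_effect(self):
        df = pd.DataFrame({"a": [10, 90], "b": [10, 90]}, index=["g1", "g2"])
        tbl = estimate_log2fc(CountMatrix(df), ["a"], ["b"])
        assert (tbl.table["effect"] == 0).all()

    def test_mean_cpm_ratio_40_vs_10(self):
        # gene at CPM 40 in group a, CPM 10 in group b; pseudocount 0 -> 2.0
        counts = self._counts(40, 999960, 10, 999990)
        tbl = estimate_log2fc(counts, ["a1"], ["b1"], pseudocount=0.0)
        assert tbl.effects()["g1"] == pytest.approx(2.0, abs=1e-12)

    def test_cpm_scale_invariance(self):
        df = pd.DataFrame({"a": [25, 975], "b": [50, 950]}, index=["g1", "g2"])
        t1 = estimate_log2fc(CountMatrix(df), ["a"], ["b"])
        t2 = estimate_log2fc(CountMatrix(df * 2), ["a"], ["b"])
        np.testing.assert_allclose(t1.table["effect"], t2.table["effect"])

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"a": [1]}, index=["g"])
        with pytest.raises(ValidationError):
            estimate_log2fc(CountMatrix(df), [], ["a"])


class TestSignificance:
    def test_external_passthrough(self):
        tbl = make_table(["a"], [1.0], p=[0.01], fdr=[0.02])
        out = attach_significance(tbl, method="external")
        pd.testing.assert_frame_equal(out.table, tbl.table)

    def test_external_requires_statistics(self):
        tbl = make_table(["a"], [1.0])
        with pytest.raises(ValidationError):
            attach_significance(tbl, method="external")

    def test_bh_hand_example(self):
        # BH on (0.01, 0.02, 0.03, 0.04): adjusted = min over j>=i of p_j*n/j
        np.testing.assert_allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04])

    def test_identical_groups_never_significant(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(20, 6)),
                            index=[f"u{i}" for i in range(20)])
        tbl = make_table(list(vals.index), np.zeros(20))
        out = attach_significance(tbl, vals.iloc[:, :3], vals.iloc[:, :3],
                                  "welch_bh")
        for preset in PRESETS.values():
            assert filter_significant(out, preset, "gene") == set()

    def test_single_sample_uses_control_zscore(self):
        # patient value 3 control SD above the mean -> p = 2*Phi(-3)
        from scipy.stats import norm
        ctrl = pd.DataFrame([[0.0, 1.0, 2.0, -1.0, -2.0, 0.0]], index=["u"])
        sd = ctrl.iloc[0].std(ddof=1)
        x = pd.DataFrame([[3 * sd]], index=["u"])
        tbl = make_table(["u"], [float(x.iloc[0, 0])])
        out = attach_significance(tbl, x, ctrl, "welch_bh")
        assert out.table["p_value"][0] == pytest.approx(2 * norm.sf(3), rel=1e-9)

    def test_zero_control_sd_excluded_with_warning(self, caplog):
        ctrl = pd.DataFrame([[1.0, 1.0, 1.0]], index=["u"])
        x = pd.DataFrame([[2.0]], index=["u"])
        tbl = make_table(["u"], [1.0])
        with caplog.at_level("WARNING", logger="dmrescue"):
            out = attach_significance(tbl, x, ctrl, "welch_bh", sd_floor=0.0)
        assert len(out.table) == 0
        assert any("untestable" in r.message for r in caplog.records)

    def test_sd_floor_keeps_zero_variance_units(self):
        ctrl = pd.DataFrame([[1.0, 1.0, 1.0]], index=["u"])
        x = pd.DataFrame([[2.0]], index=["u"])
        tbl = make_table(["u"], [1.0])
        out = attach_significance(tbl, x, ctrl, "welch_bh", sd_floor=0.1)
        assert out.table["p_value"][0] < 1e-6


class TestFilterSignificant:
    def test_strength_gene_example(self):
        tbl = make_table(["kept", "boundary"], [2.5, 2.0],
                         p=[0.01, 0.01], fdr=[0.1, 0.1])
        sig = filter_significant(tbl, PRESETS["strength"], "gene")
        assert sig == {"kept"}  # strict '>': |lfc| exactly 2.0 is dropped

    def test_preset_contrast_on_small_dpsi_event(self):
        tbl = make_table(["ev"], [0.06], p=[1e-5], fdr=[0.01])
        assert filter_significant(tbl, PRESETS["cycling"], "event") == {"ev"}
        assert filter_significant(tbl, PRESETS["strength"], "event") == set()

    def test_missing_statistic_names_unit(self):
        tbl = make_table(["u1"], [1.0], p=[np.nan], fdr=[0.01])
        with pytest.raises(ValidationError, match="u1"):
            filter_significant(tbl, PRESETS["strength"], "gene")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_relaxing_thresholds_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        tbl = make_table([f"u{i}" for i in range(n)],
                         rng.normal(0, 2, n), p=rng.random(n),
                         fdr=rng.random(n))
        tight = Thresholds(lfc_min=2.0, deg_p_max=0.05, dpsi_min=0.2,
                           splice_fdr_max=0.05)
        loose = Thresholds(lfc_min=1.0, deg_p_max=0.2, dpsi_min=0.1,
                           splice_fdr_max=0.2)
        for modality in ("gene", "event"):
            assert filter_significant(tbl, tight, modality) <= \
                filter_significant(tbl, loose, modality)

    def test_preset_lookup_and_overrides(self):
        th = get_thresholds("strength", lfc_min=1.0)
        assert th.lfc_min == 1.0 and th.deg_p_max == 0.05
        with pytest.raises(ValidationError):
            get_thresholds("swimming")


class TestDeltaLog2fc:
    def test_hand_example(self):
        pre = make_table(["g"], [2.0])
        post = make_table(["g"], [0.5])
        out = delta_log2fc(pre, post)
        assert out["delta_lfc"][0] == pytest.approx(-1.5)

    def test_identity(self):
        t = make_table(["g1", "g2"], [1.0, -1.0])
        assert (delta_log2fc(t, t)["delta_lfc"] == 0).all()

    def test_antisymmetric_under_swap(self):
        pre = make_table(["a", "b"], [2.0, -0.5])
        post = make_table(["a", "b"], [0.25, 1.5])
        d1 = delta_log2fc(pre, post)["delta_lfc"]
        d2 = delta_log2fc(post, pre)["delta_lfc"]
        np.testing.assert_allclose(d1, -d2)

    def test_unmatched_units_excluded_with_warning(self, caplog):
        pre = make_table(["a", "b"], [1.0, 2.0])
        post = make_table(["a", "c"], [1.0, 2.0])
        with caplog.at_level("WARNING", logger="dmrescue"):
            out = delta_log2fc(pre, post)
        assert list(out["unit_id"]) == ["a"]
        assert any("2 unit" in r.message for r in caplog.records)

    def test_masking_by_symmetric_construction(self):
        """Two subjects with opposite pre/post profiles: each individual
        |delta| is large while the pooled-contrast delta vanishes."""
        filler = {f"f{i}": 1000 for i in range(999)}
        base = {"m": 1000, **filler}

        def col(m):
            d = dict(base)
            d["m"] = m
            return d

        df = pd.DataFrame({
            "ctl1": col(1000), "ctl2": col(1000),
            "A_pre": col(4000), "A_post": col(1414),
            "B_pre": col(1414), "B_post": col(4000),
        })
        counts = CountMatrix(df)
        ctl = ["ctl1", "ctl2"]
        deltas = {}
        for subj in ("A", "B"):
            pre = estimate_log2fc(counts, [f"{subj}_pre"], ctl)
            post = estimate_log2fc(counts, [f"{subj}_post"], ctl)
            d = delta_log2fc(pre, post).set_index("unit_id")
            deltas[subj] = d.loc["m", "delta_lfc"]
        gpre = estimate_log2fc(counts, ["A_pre", "B_pre"], ctl)
        gpost = estimate_log2fc(counts, ["A_post", "B_post"], ctl)
        grouped = delta_log2fc(gpre, gpost).set_index("unit_id") \
            .loc["m", "delta_lfc"]
        assert abs(deltas["A"]) >= 1.0 and abs(deltas["B"]) >= 1.0
        assert abs(deltas["A"] + deltas["B"]) < 0.05
        assert abs(grouped) <= 0.05


class TestRawFilters:
    def test_low_count_filter_every_vs_any(self):
        df = pd.DataFrame({"s1": [5, 5, 50], "s2": [5, 50, 50]},
                          index=["low_all", "low_one", "high"])
        every = filter_low_counts(CountMatrix(df), 10, "every")
        assert every.gene_ids == ["low_one", "high"]
        any_ = filter_low_counts(CountMatrix(df), 10, "any")
        assert any_.gene_ids == ["high"]

    def test_support_filter_sets_cells_missing(self):
        psi = pd.DataFrame([[0.5, 0.6]], index=["e"], columns=["a", "b"])
        sup = pd.DataFrame([[5, 6]], index=["e"], columns=["a", "b"])
        out = apply_support_filter(PsiMatrix(psi, sup), min_reads=5)
        assert np.isnan(out.psi.loc["e", "a"])  # 5 reads: filtered (<=)
        assert out.psi.loc["e", "b"] == 0.6

    def test_delta_psi_contrast_nan_aware(self):
        psi = pd.DataFrame([[0.8, np.nan, 0.4, 0.6]], index=["e"],
                           columns=["p1", "p2", "c1", "c2"])
        tbl = delta_psi_contrast(psi, ["p1", "p2"], ["c1", "c2"])
        assert tbl.effects()["e"] == pytest.approx(0.8 - 0.5)
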