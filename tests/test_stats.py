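"""Contingency tests, Welch t, rounding/formatting, report assembly."""

import json

import numpy as np
import pandas as pd
import pytest

from hlpacnv.stats import (
    StatsError,
    TwoByTwo,
    build_report,
    chi2_test,
    detection_rates,
    fisher_exact,
    format_p,
    percent,
    round_half_up,
    subgroup_analysis,
    welch_t,
    write_report,
)


class TestChi2:
    def test_equal_proportions_give_zero_statistic(self):
        stat, p, dof = chi2_test(TwoByTwo(10, 90, 20, 180))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert dof == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError, match="margin"):
            chi2_test(TwoByTwo(0, 0, 5, 5))

    def test_negative_cell_rejected(self):
        with pytest.raises(StatsError, match="non-negative"):
            TwoByTwo(-1, 2, 3, 4)

    def test_expected_counts(self):
        t = TwoByTwo(10, 10, 10, 10)
        assert np.allclose(t.expected(), [[10, 10], [10, 10]])

    def test_yates_correction_shrinks_statistic(self):
        plain, _, _ = chi2_test(TwoByTwo(12, 5, 7, 14))
        yates, _, _ = chi2_test(TwoByTwo(12, 5, 7, 14), correction=True)
        assert yates < plain


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_exact(TwoByTwo(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_extreme_table(self):
        # P = 2 * C(5,5)*C(5,0)/C(10,5) = 2/252
        assert fisher_exact(TwoByTwo(5, 0, 0, 5)) == pytest.approx(2 / 252)


class TestWelch:
    def test_identical_degenerate_groups_give_p_one(self):
        t, df, p = welch_t((5.0, 0.0, 30), (5.0, 0.0, 40))
        assert (t, p) == (0.0, 1.0)

    def test_summary_and_raw_agree(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(10, 2, 60), rng.normal(11, 3, 45)
        sa = (a.mean(), a.std(ddof=1), len(a))
        sb = (b.mean(), b.std(ddof=1), len(b))
        t1, d1, p1 = welch_t(a, b)
        t2, d2, p2 = welch_t(sa, sb)
        assert t1 == pytest.approx(t2, abs=1e-10)
        assert d1 == pytest.approx(d2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_sample_size_below_two_rejected(self):
        with pytest.raises(StatsError, match="n >= 2"):
            welch_t((5.0, 1.0, 1), (6.0, 1.0, 10))

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(StatsError, match="zero variance"):
            welch_t((5.0, 0.0, 10), (6.0, 0.0, 10))


class TestFormatting:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(21.4545, 2, 21.45), (2.385, 2, 2.39), (2.375, 2, 2.38), (0.5, 0, 1.0), (1.5, 0, 2.0)],
    )
    def test_round_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected

    def test_percent(self):
        assert percent(378, 1762) == 21.45
        assert percent(42, 1762) == 2.38

    @pytest.mark.parametrize(
        "p,expected",
        [(0.0004, "<0.001"), (0.0012423, "0.001"), (0.021, "0.021"), (0.0896, "0.090")],
    )
    def test_format_p(self, p, expected):
        assert format_p(p) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(StatsError, match="denominator"):
            percent(1, 0)


class TestDetectionRates:
    def test_counts_and_percentages(self):
        flags = pd.DataFrame(
            {"any_cnv": [True, True, False, False], "ppcnv": [True, False, False, False]}
        )
        rates = detection_rates(flags)
        assert rates["any_cnv"] == (2, 4, 50.0)
        assert rates["ppcnv"] == (1, 4, 25.0)

    def test_empty_frame_rejected(self):
        with pytest.raises(StatsError, match="empty"):
            detection_rates(pd.DataFrame(columns=["any_cnv"]))


def _toy_cohort(n_carrier=20, n_noncarrier=80, seed=5):
    rng = np.random.default_rng(seed)
    ids = [f"S{i:03d}" for i in range(n_carrier + n_noncarrier)]
    flags = pd.DataFrame(
        {"ppcnv": [True] * n_carrier + [False] * n_noncarrier},
        index=pd.Index(ids, name="sample_id"),
    )
    clinical = pd.DataFrame(
        {
            "sample_id": ids,
            "subgroup": rng.choice(
                ["septal_defects", "conotruncal_defects", "lvoto"], size=len(ids)
            ),
            "cpbt_min": rng.normal(70, 20, size=len(ids)).clip(min=0),
            "complex_surgery": rng.random(len(ids)) < 0.4,
        }
    )
    return flags, clinical


class TestSubgroups:
    def test_one_vs_rest_margins(self):
        flags, clinical = _toy_cohort()
        res = subgroup_analysis(flags, clinical).set_index("subgroup")
        assert int(res["n"].sum()) == len(clinical)
        assert int(res["n_present"].sum()) == int(flags["ppcnv"].sum())
        assert ((res["p_value"] >= 0) & (res["p_value"] <= 1)).all()
        assert set(res["method"]) <= {"chi2", "fisher"}

    def test_single_subgroup_rejected(self):
        flags, clinical = _toy_cohort()
        clinical["subgroup"] = "septal_defects"
        with pytest.raises(StatsError, match="at least two"):
            subgroup_analysis(flags, clinical)

    def test_unknown_label_rejected(self):
        flags, clinical = _toy_cohort()
        clinical.loc[0, "subgroup"] = "martian"
        with pytest.raises(StatsError, match="unknown subgroup"):
            subgroup_analysis(flags, clinical)


class TestReport:
    def test_report_round_trip_and_determinism(self, tmp_path):
        flags, clinical = _toy_cohort()
        classified = pd.DataFrame({"category": ["pathogenic", "benign", "benign"]})
        r1 = build_report(flags, classified, clinical)
        r2 = build_report(flags, classified, clinical)
        assert r1 == r2
        out = tmp_path / "report.json"
        write_report(r1, out)
        loaded = json.loads(out.read_text())
        assert loaded == r1
        assert loaded["n_carrier"] == 20
        assert loaded["rates"]["ppcnv"]["percent"] == 20.0
        assert loaded["category_counts"] == {"benign": 2, "pathogenic": 1}
        assert loaded["tests"]["cpbt_min"]["method"] == "welch_t"
        assert loaded["tests"]["complex_surgery"]["method"] in ("chi2", "fisher")

    def test_missing_sample_rejected(self):
        flags, clinical = _toy_cohort()
        clinical.loc[0, "sample_id"] = "GHOST"
        with pytest.raises(StatsError, match="missing from flags"):
            build_report(flags, pd.DataFrame({"category": []}), clinical)
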