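"""Five-tier classification cascade, reciprocal overlap, control burden."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlpacnv.classify import (
    ClassifyConfig,
    ClassifyError,
    classify_calls,
    classify_cnv,
    control_burden,
    flag_ppcnv,
    reciprocal_overlap,
)
from hlpacnv.kb import KnowledgeBase, default_knowledge_base


@pytest.fixture(scope="module")
def kb():
    return default_knowledge_base()


def _call(chrom, start, end, svtype, sample="S1"):
    return {
        "sample_id": sample, "chrom": chrom, "start": start, "end": end,
        "svtype": svtype, "copy_number": 1 if svtype == "DEL" else 3,
        "n_support_probes": 4, "region_id": None, "mean_ratio": 1.0,
    }


class TestReciprocalOverlap:
    def test_identity_is_one(self):
        assert reciprocal_overlap(("1", 0, 100), ("1", 0, 100)) == 1.0

    def test_disjoint_and_cross_chromosome_are_zero(self):
        assert reciprocal_overlap(("1", 0, 100), ("1", 200, 300)) == 0.0
        assert reciprocal_overlap(("1", 0, 100), ("2", 0, 100)) == 0.0

    def test_half_overlap(self):
        assert reciprocal_overlap(("1", 0, 100), ("1", 50, 150)) == 0.5

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ClassifyError, match="zero-length"):
            reciprocal_overlap(("1", 5, 5), ("1", 0, 100))

    @given(
        s1=st.integers(0, 10_000), l1=st.integers(1, 10_000),
        s2=st.integers(0, 10_000), l2=st.integers(1, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a, b = ("1", s1, s1 + l1), ("1", s2, s2 + l2)
        ro = reciprocal_overlap(a, b)
        assert ro == reciprocal_overlap(b, a)
        assert 0.0 <= ro <= 1.0


class TestCascade:
    def test_syndrome_match_is_pathogenic(self, kb):
        # near-exact match of the 22q11 deletion syndrome interval
        r = classify_cnv(_call("22", 18_950_000, 21_500_000, "DEL"), kb)
        assert r["category"] == "pathogenic"
        assert r["matched_syndrome"] == "22q11 deletion syndrome"

    def test_effect_type_must_be_compatible(self, kb):
        # a duplication over a deletion-syndrome-only interval is not P1
        r = classify_cnv(_call("15", 30_900_000, 32_400_000, "DUP"), kb)
        assert r["category"] != "pathogenic"

    def test_partial_overlap_is_likely_pathogenic(self, kb):
        r = classify_cnv(_call("8", 10_000_000, 14_000_000, "DEL"), kb)
        assert r["category"] == "likely_pathogenic"
        assert r["rule_fired"] == "LP1_partial_overlap"

    def test_suspected_dosage_gene_is_likely_pathogenic(self, kb):
        r = classify_cnv(_call("6", 50_000_000, 50_700_000, "DUP"), kb)
        assert r["category"] == "likely_pathogenic"
        assert r["rule_fired"] == "LP1_dosage_gene"

    def test_common_variant_is_benign(self, kb):
        r = classify_cnv(_call("14", 105_000_000, 106_000_000, "DUP"), kb)
        assert r["category"] == "benign" and r["rule_fired"] == "B1_common"

    def test_rare_gene_free_variant_is_benign(self, kb):
        r = classify_cnv(_call("4", 60_000_000, 60_500_000, "DEL"), kb)
        assert r["category"] == "benign" and r["rule_fired"] == "B1_no_genes"

    def test_recurrent_gene_containing_variant_is_likely_benign(self, kb):
        r = classify_cnv(_call("16", 200_000, 260_000, "DEL"), kb)
        assert r["category"] == "likely_benign"

    def test_no_evidence_falls_through_to_vus(self, kb):
        r = classify_cnv(_call("11", 90_000_000, 90_800_000, "DEL"), kb)
        assert r["category"] == "vus" and not r["is_ppcnv"]

    def test_aneuploidy_is_always_pathogenic(self, kb):
        c = _call("21", 0, 48_000_000, "ANEUPLOIDY_GAIN")
        assert classify_cnv(c, kb)["category"] == "pathogenic"

    def test_ppcnv_flag_tracks_category(self, kb):
        for call in (
            _call("22", 18_950_000, 21_500_000, "DEL"),
            _call("14", 105_000_000, 106_000_000, "DUP"),
            _call("11", 90_000_000, 90_800_000, "DEL"),
        ):
            r = classify_cnv(call, kb)
            assert r["is_ppcnv"] == (r["category"] in ("pathogenic", "likely_pathogenic"))

    def test_increasing_frequency_never_promotes_to_pathogenic(self, kb):
        """Cascade consistency: frequency can only move calls toward benign."""
        base = _call("16", 200_000, 260_000, "DEL")
        order = {"benign": 0, "likely_benign": 1, "vus": 2, "likely_pathogenic": 3, "pathogenic": 4}
        prev = None
        for freq in (0.0001, 0.005, 0.02, 0.2):
            kb2 = KnowledgeBase(
                kb.syndromes.copy(),
                kb.population_cnvs.assign(frequency=freq),
                kb.genes.copy(),
            )
            cat = classify_cnv(base, kb2)["category"]
            if prev is not None:
                assert order[cat] <= order[prev]
            prev = cat


class TestFlags:
    def _frame(self, rows):
        return classify_calls(pd.DataFrame(rows), default_knowledge_base())

    def test_mixed_calls_set_all_flags(self):
        rows = [
            _call("22", 18_950_000, 21_500_000, "DEL", sample="A"),
            _call("14", 105_000_000, 106_000_000, "DUP", sample="A"),
            _call("11", 90_000_000, 90_800_000, "DEL", sample="B"),
        ]
        flags = flag_ppcnv(self._frame(rows), ["A", "B", "C"])
        assert flags.loc["A", ["any_cnv", "multiple_cnv", "ppcnv", "del22q11_or_dup"]].all()
        assert not flags.loc["A", "aneuploidy"]
        assert flags.loc["B", "any_cnv"] and not flags.loc["B", "ppcnv"]
        assert not flags.loc["C"].any()

    def test_other_syndrome_separated_from_22q11(self):
        rows = [_call("7", 72_700_000, 74_100_000, "DEL", sample="A")]
        flags = flag_ppcnv(self._frame(rows), ["A"])
        assert flags.loc["A", "other_syndrome"]
        assert not flags.loc["A", "del22q11_or_dup"]


class TestControlBurden:
    def test_seeded_carriers_counted(self):
        case = [("22", 18_900_000, 21_500_000)]
        carriers = [[("22", 18_960_000, 21_500_000)]] * 11  # RO ~0.977
        clean = [[("5", 1_000_000, 2_000_000)]] * 292
        n, frac = control_burden(case, carriers + clean)
        assert (n, frac) == (11, 11 / 303)

    def test_below_threshold_overlap_not_counted(self):
        case = [("1", 0, 100)]
        controls = [[("1", 50, 150)]] * 5  # RO = 0.5
        assert control_burden(case, controls) == (0, 0.0)

    def test_empty_case_list_gives_zero(self):
        assert control_burden([], [[("1", 0, 100)]]) == (0, 0.0)

    def test_empty_controls_rejected(self):
        with pytest.raises(ClassifyError, match="empty control"):
            control_burden([("1", 0, 100)], [])
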