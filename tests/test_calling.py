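"""Probe states, region calls, backbone segmentation, karyotyping."""

import numpy as np
import pandas as pd
import pytest

import hlpacnv as h
from hlpacnv import simulate as sim
from hlpacnv.calling import (
    GAIN,
    LOSS,
    NEUTRAL,
    CallingConfig,
    CallingError,
    call_cnvs,
    call_probe_states,
    call_regions,
    merge_backbone_segments,
)


def _flat_ratios(panel, value=2.0, sample="S"):
    """Flat diploid female ratio row: autosomes/X at `value`, Y at zero."""
    df = pd.DataFrame(
        [[value] * panel.n_probes], index=[sample], columns=panel.probe_ids
    )
    y_cols = panel.probes.loc[panel.probes["chrom"] == "Y", "probe_id"]
    df[y_cols] = 0.0
    return df


def _xx_sexes(df):
    return {s: "XX" for s in df.index}


class TestProbeStates:
    @pytest.mark.parametrize("ratio,expected", [(1.0, LOSS), (2.0, NEUTRAL), (3.0, GAIN)])
    def test_autosomal_thresholds(self, panel, ratio, expected):
        df = _flat_ratios(panel)
        auto = panel.probes.loc[~panel.probes["chrom"].isin(["X", "Y"]), "probe_id"].iloc[0]
        df.loc["S", auto] = ratio
        states = call_probe_states(df, panel, sexes=_xx_sexes(df))
        assert states.loc["S", auto] == expected

    def test_xy_sample_uses_halved_expectations(self, panel):
        df = _flat_ratios(panel)
        x_cols = panel.probes.loc[panel.probes["chrom"] == "X", "probe_id"]
        y_cols = panel.probes.loc[panel.probes["chrom"] == "Y", "probe_id"]
        df[x_cols] = 1.0  # one X copy: neutral for a male
        df[y_cols] = 1.0
        states = call_probe_states(df, panel, sexes={"S": "XY"})
        assert (states.loc["S", x_cols] == NEUTRAL).all()
        assert (states.loc["S", y_cols] == NEUTRAL).all()

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(CallingError, match="del_max < 2 < dup_min"):
            CallingConfig(del_max=2.5, dup_min=1.5)


class TestRegionCalls:
    def test_zero_noise_truth_recovered_exactly(self, panel, noiseless_cohort, noiseless_ratios):
        """Region calls on the zero-noise cohort equal the spiked truth."""
        everyone, refs, peaks = noiseless_cohort
        calls, karyotypes = call_cnvs(noiseless_ratios, panel)
        region_calls = calls[calls["region_id"].notna()]
        got = {
            (r["sample_id"], r["region_id"], r["svtype"], r["copy_number"])
            for _, r in region_calls.iterrows()
        }
        expected = set()
        for t in everyone:
            aneuploid = {c for c, _ in t.aneuploidies}
            for chrom, start, end, copy, rid in t.cnvs:
                if chrom in aneuploid:
                    continue
                svtype = "DEL" if copy < 2 else "DUP"
                expected.add((t.sample_id, rid, svtype, copy))
        assert got == expected

    def test_two_of_four_probes_insufficient(self, panel):
        df = _flat_ratios(panel)
        reg = panel.regions().iloc[0]
        pids = panel.probes.loc[panel.probes["region_id"] == reg["region_id"], "probe_id"]
        df[pids[:2]] = 1.0
        states = call_probe_states(df, panel, sexes=_xx_sexes(df))
        assert call_regions(states, df, panel, sexes=_xx_sexes(df)) == []

    def test_duplication_copy_number_rounds_from_mean_ratio(self, panel):
        df = _flat_ratios(panel)
        reg = panel.regions()[panel.regions()["chrom"] == "7"].iloc[0]
        pids = panel.probes.loc[panel.probes["region_id"] == reg["region_id"], "probe_id"]
        df[pids] = 2.97
        states = call_probe_states(df, panel, sexes=_xx_sexes(df))
        calls = call_regions(states, df, panel, sexes=_xx_sexes(df))
        assert len(calls) == 1
        assert calls[0].svtype == "DUP" and calls[0].copy_number == 3

    def test_raising_dup_min_only_removes_gain_calls(self, panel, noiseless_ratios):
        loose = call_cnvs(noiseless_ratios, panel, CallingConfig(dup_min=2.5))[0]
        strict = call_cnvs(noiseless_ratios, panel, CallingConfig(dup_min=3.4))[0]
        key = ["sample_id", "chrom", "start", "svtype"]
        loose_gains = {tuple(r) for r in loose[loose.svtype.str.contains("DUP|GAIN")][key].itertuples(index=False)}
        strict_gains = {tuple(r) for r in strict[strict.svtype.str.contains("DUP|GAIN")][key].itertuples(index=False)}
        assert strict_gains <= loose_gains
        loose_losses = {tuple(r) for r in loose[loose.svtype.str.contains("DEL|LOSS")][key].itertuples(index=False)}
        strict_losses = {tuple(r) for r in strict[strict.svtype.str.contains("DEL|LOSS")][key].itertuples(index=False)}
        assert strict_losses == loose_losses


class TestBackboneSegments:
    def _bb_probes(self, panel, chrom="3"):
        bb = panel.probes[
            (panel.probes["kind"].isin(["backbone", "telomeric"])) & (panel.probes["chrom"] == chrom)
        ].sort_values("start")
        return bb["probe_id"].tolist()

    def test_run_of_five_becomes_one_duplication(self, panel):
        df = _flat_ratios(panel)
        pids = self._bb_probes(panel)[2:7]
        df[pids] = 3.0
        states = call_probe_states(df, panel, sexes=_xx_sexes(df))
        calls = merge_backbone_segments(states, df, panel, sexes=_xx_sexes(df))
        assert len(calls) == 1
        assert calls[0].svtype == "DUP" and calls[0].n_support_probes == 5

    def test_short_run_and_alternation_ignored(self, panel):
        df = _flat_ratios(panel)
        pids = self._bb_probes(panel)
        df[pids[0:3]] = 3.0  # run of 3 < min_run
        df[pids[4]] = 1.0    # isolated
        df[pids[6]] = 3.0    # isolated
        states = call_probe_states(df, panel, sexes=_xx_sexes(df))
        assert merge_backbone_segments(states, df, panel, sexes=_xx_sexes(df)) == []


class TestKaryotypes:
    @pytest.mark.parametrize(
        "sample_id,designation",
        [("T21", "47,XX,+21"), ("X0", "45,X"), ("XXY", "47,XXY"), ("NORM", "46,XY"), ("BEN", "46,XX")],
    )
    def test_iscn_designations(self, panel, noiseless_ratios, sample_id, designation):
        _, karyotypes = call_cnvs(noiseless_ratios, panel)
        row = karyotypes.set_index("sample_id").loc[sample_id]
        assert row["designation"] == designation

    def test_diploid_samples_produce_no_calls(self, panel, noiseless_ratios):
        calls, _ = call_cnvs(noiseless_ratios, panel)
        assert calls[calls["sample_id"] == "NORM"].empty

    def test_aneuploid_chromosome_excluded_from_region_calls(self, panel, noiseless_ratios):
        calls, _ = call_cnvs(noiseless_ratios, panel)
        t21 = calls[calls["sample_id"] == "T21"]
        assert (t21["svtype"] == "ANEUPLOIDY_GAIN").all()


def test_no_overlapping_calls_per_sample(panel):
    """Emitted calls never overlap on the genome within one sample."""
    truth = sim.simulate_genotypes(30, seed=11, panel=panel)
    refs = sim.make_references(6, seed=11)
    peaks = sim.simulate_signals(truth + refs, panel, sim.SignalModel(noise_cv=0.05, seed=11))
    rm = h.quantify(peaks, panel, [r.sample_id for r in refs])
    calls, _ = call_cnvs(rm, panel)
    for sid, g in calls.groupby("sample_id"):
        g = g.sort_values(["chrom", "start"])
        for chrom, gc in g.groupby("chrom"):
            starts = gc["start"].to_numpy()
            ends = gc["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all(), f"overlap in {sid} chr{chrom}"
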