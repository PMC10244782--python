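import numpy as np
import pandas as pd
import pytest

import hlpacnv as h
from hlpacnv import simulate as sim


@pytest.fixture(scope="session")
def full_panel():
    """The bundled 1,602-probe genome-wide panel."""
    return h.default_panel()


@pytest.fixture(scope="session")
def panel():
    """Smaller genome-wide panel (all curated core regions) for fast tests."""
    return h.make_default_panel(
        n_core_regions=25, probes_per_region=4, backbone_spacing=20_000_000,
        seed=1, target_size=None,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(panel):
    """Deterministic zero-noise cohort with one event of each kind."""
    truths = [
        sim.GenotypeTruth("T21", "XX", [("21", 3)]),
        sim.GenotypeTruth("X0", "XX", [("X", 1)]),
        sim.GenotypeTruth("XXY", "XX", [("Y", 1)]),
        sim.GenotypeTruth("DEL22", "XY", cnvs=[("22", 18_900_000, 21_500_000, 1, "22q11_del")]),
        sim.GenotypeTruth("DUPW", "XX", cnvs=[("7", 72_700_000, 74_100_000, 3, "wbs")]),
        sim.GenotypeTruth("LP", "XY", cnvs=[("8", 10_000_000, 14_000_000, 1, "lp_partial_8p23")]),
        sim.GenotypeTruth("BEN", "XX", cnvs=[("14", 105_000_000, 106_000_000, 3, "benign_common")]),
        sim.GenotypeTruth("HBA", "XY", cnvs=[("16", 200_000, 260_000, 1, "hba_region")]),
        sim.GenotypeTruth("VUS", "XX", cnvs=[("11", 90_000_000, 90_800_000, 1, "vus_novel")]),
        sim.GenotypeTruth("NORM", "XY"),
    ]
    refs = sim.make_references(6, seed=0)
    everyone = truths + refs
    peaks = sim.simulate_signals(everyone, panel, sim.SignalModel(noise_cv=0.0, seed=1))
    return everyone, refs, peaks


@pytest.fixture(scope="session")
def noiseless_ratios(panel, noiseless_cohort):
    everyone, refs, peaks = noiseless_cohort
    return h.quantify(peaks, panel, [r.sample_id for r in refs])
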