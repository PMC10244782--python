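"""Synthetic cohort generator with known copy-number truth.

Produces, for a given probe panel: per-sample genotype truth (sex, whole
chromosome aneuploidies, interval CNVs), raw probe peak intensities under a
multiplicative signal model, and clinical covariates matching the published
group summaries. Every source of randomness is seeded, so a cohort is fully
reproducible.

Signal model
------------
The expected peak of probe *j* in sample *i* is

    peak[i, j] = efficiency[j] * scale[i] * copy[i, j] / 2

with multiplicative lognormal noise of a stated coefficient of variation.
This is the standard model for fluorescent amplicon peak heights and makes
the two-stage ratio normalization exact in expectation. At ``noise_cv = 0``
the pipeline's final ratios equal the local copy number exactly, which the
test-suite uses as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import study_data
from .genome import is_autosome, normalize_chrom
from .loci import BENCHMARK_LOCI, PPCNV_REGION_IDS, SYNDROME_LOCI
from .panel import ProbePanel


class CohortError(ValueError):
    pass


@dataclass
class GenotypeTruth:
    """Ground-truth genotype of one synthetic sample.

    ``sex`` is the base sex-chromosome template (XX or XY); sex-chromosome
    aneuploidies are expressed relative to it, e.g. 47,XXY is XX plus a
    single-copy Y gain and 45,X is XX with the X count overridden to 1.
    """

    sample_id: str
    sex: str  # "XX" | "XY"
    aneuploidies: list[tuple[str, int]] = field(default_factory=list)  # (chrom, copy)
    cnvs: list[tuple[str, int, int, int, str]] = field(default_factory=list)
    # (chrom, start, end, copy_number, source_region_id); copy in {0,1,3,4}
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY"):
            raise CohortError(f"{self.sample_id}: sex must be XX or XY")
        for chrom, start, end, copy, rid in self.cnvs:
            if copy not in (0, 1, 3, 4):
                raise CohortError(f"{self.sample_id}: CNV copy {copy} not in {{0,1,3,4}}")
        for chrom, copy in self.aneuploidies:
            if copy not in (1, 2, 3):
                raise CohortError(f"{self.sample_id}: aneuploidy copy {copy} not in {{1,2,3}}")

    def is_ppcnv_carrier(self) -> bool:
        """True when the sample carries an aneuploidy or a CNV at a locus
        whose canonical classification is pathogenic / likely pathogenic."""
        if self.aneuploidies:
            return True
        return any(rid in PPCNV_REGION_IDS for *_, rid in self.cnvs)

    def chrom_copies(self) -> dict[str, int]:
        base = {str(c): 2 for c in range(1, 23)}
        if self.sex == "XX":
            base["X"], base["Y"] = 2, 0
        else:
            base["X"], base["Y"] = 1, 1
        for chrom, copy in self.aneuploidies:
            base[chrom] = copy
        return base


@dataclass
class SignalModel:
    """Multiplicative probe-efficiency x sample-scale x copy signal model."""

    noise_cv: float = 0.05
    efficiency_sigma: float = 0.25  # lognormal sd of per-probe efficiency
    scale_sigma: float = 0.15       # lognormal sd of per-sample scale
    probe_efficiency: np.ndarray | None = None
    sample_scale: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise CohortError("noise_cv must be >= 0")
        for arr in (self.probe_efficiency, self.sample_scale):
            if arr is not None and np.any(np.asarray(arr) <= 0):
                raise CohortError("scale factors must be positive")


# ---------------------------------------------------------------------------
# Event catalogue


def _curated_intervals() -> dict[str, tuple[str, int, int]]:
    out: dict[str, tuple[str, int, int]] = {}
    for loc in list(SYNDROME_LOCI) + list(BENCHMARK_LOCI):
        out[loc.region_id] = (loc.chrom, loc.start, loc.end)
    return out


_ANEUPLOIDY_EVENTS: dict[str, tuple[str, int, str | None]] = {
    # key -> (chrom, copy, forced base sex)
    "trisomy_13": ("13", 3, None),
    "trisomy_18": ("18", 3, None),
    "trisomy_21": ("21", 3, None),
    "XXX": ("X", 3, "XX"),
    "XXY": ("Y", 1, "XX"),      # XX template + one Y = 47,XXY
    "monosomy_X": ("X", 1, "XX"),
}


def default_event_frequencies() -> dict[str, float]:
    """Event probabilities reproducing the published cohort composition.

    Keys are aneuploidy names or ``<region_id>:DEL`` / ``<region_id>:DUP``;
    values are per-sample probabilities (published count / 1,762). Events are
    drawn independently per sample.
    """
    n = study_data.N_TOTAL
    counts = {
        "trisomy_21": 25, "XXX": 4, "XXY": 2, "monosomy_X": 4,
        "22q11_del:DEL": 36, "wbs:DEL": 21, "22q11_dup:DUP": 6,
        "16p13_11:DEL": 2, "16p13_11:DUP": 2, "15q11_2:DEL": 4,
        "1q21_tar:DEL": 4, "1q21_dup:DUP": 4, "cmt1a:DUP": 2,
        "22q11_distal:DEL": 1, "3q29:DEL": 1, "2p21:DEL": 1,
        "miller_dieker:DEL": 1, "15q13_3:DEL": 1, "15q24:DEL": 1,
        "16p12_1:DEL": 1, "rcad:DEL": 1, "leri_weill:DEL": 1,
        "cri_du_chat:DEL": 1, "8p23_1:DEL": 1, "7q11_dup:DUP": 1,
        "hnpp:DEL": 1,
        "lp_partial_8p23:DEL": 13, "lp_dosage_gene:DUP": 13,
        "benign_common:DUP": 53, "benign_nogene:DEL": 50,
        "hba_region:DEL": 43, "nphp1:DUP": 25,
        "vus_novel:DEL": 33,
    }
    return {k: v / n for k, v in counts.items()}


def simulate_genotypes(
    n_samples: int,
    event_frequencies: dict[str, float] | None = None,
    seed: int = 0,
    male_fraction: float = 0.51,
    panel: ProbePanel | None = None,
) -> list[GenotypeTruth]:
    """Draw per-sample genotypes with independent event spike-ins.

    CNV event keys resolve against the curated locus catalogue and, when a
    panel is supplied, against its core-region intervals; unknown ids raise.
    """
    if event_frequencies is None:
        event_frequencies = default_event_frequencies()
    if any(not 0 <= p <= 1 for p in event_frequencies.values()):
        raise CohortError("event probabilities must be in [0, 1]")
    intervals = _curated_intervals()
    if panel is not None:
        for _, r in panel.regions().iterrows():
            intervals.setdefault(r["region_id"], (r["chrom"], int(r["start"]), int(r["end"])))
    cnv_events: dict[str, tuple[str, int, int, int, str]] = {}
    for key in event_frequencies:
        if key in _ANEUPLOIDY_EVENTS:
            continue
        if ":" not in key:
            raise CohortError(f"unknown event {key!r}")
        rid, svtype = key.rsplit(":", 1)
        if rid not in intervals or svtype not in ("DEL", "DUP"):
            raise CohortError(f"unknown event {key!r}")
        chrom, start, end = intervals[rid]
        cnv_events[key] = (chrom, start, end, svtype, rid)

    rng = np.random.default_rng(seed)
    out: list[GenotypeTruth] = []
    for i in range(n_samples):
        sex = "XY" if rng.random() < male_fraction else "XX"
        aneuploidies: list[tuple[str, int]] = []
        cnvs: list[tuple[str, int, int, int, str]] = []
        for key, p in event_frequencies.items():
            if rng.random() >= p:
                continue
            if key in _ANEUPLOIDY_EVENTS:
                chrom, copy, forced = _ANEUPLOIDY_EVENTS[key]
                if forced is not None:
                    sex = forced
                aneuploidies.append((chrom, copy))
            else:
                chrom, start, end, svtype, rid = cnv_events[key]
                # copy change relative to the sex-specific baseline, so a
                # deletion on X in an XY sample goes to zero copies
                base = 2 if chrom not in ("X", "Y") else (
                    {"XX": {"X": 2, "Y": 0}, "XY": {"X": 1, "Y": 1}}[sex][chrom]
                )
                copy = max(base - 1, 0) if svtype == "DEL" else base + 1
                cnvs.append((chrom, start, end, copy, rid))
        out.append(GenotypeTruth(f"S{i:04d}", sex, aneuploidies, cnvs))
    return out


def make_references(n: int = 20, seed: int = 0, prefix: str = "REF") -> list[GenotypeTruth]:
    """Diploid control samples, alternating XX/XY, flagged as references."""
    return [
        GenotypeTruth(f"{prefix}{i:03d}", "XX" if i % 2 == 0 else "XY", is_reference=True)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Signals


def copy_number_matrix(truth: list[GenotypeTruth], panel: ProbePanel) -> pd.DataFrame:
    """True local copy number for every (sample, probe)."""
    probes = panel.probes
    mid = ((probes["start"] + probes["end"]) // 2).to_numpy()
    chroms = probes["chrom"].to_numpy()
    mat = np.empty((len(truth), len(probes)))
    for i, t in enumerate(truth):
        copies = t.chrom_copies()
        row = np.array([copies[c] for c in chroms], dtype=float)
        for chrom, start, end, copy, _ in t.cnvs:
            chrom = normalize_chrom(chrom)
            sel = (chroms == chrom) & (mid >= start) & (mid < end)
            row[sel] = copy
        mat[i] = row
    return pd.DataFrame(mat, index=[t.sample_id for t in truth], columns=panel.probe_ids)


def simulate_signals(
    truth: list[GenotypeTruth], panel: ProbePanel, model: SignalModel
) -> pd.DataFrame:
    """Raw peak-intensity table (samples x probes) under the signal model."""
    rng = np.random.default_rng(model.seed)
    n_s, n_p = len(truth), panel.n_probes
    if model.probe_efficiency is not None:
        eff = np.asarray(model.probe_efficiency, dtype=float)
        if eff.shape != (n_p,):
            raise CohortError("probe_efficiency length != panel size")
    else:
        eff = rng.lognormal(0.0, model.efficiency_sigma, size=n_p)
    if model.sample_scale is not None:
        scale = np.asarray(model.sample_scale, dtype=float)
        if scale.shape != (n_s,):
            raise CohortError("sample_scale length != number of samples")
    else:
        scale = rng.lognormal(0.0, model.scale_sigma, size=n_s)

    cn = copy_number_matrix(truth, panel).to_numpy()
    expected = eff[None, :] * scale[:, None] * cn / 2.0
    if model.noise_cv > 0:
        sigma = np.sqrt(np.log1p(model.noise_cv**2))
        noise = rng.lognormal(-sigma**2 / 2, sigma, size=expected.shape)
        expected = expected * noise
    return pd.DataFrame(
        expected, index=[t.sample_id for t in truth], columns=panel.probe_ids
    )


# ---------------------------------------------------------------------------
# Clinical covariates


@dataclass
class ClinicalParams:
    """Group means/SDs and proportions by ppCNV-carrier stratum.

    ``continuous``: field -> (carrier mean, carrier sd, non-carrier mean,
    non-carrier sd), truncated-at-zero normal. ``binary``: field ->
    (carrier rate, non-carrier rate). ``subgroup_probs``: per-stratum
    multinomial over the 12 CHD subgroups.
    """

    continuous: dict[str, tuple[float, float, float, float]]
    binary: dict[str, tuple[float, float]]
    subgroup_probs: dict[str, np.ndarray]  # "carrier"/"noncarrier" -> probs

    def __post_init__(self) -> None:
        for f, (m1, s1, m2, s2) in self.continuous.items():
            if s1 < 0 or s2 < 0:
                raise CohortError(f"{f}: negative SD")

    @classmethod
    def from_study(cls) -> "ClinicalParams":
        binary = {
            f: (c / study_data.N_CARRIER, nc / study_data.N_NONCARRIER)
            for f, (c, nc) in study_data.BINARY_COUNTS.items()
        }
        pres = np.array([p for _, p, _ in study_data.SUBGROUP_COUNTS], dtype=float)
        absn = np.array([a for _, _, a in study_data.SUBGROUP_COUNTS], dtype=float)
        return cls(
            continuous=dict(study_data.CONTINUOUS_SUMMARIES),
            binary=binary,
            subgroup_probs={
                "carrier": pres / pres.sum(),
                "noncarrier": absn / absn.sum(),
            },
        )


BINARY_FLAG_FIELDS = [
    f for f in study_data.BINARY_COUNTS if f not in ("male", "complex_surgery", "died_1mo")
]


def simulate_clinical(
    truth: list[GenotypeTruth],
    params: ClinicalParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical covariate sheet with the published per-stratum structure.

    Covariates are conditionally independent given the carrier stratum (only
    marginal group statistics are published). Continuous draws are truncated
    at zero. Reference samples are excluded.
    """
    if params is None:
        params = ClinicalParams.from_study()
    rng = np.random.default_rng(seed)
    rows = []
    for t in truth:
        if t.is_reference:
            continue
        carrier = t.is_ppcnv_carrier()
        k = 0 if carrier else 2
        rec: dict[str, object] = {
            "sample_id": t.sample_id,
            "sex": t.sex,
            "is_ppcnv_carrier_truth": carrier,
        }
        for f, v in params.continuous.items():
            rec[f] = max(0.0, rng.normal(v[k], v[k + 1]))
        probs = params.subgroup_probs["carrier" if carrier else "noncarrier"]
        rec["subgroup"] = study_data.SUBGROUPS[int(rng.choice(len(probs), p=probs))]
        for f, (pc, pn) in params.binary.items():
            if f == "male":
                continue  # sex comes from genotype truth
            rec[f] = bool(rng.random() < (pc if carrier else pn))
        rec["outcome"] = "died_1mo" if rec.pop("died_1mo") else "cured"
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort I/O


def truth_to_frame(truth: list[GenotypeTruth]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {
                "sample_id": t.sample_id,
                "sex": t.sex,
                "is_reference": t.is_reference,
                "aneuploidies": ";".join(f"{c}:{n}" for c, n in t.aneuploidies),
                "cnvs": ";".join(
                    f"{c}:{s}-{e}:{cp}:{rid}" for c, s, e, cp, rid in t.cnvs
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "sex", "is_reference", "aneuploidies", "cnvs"]
    )


def truth_from_frame(df: pd.DataFrame) -> list[GenotypeTruth]:
    out = []
    for _, r in df.iterrows():
        aneu = []
        if isinstance(r["aneuploidies"], str) and r["aneuploidies"]:
            for tok in r["aneuploidies"].split(";"):
                c, n = tok.split(":")
                aneu.append((c, int(n)))
        cnvs = []
        if isinstance(r["cnvs"], str) and r["cnvs"]:
            for tok in r["cnvs"].split(";"):
                c, span, cp, rid = tok.split(":")
                s, e = span.split("-")
                cnvs.append((c, int(s), int(e), int(cp), rid))
        is_ref = str(r["is_reference"]).strip().lower() in ("true", "1")
        out.append(GenotypeTruth(r["sample_id"], r["sex"], aneu, cnvs, is_ref))
    return out


def write_cohort(
    truth: list[GenotypeTruth],
    peaks: pd.DataFrame,
    clinical: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write samples/truth/clinical sheets and per-sample peak TSVs."""
    outdir = Path(outdir)
    ids = [t.sample_id for t in truth]
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate sample_id in truth")
    if set(peaks.index) != set(ids):
        raise CohortError("peak table sample ids do not match truth")
    if not clinical.empty and not set(clinical["sample_id"]).issubset(ids):
        raise CohortError("clinical sheet contains unknown sample ids")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    paths = {}
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "sex": [t.sex for t in truth],
            "is_reference": [t.is_reference for t in truth],
        }
    )
    paths["samples"] = outdir / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    truth_to_frame(truth).to_csv(paths["truth"], sep="\t", index=False)
    paths["clinical"] = outdir / "clinical.tsv"
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    for sid in ids:
        p = outdir / "peaks" / f"{sid}.tsv"
        peaks.loc[sid].rename("peak").rename_axis("probe_id").to_csv(p, sep="\t")
    paths["peaks_dir"] = outdir / "peaks"
    return paths


def load_cohort(outdir: str | Path) -> tuple[list[GenotypeTruth], pd.DataFrame, pd.DataFrame]:
    """Round-trip counterpart of :func:`write_cohort`."""
    outdir = Path(outdir)
    truth = truth_from_frame(
        pd.read_csv(outdir / "truth.tsv", sep="\t", keep_default_na=False)
    )
    clinical = pd.read_csv(outdir / "clinical.tsv", sep="\t")
    rows = {}
    for t in truth:
        s = pd.read_csv(outdir / "peaks" / f"{t.sample_id}.tsv", sep="\t", index_col=0)
        rows[t.sample_id] = s["peak"]
    peaks = pd.DataFrame(rows).T.loc[[t.sample_id for t in truth]]
    peaks.index.name = None
    return truth, peaks, clinical
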