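"""Copy-number calling from probe ratios.

Three callers operate per sample on the 2.0-scale ratio matrix:

* probe-state calling — each probe is LOSS / NEUTRAL / GAIN against
  thresholds placed at the midpoints between integer copy expectations
  (defaults 1.5 and 2.5), with expectations halved on the sex chromosomes
  of XY samples;
* region calling — a core region is called when at least ``min_probes``
  (default 4, the panel's minimum region coverage) of its probes agree on a
  non-neutral state and those probes make up at least 80% of the region;
* backbone segmentation — maximal runs of at least ``min_run`` consecutive
  concordant backbone/telomeric probes become one segment call, catching
  large events outside the targeted regions;
* aneuploidy calling — a chromosome with at least ``chrom_fraction`` of its
  probes in one non-neutral state is a whole-chromosome gain/loss; sex
  chromosome counts are estimated from median ratios and assembled into an
  ISCN-like karyotype designation (e.g. ``47,XX,+21``).

Aneuploid chromosomes are excluded from region/backbone output, and
backbone segments overlapping a region call are suppressed, so one sample's
calls never overlap on the genome.

Mosaic (intermediate-ratio) states are not modelled: a chromosome-wide
ratio of ~2.5 falls to NEUTRAL or GAIN by threshold. Breakpoints are
probe-resolution only; balanced rearrangements are invisible to a dosage
assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import AUTOSOMES, is_autosome
from .panel import ProbePanel
from .quantify import RatioMatrix, _safe_nanmedian, infer_sex

LOSS, NEUTRAL, GAIN, NOCALL = "LOSS", "NEUTRAL", "GAIN", "NOCALL"

CALL_COLUMNS = [
    "sample_id", "chrom", "start", "end", "svtype", "copy_number",
    "n_support_probes", "region_id", "mean_ratio",
]


class CallingError(ValueError):
    pass


@dataclass
class CallingConfig:
    del_max: float = 1.5
    dup_min: float = 2.5
    min_probes: int = 4          # minimum supporting probes for a region call
    region_fraction: float = 0.8  # concordant fraction required within a region
    min_run: int = 4             # minimum backbone run length
    chrom_fraction: float = 0.8  # fraction of probes for a whole-chromosome call

    def __post_init__(self) -> None:
        if not self.del_max < 2 < self.dup_min:
            raise CallingError("thresholds must satisfy del_max < 2 < dup_min")
        if self.min_probes < 1:
            raise CallingError("min_probes must be >= 1")
        if not 0.5 < self.chrom_fraction <= 1:
            raise CallingError("chrom_fraction must be in (0.5, 1]")


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: str  # DEL | DUP | ANEUPLOIDY_GAIN | ANEUPLOIDY_LOSS
    copy_number: int
    n_support_probes: int
    region_id: str | None
    mean_ratio: float


@dataclass(frozen=True)
class Karyotype:
    sample_id: str
    total_count: int
    sex_chromosomes: str
    designation: str


def _expected_copies(sex: str, chrom: str) -> int:
    if is_autosome(chrom):
        return 2
    if sex == "XX":
        return 2 if chrom == "X" else 0
    if sex == "XY":
        return 1
    return 2  # indeterminate handled separately by the aneuploidy caller


def call_probe_states(
    ratios: RatioMatrix | pd.DataFrame,
    panel: ProbePanel,
    cfg: CallingConfig | None = None,
    sexes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-probe LOSS/NEUTRAL/GAIN/NOCALL state table.

    Thresholds scale with the sex-specific expected copy number: an XY
    sample's X and Y probes use half thresholds. A probe whose expectation
    is zero copies (Y in XX) is NEUTRAL unless signal appears (ratio >=
    0.5, an unexpected Y -> GAIN). Samples of indeterminate sex get NOCALL
    on the sex chromosomes; the aneuploidy caller evaluates those directly.
    """
    cfg = cfg or CallingConfig()
    df = ratios.ratios if isinstance(ratios, RatioMatrix) else ratios
    chroms = panel.probes.set_index("probe_id")["chrom"].reindex(df.columns)
    if sexes is None:
        sexes = {s: infer_sex(df.loc[s], panel) for s in df.index}

    vals = df.to_numpy(dtype=float)
    states = np.full(vals.shape, NEUTRAL, dtype=object)
    chrom_arr = chroms.to_numpy()
    x_mask = chrom_arr == "X"
    y_mask = chrom_arr == "Y"
    auto_mask = ~(x_mask | y_mask)

    for i, sid in enumerate(df.index):
        sex = sexes.get(sid, "indeterminate")
        row = vals[i]
        for mask, exp in ((auto_mask, 2), (x_mask, _expected_copies(sex, "X")),
                          (y_mask, _expected_copies(sex, "Y"))):
            if not mask.any():
                continue
            if sex == "indeterminate" and mask is not auto_mask:
                states[i, mask] = NOCALL
                continue
            if exp == 0:
                states[i, mask & (row >= 0.5)] = GAIN
                continue
            f = exp / 2.0
            states[i, mask & (row <= cfg.del_max * f)] = LOSS
            states[i, mask & (row >= cfg.dup_min * f)] = GAIN
        states[i, np.isnan(row)] = NOCALL
    return pd.DataFrame(states, index=df.index, columns=df.columns)


def _copy_number(mean_ratio: float, svtype: str, expected: int) -> int:
    c = int(np.clip(np.round(mean_ratio), 0, 4))
    if svtype in ("DEL", "ANEUPLOIDY_LOSS"):
        c = min(c, expected - 1)
    else:
        c = max(c, expected + 1)
    return int(np.clip(c, 0, 4))


def _col_indices(df: pd.DataFrame, pids: list[str]) -> np.ndarray:
    lookup = {p: i for i, p in enumerate(df.columns)}
    return np.array([lookup[p] for p in pids], dtype=int)


def call_regions(
    states: pd.DataFrame,
    ratios: RatioMatrix | pd.DataFrame,
    panel: ProbePanel,
    cfg: CallingConfig | None = None,
    sexes: dict[str, str] | None = None,
) -> list[CnvCall]:
    """Core-region CNV calls from concordant probe states."""
    cfg = cfg or CallingConfig()
    df = ratios.ratios if isinstance(ratios, RatioMatrix) else ratios
    if sexes is None:
        sexes = {s: infer_sex(df.loc[s], panel) for s in df.index}
    regions = panel.regions()
    core = panel.probes[panel.probes["kind"] == "core_cnv"]
    probes_by_region = {rid: g["probe_id"].tolist() for rid, g in core.groupby("region_id")}

    st_arr = states.to_numpy()
    val_arr = df.to_numpy(dtype=float)
    sample_ids = list(states.index)

    calls: list[CnvCall] = []
    for _, reg in regions.iterrows():
        idx = _col_indices(states, probes_by_region[reg["region_id"]])
        sub = st_arr[:, idx]
        n = len(idx)
        need = max(cfg.min_probes, int(np.ceil(cfg.region_fraction * n)))
        for state, svtype in ((LOSS, "DEL"), (GAIN, "DUP")):
            counts = (sub == state).sum(axis=1)
            for i in np.flatnonzero(counts >= need):
                sid = sample_ids[i]
                exp = _expected_copies(sexes.get(sid, "XX"), reg["chrom"])
                mean_ratio = float(np.nanmean(val_arr[i, idx]))
                calls.append(
                    CnvCall(
                        sample_id=sid,
                        chrom=reg["chrom"],
                        start=int(reg["start"]),
                        end=int(reg["end"]),
                        svtype=svtype,
                        copy_number=_copy_number(mean_ratio, svtype, exp),
                        n_support_probes=int(counts[i]),
                        region_id=reg["region_id"],
                        mean_ratio=round(mean_ratio, 3),
                    )
                )
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start))
    return calls


def merge_backbone_segments(
    states: pd.DataFrame,
    ratios: RatioMatrix | pd.DataFrame,
    panel: ProbePanel,
    cfg: CallingConfig | None = None,
    sexes: dict[str, str] | None = None,
) -> list[CnvCall]:
    """Segment calls from runs of concordant backbone/telomeric probes."""
    cfg = cfg or CallingConfig()
    df = ratios.ratios if isinstance(ratios, RatioMatrix) else ratios
    if sexes is None:
        sexes = {s: infer_sex(df.loc[s], panel) for s in df.index}
    bb = panel.probes[panel.probes["kind"].isin(("backbone", "telomeric"))]
    st_arr = states.to_numpy()
    val_arr = df.to_numpy(dtype=float)
    sample_ids = list(states.index)

    calls: list[CnvCall] = []
    for chrom, g in bb.groupby("chrom", sort=False):
        g = g.sort_values("start")
        idx = _col_indices(states, g["probe_id"].tolist())
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        sub = st_arr[:, idx]
        for si in range(len(sample_ids)):
            st = sub[si]
            sid = sample_ids[si]
            i = 0
            while i < len(idx):
                if st[i] not in (LOSS, GAIN):
                    i += 1
                    continue
                j = i
                while j + 1 < len(idx) and st[j + 1] == st[i]:
                    j += 1
                if j - i + 1 >= cfg.min_run:
                    svtype = "DEL" if st[i] == LOSS else "DUP"
                    exp = _expected_copies(sexes.get(sid, "XX"), chrom)
                    mean_ratio = float(np.nanmean(val_arr[si, idx[i : j + 1]]))
                    calls.append(
                        CnvCall(
                            sample_id=sid,
                            chrom=chrom,
                            start=int(starts[i]),
                            end=int(ends[j]),
                            svtype=svtype,
                            copy_number=_copy_number(mean_ratio, svtype, exp),
                            n_support_probes=j - i + 1,
                            region_id=None,
                            mean_ratio=round(mean_ratio, 3),
                        )
                    )
                i = j + 1
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.start))
    return calls


def call_aneuploidies(
    states: pd.DataFrame,
    ratios: RatioMatrix | pd.DataFrame,
    panel: ProbePanel,
    cfg: CallingConfig | None = None,
) -> tuple[list[CnvCall], list[Karyotype]]:
    """Whole-chromosome gain/loss calls and per-sample karyotypes.

    Sex-chromosome counts are the rounded median X/Y ratios (the ratio scale
    estimates copy number directly); autosomal aneuploidy requires
    ``chrom_fraction`` of the chromosome's probes in one state.
    """
    cfg = cfg or CallingConfig()
    df = ratios.ratios if isinstance(ratios, RatioMatrix) else ratios
    probes = panel.probes
    by_chrom = {c: g["probe_id"].tolist() for c, g in probes.groupby("chrom", sort=False)}
    chrom_len = panel.chrom_lengths
    idx_by_chrom = {c: _col_indices(states, pids) for c, pids in by_chrom.items()}
    st_arr = states.to_numpy()
    val_arr = df.to_numpy(dtype=float)
    sample_ids = list(states.index)

    calls: list[CnvCall] = []
    karyotypes: list[Karyotype] = []
    for si, sid in enumerate(sample_ids):
        autosome_copies: dict[str, int] = {}
        for chrom in AUTOSOMES:
            idx = idx_by_chrom.get(chrom)
            if idx is None or idx.size == 0:
                autosome_copies[chrom] = 2
                continue
            st = st_arr[si, idx]
            n = idx.size
            copy = 2
            for state, svtype in ((GAIN, "ANEUPLOIDY_GAIN"), (LOSS, "ANEUPLOIDY_LOSS")):
                k = int((st == state).sum())
                if k >= cfg.chrom_fraction * n:
                    mean_ratio = float(np.nanmean(val_arr[si, idx]))
                    copy = _copy_number(mean_ratio, svtype, 2)
                    calls.append(
                        CnvCall(sid, chrom, 0, chrom_len[chrom], svtype, copy,
                                k, None, round(mean_ratio, 3))
                    )
                    break
            autosome_copies[chrom] = copy

        rrow = df.iloc[si]
        nx, ny = _sex_chromosome_counts(rrow, by_chrom)
        calls.extend(_sex_aneuploidy_calls(sid, nx, ny, rrow, by_chrom, chrom_len))

        total = sum(autosome_copies.values()) + nx + ny
        sex_str = "X" * nx + "Y" * ny or "-"
        extras = []
        for chrom in AUTOSOMES:
            c = autosome_copies[chrom]
            if c > 2:
                extras.append(f"+{chrom}")
            elif c < 2:
                extras.append(f"-{chrom}")
        designation = ",".join([str(total), sex_str] + extras)
        karyotypes.append(Karyotype(sid, total, sex_str, designation))
    return calls, karyotypes


def _sex_chromosome_counts(rrow: pd.Series, by_chrom: dict) -> tuple[int, int]:
    def med(chrom: str) -> float:
        pids = by_chrom.get(chrom, [])
        if not pids:
            return np.nan
        return _safe_nanmedian(rrow[pids])

    mx, my = med("X"), med("Y")
    nx = int(np.clip(np.round(mx), 0, 4)) if np.isfinite(mx) else 0
    ny = int(np.clip(np.round(my), 0, 4)) if np.isfinite(my) else 0
    return nx, ny


def _sex_aneuploidy_calls(
    sid: str, nx: int, ny: int, rrow: pd.Series, by_chrom: dict, chrom_len: dict
) -> list[CnvCall]:
    """Deviations from the nearest normal sex-chromosome complement."""
    exp = (2, 0) if ny == 0 else (1, 1)
    out = []
    for chrom, n, e in (("X", nx, exp[0]), ("Y", ny, exp[1])):
        if n == e or not by_chrom.get(chrom):
            continue
        svtype = "ANEUPLOIDY_GAIN" if n > e else "ANEUPLOIDY_LOSS"
        mean_ratio = _safe_nanmedian(rrow[by_chrom[chrom]])
        out.append(
            CnvCall(sid, chrom, 0, chrom_len[chrom], svtype, n,
                    len(by_chrom[chrom]), None, round(mean_ratio, 3))
        )
    return out


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    if not calls:
        return pd.DataFrame(columns=CALL_COLUMNS)
    df = pd.DataFrame([c.__dict__ for c in calls])
    return df[CALL_COLUMNS]


def karyotypes_to_frame(karyotypes: list[Karyotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [k.__dict__ for k in karyotypes],
        columns=["sample_id", "total_count", "sex_chromosomes", "designation"],
    )


def _overlaps(a: CnvCall, b: CnvCall) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def call_cnvs(
    ratios: RatioMatrix | pd.DataFrame,
    panel: ProbePanel,
    cfg: CallingConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all three callers and merge per-sample non-overlapping calls.

    Precedence on overlap: aneuploidy > core region > backbone segment.
    Region and backbone calls on aneuploid chromosomes are dropped to avoid
    double reporting. Returns ``(calls, karyotypes)`` DataFrames.
    """
    cfg = cfg or CallingConfig()
    df = ratios.ratios if isinstance(ratios, RatioMatrix) else ratios
    sexes = {s: infer_sex(df.loc[s], panel) for s in df.index}
    states = call_probe_states(ratios, panel, cfg, sexes)
    aneu_calls, karyotypes = call_aneuploidies(states, ratios, panel, cfg)
    region_calls = call_regions(states, ratios, panel, cfg, sexes)
    backbone_calls = merge_backbone_segments(states, ratios, panel, cfg, sexes)

    aneu_chroms = {(c.sample_id, c.chrom) for c in aneu_calls}
    kept: list[CnvCall] = list(aneu_calls)
    for c in region_calls:
        if (c.sample_id, c.chrom) not in aneu_chroms:
            kept.append(c)
    region_kept = [c for c in kept if c.svtype in ("DEL", "DUP")]
    for c in backbone_calls:
        if (c.sample_id, c.chrom) in aneu_chroms:
            continue
        if any(_overlaps(c, r) for r in region_kept if r.sample_id == c.sample_id):
            continue
        kept.append(c)
    return calls_to_frame(kept), karyotypes_to_frame(karyotypes)


def write_vcf(calls: pd.DataFrame, path, sample_order: list[str] | None = None) -> None:
    """Minimal VCF 4.2 export of CNV calls (SVTYPE/END/CN in INFO)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy number">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, r in calls.iterrows():
        svtype = "DEL" if "LOSS" in r["svtype"] or r["svtype"] == "DEL" else "DUP"
        info = (
            f"SVTYPE={svtype};END={r['end']};CN={r['copy_number']};SAMPLE={r['sample_id']}"
        )
        lines.append(
            f"{r['chrom']}\t{r['start'] + 1}\tcnv_{i}\tN\t<{svtype}>\t.\tPASS\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
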