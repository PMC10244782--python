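"""Probe-panel model for multiplex ligation-probe CNV assays.

A panel is an ordered set of genomic probes, each belonging to a target
region: a recurrent-CNV *core* region covered by at least four probes, a
*telomeric* anchor placed at about 0/10/20 Mb from a chromosome end, or a
*backbone* probe spaced evenly along the chromosome. Probes carry a
fluorophore channel (1..4) and an amplicon length that must be unique within
the channel, because capillary electrophoresis separates amplicons of one
fluorophore by size alone.

Coordinates are 0-based half-open internally; BED export is native, and only
human-readable reports use 1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    AUTOSOMES,
    CHROMOSOMES,
    GRCH37_CHROM_LENGTHS,
    chrom_sort_key,
    normalize_chrom,
)
from .loci import BENCHMARK_LOCI, SYNDROME_LOCI

PROBE_COLUMNS = [
    "probe_id",
    "chrom",
    "start",
    "end",
    "region_id",
    "kind",
    "channel",
    "amplicon_length",
]

KINDS = ("core_cnv", "telomeric", "backbone", "snv_locus")

#: probes in the published assay configuration
DEFAULT_PANEL_SIZE = 1602

PROBE_FOOTPRINT = 100  # bp spanned by one ligation probe pair


class PanelError(ValueError):
    """Malformed or invariant-violating panel input."""


@dataclass(frozen=True)
class Probe:
    probe_id: str
    chrom: str
    start: int
    end: int
    region_id: str
    kind: str
    channel: int
    amplicon_length: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(f"probe {self.probe_id}: start >= end")
        if self.kind not in KINDS:
            raise PanelError(f"probe {self.probe_id}: unknown kind {self.kind!r}")
        if not 1 <= self.channel <= 4:
            raise PanelError(f"probe {self.probe_id}: channel must be 1..4")


@dataclass(frozen=True)
class TargetRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    kind: str
    syndrome_name: str | None = None


@dataclass
class ProbePanel:
    """Validated, position-sorted probe panel."""

    probes: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(GRCH37_CHROM_LENGTHS))

    def __post_init__(self) -> None:
        df = self.probes
        missing = [c for c in PROBE_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"panel table missing columns: {missing}")
        df = df[PROBE_COLUMNS].copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        for col in ("start", "end", "channel", "amplicon_length"):
            df[col] = df[col].astype(int)
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
            raise PanelError(f"duplicate probe ids: {dups[:5]}")
        if df.duplicated(subset=["channel", "amplicon_length"]).any():
            bad = df[df.duplicated(subset=["channel", "amplicon_length"], keep=False)]
            pair = bad.iloc[0][["channel", "amplicon_length"]].tolist()
            raise PanelError(
                f"amplicon length reused within a channel (channel={pair[0]}, length={pair[1]}): "
                "size-based separation requires uniqueness"
            )
        if (df["start"] >= df["end"]).any():
            raise PanelError("probe with start >= end")
        order = df["chrom"].map(chrom_sort_key)
        df = df.assign(_ord=order).sort_values(["_ord", "start", "end"]).drop(columns="_ord")
        self.probes = df.reset_index(drop=True)

    # -- derived views ------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return self.probes["probe_id"].tolist()

    def regions(self) -> pd.DataFrame:
        """Target regions derived from probe membership.

        Core regions span min(start)..max(end) of their probes; backbone and
        telomeric probes are not grouped into regions.
        """
        core = self.probes[self.probes["kind"] == "core_cnv"]
        if core.empty:
            return pd.DataFrame(columns=["region_id", "chrom", "start", "end", "n_probes"])
        g = core.groupby("region_id", sort=False)
        out = pd.DataFrame(
            {
                "region_id": list(g.groups),
                "chrom": g["chrom"].first().values,
                "start": g["start"].min().values,
                "end": g["end"].max().values,
                "n_probes": g.size().values,
            }
        )
        out = out.assign(_ord=out["chrom"].map(chrom_sort_key)).sort_values(
            ["_ord", "start"]
        ).drop(columns="_ord")
        return out.reset_index(drop=True)

    def probe_rows(self) -> list[Probe]:
        return [Probe(**rec) for rec in self.probes.to_dict("records")]


# ---------------------------------------------------------------------------
# I/O


def load_panel(path: str | Path) -> ProbePanel:
    """Read a panel TSV.

    Required columns: probe_id, chrom, start, end, region_id, kind.
    channel and amplicon_length are assigned (round-robin / sequential) when
    absent. Raises :class:`PanelError` with the offending line on bad rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise PanelError(f"{path}: cannot parse panel table: {exc}") from exc
    required = ["probe_id", "chrom", "start", "end", "region_id", "kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing columns {missing}")
    for col in ("start", "end"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise PanelError(f"{path}:{line}: non-numeric {col!r}")
    if "channel" not in df.columns or "amplicon_length" not in df.columns:
        df = _assign_channels(df)
    return ProbePanel(probes=df)


def write_panel(panel: ProbePanel, path: str | Path) -> None:
    panel.probes.to_csv(path, sep="\t", index=False)


def write_bed(panel: ProbePanel, path: str | Path) -> None:
    """Export probes as BED6 (name = probe_id, score = channel)."""
    bed = panel.probes[["chrom", "start", "end", "probe_id", "channel"]].copy()
    bed["strand"] = "+"
    bed.to_csv(path, sep="\t", index=False, header=False)


def _assign_channels(df: pd.DataFrame) -> pd.DataFrame:
    """Round-robin channels and sequential per-channel amplicon lengths."""
    df = df.copy()
    n = len(df)
    channels = np.arange(n) % 4 + 1
    lengths = 100 + (np.arange(n) // 4) * 4
    df["channel"] = channels
    df["amplicon_length"] = lengths
    return df


# ---------------------------------------------------------------------------
# Validation


def validate_panel(panel: ProbePanel) -> list[str]:
    """Report invariant violations without raising.

    Checks: probes sorted by (chrom, start), every core region covered by at
    least four probes, all 24 chromosomes represented, telomeric probes near
    a 0/10/20 Mb telomere offset.
    """
    violations: list[str] = []
    df = panel.probes
    order = df["chrom"].map(chrom_sort_key)
    sorted_ok = (
        order.is_monotonic_increasing
        and df.groupby(order, sort=False)["start"].apply(lambda s: s.is_monotonic_increasing).all()
    )
    if not sorted_ok:
        violations.append("probes are not sorted by chromosome and start")
    regions = panel.regions()
    for _, r in regions.iterrows():
        if r["n_probes"] < 4:
            violations.append(
                f"core region {r['region_id']} has {r['n_probes']} probes (needs >= 4)"
            )
    present = set(df["chrom"])
    absent = [c for c in CHROMOSOMES if c not in present]
    if absent:
        violations.append(f"chromosomes without probes: {absent}")
    telo = df[df["kind"] == "telomeric"]
    for _, p in telo.iterrows():
        clen = panel.chrom_lengths[p["chrom"]]
        dist = min(p["start"], clen - p["end"])
        offsets = (0, 10_000_000, 20_000_000)
        if min(abs(dist - o) for o in offsets) > 2_000_000:
            violations.append(
                f"telomeric probe {p['probe_id']} is {dist} bp from the telomere, "
                "not near 0/10/20 Mb"
            )
    return violations


# ---------------------------------------------------------------------------
# Default panel construction


def make_default_panel(
    n_core_regions: int = 206,
    probes_per_region: int = 4,
    backbone_spacing: int = 4_500_000,
    seed: int = 0,
    target_size: int | None = DEFAULT_PANEL_SIZE,
) -> ProbePanel:
    """Build a synthetic genome-wide panel mirroring the assay design.

    The first core regions are the curated recurrent-syndrome and benchmark
    loci; the remainder are placed uniformly at random (seeded) on autosomes
    without overlapping. Telomeric probes sit at ~0/10/20 Mb from both ends
    of every chromosome; backbone probes are spaced ``backbone_spacing``
    apart. If ``target_size`` is given, backbone probes are thinned
    deterministically so the panel totals exactly that many probes.
    """
    if n_core_regions < 1:
        raise PanelError("n_core_regions must be >= 1")
    if probes_per_region < 4:
        raise PanelError(
            "probes_per_region must be >= 4: core regions require at least "
            "four supporting probes"
        )
    rng = np.random.default_rng(seed)

    # unique physical intervals among curated loci (del/dup pairs share probes)
    curated: list[tuple[str, str, int, int]] = []
    seen: set[tuple[str, int, int]] = set()
    for loc in list(SYNDROME_LOCI) + list(BENCHMARK_LOCI):
        key = (loc.chrom, loc.start, loc.end)
        if key in seen:
            continue
        seen.add(key)
        curated.append((loc.region_id, loc.chrom, loc.start, loc.end))

    regions = curated[:n_core_regions]
    taken: dict[str, list[tuple[int, int]]] = {}
    for _, c, s, e in regions:
        taken.setdefault(c, []).append((s, e))

    i = 0
    while len(regions) < n_core_regions:
        chrom = AUTOSOMES[int(rng.integers(0, len(AUTOSOMES)))]
        clen = GRCH37_CHROM_LENGTHS[chrom]
        span = int(rng.integers(1_000_000, 3_000_000))
        start = int(rng.integers(1_000_000, clen - span - 1_000_000))
        end = start + span
        if any(s < end and start < e for s, e in taken.get(chrom, [])):
            continue
        rid = f"core_{i:04d}"
        i += 1
        regions.append((rid, chrom, start, end))
        taken.setdefault(chrom, []).append((start, end))

    rows: list[tuple] = []
    for rid, chrom, start, end in regions:
        pos = np.linspace(start, end - PROBE_FOOTPRINT, probes_per_region).astype(int)
        for j, p in enumerate(pos):
            rows.append((f"{rid}_p{j}", chrom, int(p), int(p) + PROBE_FOOTPRINT, rid, "core_cnv"))

    for chrom in CHROMOSOMES:
        clen = GRCH37_CHROM_LENGTHS[chrom]
        for j, off in enumerate((0, 10_000_000, 20_000_000)):
            s = min(off + 50_000, clen - PROBE_FOOTPRINT)
            rows.append((f"tel_{chrom}_p_{j}", chrom, s, s + PROBE_FOOTPRINT, "telomeric", "telomeric"))
            e = max(clen - off - 50_000, PROBE_FOOTPRINT)
            rows.append((f"tel_{chrom}_q_{j}", chrom, e - PROBE_FOOTPRINT, e, "telomeric", "telomeric"))

    backbone: list[tuple] = []
    for chrom in CHROMOSOMES:
        clen = GRCH37_CHROM_LENGTHS[chrom]
        for j, p in enumerate(range(backbone_spacing // 2, clen - PROBE_FOOTPRINT, backbone_spacing)):
            backbone.append((f"bb_{chrom}_{j:03d}", chrom, p, p + PROBE_FOOTPRINT, "backbone", "backbone"))

    if target_size is not None:
        n_fixed = len(rows)
        n_keep = target_size - n_fixed
        if n_keep < 0:
            raise PanelError(
                f"target_size {target_size} smaller than core+telomeric probe count {n_fixed}"
            )
        if n_keep > len(backbone):
            raise PanelError(
                f"target_size {target_size} needs {n_keep} backbone probes but spacing "
                f"{backbone_spacing} yields only {len(backbone)}; reduce backbone_spacing"
            )
        # thin evenly so coverage stays genome-wide
        idx = np.floor(np.linspace(0, len(backbone) - 1, n_keep)).astype(int)
        backbone = [backbone[k] for k in np.unique(idx)]
    rows.extend(backbone)

    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end", "region_id", "kind"])
    df = _assign_channels(df)
    return ProbePanel(probes=df)


def default_panel() -> ProbePanel:
    """The bundled 1,602-probe genome-wide panel (deterministic)."""
    return make_default_panel()
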