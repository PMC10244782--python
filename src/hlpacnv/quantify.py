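"""Probe-ratio quantification: raw peaks to the diploid≈2.0 ratio scale.

Two-stage normalization:

1. *Intra-sample*: each probe's peak is divided by the median peak of the
   sample's autosomal backbone probes, cancelling the per-sample scale
   (total DNA input, PCR yield).
2. *Inter-sample*: each relative value is divided by the per-probe median
   over designated reference (control) samples and multiplied by 2,
   cancelling per-probe efficiency. The final ratio sits near 2.0 for a
   copy-neutral diploid locus, near 1.0 for a heterozygous deletion and
   near 3.0 for a single-copy duplication — i.e. it estimates the local
   copy number directly.

Sex chromosomes are normalized against same-sex references (X against XX
references, Y against twice the XY-reference median) so that the ratio
remains an unbiased copy-number estimate on both sex chromosomes: an XY
sample reads ≈1.0 on X and ≈1.0 on Y; an XX sample ≈2.0 on X and ≈0 on Y.
Medians are used throughout for robustness to the samples' own CNVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import is_autosome
from .panel import ProbePanel


class QuantifyError(ValueError):
    pass


#: fraction of missing probes above which a sample fails QC
MISSING_PROBE_QC_THRESHOLD = 0.10


@dataclass
class RatioMatrix:
    """Samples x probes matrix of final normalized ratios (diploid ≈ 2.0)."""

    ratios: pd.DataFrame
    reference_ids: list[str] = field(default_factory=list)
    qc_failed: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratios.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.ratios.columns)


def _backbone_autosomal_mask(panel: ProbePanel) -> np.ndarray:
    probes = panel.probes
    auto = probes["chrom"].map(is_autosome).to_numpy()
    backbone = (probes["kind"] == "backbone").to_numpy()
    mask = auto & backbone
    if not mask.any():
        # tiny hand-built panels may carry no backbone probes; fall back to
        # all autosomal probes so the scale still cancels
        mask = auto
    return mask


def intra_sample_normalize(
    peaks: pd.DataFrame, panel: ProbePanel
) -> tuple[pd.DataFrame, list[str]]:
    """Divide each sample by its median autosomal backbone peak.

    Non-positive or NaN peaks are treated as missing; samples missing more
    than 10% of probes are flagged QC-fail and excluded from the returned
    table. Returns ``(relative_values, qc_failed_sample_ids)``.
    """
    missing_cols = [p for p in panel.probe_ids if p not in peaks.columns]
    if missing_cols:
        raise QuantifyError(f"peak table lacks panel probes: {missing_cols[:5]}")
    peaks = peaks[panel.probe_ids].astype(float)
    vals = peaks.to_numpy().copy()
    vals[~(vals > 0)] = np.nan

    missing_frac = np.isnan(vals).mean(axis=1)
    qc_failed = [s for s, f in zip(peaks.index, missing_frac) if f > MISSING_PROBE_QC_THRESHOLD]
    keep = ~np.isin(peaks.index, qc_failed)

    mask = _backbone_autosomal_mask(panel)
    sub = vals[:, mask]
    denom = np.full(len(sub), np.nan)
    has_data = ~np.isnan(sub).all(axis=1)
    denom[has_data] = np.nanmedian(sub[has_data], axis=1)
    rel = vals / denom[:, None]
    out = pd.DataFrame(rel[keep], index=peaks.index[keep], columns=peaks.columns)
    return out, qc_failed


def _classify_reference_sex(ref_rel: pd.DataFrame, panel: ProbePanel) -> pd.Series:
    """XX/XY for each reference from raw relative values (Y median > 0.25)."""
    y_probes = panel.probes.loc[panel.probes["chrom"] == "Y", "probe_id"]
    if y_probes.empty:
        return pd.Series("XX", index=ref_rel.index)
    med_y = ref_rel[y_probes].median(axis=1)
    return pd.Series(np.where(med_y > 0.25, "XY", "XX"), index=ref_rel.index)


def inter_sample_normalize(
    relvals: pd.DataFrame,
    reference_ids: list[str],
    panel: ProbePanel,
) -> RatioMatrix:
    """Scale relative values by per-probe reference medians onto the 2.0 scale.

    Requires at least three references. Per-probe baselines: autosomes use
    the median over all references; X uses the XX references (or 2x the XY
    median when none are XX); Y uses 2x the XY-reference median. Probes
    whose baseline cannot be formed yield NaN (no-call) ratios.
    """
    refs = [r for r in reference_ids if r in relvals.index]
    if len(refs) < 3:
        raise QuantifyError(
            f"inter-sample normalization needs >= 3 reference samples, got {len(refs)}"
        )
    ref_rel = relvals.loc[refs]
    ref_sex = _classify_reference_sex(ref_rel, panel)
    chroms = panel.probes.set_index("probe_id")["chrom"]

    baseline = ref_rel.median(axis=0)
    xx = ref_sex[ref_sex == "XX"].index
    xy = ref_sex[ref_sex == "XY"].index
    x_cols = [p for p in relvals.columns if chroms[p] == "X"]
    y_cols = [p for p in relvals.columns if chroms[p] == "Y"]
    if x_cols:
        if len(xx) > 0:
            baseline[x_cols] = ref_rel.loc[xx, x_cols].median(axis=0)
        else:
            baseline[x_cols] = 2.0 * ref_rel.loc[xy, x_cols].median(axis=0)
    if y_cols:
        if len(xy) > 0:
            baseline[y_cols] = 2.0 * ref_rel.loc[xy, y_cols].median(axis=0)
        else:
            baseline[y_cols] = np.nan  # no male reference: Y is no-call
    baseline[~(baseline > 0)] = np.nan

    ratios = 2.0 * relvals / baseline
    return RatioMatrix(ratios=ratios, reference_ids=refs)


def quantify(
    peaks: pd.DataFrame, panel: ProbePanel, reference_ids: list[str] | None = None
) -> RatioMatrix:
    """Full two-stage normalization.

    When no references are designated, the cohort itself serves as the
    reference set (per-probe cohort medians): with rare events and a large
    cohort the median sample is copy-neutral at every probe.
    """
    rel, qc_failed = intra_sample_normalize(peaks, panel)
    refs = list(reference_ids) if reference_ids else list(rel.index)
    rm = inter_sample_normalize(rel, refs, panel)
    rm.qc_failed = qc_failed
    if reference_ids is None:
        rm.reference_ids = []
    return rm


def _safe_nanmedian(values) -> float:
    """nanmedian that returns NaN silently on an all-NaN slice."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(np.median(arr)) if arr.size else float("nan")


def infer_sex(ratio_row: pd.Series, panel: ProbePanel) -> str:
    """Classify a sample's sex-chromosome template from its ratios.

    Returns ``"XX"``, ``"XY"`` or ``"indeterminate"``; the last routes the
    sample to explicit sex-chromosome aneuploidy evaluation. Requires at
    least two X and two Y probes on the panel.
    """
    chroms = panel.probes.set_index("probe_id")["chrom"]
    x_cols = [p for p in ratio_row.index if chroms.get(p) == "X"]
    y_cols = [p for p in ratio_row.index if chroms.get(p) == "Y"]
    if len(x_cols) < 2 or len(y_cols) < 2:
        raise QuantifyError("sex inference needs >= 2 probes on each of X and Y")
    auto_cols = [p for p in ratio_row.index if is_autosome(chroms.get(p, "1"))]
    med_a = _safe_nanmedian(ratio_row[auto_cols])
    med_x = _safe_nanmedian(ratio_row[x_cols])
    med_y = _safe_nanmedian(ratio_row[y_cols])
    if not np.isfinite(med_a) or med_a <= 0:
        return "indeterminate"
    rx, ry = med_x / med_a, (0.0 if not np.isfinite(med_y) else med_y / med_a)
    if 0.375 <= rx <= 0.625 and 0.35 <= ry <= 0.65:
        return "XY"
    if 0.75 <= rx <= 1.25 and ry <= 0.15:
        return "XX"
    return "indeterminate"
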