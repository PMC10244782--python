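"""Five-tier CNV pathogenicity classification and control-burden comparison.

Each call receives exactly one of five categories through a fixed-precedence
rule cascade evaluated against the knowledge base:

* **P1 pathogenic** — whole-chromosome aneuploidy, or a deletion/duplication
  matching a known syndrome region in location and size (reciprocal overlap
  >= ``match_ro``, default 0.90) with a compatible effect type;
* **LP1 likely pathogenic** — partial overlap (positive but below
  ``match_ro``) with a compatible syndrome region, or overlap of a gene
  with suspected/partial dosage-sensitivity evidence;
* **B1 benign** — population frequency above ``benign_freq`` (default 1%),
  or listed benign in a curated database, or present in the population
  catalogue below 1% while containing no genes;
* **LB1 likely benign** — gene-containing, observed at least ``min_obs``
  times in normal populations at below-1% frequency;
* **VUS** — anything else (insufficient evidence).

Pathogenic-first precedence is deliberate: a syndrome-region match
overrides frequency evidence. Pathogenic + likely pathogenic together form
the "potentially pathogenic" (ppCNV) group used in all cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kb import KnowledgeBase

CATEGORIES = ("benign", "likely_benign", "vus", "likely_pathogenic", "pathogenic")
PP_CATEGORIES = ("likely_pathogenic", "pathogenic")

FLAG_COLUMNS = [
    "any_cnv", "multiple_cnv", "ppcnv", "aneuploidy", "del22q11_or_dup", "other_syndrome",
]


class ClassifyError(ValueError):
    pass


@dataclass
class ClassifyConfig:
    match_ro: float = 0.90    # "matched in location and size"
    freq_ro: float = 0.50     # overlap needed to adopt a population record's frequency
    min_obs: int = 3          # recurrence bar for likely benign
    benign_freq: float = 0.01  # population-frequency bar for benign


def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """Overlap length divided by the longer interval; 0 across chromosomes.

    Symmetric by construction. Raises on zero-length intervals.
    """
    ca, sa, ea = a
    cb, sb, eb = b
    if ea <= sa or eb <= sb:
        raise ClassifyError("zero-length interval in reciprocal overlap")
    if str(ca) != str(cb):
        return 0.0
    ov = min(ea, eb) - max(sa, sb)
    if ov <= 0:
        return 0.0
    return ov / max(ea - sa, eb - sb)


def _effect_compatible(svtype: str, effect: str) -> bool:
    return effect == "both" or effect == svtype


def classify_cnv(call: pd.Series | dict, kb: KnowledgeBase, cfg: ClassifyConfig | None = None) -> dict:
    """Classify one call; returns category, ppCNV flag, matched syndrome, rule.

    ``call`` needs fields chrom/start/end/svtype (a row of the calls table).
    """
    cfg = cfg or ClassifyConfig()
    c = dict(call)
    ivl = (str(c["chrom"]), int(c["start"]), int(c["end"]))
    svtype = c["svtype"]

    result = {
        "category": "vus",
        "is_ppcnv": False,
        "matched_syndrome": None,
        "rule_fired": "VUS",
    }

    if svtype in ("ANEUPLOIDY_GAIN", "ANEUPLOIDY_LOSS"):
        result.update(category="pathogenic", is_ppcnv=True, rule_fired="P1_aneuploidy")
        return result

    syn = kb.syndromes
    compat = syn[syn["effect"].map(lambda e: _effect_compatible(svtype, e))]
    ros = [
        (reciprocal_overlap(ivl, (r["chrom"], r["start"], r["end"])), r["syndrome_name"])
        for _, r in compat.iterrows()
    ]
    if ros:
        best_ro, best_name = max(ros, key=lambda t: t[0])
        if best_ro >= cfg.match_ro:
            result.update(
                category="pathogenic", is_ppcnv=True,
                matched_syndrome=best_name, rule_fired="P1_syndrome_match",
            )
            return result
        if best_ro > 0:
            result.update(
                category="likely_pathogenic", is_ppcnv=True,
                matched_syndrome=best_name, rule_fired="LP1_partial_overlap",
            )
            return result

    genes = kb.genes[kb.genes["chrom"] == ivl[0]]
    hit_genes = genes[(genes["start"] < ivl[2]) & (ivl[1] < genes["end"])]
    if hit_genes["dosage_evidence"].isin(("suspected", "partial")).any():
        result.update(
            category="likely_pathogenic", is_ppcnv=True, rule_fired="LP1_dosage_gene"
        )
        return result

    pop = kb.population_cnvs
    pop = pop[pop["svtype"] == svtype]
    matches = pop[
        pop.apply(
            lambda r: reciprocal_overlap(ivl, (r["chrom"], r["start"], r["end"]))
            >= cfg.freq_ro,
            axis=1,
        )
    ] if not pop.empty else pop
    freq = float(matches["frequency"].max()) if not matches.empty else np.nan
    n_obs = int(matches["n_observations"].max()) if not matches.empty else 0
    listed_benign = bool(matches["benign_listed"].any()) if not matches.empty else False
    has_genes = not hit_genes.empty

    if np.isfinite(freq) and freq > cfg.benign_freq:
        result.update(category="benign", rule_fired="B1_common")
        return result
    if listed_benign:
        result.update(category="benign", rule_fired="B1_listed")
        return result
    if np.isfinite(freq) and freq <= cfg.benign_freq and not has_genes:
        result.update(category="benign", rule_fired="B1_no_genes")
        return result
    if has_genes and np.isfinite(freq) and n_obs >= cfg.min_obs:
        result.update(category="likely_benign", rule_fired="LB1_recurrent")
        return result
    return result


def classify_calls(
    calls: pd.DataFrame, kb: KnowledgeBase, cfg: ClassifyConfig | None = None
) -> pd.DataFrame:
    """Vector version of :func:`classify_cnv` over a calls table."""
    if calls.empty:
        return calls.assign(
            category=pd.Series(dtype=str), is_ppcnv=pd.Series(dtype=bool),
            matched_syndrome=pd.Series(dtype=object), rule_fired=pd.Series(dtype=str),
        )
    extra = pd.DataFrame([classify_cnv(row, kb, cfg) for _, row in calls.iterrows()],
                         index=calls.index)
    return pd.concat([calls, extra], axis=1)


def flag_ppcnv(classified: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Per-sample abnormality flags from classified calls.

    ``any_cnv`` counts every retained call including VUS; ``multiple_cnv``
    means two or more retained calls; ``del22q11_or_dup`` marks a matched
    22q11 deletion/duplication syndrome; ``other_syndrome`` marks any other
    non-aneuploidy ppCNV.
    """
    flags = pd.DataFrame(
        False, index=pd.Index(sample_ids, name="sample_id"), columns=FLAG_COLUMNS
    )
    if classified.empty:
        return flags
    for sid, g in classified.groupby("sample_id"):
        if sid not in flags.index:
            raise ClassifyError(f"classified call for unknown sample {sid!r}")
        flags.loc[sid, "any_cnv"] = True
        flags.loc[sid, "multiple_cnv"] = len(g) >= 2
        pp = g[g["is_ppcnv"]]
        flags.loc[sid, "ppcnv"] = not pp.empty
        aneu = pp["svtype"].isin(("ANEUPLOIDY_GAIN", "ANEUPLOIDY_LOSS"))
        flags.loc[sid, "aneuploidy"] = bool(aneu.any())
        syn = pp["matched_syndrome"].fillna("")
        is_22q11 = syn.str.contains("22q11")
        flags.loc[sid, "del22q11_or_dup"] = bool(is_22q11.any())
        flags.loc[sid, "other_syndrome"] = bool((~aneu & ~is_22q11).any())
    return flags


def control_burden(
    case_ppcnvs: list[tuple[str, int, int]],
    controls: list[list[tuple[str, int, int]]],
    ro_threshold: float = 0.90,
) -> tuple[int, float]:
    """Count controls carrying any case ppCNV at the reciprocal-overlap bar.

    A control individual is a carrier iff any of its CNVs has reciprocal
    overlap >= ``ro_threshold`` with any case ppCNV region.
    """
    if not 0 < ro_threshold <= 1:
        raise ClassifyError("ro_threshold must be in (0, 1]")
    if not controls:
        raise ClassifyError("empty control set")
    n = 0
    for cnvs in controls:
        if any(
            reciprocal_overlap(c, p) >= ro_threshold for c in cnvs for p in case_ppcnvs
        ):
            n += 1
    return n, n / len(controls)
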