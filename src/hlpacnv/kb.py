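"""CNV knowledge base: syndrome regions, population CNVs, gene intervals.

The bundled default knowledge base is a synthetic curation (see
:mod:`hlpacnv.loci`): the recurrent syndrome regions at approximate hg19
coordinates plus invented population-frequency and gene-dosage records that
exercise every classification tier. It is not a DGV / ISCA / DECIPHER /
ClinGen export.

File formats (TSV):

* ``syndromes.tsv``: chrom start end syndrome_name effect(DEL|DUP|both)
* ``population_cnvs.tsv``: chrom start end svtype frequency n_observations
  [benign_listed]
* ``genes.tsv``: chrom start end gene_name dosage_evidence
  (confirmed|suspected|partial|none)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import normalize_chrom
from .loci import BENCHMARK_LOCI, SYNDROME_LOCI


class KnowledgeBaseError(ValueError):
    pass


SYNDROME_COLS = ["chrom", "start", "end", "syndrome_name", "effect"]
POPULATION_COLS = ["chrom", "start", "end", "svtype", "frequency", "n_observations", "benign_listed"]
GENE_COLS = ["chrom", "start", "end", "gene_name", "dosage_evidence"]

DOSAGE_LEVELS = ("confirmed", "suspected", "partial", "none")


@dataclass
class KnowledgeBase:
    syndromes: pd.DataFrame
    population_cnvs: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.syndromes = self._check(self.syndromes, SYNDROME_COLS)
        if "benign_listed" not in self.population_cnvs.columns:
            self.population_cnvs = self.population_cnvs.assign(benign_listed=False)
        self.population_cnvs = self._check(self.population_cnvs, POPULATION_COLS)
        self.genes = self._check(self.genes, GENE_COLS)
        freq = self.population_cnvs["frequency"]
        if ((freq < 0) | (freq > 1)).any():
            raise KnowledgeBaseError("population frequencies must be in [0, 1]")
        bad = ~self.genes["dosage_evidence"].isin(DOSAGE_LEVELS)
        if bad.any():
            raise KnowledgeBaseError(
                f"unknown dosage_evidence: {self.genes.loc[bad, 'dosage_evidence'].unique()}"
            )

    @staticmethod
    def _check(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KnowledgeBaseError(f"knowledge-base table missing columns {missing}")
        df = df[cols].copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] >= df["end"]).any():
            raise KnowledgeBaseError("knowledge-base interval with start >= end")
        return df

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("syndromes", self.syndromes),
            ("population_cnvs", self.population_cnvs),
            ("genes", self.genes),
        ):
            paths[name] = outdir / f"{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=False)
        return paths

    @classmethod
    def load(cls, indir: str | Path) -> "KnowledgeBase":
        indir = Path(indir)
        return cls(
            syndromes=pd.read_csv(indir / "syndromes.tsv", sep="\t", dtype={"chrom": str}),
            population_cnvs=pd.read_csv(indir / "population_cnvs.tsv", sep="\t", dtype={"chrom": str}),
            genes=pd.read_csv(indir / "genes.tsv", sep="\t", dtype={"chrom": str}),
        )


def default_knowledge_base() -> KnowledgeBase:
    """Synthetic default knowledge base aligned with the curated loci."""
    syn = pd.DataFrame(
        [(l.chrom, l.start, l.end, l.syndrome_name, l.effect) for l in SYNDROME_LOCI],
        columns=SYNDROME_COLS,
    )
    bm = {l.region_id: l for l in BENCHMARK_LOCI}
    pop_rows = [
        # common polymorphic duplication: frequency above the 1% benign bar
        (bm["benign_common"], "DUP", 0.020, 40, False),
        # rare, gene-free: benign by the "no genes" clause
        (bm["benign_nogene"], "DEL", 0.002, 5, False),
        # recurrent gene-containing rare CNVs: likely benign
        (bm["hba_region"], "DEL", 0.008, 12, False),
        (bm["nphp1"], "DUP", 0.006, 9, False),
    ]
    pop = pd.DataFrame(
        [(l.chrom, l.start, l.end, sv, f, n, bl) for l, sv, f, n, bl in pop_rows],
        columns=POPULATION_COLS,
    )
    genes = pd.DataFrame(
        [
            ("22", 19_744_000, 19_772_000, "TBX1", "confirmed"),
            ("7", 73_440_000, 73_484_000, "ELN", "confirmed"),
            ("16", 222_000, 228_000, "HBA1", "none"),
            ("16", 215_000, 221_000, "HBA2", "none"),
            ("2", 110_880_000, 110_962_000, "NPHP1", "none"),
            # invented gene with suspected but unconfirmed dosage sensitivity
            ("6", 50_300_000, 50_400_000, "DOSG1", "suspected"),
        ],
        columns=GENE_COLS,
    )
    return KnowledgeBase(syndromes=syn, population_cnvs=pop, genes=genes)
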