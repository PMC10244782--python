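# Methods

## Assay and panel model

The modeled assay is high-throughput ligation-dependent probe
amplification (HLPA): probe pairs ligate on their exact genomic targets,
ligation products are amplified in multiplex PCR, and capillary
electrophoresis peak heights are read out per probe. Peak height is
proportional to target copy number, so a genome-wide panel converts one
electropherogram into a copy-number profile.

The bundled default panel holds 1,602 probes on GRCh37 coordinates
(0-based, half-open internally): 206 core CNV regions × 4 probes covering
curated microdeletion/microduplication syndrome intervals plus randomly
placed autosomal regions, 144 telomeric probes (both arms of all 24
chromosomes at 0/10/20 Mb offsets from the telomere), and 634 backbone
probes at ~10 Mb genome-wide spacing. Panel invariants (sorted
coordinates, ≥4 probes per region, all chromosomes covered, unique
(channel, amplicon length) pairs) are enforced at load time and checkable
with `validate_panel`.

## Signal model

A raw peak is modeled multiplicatively:

    peak[i, j] = efficiency[j] · scale[i] · (copy[i, j] / 2) · ε[i, j]

with per-probe ligation/PCR efficiency, per-sample input scale, local copy
number, and mean-1 lognormal noise ε parameterized by a coefficient of
variation (σ² = log(1 + cv²), μ = −σ²/2). At `noise_cv = 0` the model is
exact, which is what makes exact-recovery property testing possible.

Ground-truth genotypes are a base sex template (XX/XY) plus relative
events: whole-chromosome aneuploidies (copy 1–3; 47,XXY is XX plus a
one-copy Y gain, 45,X is XX with X forced to one copy) and focal CNVs
(copy 0/1/3/4, computed relative to the sex-specific baseline so an
X-deletion in an XY sample reaches zero copies). Default event
frequencies reproduce the composition of a 1,762-child CHD screening
cohort; clinical covariates (age, weight, bypass/cross-clamp/ventilation
times, complication flags, 12 CHD subgroups) are drawn per carrier stratum
from the published group summaries, truncated at zero.

## Quantification

Normalization is two-stage:

1. **Intra-sample** — each sample is divided by its median autosomal
   backbone peak, canceling the sample scale. Non-positive peaks count as
   missing; samples missing >10% of probes fail QC and are excluded.
2. **Inter-sample** — each probe is divided by the median of ≥3 reference
   samples and multiplied by 2, canceling probe efficiency and putting
   ratios on a copy-number scale (diploid ≈2.0). X-probe baselines come
   from XX references (or 2× the XY median when none are XX); Y-probe
   baselines are 2× the XY-reference median, so the ratio approximates the
   copy count on both sex chromosomes.

Sample sex is inferred from median X and Y ratios; samples that fit
neither XX nor XY windows are flagged indeterminate and their
sex-chromosome probes are not called.

## Calling

Per-probe states are LOSS (ratio ≤ 1.5), GAIN (≥ 2.5), NEUTRAL, or NOCALL,
with thresholds halved on single-copy sex chromosomes of XY samples. Three
callers run in precedence order aneuploidy > region > backbone:

- **aneuploidy** — ≥80% concordant probe states across a chromosome; sex
  chromosome counts are the rounded median X/Y ratios; results are
  summarized as ISCN designations (47,XX,+21; 45,X; 47,XXY);
- **region** — a core region is called when ≥max(4, 80% of its probes)
  agree; copy number is the rounded mean ratio clipped to [0, 4];
- **backbone** — runs of ≥4 concordant backbone/telomeric probes merge
  into segments.

Calls on aneuploid chromosomes are suppressed, as are backbone segments
overlapping region calls, so per-sample calls never overlap. Calls export
to TSV and minimal VCF 4.2 (SVTYPE/END/CN).

## Classification

Each call passes through a five-tier cascade, first match wins:

1. **Pathogenic** — aneuploidy, or ≥90% reciprocal overlap (RO; overlap
   divided by the longer interval) with a syndrome region of compatible
   effect (deletion vs duplication);
2. **Likely pathogenic** — partial syndrome overlap (0 < RO < 0.90), or
   content of a suspected dosage-sensitive gene;
3. **Benign** — population frequency >1%, or listed benign, or catalogued
   rare variant containing no genes;
4. **Likely benign** — gene-containing, frequency <1%, seen ≥3 times in
   the population catalogue;
5. **VUS** — everything else.

ppCNV = pathogenic ∪ likely pathogenic. Frequency lookups use RO ≥ 0.5;
control-cohort burden uses RO ≥ 0.90, matching the 90%-reciprocal-overlap
convention for calling two CNVs "the same".

## Statistics

Conventions follow common clinical-cohort practice (SPSS-style): Pearson
chi-squared without Yates continuity correction by default, Fisher's exact
test whenever any expected cell count is below 5, and Welch's
unequal-variance t-test for continuous covariates — computable directly
from `(mean, sd, n)` group summaries with the Welch–Satterthwaite degrees
of freedom, so published tables can be re-tested without raw data.
Percentages are rounded half-up to two decimals; displayed P-values use
three decimals with `<0.001` below 0.0005. Subgroup enrichment is
one-vs-rest over the closed 12-level CHD subgroup vocabulary.

## Verification strategy

Because raw assay data for such cohorts are not generally deposited, the
pipeline is verified two ways: (i) the cohort-level statistics are
recomputed from bundled published counts/summaries and pinned to their
printed values (detection rates to 2 dp, burden P = 0.0012, complex
surgery 62.35% vs 37.63%, Welch P = 0.021/0.090, AVSD P = 0.002); and
(ii) the signal chain is property-tested — exact truth recovery at zero
noise, and ≥95% sensitivity with ≤1% false-positive region calls per
sample at 5% noise with 20 references over five seeds. The 2×2 tests are
additionally checked against independent oracles: exhaustive
hypergeometric enumeration for Fisher (all margins totaling ≤60, reduced
by row/column symmetries) and the direct Σ(O−E)²/E formula for
chi-squared.

Known internal inconsistencies of the printed source tables are carried
as-is and documented in `hlpacnv/study_data.py` (complex-surgery cells sum
to 1,761; subgroup cells sum to 1,761 with 1,599 non-carriers).
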