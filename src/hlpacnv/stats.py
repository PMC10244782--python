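"""Cohort association statistics: detection rates, 2x2 tests, group comparisons.

Conventions chosen to match how such cohorts are usually analysed in SPSS:
Pearson chi-squared without Yates continuity correction by default
(correction available by flag), Fisher's exact test whenever any expected
cell count falls below 5, and Welch's unequal-variance t-test for
continuous covariates compared from group summary statistics. Percentages
are rounded half-up to two decimals; displayed P-values use three decimals
with "<0.001" below 0.0005.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import study_data


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table: rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError("cell counts must be non-negative")
        if self.total == 0:
            raise StatsError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def expected(self) -> np.ndarray:
        t = self.as_array()
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    return "<0.001" if p < 0.0005 else f"{round_half_up(p, 3):.3f}"


def percent(num: int, den: int, ndigits: int = 2) -> float:
    if den == 0:
        raise StatsError("zero denominator")
    return round_half_up(100.0 * num / den, ndigits)


# ---------------------------------------------------------------------------
# Tests


def chi2_test(t: TwoByTwo, correction: bool = False) -> tuple[float, float, int]:
    """Pearson chi-squared on a 2x2 table, optionally Yates-corrected.

    Raises when a margin is zero (expected counts undefined for the test);
    callers should use Fisher's exact test there.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError("zero margin: use fisher_exact instead")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=correction)
    return float(chi2), float(p), int(dof)


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher's exact p (sum of hypergeometric probabilities not
    exceeding the observed table's)."""
    _, p = sps.fisher_exact(t.as_array(), alternative="two-sided")
    return float(p)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Each argument is either a ``(mean, sd, n)`` summary triple or a vector
    of raw observations. Returns ``(t, df, p)``.
    """
    def to_summary(x) -> tuple[float, float, int]:
        x = np.asarray(x, dtype=float) if not (isinstance(x, tuple) and len(x) == 3) else x
        if isinstance(x, tuple):
            m, s, n = x
        else:
            if x.ndim != 1 or len(x) < 2:
                raise StatsError("raw-vector input needs >= 2 observations")
            m, s, n = float(np.mean(x)), float(np.std(x, ddof=1)), len(x)
        if n < 2 or s < 0:
            raise StatsError("welch_t needs n >= 2 and sd >= 0 in both groups")
        return float(m), float(s), int(n)

    m1, s1, n1 = to_summary(a)
    m2, s2, n2 = to_summary(b)
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise StatsError("zero variance in both groups with unequal means")
    v1, v2 = s1**2 / n1, s2**2 / n2
    tstat = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(tstat), df)
    return float(tstat), float(df), float(p)


# ---------------------------------------------------------------------------
# Cohort-level summaries


def detection_rates(flags: pd.DataFrame) -> dict[str, tuple[int, int, float]]:
    """Per-metric (numerator, denominator, percent) over the cohort."""
    if flags.empty:
        raise StatsError("empty cohort")
    den = len(flags)
    out = {}
    for col in flags.columns:
        num = int(flags[col].sum())
        out[col] = (num, den, percent(num, den))
    return out


def _auto_test(t: TwoByTwo, yates: bool = False) -> tuple[float, str]:
    """chi-squared unless any expected count < 5 (then Fisher), SPSS-style."""
    if (t.expected() < 5).any():
        return fisher_exact(t), "fisher"
    _, p, _ = chi2_test(t, correction=yates)
    return p, "chi2"


def subgroup_analysis(
    flags: pd.DataFrame, clinical: pd.DataFrame, yates: bool = False
) -> pd.DataFrame:
    """One-vs-rest ppCNV enrichment per CHD subgroup.

    For each of the 12 subgroups, builds the 2x2 of (in subgroup vs rest) x
    (ppCNV present vs absent), applies chi-squared (or Fisher when any
    expected count is below 5), and reports the subgroup carrier percentage.
    """
    clinical = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    unknown = set(clinical["subgroup"]) - set(study_data.SUBGROUPS)
    if unknown:
        raise StatsError(f"unknown subgroup labels: {sorted(unknown)}")
    joined = clinical.join(flags["ppcnv"], how="inner")
    if joined["subgroup"].nunique() < 2:
        raise StatsError("subgroup analysis needs at least two subgroups")
    rows = []
    for sg in study_data.SUBGROUPS:
        ing = joined["subgroup"] == sg
        if not ing.any():
            continue
        a = int((ing & joined["ppcnv"]).sum())
        b = int((ing & ~joined["ppcnv"]).sum())
        c = int((~ing & joined["ppcnv"]).sum())
        d = int((~ing & ~joined["ppcnv"]).sum())
        t = TwoByTwo(a, b, c, d)
        p, method = _auto_test(t, yates)
        rows.append(
            {
                "subgroup": sg,
                "n_present": a,
                "n_absent": b,
                "n": a + b,
                "percent_present": percent(a, a + b),
                "p_value": p,
                "method": method,
            }
        )
    return pd.DataFrame(rows)


def build_report(
    flags: pd.DataFrame,
    classified: pd.DataFrame,
    clinical: pd.DataFrame,
    yates: bool = False,
) -> dict:
    """Machine-readable cohort report: rates, group tests, subgroup table.

    Continuous covariates are compared carrier vs non-carrier with Welch's
    t-test; binary covariates with chi-squared/Fisher. Deterministic for
    identical inputs.
    """
    if not set(clinical["sample_id"]).issubset(set(flags.index)):
        raise StatsError("clinical sheet contains samples missing from flags")
    rates = detection_rates(flags)
    cl = clinical.set_index("sample_id").join(flags["ppcnv"], how="inner")
    carrier = cl[cl["ppcnv"]]
    noncarrier = cl[~cl["ppcnv"]]

    tests: dict[str, dict] = {}
    for f in study_data.CONTINUOUS_SUMMARIES:
        if f not in cl.columns:
            continue
        try:
            tstat, df, p = welch_t(carrier[f].to_numpy(), noncarrier[f].to_numpy())
        except StatsError:
            continue  # untestable group structure (e.g. < 2 carriers)
        tests[f] = {"statistic": tstat, "df": df, "p_value": p, "method": "welch_t"}
    binary_fields = [
        f for f in study_data.BINARY_COUNTS
        if f in cl.columns and f not in ("male", "died_1mo")
    ]
    for f in binary_fields:
        t = TwoByTwo(
            int(carrier[f].sum()), int((~carrier[f].astype(bool)).sum()),
            int(noncarrier[f].sum()), int((~noncarrier[f].astype(bool)).sum()),
        )
        try:
            p, method = _auto_test(t, yates)
        except StatsError:
            continue
        tests[f] = {"p_value": p, "method": method}

    category_counts = (
        classified["category"].value_counts().to_dict() if not classified.empty else {}
    )
    report = {
        "n_total": int(len(flags)),
        "n_carrier": int(len(carrier)),
        "n_noncarrier": int(len(noncarrier)),
        "rates": {
            k: {"numerator": n, "denominator": d, "percent": pc}
            for k, (n, d, pc) in rates.items()
        },
        "category_counts": {k: int(v) for k, v in sorted(category_counts.items())},
        "tests": tests,
        "subgroups": subgroup_analysis(flags, clinical, yates).to_dict("records")
        if "subgroup" in clinical.columns
        else [],
    }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
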