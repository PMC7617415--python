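"""2x2 contingency tables and exact association tests over annotated tumors.

The central statistic is the two-sided Fisher exact test under the
minimum-likelihood rule: conditioning on both margins, the p-value is the sum
of hypergeometric point probabilities of every table whose probability does
not exceed that of the observed table.  This is the convention of mainstream
statistical software and reproduces the printed p-values of the source
contingency comparisons (e.g. p = 0.005 for the codon-466 proximal-location
table [[13, 5], [12, 27]]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotate import BrafClass, TumorRecord

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "build_table",
    "fisher_exact_2x2",
    "cohort_summary",
    "benjamini_hochberg",
]

# Relative tie tolerance when comparing hypergeometric point probabilities;
# absorbs floating-point noise in pmf evaluation (same role as the factor
# used by standard implementations).
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")
    n_excluded: int = 0

    def __post_init__(self):
        flat = [c for row in self.counts for c in row]
        if len(self.counts) != 2 or any(len(r) != 2 for r in self.counts):
            raise ValueError("counts must be 2x2")
        if any(c < 0 or int(c) != c for c in flat):
            raise ValueError("counts must be non-negative integers")

    @property
    def a(self):
        return self.counts[0][0]

    @property
    def b(self):
        return self.counts[0][1]

    @property
    def c(self):
        return self.counts[1][0]

    @property
    def d(self):
        return self.counts[1][1]

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(
            ((self.a, self.c), (self.b, self.d)), self.col_labels, self.row_labels
        )


@dataclass(frozen=True)
class AssociationResult:
    table: ContingencyTable
    odds_ratio: float          # sample OR (a*d)/(b*c); inf when b*c == 0 < a*d
    p_two_sided: float
    odds_ratio_defined: bool = True


def fisher_exact_2x2(table: ContingencyTable) -> AssociationResult:
    """Two-sided Fisher exact test (minimum-likelihood rule) on a 2x2 table.

    With both margins fixed, the first cell ``a`` follows a hypergeometric
    law; the two-sided p sums P(A = k) over every k in the support whose
    point probability is <= that of the observed ``a`` (up to a relative tie
    tolerance).  A zero margin makes the table degenerate: p = 1 by
    convention, with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n < 1:
        raise ValueError("table total must be >= 1")
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1 by convention")
        p = 1.0
    else:
        lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, n, r1, c1)
        p_obs = pmf[a - lo]
        p = float(pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())
        # snap to the exact bound when the whole support is included
        p = 1.0 if p >= 1.0 - 1e-12 else p
    if b * c == 0:
        if a * d == 0:
            return AssociationResult(table, math.nan, p, odds_ratio_defined=False)
        return AssociationResult(table, math.inf, p)
    return AssociationResult(table, (a * d) / (b * c), p)


def build_table(
    cohort: Sequence[TumorRecord],
    row_feature: Callable[[TumorRecord], bool | None],
    col_feature: Callable[[TumorRecord], bool | None],
    row_labels: tuple[str, str] = ("row+", "row-"),
    col_labels: tuple[str, str] = ("col+", "col-"),
) -> ContingencyTable:
    """Cross-tabulate two boolean predicates over a cohort.

    A predicate returning ``None`` marks the record as missing for that
    feature; such records are dropped listwise and tallied in
    ``n_excluded``.
    """
    counts = [[0, 0], [0, 0]]
    excluded = 0
    kept = 0
    for rec in cohort:
        r = row_feature(rec)
        c = col_feature(rec)
        if r is None or c is None:
            excluded += 1
            continue
        counts[0 if r else 1][0 if c else 1] += 1
        kept += 1
    if kept == 0:
        raise ValueError("empty cohort after missing-data exclusions")
    return ContingencyTable(
        tuple(tuple(row) for row in counts), row_labels, col_labels, n_excluded=excluded
    )


# Predicate helpers ---------------------------------------------------------

def is_class(cls: BrafClass) -> Callable[[TumorRecord], bool | None]:
    def pred(rec: TumorRecord) -> bool | None:
        if rec.multi_class or rec.braf_class is BrafClass.unclassified:
            return None
        return rec.braf_class is cls
    return pred


def has_additional_ras(rec: TumorRecord) -> bool:
    return rec.additional_ras


def is_proximal(rec: TumorRecord) -> bool | None:
    if rec.location not in ("proximal", "distal"):
        return None
    return rec.location == "proximal"


def is_msi(rec: TumorRecord) -> bool | None:
    if rec.msi_status not in ("MSI", "MSS"):
        return None
    return rec.msi_status == "MSI"


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n if n else math.nan


def cohort_summary(cohort: Sequence[TumorRecord]) -> pd.DataFrame:
    """Per-class clinicopathologic summary in the style of the source table.

    One row per BRAF class (1/2/3), plus unclassified, total BRAF-mutant and
    wild-type rows.  Tumors carrying two distinct BRAF classes are counted in
    the BRAF-mutant totals but excluded from single-class rows.  Percentages
    use non-missing denominators, reported alongside each count.
    """
    n_profiled = len(cohort)
    mutant = [r for r in cohort if r.braf_class is not BrafClass.wild_type]
    multi = [r for r in mutant if r.multi_class]
    rows = []

    def summarise(label: str, recs: list[TumorRecord]) -> dict:
        n = len(recs)
        add = [r for r in recs if r.additional_ras]
        atyp = [r for r in add if r.additional_ras_atypical]
        msi_known = [r for r in recs if r.msi_status in ("MSI", "MSS")]
        loc_known = [r for r in recs if r.location in ("proximal", "distal")]
        sex_known = [r for r in recs if r.sex in ("male", "female")]
        stage_known = [r for r in recs if r.stage in ("I", "II", "III", "IV")]
        ages = [r.age for r in recs if r.age is not None]
        row = {
            "group": label,
            "n_tumors": n,
            "pct_of_profiled": _pct(n, n_profiled),
            "n_additional_ras": len(add),
            "pct_additional_ras": _pct(len(add), n),
            "n_atypical_among_additional": len(atyp),
            "pct_atypical_among_additional": _pct(len(atyp), len(add)),
            "n_msi": sum(r.msi_status == "MSI" for r in msi_known),
            "pct_msi": _pct(sum(r.msi_status == "MSI" for r in msi_known), len(msi_known)),
            "n_msi_known": len(msi_known),
            "n_proximal": sum(r.location == "proximal" for r in loc_known),
            "n_distal": sum(r.location == "distal" for r in loc_known),
            "pct_distal": _pct(sum(r.location == "distal" for r in loc_known), len(loc_known)),
            "n_location_known": len(loc_known),
            "n_male": sum(r.sex == "male" for r in sex_known),
            "pct_male": _pct(sum(r.sex == "male" for r in sex_known), len(sex_known)),
            "mean_age": float(np.mean(ages)) if ages else math.nan,
        }
        for st in ("I", "II", "III", "IV"):
            row[f"n_stage_{st}"] = sum(r.stage == st for r in stage_known)
            row[f"pct_stage_{st}"] = _pct(sum(r.stage == st for r in stage_known), len(stage_known))
        return row

    for cls, label in [
        (BrafClass.class1, "class1"),
        (BrafClass.class2, "class2"),
        (BrafClass.class3, "class3"),
        (BrafClass.unclassified, "unclassified"),
    ]:
        recs = [r for r in mutant if r.braf_class is cls and not r.multi_class]
        rows.append(summarise(label, recs))
    rows.append(summarise("multi_class", multi))
    rows.append(summarise("total_braf_mutant", mutant))
    rows.append(summarise("braf_wild_type", [r for r in cohort if r.braf_class is BrafClass.wild_type]))
    return pd.DataFrame(rows)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (optional; nominal p-values are the default)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(pvals), method="fdr_bh")[1]


def association_to_row(name: str, res: AssociationResult) -> dict:
    t = res.table
    return {
        "comparison": name,
        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
        "row_labels": "|".join(t.row_labels),
        "col_labels": "|".join(t.col_labels),
        "odds_ratio": res.odds_ratio,
        "p_two_sided": res.p_two_sided,
        "n_excluded": t.n_excluded,
    }
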