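"""Purity/copy-number-aware clonality inference for somatic mutations.

For a mutation carried by every cancer cell, the expected variant allele
frequency in a bulk sample of purity ``p`` is

    VAF = p * Nmut / (p * (Nmut + Nwtcan) + 2 * (1 - p))

where ``Nmut`` and ``Nwtcan`` are the mutant- and wild-type-allele copy
numbers per cancer cell and the ``2`` is the diploid wild-type content of the
admixed normal cells.  Inverting for purity,

    purity = 2 / (Nmut / VAF - Nmut - Nwtcan + 2)

which reduces to purity = 2*VAF in the clonal diploid heterozygote.  Because
allele-specific copy-number callers report an unordered pair (major, minor)
without saying which allele carries the mutation, substituting each value as
``Nmut`` in turn generally leaves only one assignment whose implied purity is
consistent with the sample's purity estimate — this is how mutant copy number
is assigned here.  The implied purity divided by the sample purity is the
corrected allele fraction (cancer-cell fraction): 1 means clonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2_contingency

__all__ = [
    "AlleleCopyContext",
    "ClonalityCall",
    "PairClonality",
    "AssignmentStatus",
    "expected_vaf",
    "solve_purity",
    "assign_mutant_copy_number",
    "corrected_allele_fraction",
    "test_pair_clonality",
    "run_pair_table",
]

# Slack above 1 tolerated for an implied purity before it is flagged invalid;
# absorbs sampling noise in the VAF.
PURITY_EPS = 0.05
# |implied - estimated| tolerance for accepting an allele assignment
# (CCube-style purity estimates carry roughly this uncertainty).
ASSIGN_TOL = 0.10


def expected_vaf(purity: float, n_mut: int, n_wt_cancer: int) -> float:
    """Expected VAF of a clonal mutation given purity and allele copy numbers."""
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if n_mut < 0 or n_wt_cancer < 0:
        raise ValueError("copy numbers must be non-negative")
    if n_mut == 0:
        return 0.0
    return purity * n_mut / (purity * (n_mut + n_wt_cancer) + 2.0 * (1.0 - purity))


def solve_purity(
    vaf: float, n_mut: int, n_wt_cancer: int, eps: float = PURITY_EPS
) -> tuple[float, bool]:
    """Invert the VAF relation for purity.

    Returns ``(purity, valid)``; ``valid`` is False when the algebraic
    solution falls outside (0, 1 + eps] (no clonal solution for this
    assignment) or when vaf == 0 (no solution at all).
    """
    if not 0 <= vaf <= 1:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    if n_mut < 1:
        raise ValueError("n_mut must be >= 1 to solve for purity")
    if vaf == 0:
        return 0.0, False
    denom = n_mut / vaf - n_mut - n_wt_cancer + 2.0
    if denom <= 0:
        return math.inf, False
    purity = 2.0 / denom
    return purity, (0.0 < purity <= 1.0 + eps)


class AssignmentStatus(str, Enum):
    unique = "unique"
    ambiguous = "ambiguous"
    no_fit = "no_fit"


@dataclass(frozen=True)
class Assignment:
    n_mut: int
    n_wt_cancer: int
    implied_purity: float
    residual: float           # |implied - sample purity|
    status: AssignmentStatus
    alt_implied_purity: float
    alt_residual: float


def assign_mutant_copy_number(
    vaf: float,
    purity: float,
    allele_cn_pair: tuple[int, int],
    tol: float = ASSIGN_TOL,
) -> Assignment:
    """Decide which allele of a (major, minor) copy-number pair is mutated.

    Both assignments are scored by the purity each implies from the VAF; the
    one closer to the sample purity wins, provided it is within ``tol``.
    Equal-copy pairs are unique by symmetry.  When both assignments fit and
    cannot be told apart the result is flagged ambiguous; when neither fits,
    no_fit (a subclonality signal).
    """
    a, b = allele_cn_pair
    if a < 0 or b < 0:
        raise ValueError("allele copy numbers must be non-negative")
    if max(a, b) < 1:
        raise ValueError("at least one allele copy must be present")
    candidates = []
    for n_mut, n_wt in ((a, b), (b, a)):
        if n_mut < 1:
            continue
        implied, _ = solve_purity(vaf, n_mut, n_wt)
        candidates.append((n_mut, n_wt, implied, abs(implied - purity)))
    candidates.sort(key=lambda t: t[3])
    best = candidates[0]
    alt = candidates[1] if len(candidates) > 1 else best
    if a == b:
        status = AssignmentStatus.unique if best[3] <= tol else AssignmentStatus.no_fit
    elif best[3] > tol:
        status = AssignmentStatus.no_fit
    elif alt[3] <= tol and math.isclose(best[3], alt[3], abs_tol=1e-9):
        status = AssignmentStatus.ambiguous
    else:
        status = AssignmentStatus.unique
    return Assignment(
        n_mut=best[0],
        n_wt_cancer=best[1],
        implied_purity=best[2],
        residual=best[3],
        status=status,
        alt_implied_purity=alt[2],
        alt_residual=alt[3],
    )


@dataclass(frozen=True)
class AlleleCopyContext:
    """Everything needed to place one mutation in the purity/CN model."""

    purity: float
    n_mut: int
    n_wt_cancer: int
    mutant_reads: int
    total_reads: int
    mutation_id: str = ""
    no_fit: bool = False

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.mutant_reads < 0 or self.total_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.mutant_reads > self.total_reads:
            raise ValueError("mutant_reads exceeds total_reads")
        if self.n_mut + self.n_wt_cancer < 1:
            raise ValueError("a mutated locus needs at least one allele copy")

    @property
    def vaf(self) -> float:
        if self.total_reads == 0:
            raise ValueError("zero depth")
        return self.mutant_reads / self.total_reads


def corrected_allele_fraction(ctx: AlleleCopyContext, eps: float = PURITY_EPS) -> float:
    """Fraction of cancer cells carrying the mutation (1.0 = clonal).

    The purity implied by the observed VAF under the clonal model, divided by
    the sample purity, capped at 1 + eps.  Propagates a no-fit flag as NaN.
    """
    if ctx.no_fit:
        return math.nan
    implied, _ = solve_purity(ctx.vaf, ctx.n_mut, ctx.n_wt_cancer)
    return min(implied / ctx.purity, 1.0 + eps)


class ClonalityCall(str, Enum):
    co_clonal = "co_clonal"
    nested = "nested"
    distinct = "distinct"
    ambiguous = "ambiguous"


@dataclass(frozen=True)
class PairClonality:
    mutation_ids: tuple[str, str]
    call: ClonalityCall
    p_binomial: tuple[float, float]       # per-variant clonal-consistency p
    ccf: tuple[float, float]              # corrected allele fractions
    chi2_statistic: float                 # independence test, corrected counts
    p_chi2: float
    chi2_statistic_raw: float             # same test on raw counts
    p_chi2_raw: float


def _clonal_consistency(ctx: AlleleCopyContext) -> tuple[float, float]:
    """Two-sided and one-sided-low binomial p for reads vs the clonal VAF."""
    exp = expected_vaf(ctx.purity, ctx.n_mut, ctx.n_wt_cancer)
    exp = min(max(exp, 1e-12), 1 - 1e-12)
    two = binomtest(ctx.mutant_reads, ctx.total_reads, exp).pvalue
    low = binomtest(ctx.mutant_reads, ctx.total_reads, exp, alternative="less").pvalue
    return two, low


def _corrected_counts(ctx: AlleleCopyContext) -> tuple[float, float]:
    """Mutant/reference read counts rescaled to per-allele-copy units.

    Mutant reads are divided by the mutant copy number; reference reads by
    the total wild-type content per cancer-cell-equivalent
    (Nwtcan + 2 (1 - p)/p), so that a clonal mutation yields equal scaled
    rates regardless of local copy number.
    """
    m = ctx.mutant_reads / max(ctx.n_mut, 1)
    wt_content = ctx.n_wt_cancer + 2.0 * (1.0 - ctx.purity) / ctx.purity
    r = (ctx.total_reads - ctx.mutant_reads) / max(wt_content, 1e-9)
    return m, r


def test_pair_clonality(
    ctx_a: AlleleCopyContext,
    ctx_b: AlleleCopyContext,
    alpha: float = 0.05,
) -> PairClonality:
    """Test whether two mutations in one tumor occupy the same clone.

    (i) each variant's mutant read count is tested against its expected
    clonal VAF (exact binomial, two-sided); (ii) the two variants'
    copy-number-corrected mutant/reference counts are compared by a Pearson
    chi-square test of independence.  Both variants consistent with
    clonality -> co_clonal; exactly one consistent and the other
    significantly below its clonal expectation -> nested; both below with
    corrected fractions summing to <= 1 -> distinct; otherwise ambiguous.

    ``alpha`` is the nominal level of the pair-level co-clonality decision;
    since that decision requires two per-variant tests to pass jointly, each
    is run at the Sidak-corrected level 1 - (1 - alpha)^(1/2), keeping the
    rate at which a truly co-clonal pair is mislabelled near ``alpha``.
    """
    for ctx in (ctx_a, ctx_b):
        if ctx.total_reads == 0:
            raise ValueError("zero depth in clonality test")
    alpha_variant = 1.0 - (1.0 - alpha) ** 0.5
    p2a, plo_a = _clonal_consistency(ctx_a)
    p2b, plo_b = _clonal_consistency(ctx_b)
    ccf_a = corrected_allele_fraction(ctx_a)
    ccf_b = corrected_allele_fraction(ctx_b)

    ma, ra = _corrected_counts(ctx_a)
    mb, rb = _corrected_counts(ctx_b)
    obs = np.array([[ma, ra], [mb, rb]])
    if obs.sum() == 0 or (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        chi2_stat, p_chi2 = math.nan, math.nan
    else:
        chi2_stat, p_chi2, _, _ = chi2_contingency(obs, correction=False)
    raw = np.array(
        [
            [ctx_a.mutant_reads, ctx_a.total_reads - ctx_a.mutant_reads],
            [ctx_b.mutant_reads, ctx_b.total_reads - ctx_b.mutant_reads],
        ]
    )
    if raw.sum() == 0 or (raw.sum(axis=0) == 0).any() or (raw.sum(axis=1) == 0).any():
        chi2_raw, p_raw = math.nan, math.nan
    else:
        chi2_raw, p_raw, _, _ = chi2_contingency(raw, correction=False)

    pass_a = p2a >= alpha_variant
    pass_b = p2b >= alpha_variant
    if pass_a and pass_b:
        call = ClonalityCall.co_clonal
    elif pass_a != pass_b:
        # the failing variant must be significantly *below* clonal expectation
        fail_low = (plo_b < alpha_variant) if pass_a else (plo_a < alpha_variant)
        call = ClonalityCall.nested if fail_low else ClonalityCall.ambiguous
    elif (not pass_a) and (not pass_b) and (ccf_a + ccf_b) <= 1.0:
        call = ClonalityCall.distinct
    else:
        call = ClonalityCall.ambiguous
    return PairClonality(
        mutation_ids=(ctx_a.mutation_id, ctx_b.mutation_id),
        call=call,
        p_binomial=(p2a, p2b),
        ccf=(ccf_a, ccf_b),
        chi2_statistic=float(chi2_stat),
        p_chi2=float(p_chi2),
        chi2_statistic_raw=float(chi2_raw),
        p_chi2_raw=float(p_raw),
    )


# TSV-level driver ----------------------------------------------------------

def _segment_lookup(segments: pd.DataFrame, sample_id: str, chrom: str, pos: int):
    """Find (major, minor) for a 0-based position in half-open segments."""
    seg = segments[
        (segments["sample_id"] == sample_id)
        & (segments["chromosome"].astype(str) == str(chrom))
        & (segments["start"] <= pos)
        & (pos < segments["end"])
    ]
    if seg.empty:
        return None
    row = seg.iloc[0]
    return int(row["major_cn"]), int(row["minor_cn"])


def build_context(
    mutant_reads: int,
    total_reads: int,
    purity: float,
    allele_cn_pair: tuple[int, int],
    mutation_id: str = "",
    tol: float = ASSIGN_TOL,
) -> tuple[AlleleCopyContext, Assignment]:
    """Assign allele copy numbers from a segment pair and wrap into a context."""
    vaf = mutant_reads / total_reads
    assignment = assign_mutant_copy_number(vaf, purity, allele_cn_pair, tol=tol)
    ctx = AlleleCopyContext(
        purity=purity,
        n_mut=assignment.n_mut,
        n_wt_cancer=assignment.n_wt_cancer,
        mutant_reads=mutant_reads,
        total_reads=total_reads,
        mutation_id=mutation_id,
        no_fit=assignment.status is AssignmentStatus.no_fit,
    )
    return ctx, assignment


def run_pair_table(
    reads: pd.DataFrame,
    purity: pd.DataFrame,
    pairs: pd.DataFrame,
    segments: pd.DataFrame | None = None,
    cn_map: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Clonality-call every (sample, mutation A, mutation B) row of ``pairs``.

    Copy numbers come either from Battenberg-style ``segments``
    (chromosome/start/end/major_cn/minor_cn, 0-based half-open; requires
    chromosome+position columns in ``reads``) or from a direct ``cn_map``
    (sample_id, mutation_id, major_cn, minor_cn).
    """
    purity_by_id = dict(zip(purity["sample_id"].astype(str), purity["purity"]))
    reads_idx = reads.set_index(["sample_id", "mutation_id"])
    rows = []
    for _, pair in pairs.iterrows():
        sid = str(pair["sample_id"])
        p = float(purity_by_id[sid])
        ctxs = []
        for key in ("mutation_a", "mutation_b"):
            mid = str(pair[key])
            r = reads_idx.loc[(sid, mid)]
            if cn_map is not None:
                cn_row = cn_map[
                    (cn_map["sample_id"].astype(str) == sid)
                    & (cn_map["mutation_id"].astype(str) == mid)
                ].iloc[0]
                pair_cn = (int(cn_row["major_cn"]), int(cn_row["minor_cn"]))
            elif segments is not None:
                pair_cn = _segment_lookup(segments, sid, r["chromosome"], int(r["position"]))
                if pair_cn is None:
                    raise ValueError(f"no copy-number segment covers {sid}:{mid}")
            else:
                raise ValueError("need either segments or cn_map")
            ctx, assignment = build_context(
                int(r["mutant_reads"]), int(r["total_reads"]), p, pair_cn, mutation_id=mid
            )
            ctxs.append((ctx, assignment))
        (ctx_a, asg_a), (ctx_b, asg_b) = ctxs
        res = test_pair_clonality(ctx_a, ctx_b, alpha=alpha)
        rows.append(
            {
                "sample_id": sid,
                "mutation_a": res.mutation_ids[0],
                "mutation_b": res.mutation_ids[1],
                "call": res.call.value,
                "n_mut_a": ctx_a.n_mut, "n_wt_a": ctx_a.n_wt_cancer,
                "n_mut_b": ctx_b.n_mut, "n_wt_b": ctx_b.n_wt_cancer,
                "assignment_a": asg_a.status.value,
                "assignment_b": asg_b.status.value,
                "implied_purity_a": asg_a.implied_purity,
                "implied_purity_b": asg_b.implied_purity,
                "ccf_a": res.ccf[0], "ccf_b": res.ccf[1],
                "p_binomial_a": res.p_binomial[0],
                "p_binomial_b": res.p_binomial[1],
                "chi2_statistic": res.chi2_statistic,
                "p_chi2": res.p_chi2,
                "chi2_statistic_raw": res.chi2_statistic_raw,
                "p_chi2_raw": res.p_chi2_raw,
            }
        )
    return pd.DataFrame(rows)
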