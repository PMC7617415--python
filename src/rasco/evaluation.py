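"""End-to-end recomputation of the analysis' headline quantities.

Every function here rebuilds its inputs (from the printed combined-cohort
margins or from the seeded generators), runs the package's own operations
and measures the result; nothing is read off a lookup table.  Used by the
acceptance script and the acceptance tests.
"""

from __future__ import annotations

import numpy as np

from .annotate import BrafClass
from .clonality import (
    AssignmentStatus,
    ClonalityCall,
    assign_mutant_copy_number,
    build_context,
    expected_vaf,
    solve_purity,
    test_pair_clonality,
)
from .cooccur import ContingencyTable, cohort_summary, fisher_exact_2x2
from .published import ATYPICAL_KRAS, CODON466_LOCATION_TABLE, reconstruct_cohort
from .simulate import (
    CatalogConfig,
    CohortConfig,
    ReadSimConfig,
    default_channel_vector,
    generate_catalog,
    generate_cohort,
    generate_read_counts,
)
from .annotate import annotate_cohort
from .spectra import CHANNELS, CausalChannelSet, causal_channel_proportion, spectra_from_catalog


def printed_cohort_statistics() -> dict[str, float]:
    """Class-wise proportions and the codon-466 Fisher test, recomputed from
    a cohort reconstructed to the printed combined-cohort margins."""
    cohort = reconstruct_cohort()
    s = cohort_summary(cohort).set_index("group")
    res = fisher_exact_2x2(CODON466_LOCATION_TABLE)
    stats = {
        "class1_pct_of_profiled": float(s.loc["class1", "pct_of_profiled"]),
        "class2_pct_of_profiled": float(s.loc["class2", "pct_of_profiled"]),
        "class3_pct_of_profiled": float(s.loc["class3", "pct_of_profiled"]),
        "class1_pct_additional_ras": float(s.loc["class1", "pct_additional_ras"]),
        "class2_pct_additional_ras": float(s.loc["class2", "pct_additional_ras"]),
        "class3_pct_additional_ras": float(s.loc["class3", "pct_additional_ras"]),
        "class1_pct_msi": float(s.loc["class1", "pct_msi"]),
        "codon466_location_fisher_p": res.p_two_sided,
        "codon466_location_odds_ratio": res.odds_ratio,
    }
    # distal fraction pooled over classes 2 and 3 (their printed location data)
    n_distal = s.loc["class2", "n_distal"] + s.loc["class3", "n_distal"]
    n_known = s.loc["class2", "n_location_known"] + s.loc["class3", "n_location_known"]
    stats["class2_3_pct_distal"] = 100.0 * float(n_distal) / float(n_known)
    # class 3 vs class 1 additional-Ras enrichment, recomputed from the flags
    t31 = _class_vs_class_table(cohort, BrafClass.class3, BrafClass.class1)
    stats["class3_vs_class1_fisher_p"] = fisher_exact_2x2(t31).p_two_sided
    return stats


def _class_vs_class_table(cohort, cls_a, cls_b) -> ContingencyTable:
    def cell(cls, flag):
        return sum(
            1
            for r in cohort
            if r.braf_class is cls and not r.multi_class and r.additional_ras is flag
        )
    return ContingencyTable(
        ((cell(cls_a, True), cell(cls_a, False)), (cell(cls_b, True), cell(cls_b, False))),
        row_labels=(cls_a.value, cls_b.value),
        col_labels=("additional_ras", "no_additional_ras"),
    )


def atypical_kras_breakdown() -> dict[str, float]:
    """Recount the atypical-KRAS co-mutation breakdown from its margins."""
    n = ATYPICAL_KRAS["n"]
    flags = (
        ["none"] * ATYPICAL_KRAS["no_additional"]
        + ["class3_braf"] * ATYPICAL_KRAS["class3_braf"]
        + ["typical_kras"] * ATYPICAL_KRAS["typical_kras"]
    )
    flags += ["other"] * (n - len(flags))
    return {
        "atypical_kras_pct_no_additional": 100.0 * flags.count("none") / n,
        "atypical_kras_pct_class3_braf": 100.0 * flags.count("class3_braf") / n,
        "atypical_kras_pct_typical_kras": 100.0 * flags.count("typical_kras") / n,
    }


def eq_a_diagnostics() -> dict[str, float]:
    """Analytic checks of the purity-VAF-copy-number relation."""
    max_roundtrip = 0.0
    for p in np.arange(0.1, 1.0001, 0.1):
        for m in (1, 2, 3):
            for w in (0, 1, 2):
                implied, _ = solve_purity(expected_vaf(p, m, w), m, w)
                max_roundtrip = max(max_roundtrip, abs(implied - p))
    max_diploid = max(
        abs(expected_vaf(p, 1, 1) - p / 2) for p in np.linspace(0.05, 1.0, 50)
    )
    return {
        "eqA_max_roundtrip_error": max_roundtrip,
        "eqA_max_diploid_deviation": max_diploid,
        "eqA_diploid_het_vaf_pure_tumor": expected_vaf(1.0, 1, 1),
    }


def clonality_recovery(
    seed: int, n_pairs: int = 200, purity: float = 0.7
) -> dict[str, float]:
    """Simulate co-clonal and subclonal tumor pairs and score call recovery.

    Two scenarios of ``n_pairs`` tumors each at the stated purity, depths
    uniform on [200, 1000]: both mutations clonal (truth co_clonal) vs one
    clonal and one in 30% of cancer cells (truth non-co-clonal).  Accuracy is
    the pooled fraction of pairs whose call is co_clonal exactly when the
    truth is.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 1011])
    states = [(1, 1), (2, 1), (2, 2)]
    accuracy = {}
    for scenario, ccfs in [("co_clonal", (1.0, 1.0)), ("subclonal", (1.0, 0.3))]:
        correct = 0
        for _ in range(n_pairs):
            ctxs = []
            for ccf in ccfs:
                major, minor = states[rng.integers(len(states))]
                n_mut = int(rng.choice([major, minor]))
                n_wt = major + minor - n_mut
                depth = int(rng.integers(200, 1001))
                vaf = ccf * expected_vaf(purity, n_mut, n_wt)
                mutant = int(rng.binomial(depth, vaf))
                ctx, _ = build_context(mutant, depth, purity, (major, minor))
                ctxs.append(ctx)
            call = test_pair_clonality(ctxs[0], ctxs[1]).call
            if scenario == "co_clonal":
                correct += call is ClonalityCall.co_clonal
            else:
                correct += call is not ClonalityCall.co_clonal
        accuracy[scenario] = correct / n_pairs
    return {
        "clonality_recovery_co_clonal": accuracy["co_clonal"],
        "clonality_recovery_subclonal": accuracy["subclonal"],
        "clonality_recovery_pooled": (accuracy["co_clonal"] + accuracy["subclonal"]) / 2,
    }


def assignment_recovery(seed: int, n_mutations: int = 500) -> dict[str, float]:
    """Fraction of unambiguous simulated cases where the generating
    (n_mut, n_wt) assignment is recovered at depth >= 500."""
    truth = generate_read_counts(
        ReadSimConfig(n_mutations=n_mutations, depth_low=500, depth_high=1500),
        seed=int(seed) % (2**31),
    )
    hits = total = 0
    for _, row in truth.iterrows():
        if row["major_cn"] == row["minor_cn"] or row["mutant_reads"] == 0:
            continue
        asg = assign_mutant_copy_number(
            row["mutant_reads"] / row["total_reads"],
            row["purity"],
            (int(row["major_cn"]), int(row["minor_cn"])),
        )
        if asg.status is not AssignmentStatus.unique:
            continue
        total += 1
        hits += (asg.n_mut, asg.n_wt_cancer) == (int(row["n_mut"]), int(row["n_wt"]))
    return {
        "cn_assignment_recovery": hits / total if total else float("nan"),
        "cn_assignment_n_scored": total,
    }


def spectrum_recovery(seed: int, n_mutations: int = 10_000) -> dict[str, float]:
    """Draw a catalog from the default 96-vector and measure recovery."""
    vec = default_channel_vector()
    cat = generate_catalog(
        CatalogConfig(n_samples=1, mutations_per_sample=n_mutations, channel_probs=vec),
        seed=int(seed) % (2**31),
    )
    (spectrum,) = spectra_from_catalog(cat)
    half1 = CausalChannelSet("h1", frozenset(CHANNELS[:48]))
    half2 = CausalChannelSet("h2", frozenset(CHANNELS[48:]))
    return {
        "spectrum_weight_sum": float(spectrum.channel_weights.sum()),
        "spectrum_max_channel_deviation": float(
            np.max(np.abs(spectrum.channel_weights - vec))
        ),
        "spectrum_partition_proportion_sum": causal_channel_proportion(spectrum, half1)
        + causal_channel_proportion(spectrum, half2),
    }


def generator_fidelity(seed: int, n_tumors: int = 10_000) -> dict[str, float]:
    """Annotate a default synthetic cohort and report key recovered rates."""
    cfg = CohortConfig(n_tumors=n_tumors)
    muts, clin = generate_cohort(cfg, seed=int(seed) % (2**31))
    recs = annotate_cohort(muts, clin, all_sample_ids=clin["sample_id"].tolist())
    s = cohort_summary(recs).set_index("group")
    out = {}
    for cls in ("class1", "class2", "class3"):
        out[f"sim_{cls}_frequency"] = float(s.loc[cls, "n_tumors"]) / n_tumors
        out[f"sim_{cls}_pct_additional_ras"] = float(s.loc[cls, "pct_additional_ras"])
    out["sim_class1_pct_msi"] = float(s.loc["class1", "pct_msi"])
    out["sim_class3_pct_distal"] = float(s.loc["class3", "pct_distal"])
    return out
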