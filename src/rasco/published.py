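"""Printed summary counts of the combined published cohort, as analysis inputs.

The study's per-patient data are access-controlled; what is public is the
aggregate contingency structure: per-class tumor counts, additional-Ras
co-occurrence counts, MSI/location denominators, the codon-466 location
table, and the atypical-KRAS breakdown.  These counts are inputs to the
pipeline — tumor-record cohorts are reconstructed from them so that the
summary and exact-test operations recompute the published proportions and
p-values from scratch rather than copying them.

Reconstruction assigns marginal flags independently (the joint distribution
beyond the printed margins is unknown); every statistic computed from these
cohorts therefore only uses printed margins and tables.
"""

from __future__ import annotations

from .annotate import BrafClass, BrafDomain, TumorRecord
from .cooccur import ContingencyTable

__all__ = ["COMBINED_COHORT", "CODON466_LOCATION_TABLE", "ATYPICAL_KRAS", "reconstruct_cohort"]

# Combined-cohort summary counts per BRAF class.
# msi / location counts are over tumors with that datum available.
COMBINED_COHORT = {
    "n_profiled": 6605,
    "class1": {
        "n": 709,
        "additional_ras": 17,
        "atypical_among_additional": 13,
        "msi": 275, "msi_known": 525,
        "proximal": 452, "distal": 88,
    },
    "class2": {
        "n": 31,
        "additional_ras": 9,
        "atypical_among_additional": 5,
        "msi": 0, "msi_known": 23,
        "proximal": 9, "distal": 15,
    },
    "class3": {
        "n": 81,
        "additional_ras": 37,
        "atypical_among_additional": 29,
        "msi": 0, "msi_known": 69,
        "proximal": 25, "distal": 32,
    },
}

# Class-3 tumors by codon (466 vs other) and location (proximal vs distal):
# 13/18 codon-466 tumors proximal vs 12/39 for other class-3 variants.
CODON466_LOCATION_TABLE = ContingencyTable(
    ((13, 5), (12, 27)),
    row_labels=("codon466", "other_class3"),
    col_labels=("proximal", "distal"),
)

# Breakdown of the 335 tumors carrying an atypical KRAS mutation.
ATYPICAL_KRAS = {
    "n": 335,
    "no_additional": 291,      # no further BRAF/NRAS/NF1/typical-KRAS driver
    "class3_braf": 18,         # co-occurring BRAF, all class 3
    "typical_kras": 13,        # co-occurring typical KRAS hotspot mutation
    "nras_nf1_among_no_braf": 13,
    "no_braf": 317,
}


def _cls_enum(name: str) -> BrafClass:
    return BrafClass(name)


def reconstruct_cohort() -> list[TumorRecord]:
    """Rebuild a tumor-record cohort matching the printed class margins.

    Flags are assigned column-wise to match each printed margin: counts of
    additional-Ras (with the atypical subset nested inside it), MSI status
    over its own denominator, and location over its denominator.  Tumors
    outside a denominator carry "unknown".  BRAF wild-type and unclassified
    tumors fill the cohort to the profiled total so percent-of-profiled
    denominators are correct.
    """
    records: list[TumorRecord] = []
    i = 0
    for cls in ("class1", "class2", "class3"):
        c = COMBINED_COHORT[cls]
        for j in range(c["n"]):
            add = j < c["additional_ras"]
            atyp = j < c["atypical_among_additional"]
            if j < c["msi"]:
                msi = "MSI"
            elif j < c["msi_known"]:
                msi = "MSS"
            else:
                msi = "unknown"
            if j < c["proximal"]:
                loc = "proximal"
            elif j < c["proximal"] + c["distal"]:
                loc = "distal"
            else:
                loc = "unknown"
            records.append(
                TumorRecord(
                    sample_id=f"P{i:05d}",
                    braf_class=_cls_enum(cls),
                    braf_classes=frozenset({_cls_enum(cls)}),
                    braf_domain=BrafDomain.unassigned,
                    additional_ras=add,
                    additional_ras_atypical=add and atyp,
                    msi_status=msi,
                    location=loc,
                )
            )
            i += 1
    while i < COMBINED_COHORT["n_profiled"]:
        records.append(TumorRecord(sample_id=f"P{i:05d}"))
        i += 1
    return records
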