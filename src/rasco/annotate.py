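"""Driver-mutation classification for BRAF and other Ras-pathway genes.

BRAF missense mutations are grouped into three functional classes by codon:
class 1 (codon 600, V600E-type constitutively active monomers), class 2
(codons 464/469/597/601, Ras-independent active dimers) and class 3
(codons 466/581/594/595/596, kinase-impaired mutants that signal through
Ras-dependent BRAF-CRAF heterodimers).  A parallel positional scheme labels
the same mutations by protein domain: A (codon 600), B (codons 581-601
excluding 600) and C (the ATP-binding site, codons 464/466/469).

KRAS substitutions at the 12/13/61 hotspots are "typical" drivers; those at a
prespecified list of weaker pathogenic codons are "atypical".  All pathogenic
NRAS substitutions (codons 12/13/61) and protein-truncating NF1 mutations are
also counted as atypical Ras-pathway drivers, reflecting their low frequency
in colorectal cancer.

The codon sets live in ``data/rules.yaml`` so they can be edited without code
changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Consequence",
    "BrafClass",
    "BrafDomain",
    "RasCategory",
    "VariantCall",
    "TumorRecord",
    "ClassificationRules",
    "ProteinChangeError",
    "parse_protein_change",
    "classify_braf",
    "classify_braf_domain",
    "classify_ras_pathway",
    "annotate_tumor",
    "annotate_cohort",
    "read_mutation_table",
    "read_clinical_table",
    "write_annotated_table",
]


class Consequence(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splice = "splice"
    synonymous = "synonymous"
    other = "other"


class BrafClass(str, Enum):
    class1 = "class1"
    class2 = "class2"
    class3 = "class3"
    unclassified = "unclassified"
    wild_type = "wild_type"


class BrafDomain(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    unassigned = "unassigned"


class RasCategory(str, Enum):
    kras_typical = "kras_typical"
    atypical_ras = "atypical_ras"
    non_driver = "non_driver"


class ProteinChangeError(ValueError):
    """Raised when an HGVS p. short string cannot be parsed."""


_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}
_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

_PC_RE = re.compile(
    r"^(?:p\.)?"
    r"(?P<ref>[A-Z][a-z]{2}|[A-Z\*])"
    r"(?P<codon>\d+)"
    r"(?P<alt>fs\*?\d*|fs|[A-Z][a-z]{2}|[A-Z\*]|del|dup|=)$"
)


def _norm_aa(token: str) -> str:
    if token in _AA3TO1:
        return _AA3TO1[token]
    return token


def parse_protein_change(protein_change: str) -> tuple[int, str, str, Consequence]:
    """Parse an HGVS p. short string like ``V600E`` into its parts.

    Returns ``(codon, ref_aa, alt_aa, consequence)``.  Three-letter amino-acid
    codes and a leading ``p.`` prefix are accepted and normalised.  ``*``
    (or ``Ter``) as the alternate residue means nonsense; ``fs`` means
    frameshift; identical residues (or ``=``) mean synonymous.
    """
    if not protein_change or not isinstance(protein_change, str):
        raise ProteinChangeError(f"empty protein change: {protein_change!r}")
    s = protein_change.strip()
    m = _PC_RE.match(s)
    if m is None:
        raise ProteinChangeError(f"cannot parse protein change {protein_change!r}")
    ref = _norm_aa(m.group("ref"))
    alt_tok = m.group("alt")
    codon = int(m.group("codon"))
    if codon < 1:
        raise ProteinChangeError(f"codon must be >= 1 in {protein_change!r}")
    if ref not in _AA1 and ref != "*":
        raise ProteinChangeError(f"invalid reference residue in {protein_change!r}")
    if alt_tok.startswith("fs"):
        return codon, ref, "fs", Consequence.frameshift
    if alt_tok in ("del", "dup"):
        return codon, ref, alt_tok, Consequence.other
    alt = _norm_aa(alt_tok)
    if alt == "=":
        return codon, ref, ref, Consequence.synonymous
    if alt == "*":
        return codon, ref, "*", Consequence.nonsense
    if alt not in _AA1:
        raise ProteinChangeError(f"invalid alternate residue in {protein_change!r}")
    if alt == ref:
        return codon, ref, alt, Consequence.synonymous
    return codon, ref, alt, Consequence.missense


_DNA = set("ACGT")


@dataclass(frozen=True)
class VariantCall:
    """One somatic mutation call, protein-level with optional read support."""

    sample_id: str
    gene: str
    protein_change: str
    codon: int | None = None
    consequence: Consequence | None = None
    trinucleotide_context: str | None = None
    ref_base: str | None = None
    alt_base: str | None = None
    mutant_reads: int | None = None
    total_reads: int | None = None

    def __post_init__(self):
        # Fill codon/consequence from the protein change when absent.
        if self.codon is None or self.consequence is None:
            codon, _, _, cons = parse_protein_change(self.protein_change)
            if self.codon is None:
                object.__setattr__(self, "codon", codon)
            if self.consequence is None:
                object.__setattr__(self, "consequence", cons)
        if self.codon is not None and self.codon < 1:
            raise ValueError(f"codon must be >= 1, got {self.codon}")
        ctx = self.trinucleotide_context
        if ctx is not None:
            if len(ctx) != 3 or set(ctx) - _DNA:
                raise ValueError(f"bad trinucleotide context {ctx!r}")
            if self.ref_base is not None and ctx[1] != self.ref_base:
                raise ValueError(
                    f"context {ctx!r} centre does not match ref base {self.ref_base!r}"
                )
        if self.mutant_reads is not None and self.total_reads is not None:
            if self.mutant_reads > self.total_reads:
                raise ValueError("mutant_reads exceeds total_reads")


def _codon_set(values: Iterable[int]) -> frozenset[int]:
    return frozenset(int(v) for v in values)


@dataclass(frozen=True)
class ClassificationRules:
    """Codon rule tables; see ``data/rules.yaml`` for the packaged defaults."""

    braf_class1_codons: frozenset[int] = frozenset({600})
    braf_class2_codons: frozenset[int] = frozenset({464, 469, 597, 601})
    braf_class3_codons: frozenset[int] = frozenset({466, 581, 594, 595, 596})
    braf_domain_A: frozenset[int] = frozenset({600})
    braf_domain_B: frozenset[int] = frozenset(range(581, 602)) - {600}
    braf_domain_C: frozenset[int] = frozenset({464, 466, 469})
    kras_typical_codons: frozenset[int] = frozenset({12, 13, 61})
    kras_atypical_codons: frozenset[int] = frozenset(
        {14, 19, 22, 33, 34, 59, 60, 68, 117, 146, 147}
    )
    nras_pathogenic_codons: frozenset[int] = frozenset({12, 13, 61})
    nf1_truncating: frozenset[Consequence] = frozenset(
        {Consequence.nonsense, Consequence.frameshift, Consequence.splice}
    )

    def __post_init__(self):
        classes = [self.braf_class1_codons, self.braf_class2_codons, self.braf_class3_codons]
        for i in range(3):
            for j in range(i + 1, 3):
                if classes[i] & classes[j]:
                    raise ValueError("BRAF class codon sets must be pairwise disjoint")
        domains = [self.braf_domain_A, self.braf_domain_B, self.braf_domain_C]
        for i in range(3):
            for j in range(i + 1, 3):
                if domains[i] & domains[j]:
                    raise ValueError("BRAF domain sets must be pairwise disjoint")
        if self.kras_typical_codons & self.kras_atypical_codons:
            raise ValueError("KRAS typical and atypical codon sets must be disjoint")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "ClassificationRules":
        if path is None:
            text = resources.files("rasco").joinpath("data/rules.yaml").read_text()
        else:
            text = Path(path).read_text()
        cfg = yaml.safe_load(text)
        braf, kras = cfg["braf"], cfg["kras"]
        lo, hi = braf["domain_B_range"]
        domain_b = set(range(int(lo), int(hi) + 1)) - set(braf.get("domain_B_exclude", []))
        trunc = {Consequence(c) for c in cfg["nf1"]["truncating_consequences"]}
        if cfg["nf1"].get("include_splice", True):
            trunc.add(Consequence.splice)
        return cls(
            braf_class1_codons=_codon_set(braf["class1_codons"]),
            braf_class2_codons=_codon_set(braf["class2_codons"]),
            braf_class3_codons=_codon_set(braf["class3_codons"]),
            braf_domain_A=_codon_set(braf["domain_A"]),
            braf_domain_B=frozenset(domain_b),
            braf_domain_C=_codon_set(braf["domain_C"]),
            kras_typical_codons=_codon_set(kras["typical_codons"]),
            kras_atypical_codons=_codon_set(kras["atypical_codons"]),
            nras_pathogenic_codons=_codon_set(cfg["nras"]["pathogenic_codons"]),
            nf1_truncating=frozenset(trunc),
        )


DEFAULT_RULES = ClassificationRules.from_yaml()


def classify_braf(variant: VariantCall, rules: ClassificationRules = DEFAULT_RULES) -> BrafClass:
    """Assign a BRAF variant to functional class 1, 2 or 3 by codon.

    Only missense changes at the listed codons are classifiable; everything
    else is ``unclassified`` (treated as a passenger in class-based analyses).
    """
    if variant.gene.upper() != "BRAF":
        raise ValueError(f"classify_braf requires a BRAF variant, got {variant.gene}")
    if variant.consequence is not Consequence.missense:
        return BrafClass.unclassified
    if variant.codon in rules.braf_class1_codons:
        return BrafClass.class1
    if variant.codon in rules.braf_class2_codons:
        return BrafClass.class2
    if variant.codon in rules.braf_class3_codons:
        return BrafClass.class3
    return BrafClass.unclassified


def classify_braf_domain(
    variant: VariantCall, rules: ClassificationRules = DEFAULT_RULES
) -> BrafDomain:
    """Positional A/B/C domain label for a BRAF missense variant."""
    if variant.gene.upper() != "BRAF":
        raise ValueError(f"classify_braf_domain requires a BRAF variant, got {variant.gene}")
    if variant.consequence is not Consequence.missense:
        return BrafDomain.unassigned
    if variant.codon in rules.braf_domain_A:
        return BrafDomain.A
    if variant.codon in rules.braf_domain_B:
        return BrafDomain.B
    if variant.codon in rules.braf_domain_C:
        return BrafDomain.C
    return BrafDomain.unassigned


_RAS_GENES = {"KRAS", "NRAS", "NF1"}


def classify_ras_pathway(
    variant: VariantCall, rules: ClassificationRules = DEFAULT_RULES
) -> RasCategory:
    """Classify a KRAS/NRAS/NF1 variant as a typical or atypical Ras driver.

    KRAS hotspot (12/13/61) substitutions are typical; KRAS substitutions at
    the prespecified weak-pathogenic codons, any pathogenic NRAS substitution,
    and protein-truncating NF1 changes are all atypical Ras-pathway drivers.
    """
    gene = variant.gene.upper()
    if gene not in _RAS_GENES:
        raise ValueError(f"classify_ras_pathway does not handle gene {variant.gene}")
    if gene == "KRAS":
        if variant.consequence is Consequence.missense:
            if variant.codon in rules.kras_typical_codons:
                return RasCategory.kras_typical
            if variant.codon in rules.kras_atypical_codons:
                return RasCategory.atypical_ras
        return RasCategory.non_driver
    if gene == "NRAS":
        if (
            variant.consequence is Consequence.missense
            and variant.codon in rules.nras_pathogenic_codons
        ):
            return RasCategory.atypical_ras
        return RasCategory.non_driver
    # NF1: protein-truncating only
    if variant.consequence in rules.nf1_truncating:
        return RasCategory.atypical_ras
    return RasCategory.non_driver


@dataclass
class TumorRecord:
    """Tumor-level annotation rolled up from its variant calls."""

    sample_id: str
    braf_class: BrafClass = BrafClass.wild_type
    braf_classes: frozenset[BrafClass] = frozenset()
    braf_domain: BrafDomain = BrafDomain.unassigned
    additional_ras: bool = False
    additional_ras_atypical: bool = False
    msi_status: str = "unknown"    # MSI | MSS | unknown
    location: str = "unknown"      # proximal | distal | unknown
    age: float | None = None
    sex: str = "unknown"
    stage: str = "unknown"
    braf_codons: tuple[int, ...] = ()

    def __post_init__(self):
        if self.braf_class is BrafClass.wild_type and self.braf_domain is not BrafDomain.unassigned:
            raise ValueError("wild-type BRAF cannot carry a domain label")
        if self.additional_ras_atypical and not self.additional_ras:
            raise ValueError("additional_ras_atypical implies additional_ras")

    @property
    def multi_class(self) -> bool:
        return len(self.braf_classes) > 1


_CLASS_TO_DOMAIN_PRIORITY = [BrafClass.class1, BrafClass.class2, BrafClass.class3]


def annotate_tumor(
    sample_id: str,
    variants: Sequence[VariantCall],
    clinical: Mapping[str, object] | None = None,
    rules: ClassificationRules = DEFAULT_RULES,
) -> TumorRecord:
    """Roll up a tumor's variant calls into a :class:`TumorRecord`.

    The full set of distinct BRAF classes present is retained; tumors with
    more than one distinct class keep ``braf_class`` set to the first by
    class-number order but are flagged ``multi_class`` and are excluded from
    single-class denominators by the summary code.  ``additional_ras`` is true
    iff any KRAS/NRAS/NF1 variant is pathogenic; ``additional_ras_atypical``
    iff any of those is atypical.
    """
    ids = {v.sample_id for v in variants}
    if ids and ids != {sample_id}:
        raise ValueError(f"variants carry sample ids {ids}, expected {{{sample_id!r}}}")

    braf_classes: set[BrafClass] = set()
    braf_domain = BrafDomain.unassigned
    braf_codons: list[int] = []
    any_braf = False
    additional_ras = False
    additional_atypical = False
    for v in sorted(variants, key=lambda v: (v.gene.upper(), v.codon or 0, v.protein_change)):
        gene = v.gene.upper()
        if gene == "BRAF":
            any_braf = True
            braf_codons.append(int(v.codon))
            c = classify_braf(v, rules)
            if c is not BrafClass.unclassified:
                braf_classes.add(c)
            d = classify_braf_domain(v, rules)
            if d is not BrafDomain.unassigned and braf_domain is BrafDomain.unassigned:
                braf_domain = d
        elif gene in _RAS_GENES:
            cat = classify_ras_pathway(v, rules)
            if cat is not RasCategory.non_driver:
                additional_ras = True
            if cat is RasCategory.atypical_ras:
                additional_atypical = True

    if not any_braf:
        braf_class = BrafClass.wild_type
    elif not braf_classes:
        braf_class = BrafClass.unclassified
    else:
        braf_class = next(c for c in _CLASS_TO_DOMAIN_PRIORITY if c in braf_classes)

    clinical = dict(clinical or {})
    age = clinical.get("age")
    return TumorRecord(
        sample_id=sample_id,
        braf_class=braf_class,
        braf_classes=frozenset(braf_classes),
        braf_domain=braf_domain,
        additional_ras=additional_ras,
        additional_ras_atypical=additional_atypical,
        msi_status=str(clinical.get("msi_status", "unknown")),
        location=str(clinical.get("location", "unknown")),
        age=float(age) if age is not None and age == age else None,
        sex=str(clinical.get("sex", "unknown")),
        stage=str(clinical.get("stage", "unknown")),
        braf_codons=tuple(sorted(braf_codons)),
    )


def annotate_cohort(
    mutations: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    rules: ClassificationRules = DEFAULT_RULES,
    all_sample_ids: Sequence[str] | None = None,
) -> list[TumorRecord]:
    """Annotate every tumor in a mutation table.

    ``all_sample_ids`` lets callers include profiled tumors with no somatic
    call in the table (BRAF wild-type, no Ras driver) in the cohort.
    """
    clin_by_id: dict[str, dict] = {}
    if clinical is not None:
        clin_by_id = {
            str(r["sample_id"]): {k: r[k] for k in clinical.columns if k != "sample_id"}
            for _, r in clinical.iterrows()
        }
    records = []
    grouped = mutations.groupby("sample_id", sort=True)
    seen = set()
    for sid, grp in grouped:
        sid = str(sid)
        seen.add(sid)
        variants = [_variant_from_row(row) for _, row in grp.iterrows()]
        records.append(annotate_tumor(sid, variants, clin_by_id.get(sid), rules))
    for sid in all_sample_ids or []:
        sid = str(sid)
        if sid not in seen:
            records.append(annotate_tumor(sid, [], clin_by_id.get(sid), rules))
    return records


def _opt_int(row, key):
    v = row.get(key)
    if v is None or (isinstance(v, float) and v != v) or v == "":
        return None
    return int(v)


def _variant_from_row(row) -> VariantCall:
    cons = row.get("consequence")
    cons = Consequence(cons) if isinstance(cons, str) and cons else None
    ctx = row.get("context")
    ctx = str(ctx) if isinstance(ctx, str) and ctx else None
    ref = row.get("ref")
    alt = row.get("alt")
    return VariantCall(
        sample_id=str(row["sample_id"]),
        gene=str(row["gene"]),
        protein_change=str(row["protein_change"]),
        codon=_opt_int(row, "codon"),
        consequence=cons,
        trinucleotide_context=ctx,
        ref_base=str(ref) if isinstance(ref, str) and ref else None,
        alt_base=str(alt) if isinstance(alt, str) and alt else None,
        mutant_reads=_opt_int(row, "mutant_reads"),
        total_reads=_opt_int(row, "total_reads"),
    )


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like TSV (sample_id, gene, protein_change, optional extras)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    required = {"sample_id", "gene", "protein_change"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table {path} missing columns: {sorted(missing)}")
    return df


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"clinical table {path} missing column: sample_id")
    return df


def records_to_frame(records: Sequence[TumorRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "braf_class": r.braf_class.value,
                "braf_classes": ";".join(sorted(c.value for c in r.braf_classes)),
                "multi_class": r.multi_class,
                "braf_domain": r.braf_domain.value,
                "additional_ras": r.additional_ras,
                "additional_ras_atypical": r.additional_ras_atypical,
                "msi_status": r.msi_status,
                "location": r.location,
                "age": r.age,
                "sex": r.sex,
                "stage": r.stage,
                "braf_codons": ";".join(str(c) for c in r.braf_codons),
            }
        )
    return pd.DataFrame(rows)


def write_annotated_table(records: Sequence[TumorRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def frame_to_records(df: pd.DataFrame) -> list[TumorRecord]:
    """Inverse of :func:`records_to_frame` (reads an annotated TSV back)."""
    out = []
    for _, r in df.iterrows():
        raw_classes = r.get("braf_classes")
        if not isinstance(raw_classes, str):
            raw_classes = ""
        classes = frozenset(BrafClass(c) for c in raw_classes.split(";") if c)
        age = r.get("age")
        out.append(
            TumorRecord(
                sample_id=str(r["sample_id"]),
                braf_class=BrafClass(r["braf_class"]),
                braf_classes=classes,
                braf_domain=BrafDomain(r.get("braf_domain", "unassigned")),
                additional_ras=bool(r["additional_ras"]),
                additional_ras_atypical=bool(r["additional_ras_atypical"]),
                msi_status=str(r.get("msi_status", "unknown")),
                location=str(r.get("location", "unknown")),
                age=float(age) if age is not None and age == age else None,
                sex=str(r.get("sex", "unknown")),
                stage=str(r.get("stage", "unknown")),
            )
        )
    return out
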