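"""Driver classification: protein-change parsing, codon rules, tumor roll-up."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rasco.annotate import (
    BrafClass,
    BrafDomain,
    ClassificationRules,
    Consequence,
    ProteinChangeError,
    RasCategory,
    VariantCall,
    annotate_tumor,
    classify_braf,
    classify_braf_domain,
    classify_ras_pathway,
    parse_protein_change,
    frame_to_records,
    records_to_frame,
)

RULES = ClassificationRules.from_yaml()


def v(gene, pc, sample="S1", **kw):
    return VariantCall(sample_id=sample, gene=gene, protein_change=pc, **kw)


@pytest.mark.parametrize(
    "text,codon,ref,alt,cons",
    [
        ("V600E", 600, "V", "E", Consequence.missense),
        ("G466V", 466, "G", "V", Consequence.missense),
        ("Q61*", 61, "Q", "*", Consequence.nonsense),
        ("K117fs", 117, "K", "fs", Consequence.frameshift),
        ("p.Val600Glu", 600, "V", "E", Consequence.missense),
        ("Arg1362Ter", 1362, "R", "*", Consequence.nonsense),
        ("L19L", 19, "L", "L", Consequence.synonymous),
    ],
)
def test_parse_protein_change(text, codon, ref, alt, cons):
    assert parse_protein_change(text) == (codon, ref, alt, cons)


@pytest.mark.parametrize("bad", ["X99X", "", "600E", "V600", "VABCE", "B600E"])
def test_parse_protein_change_rejects_garbage(bad):
    with pytest.raises(ProteinChangeError):
        parse_protein_change(bad)


@pytest.mark.parametrize(
    "pc,expected",
    [
        ("V600E", BrafClass.class1),
        ("G469V", BrafClass.class2),
        ("K601E", BrafClass.class2),
        ("D594G", BrafClass.class3),
        ("G466V", BrafClass.class3),
        ("N581S", BrafClass.class3),
        ("R250Q", BrafClass.unclassified),   # codon outside every listed set
        ("V600*", BrafClass.unclassified),   # non-missense at a listed codon
    ],
)
def test_classify_braf(pc, expected):
    assert classify_braf(v("BRAF", pc), RULES) is expected


def test_classify_braf_gene_case_insensitive():
    assert classify_braf(v("braf", "V600E"), RULES) is BrafClass.class1


@pytest.mark.parametrize(
    "pc,expected",
    [
        ("V600E", BrafDomain.A),
        ("D594G", BrafDomain.B),
        ("K601E", BrafDomain.B),
        ("G466V", BrafDomain.C),
        ("G464V", BrafDomain.C),
        ("R250Q", BrafDomain.unassigned),
        ("G467V", BrafDomain.unassigned),  # inside Fig-style 464-469 span, not in Methods set
    ],
)
def test_classify_braf_domain(pc, expected):
    assert classify_braf_domain(v("BRAF", pc), RULES) is expected


def test_domain_a_iff_class1():
    """A-domain membership coincides exactly with class 1 for missense variants."""
    for codon in range(1, 800):
        var = v("BRAF", f"A{codon}V")
        is_a = classify_braf_domain(var, RULES) is BrafDomain.A
        is_c1 = classify_braf(var, RULES) is BrafClass.class1
        assert is_a == is_c1


def test_every_listed_codon_maps_to_one_class():
    union = (
        RULES.braf_class1_codons | RULES.braf_class2_codons | RULES.braf_class3_codons
    )
    assert len(union) == (
        len(RULES.braf_class1_codons)
        + len(RULES.braf_class2_codons)
        + len(RULES.braf_class3_codons)
    )
    for codon in union:
        cls = classify_braf(v("BRAF", f"A{codon}V"), RULES)
        assert cls in (BrafClass.class1, BrafClass.class2, BrafClass.class3)


@pytest.mark.parametrize(
    "gene,pc,expected",
    [
        ("KRAS", "G12D", RasCategory.kras_typical),
        ("KRAS", "Q61H", RasCategory.kras_typical),
        ("KRAS", "L19F", RasCategory.atypical_ras),
        ("KRAS", "A146T", RasCategory.atypical_ras),
        ("KRAS", "V14L", RasCategory.atypical_ras),
        ("KRAS", "G12G", RasCategory.non_driver),    # synonymous
        ("KRAS", "E63K", RasCategory.non_driver),    # unlisted codon
        ("NRAS", "G12V", RasCategory.atypical_ras),
        ("NRAS", "Q61K", RasCategory.atypical_ras),
        ("NRAS", "A59T", RasCategory.non_driver),    # NRAS list is 12/13/61 only
        ("NF1", "R1362*", RasCategory.atypical_ras),
        ("NF1", "R440fs", RasCategory.atypical_ras),
        ("NF1", "T586M", RasCategory.non_driver),    # missense NF1 is not truncating
    ],
)
def test_classify_ras_pathway(gene, pc, expected):
    assert classify_ras_pathway(v(gene, pc), RULES) is expected


def test_classify_ras_pathway_rejects_other_genes():
    with pytest.raises(ValueError):
        classify_ras_pathway(v("BRAF", "V600E"), RULES)


def test_annotate_tumor_multi_gene_example():
    variants = [
        v("BRAF", "G466V"),
        v("KRAS", "V14L"),
        v("KRAS", "D33E"),
        v("NRAS", "G12V"),
    ]
    rec = annotate_tumor("S1", variants, rules=RULES)
    assert rec.braf_class is BrafClass.class3
    assert rec.additional_ras and rec.additional_ras_atypical


def test_annotate_tumor_braf_only():
    rec = annotate_tumor("S1", [v("BRAF", "V600E")], rules=RULES)
    assert rec.braf_class is BrafClass.class1
    assert not rec.additional_ras and not rec.additional_ras_atypical


def test_annotate_tumor_multi_class():
    rec = annotate_tumor("S1", [v("BRAF", "D594G"), v("BRAF", "G469V")], rules=RULES)
    assert rec.braf_classes == {BrafClass.class2, BrafClass.class3}
    assert rec.multi_class


def test_annotate_tumor_unclassified_braf_is_not_wild_type():
    rec = annotate_tumor("S1", [v("BRAF", "R250Q")], rules=RULES)
    assert rec.braf_class is BrafClass.unclassified


def test_annotate_tumor_rejects_mixed_samples():
    with pytest.raises(ValueError):
        annotate_tumor("S1", [v("BRAF", "V600E", sample="S2")])


@given(st.permutations(["V600E:BRAF", "L19F:KRAS", "G12V:NRAS", "R1362*:NF1", "D594G:BRAF"]))
@settings(max_examples=30, deadline=None)
def test_annotate_tumor_permutation_invariant(order):
    variants = [v(s.split(":")[1], s.split(":")[0]) for s in order]
    rec = annotate_tumor("S1", variants, rules=RULES)
    assert rec.braf_classes == {BrafClass.class1, BrafClass.class3}
    assert rec.additional_ras_atypical
    assert rec.braf_codons == (594, 600)


def test_variant_invariants():
    with pytest.raises(ValueError):
        VariantCall("S", "BRAF", "V600E", trinucleotide_context="GTGA")
    with pytest.raises(ValueError):
        VariantCall("S", "BRAF", "V600E", trinucleotide_context="GAG", ref_base="T")
    with pytest.raises(ValueError):
        VariantCall("S", "BRAF", "V600E", mutant_reads=10, total_reads=5)


def test_rules_disjointness_enforced():
    with pytest.raises(ValueError):
        ClassificationRules(
            braf_class1_codons=frozenset({600}), braf_class2_codons=frozenset({600})
        )


def test_annotated_table_round_trip():
    recs = [
        annotate_tumor("A", [v("BRAF", "D594G", sample="A"), v("KRAS", "L19F", sample="A")],
                       {"msi_status": "MSS", "location": "distal", "age": 61.0,
                        "sex": "male", "stage": "III"}),
        annotate_tumor("B", []),
    ]
    back = frame_to_records(records_to_frame(recs))
    assert [r.braf_class for r in back] == [BrafClass.class3, BrafClass.wild_type]
    assert back[0].additional_ras_atypical
    assert back[0].location == "distal" and back[0].age == 61.0
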