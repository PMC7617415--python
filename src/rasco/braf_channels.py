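"""Derivation of the causal mutation channels for BRAF driver classes.

The channel that generates a coding substitution is fixed by the substituted
base and its two neighbours in the genome.  For BRAF this is derived here
from embedded fragments of the reference coding sequence (NM_004333
numbering) spanning the two mutation-cluster regions: the exon-11
ATP-binding/P-loop region (codons 462-470) and the exon-15 activation-segment
region (codons 578-602).  Channel collapse to the pyrimidine strand makes
the result independent of which genomic strand the gene is read from, so the
coding-strand context suffices.

The class 1 (V600E, c.1799T>A) channel derives to G[T>A]G — the GTG>GAG
channel.  For classes 2 and 3 a curated list of recurrent substitutions with
well-established HGVS c. changes is mapped through the same procedure; the
20 substitutions collapse to exactly 16 distinct channels.  The full
substitution -> context -> channel audit table is available from
:func:`causal_channel_audit` and is written out by the pipeline.
"""

from __future__ import annotations

import pandas as pd

from .spectra import CausalChannelSet, collapse_to_pyrimidine

__all__ = [
    "CLASS1_CHANNELS",
    "CLASS2_3_CHANNELS",
    "causal_channel_audit",
    "channel_for_substitution",
    "causal_set_for_class",
]

# BRAF coding-sequence fragments (coding strand, NM_004333 cDNA numbering).
# Key = cDNA position of the first base of the fragment.
_CDS_FRAGMENTS = {
    # R462..T470: AGA ATT GGA TCT GGA TCA TTT GGA ACA
    1384: "AGAATTGGATCTGGATCATTTGGAACA",
    # K578..S602: AAG AGT AAT AAT ATA TTT CTT CAT GAA GAC CTC ACA GTA AAA
    #             ATA GGT GAT TTT GGT CTA GCT ACA GTG AAA TCT
    1732: "AAGAGTAATAATATATTTCTTCATGAAGACCTCACAGTAAAAATAGGTGATTTTGGTCTAGCTACAGTGAAATCT",
}

# Recurrent class 1/2/3 substitutions with their cDNA changes.
# (protein_change, braf_class, cdna_pos, ref_base, alt_base)
_SUBSTITUTIONS = [
    ("V600E", 1, 1799, "T", "A"),
    # class 2
    ("G464V", 2, 1391, "G", "T"),
    ("G464E", 2, 1391, "G", "A"),
    ("G469A", 2, 1406, "G", "C"),
    ("G469V", 2, 1406, "G", "T"),
    ("G469R", 2, 1405, "G", "A"),
    ("L597Q", 2, 1790, "T", "A"),
    ("L597V", 2, 1789, "C", "G"),
    ("K601E", 2, 1801, "A", "G"),
    ("K601N", 2, 1803, "A", "C"),
    # class 3
    ("G466V", 3, 1397, "G", "T"),
    ("G466E", 3, 1397, "G", "A"),
    ("G466A", 3, 1397, "G", "C"),
    ("N581S", 3, 1742, "A", "G"),
    ("N581I", 3, 1742, "A", "T"),
    ("D594G", 3, 1781, "A", "G"),
    ("D594N", 3, 1780, "G", "A"),
    ("D594H", 3, 1780, "G", "C"),
    ("F595L", 3, 1785, "T", "G"),
    ("G596R", 3, 1786, "G", "C"),
    ("G596D", 3, 1787, "G", "A"),
]


def _context_at(cdna_pos: int) -> str:
    for start, seq in _CDS_FRAGMENTS.items():
        off = cdna_pos - start
        if 1 <= off <= len(seq) - 2:
            return seq[off - 1 : off + 2]
    raise KeyError(f"cDNA position {cdna_pos} not covered by embedded fragments")


def channel_for_substitution(cdna_pos: int, ref: str, alt: str) -> str:
    """Pyrimidine-strand channel label for a BRAF cDNA substitution."""
    context = _context_at(cdna_pos)
    if context[1] != ref:
        raise ValueError(
            f"reference mismatch at c.{cdna_pos}: fragment has {context[1]}, got {ref}"
        )
    return collapse_to_pyrimidine(context, ref, alt).label


def causal_channel_audit() -> pd.DataFrame:
    """Substitution -> cDNA context -> channel table for all curated variants."""
    rows = []
    for pc, cls, pos, ref, alt in _SUBSTITUTIONS:
        rows.append(
            {
                "protein_change": pc,
                "braf_class": cls,
                "hgvs_c": f"c.{pos}{ref}>{alt}",
                "coding_context": _context_at(pos),
                "channel": channel_for_substitution(pos, ref, alt),
            }
        )
    return pd.DataFrame(rows)


def _channels_for_classes(classes: set[int]) -> frozenset[str]:
    return frozenset(
        channel_for_substitution(pos, ref, alt)
        for _, cls, pos, ref, alt in _SUBSTITUTIONS
        if cls in classes
    )


CLASS1_CHANNELS = CausalChannelSet.from_labels("class1", _channels_for_classes({1}))
CLASS2_3_CHANNELS = CausalChannelSet.from_labels("class2_3", _channels_for_classes({2, 3}))


def causal_set_for_class(name: str) -> CausalChannelSet:
    if name == "class1":
        return CLASS1_CHANNELS
    if name in ("class2_3", "class2", "class3", "atypical"):
        return CLASS2_3_CHANNELS
    raise KeyError(f"unknown causal channel set {name!r}")
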