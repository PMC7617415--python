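"""Optional VCF ingest (VCF 4.x via cyvcf2).

Protein-level annotation is read from a named INFO field (e.g. a simple
``PCHANGE=V600E`` tag, or the HGVS p. entry of a VEP/SnpEff-style CSQ/ANN
string handled upstream).  Gene symbols likewise come from an INFO field.
This keeps the reader free of annotation-pipeline assumptions; the TSV
mutation table remains the primary interface.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_vcf_mutations(
    path: str | Path,
    sample_id: str,
    gene_field: str = "GENE",
    protein_field: str = "PCHANGE",
) -> pd.DataFrame:
    """Read somatic SNVs from a VCF into the standard mutation-table frame."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        gene = rec.INFO.get(gene_field)
        pchange = rec.INFO.get(protein_field)
        if gene is None or pchange is None:
            continue
        rows.append(
            {
                "sample_id": sample_id,
                "gene": str(gene),
                "protein_change": str(pchange).removeprefix("p."),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "protein_change"])
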