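"""Generate the default synthetic inputs every later step consumes.

Draws a seeded cohort at the combined published cohort's size and rates
(6,605 tumors), a 500-mutation read-count set under the purity/copy-number
model, and 10 whole-genome-scale substitution catalogs, and writes them
under results/simulated/.
"""

from pathlib import Path

from rasco.simulate import (
    CatalogConfig,
    CohortConfig,
    ReadSimConfig,
    generate_catalog,
    generate_cohort,
    generate_read_counts,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    muts, clin = generate_cohort(CohortConfig(), seed=SEED)
    muts.to_csv(OUT / "mutations.tsv", sep="\t", index=False)
    clin.to_csv(OUT / "clinical.tsv", sep="\t", index=False)
    print(f"cohort: {len(clin)} tumors, {len(muts)} driver mutations -> {OUT}")

    reads = generate_read_counts(ReadSimConfig(n_mutations=500), seed=SEED)
    reads.to_csv(OUT / "reads_truth.tsv", sep="\t", index=False)
    print(f"reads: {len(reads)} simulated mutations with truth columns")

    catalog = generate_catalog(
        CatalogConfig(n_samples=10, mutations_per_sample=5000), seed=SEED
    )
    catalog.to_csv(OUT / "catalog.tsv", sep="\t", index=False)
    print(f"catalog: {len(catalog)} substitutions across 10 samples")


if __name__ == "__main__":
    main()
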