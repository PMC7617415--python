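# rasco

Colorectal cancers usually activate the MAPK pathway through a single strong
driver — BRAF V600E or a KRAS hotspot mutation. A minority instead carry
*atypical* BRAF mutations: class 2 (codons 464/469/597/601, activated
Ras-independent dimers) or class 3 (codons 466/581/594/595/596,
kinase-impaired mutants that need active Ras). `rasco` is an analysis
toolkit for the genetics of these tumors, for cancer-genomics researchers
working from somatic mutation tables, purity/copy-number calls and mutation
catalogs. It provides:

- **Driver classification** — BRAF class 1/2/3 and positional A/B/C domain
  rules, typical vs atypical KRAS/NRAS/NF1 Ras-pathway drivers, rolled up to
  per-tumor records (codon tables editable in `rasco/data/rules.yaml`).
- **Co-occurrence statistics** — 2×2 contingency tables over annotated
  cohorts with a two-sided minimum-likelihood Fisher exact test and
  class-stratified clinicopathologic summaries.
- **Clonality inference** — the purity–VAF–copy-number relation
  `VAF = p·N_mut / (p·(N_mut+N_wt) + 2(1−p))`, mutant-allele copy-number
  assignment from allele-specific segment calls, corrected allele fractions
  (cancer-cell fractions), and binomial + χ² tests of whether two drivers
  occupy the same clone.
- **Mutation spectra** — 96-channel trinucleotide spectra with
  pyrimidine-strand collapse, causal-channel proportions for each BRAF class
  (the class 2/3 set of 16 channels is derived from the BRAF coding
  sequence in `braf_channels.py`), and a logistic regression of driver
  presence on channel activity.
- **Synthetic cohorts** — seeded generators for mutation tables, read
  counts and catalogs at the published combined-cohort rates, so the whole
  pipeline is testable without controlled-access data.

## Worked example

```python
from rasco import annotate_tumor, VariantCall, fisher_exact_2x2, ContingencyTable

rec = annotate_tumor("T1", [
    VariantCall("T1", "BRAF", "G466V"),
    VariantCall("T1", "KRAS", "V14L"),
    VariantCall("T1", "NRAS", "G12V"),
])
print(rec.braf_class.value, rec.additional_ras, rec.additional_ras_atypical)
# class3 True True   <- a kinase-impaired BRAF with two atypical Ras partners

# codon-466 class-3 tumors by colorectal location (13/18 vs 12/39 proximal):
res = fisher_exact_2x2(ContingencyTable(((13, 5), (12, 27))))
print(round(res.odds_ratio, 2), round(res.p_two_sided, 3))
# 5.85 0.005   <- codon-466 mutants cluster in the proximal colon
```

The numbered scripts under `analysis/` run the full narrative on synthetic
data — `01` simulates a 6,605-tumor cohort, `02` annotates and summarises
it, `03` reproduces the published contingency statistics and reruns the
contrasts on the simulation, `04` scores clonality-call recovery against
simulated truth, `05` builds spectra and fits the channel regression —
writing their tables under `results/`. A `rasco` CLI wraps the same steps
(`rasco run --config run.yaml --out results/`, plus `annotate`, `cooccur`,
`clonality`, `spectrum`, `simulate` subcommands).

Running `analysis/04_clonality.py`, for example, prints

```
co-clonal pairs called co_clonal: 93.5%
subclonal pairs called non-co-clonal: 100.0%
pooled discrimination accuracy: 96.8%
copy-number assignment recovery (depth >= 500): 100.0% of 245 scored
```

i.e. with 200–1,000× depth at purity 0.7, mutation pairs sharing a clone are
distinguished from pairs split by a 30%-cell-fraction subclone in ~97% of
simulated tumors, and the mutant-allele copy-number assignment recovers the
generating state essentially always once depth reaches 500×.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and the generator's known simplifications.

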