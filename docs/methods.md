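# Methods

`rasco` analyses the co-occurrence of atypical BRAF driver mutations with
additional Ras-pathway mutations in colorectal cancer. Four pieces of
machinery do the scientific work: codon-rule driver classification, exact
2×2 association statistics, purity/copy-number-aware clonality inference,
and 96-channel trinucleotide mutation spectra with a channel-activity
regression. A seeded synthetic-cohort generator supplies inputs with the
statistical structure the analysis assumes, so every stage is testable
without access-controlled patient data.

## Driver classification

BRAF missense mutations are classed by codon: class 1 = {600} (V600E-type
constitutively active monomers), class 2 = {464, 469, 597, 601}
(Ras-independent activated dimers), class 3 = {466, 581, 594, 595, 596}
(kinase-impaired mutants that require active Ras and signal through
BRAF–CRAF heterodimers). Missense changes at any other codon, and
non-missense changes, are "unclassified" and treated as passengers: they are
excluded from class-based denominators but retained in cohort totals. A
parallel positional scheme labels domains A (codon 600), B (581–601
excluding 600) and C (the ATP-binding site {464, 466, 469}). Where sources
disagree on whether domain C is the explicit set {464, 466, 469} or the
span 464–469, we use the explicit set; the difference affects codons 465,
467 and 468, none of which carries a classifiable driver.

KRAS substitutions at codons 12/13/61 are typical drivers; substitutions at
{14, 19, 22, 33, 34, 59, 60, 68, 117, 146, 147} are atypical (predicted
pathogenic but weaker). All pathogenic NRAS substitutions (codons 12/13/61)
and protein-truncating NF1 mutations also count as atypical Ras-pathway
drivers. Whether NF1 splice-site variants count as truncating is not
settled; it is a config switch (`data/rules.yaml`), default included. All
codon sets live in that YAML file and can be edited without code changes.

A tumor carrying two distinct BRAF classes (observed once in the source
cohort) retains the full class set, is flagged `multi_class`, and is
excluded from single-class denominators while counting toward BRAF-mutant
totals — this avoids double-counting without discarding the tumor.

## Exact association tests

All 2×2 comparisons use the Fisher exact test with the two-sided
minimum-likelihood rule: conditioning on both margins, p is the sum of
hypergeometric point probabilities not exceeding that of the observed table
(relative tie tolerance 1e-7). This is the convention of mainstream
statistical software and reproduces the printed p = 0.005 for the codon-466
location table [[13, 5], [12, 27]]. A zero margin returns p = 1 with a
warning. The sample odds ratio (ad)/(bc) is reported, with infinity and
0/0-undefined flagged. Records missing either feature of a contrast are
dropped listwise and tallied. No multiple-testing correction is applied by
default (the source comparisons report nominal p-values); a
Benjamini–Hochberg helper exists for user analyses.

Summary tables report percentages over non-missing denominators, matching
the source table's convention of variable denominators per column.

## Clonality model

For a clonal mutation in a sample of purity p with N_mut mutant and N_wt
wild-type copies per cancer cell,

    VAF = p·N_mut / (p·(N_mut + N_wt) + 2·(1 − p))

and inverting,

    purity = 2 / (N_mut/VAF − N_mut − N_wt + 2),

which reduces to purity = 2·VAF for the diploid heterozygote. Because
allele-specific copy-number callers report an unordered (major, minor) pair,
both substitutions are evaluated; the assignment whose implied purity is
closest to the sample's estimate, within tolerance 0.1 (roughly the
uncertainty of purity estimation), wins. Equal pairs are unique by symmetry;
two indistinguishable fits are flagged ambiguous; no fit within tolerance is
flagged no-fit and read as a subclonality signal. The corrected allele
fraction (cancer-cell fraction) is implied purity divided by sample purity,
capped at 1 + ε with ε = 0.05 to absorb read-sampling noise.

Pair clonality calls combine (i) a per-variant exact binomial test of the
mutant read count against the expected clonal VAF and (ii) a Pearson χ² test
of independence on the two variants' copy-number-corrected mutant/reference
counts (mutant reads per mutant copy; reference reads per wild-type-content
unit N_wt + 2(1−p)/p), with the same test on raw counts also reported since
either operationalization is defensible. `alpha` (default 0.05) is the
nominal level of the pair-level decision; the two per-variant tests run at
the Šidák-corrected level 1 − (1 − α)^½ so that a truly co-clonal pair is
mislabelled at rate ≈ α rather than ≈ 2α. Calls: co_clonal when both
variants pass; nested when exactly one passes and the other is significantly
below clonal expectation (one-sided); distinct when both fail low and the
corrected fractions sum to ≤ 1; ambiguous otherwise. Read counts are treated
as exact binomial draws; no overdispersion model is fitted.

## Mutation spectra

Single-base substitutions are binned into the conventional 96 channels
(substitution type × flanking bases, pyrimidine strand); purine-reference
records are reverse-complemented before labelling, making the channel
strand-invariant. Raw per-sample counts are normalised to proportions
summing to one. The causal-channel proportion of a driver class is the
summed weight over the channels able to generate that class's substitutions.

The class 1 causal set is the single V600E channel G[T>A]G. The class 2/3
causal set is derived in `braf_channels.py` from embedded fragments of the
BRAF coding sequence (exon 11 P-loop region, codons 462–470, and exon 15
activation-segment region, codons 578–602; NM_004333 cDNA numbering): each
of 20 curated recurrent class 2/3 substitutions with established HGVS c.
changes is mapped to its coding-strand trinucleotide and collapsed to the
pyrimidine channel, yielding exactly 16 distinct channels. The full
substitution → context → channel audit table is written by the pipeline and
the derivation is editable at the substitution list.

The logistic model regresses driver presence on the causal-channel
proportion with tumor location (distal = 1), MSI status (MSS = 1), age and
sex (male = 1) as covariates, by maximum likelihood with Wald p-values.
Single-class outcomes and detected (quasi-)separation raise an error, with
an optional L2-penalized fallback. By default the exposure is the causal
set of the sample's own BRAF mutation class; a summed class 2/3 set is the
packaged alternative.

## Synthetic data generator

The generator's defaults are the study conditions of the combined published
cohort (6,605 profiled tumors): class frequencies 10.7% / 0.47% / 1.22%;
additional-Ras probabilities 2.4% / 29% / 45.7% per class; atypical
fractions 82% / 55.6% / 78% among those; MSI 52.4% in class 1 and 0 in
classes 2/3; distal location 16.3% / 62.5% / 56.1%; per-class sex, stage and
age (normal, σ = 10 y) distributions from the same table; and a BRAF
wild-type background with 53.2% Ras-driver prevalence. Variant spellings are
drawn from pools of changes named in the source study (V600E; G469V, K601E,
…; D594G, G466V, …; G12D vs L19F, A146T, …). Read counts are binomial with
success probability = cell-fraction-scaled expected VAF under the clonality
model above, with purity, depth, copy-number state and cell fraction
configurable; the generating truth is retained for recovery tests. Catalogs
are multinomial draws from a 96-channel vector — by default 0.69% mass on
the class 1 channel and 12.9% spread over the 16 class 2/3 channels
(whole-genome cohort means reported for the source data), flat elsewhere —
emitted on a random strand so collapse is exercised.

All generators are pure functions of (config, seed); per-component child
streams are derived from the root seed via CRC-tagged SeedSequence spawning,
so outputs are byte-identical across runs and platforms, and adding one
stage does not perturb another.

What the generator does **not** emulate: intra-tumor spatial structure,
sequencing error and strand bias, mutation-rate covariation between drivers
and background (drivers are drawn independently of catalog spectra), cohort
heterogeneity across the 13 source studies, and germline contamination.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not robustness to the full messiness of
real sequencing data.

## Numerical and scale choices

Problem sizes: generator-fidelity checks use n = 10,000 tumors (3 binomial
SEs discriminates the configured rates well at that size); clonality
recovery uses 200 pairs per scenario at purity 0.7, depths 200–1,000;
copy-number assignment recovery uses 500 mutations at depth 500–1,500;
spectrum recovery uses one 10,000-draw catalog. The exhaustive Fisher
oracle check covers every non-degenerate 2×2 table with total ≤ 60 (about
half a million tables) against exact rational enumeration.

Degenerate inputs: zero-depth contexts raise; VAF = 0 has no purity
solution and is flagged; a pure tumor with loss of the wild-type allele
saturates VAF at 1 and round-trips exactly. Implied purity up to 1.05 is
accepted as clonal (ε above); larger values are flagged invalid rather than
clipped.

## Known limitations

- Protein-level annotation only: no genome-to-protein mapping, no effect
  prediction beyond the codon tables, no external database queries.
- Copy-number calling and purity estimation are upstream inputs, not
  reimplemented; subclonal copy number is not modelled (a no-fit flag is the
  only signal).
- Raw spectra only; no signature deconvolution, indel or doublet channels.
- The cohort generator draws each tumor's covariates independently given its
  class; it does not model covariate correlations (e.g. MSI with location).
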