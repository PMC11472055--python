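# Methods

## Problem and model

A monozygotic twin pair shares its germline genome; at a reliably genotyped
site, a discordant genotype between co-twins indicates a postzygotic somatic
mutation (PZM). With germline-grade joint calling at ~24x WGS depth, the
detectable PZMs are mainly early embryonic ones: a mutation at the 2-cell
stage is expected near VAF 0.5 in the carrier twin, a 4-cell-stage mutation
near 0.25. Low-VAF discordances are enriched for sequencing artefacts, which
motivates both the allele-support QC filter and the artefact correction in
the signature analysis.

The package is organized as a filtering cascade (QC → concordance → PZM
extraction) feeding two statistical components: ordinary least-squares
regressions of mutation burden and VAF on covariates, and a likelihood-based
attribution of motif spectra to signature profiles. The attribution is the
one genuinely model-like step and is exposed as a model/results pair
(`SignatureAttribution` / `SignatureAttributionResults`); the cascade stages
are plain functions over pandas tables.

## QC filters and semantics

Defaults (`QCThresholds`): genotypes masked to Missing when DP < 5, GQ < 20,
or DP > 60 with GQ < 95 (deep but ambiguous calls are suspect); variants
dropped when the called fraction across samples is < 0.90, when not a
biallelic autosomal SNV, or when inside a region mask (BED, 0-based
half-open; VCF positions 1-based, converted only at the reader boundary).
Non-reference genotypes additionally require VAF = AD_alt/(AD_ref+AD_alt)
≥ 0.10 and AD_alt ≥ 2, computed from the VCF AD field. All boundaries are
strict as stated: values exactly at a threshold are retained.

Choices made where the procedure was open:

- A genotype failing the allele-support rule is set to Missing (the site
  then drops from both the concordance matrix and PZM extraction), the
  conservative reading of "filtering the call from the individual's VCF".
- "Allelic count" is read as alt-supporting reads, consistent with the
  adjacent VAF rule targeting weakly supported alt alleles.
- Multiallelic records are dropped whole rather than decomposed; the
  analysis is defined over biallelic SNVs.
- The call-rate filter is implemented over an arbitrary sample-presence
  vector, but in the per-pair pipeline (2 samples) it is subsumed: any
  missing genotype already excludes the site from every downstream count.
- The VAF filter runs after genotype/region QC and before concordance and
  PZM extraction (switchable via `vaf_filter=False`).
- Variant-caller recalibration is not re-implemented; callers' FILTER
  columns can be honoured upstream of the pair tables.

## Concordance

The 3×3 genotype contingency matrix is collapsed to unordered pair classes;
Ref/Ref~Ref/Ref pairs are unobservable in a variants-only callset and
excluded from the denominator. Sites Missing in either twin are excluded
(not treated as discordant) — the rate formula has no missing class. The
high/low classification uses the unrounded rate with a ≥ 0.99 cutoff
(consistent with 99.2% grouping high and 98.9% low in the reference cohort);
percentages are rounded to one decimal only for presentation. The
"discordant count" defaults to all three discordant classes
(RR~RA, RR~AA, RA~AA); the class set is a parameter because published
definitions vary between RR~RA/RA~AA and RR~RA/RR~AA.

## PZM discovery and statistics

The carrier is the twin with more alt alleles; its VAF is taken from its AD
field. Germline-database exclusion is keyed on the exact
(chrom, pos, ref, alt) tuple — position-only matching would inflate false
negatives at multi-allelic positions. Exonic labelling is interval overlap
against a BED exon model; no transcript-level consequence annotation is
attempted. Summaries use the sample (n−1) standard deviation. Regressions
are OLS via statsmodels with two-sided t-tests at n−p−1 degrees of freedom;
a rank-deficient design raises an explicit singularity error. The exonic vs
non-exonic burden comparison is the two-sided Wilcoxon rank-sum test, exact
for small tie-free samples and normal-approximated otherwise
(scipy `mannwhitneyu`, method="auto"). p-values are reported without
multiple-testing adjustment.

## Signature attribution

The 96-motif order is pinned in one table (substitution-major C>A, C>G, C>T,
T>A, T>C, T>G; then 5' A,C,G,T; then 3' A,C,G,T) shared by spectra, the
catalogue reader and all outputs. Purine-reference substitutions are
collapsed onto the pyrimidine strand by reverse-complementing the context
and complementing the alleles.

The multinomial log-likelihood uses log-gamma for the factorial terms
(direct factorials appear only in the test oracle at n ≤ 20). Zero entries
of each profile are replaced by half the profile's minimum positive entry
and the profile is **renormalized** to sum 1 — without renormalization logL
would not be a log-probability. The corrected score is
(logL_signature − logL_artefact)/n: the wording "subtract the artefact value
and divide by the number of mutations" is ambiguous about what the division
applies to, and this reading makes scores comparable across pairs with
different mutation counts (it equals the per-mutation cross-entropy gap
Σ f_k log(p_s,k/p_a,k), invariant to scaling all counts). Argmax ties break
to the lowest signature index. The artefact profile pools raw motif counts
over all low-concordance pairs and normalizes once; when no low-concordance
pairs exist the pipeline falls back to a uniform background and logs it.
Only high-concordance pairs are scored, mirroring the intended use of the
low stratum as a noise reference rather than a subject of inference.

## Synthetic data generator

The generator's defaults are the study-like conditions: 30 pairs with the
reference cohort's ages and sexes, 20 000 shared (non-reference) germline
sites per pair, 86 PZMs per pair drawn from Signature 5, depth
Poisson(24) per site and sample, alt reads Binomial(depth, true VAF).
PZM VAFs come from an equal-weight Beta mixture centred at 0.5 and 0.25 with
concentration 60, chosen once so that ~44% of PZM VAFs fall in [0.4, 0.6] —
the observed share of early-division-like mutations in the reference cohort.
Artefact sites are het calls in one twin with VAF from Beta(1.5, 15)
truncated to [0.04, 0.25): most mass is below the 10% QC cutoff, and calls
under ~4% allele fraction would not be emitted at 24x at all. Their motifs
follow a configurable artefact profile, by default 70% T>C (the excess seen
in low-concordance pairs) and uniform elsewhere. By default roughly 7/30 of
pairs get a high artefact rate (1500 expected sites) and the rest a low one
(25), producing the two concordance strata.

Genotypes are emitted by a naive caller on the allele depths (alt fraction
≥ 0.9 → Alt/Alt; ≥ 0.05 with ≥1 alt read → Ref/Alt), standing in for a
production caller — only the GT:AD:DP:GQ schema matters downstream. Allele
depths at simulated variant sites are rejection-sampled until the naive call
equals the intended truth genotype; without this, rare binomial tail draws
(about 1 per 50 000 het genotypes) would miscall a shared germline site and
break the exact noise-free identity between discordant sites and truth PZMs.
GQ is a crude Poisson(3·DP) capped at 99. Trinucleotide contexts are drawn
from a configurable 32-context table (default uniform) so no reference FASTA
is needed; the context travels in the VCF INFO field `TNC`, and round-trips
through the pysam-backed reader are lossless. Sites are unique per pair on
autosomes 1–22 with positions uniform on a 100-Mb stand-in length.

What the simulator does **not** emulate: read-level errors and mapping
artefacts (noise is injected at the genotype level), linkage and allele
frequency structure among germline sites, realistic exon placement, genuine
hg38 context frequencies, indels and sex chromosomes. Passing tests
therefore demonstrate the correctness of the filtering arithmetic,
concordance algebra, truth recovery and attribution statistics — not
robustness to alignment-level failure modes of real WGS.

## Packaged data

- `data/reference_cohort.tsv` — per-pair characteristics (age, sex, depths,
  concordance %, discordant and exonic counts) of a published 30-pair adult
  MZ twin WGS cohort; used for presentation-layer summaries and as the
  default ages/sexes of study-like simulations.
- `data/signatures_30_synthetic.tsv` — a **synthetic** 30-signature
  catalogue in the COSMIC v2 TSV schema (generated by
  `scripts/make_synthetic_signatures.py`, seed fixed). Signature 1-like
  (C>T at NpCpG) and Signature 5-like (clock-like: T>C ≈ 0.41, C>T ≈ 0.30
  of mass, flat flanks) profiles are structured; Signatures 3 and 16 are
  near-flat so that realistic confusability among flat signatures is
  preserved; a third of the remaining profiles contain genuine zeros to
  exercise the zero-complement step. A real COSMIC v2 probability file
  drops in via `read_cosmic_v2()` unchanged.

## Numerical and testing notes

- Signature recovery: with n = 500 mutations from Signature 5 and a uniform
  artefact background, the initial 200-replicate oracle run recovered the
  generator 200/200; the frozen test threshold is ≥ 90%. Across all 30
  catalogue signatures the weakest recovery in a 20-replicate spot check was
  0.95 (the near-flat Signature 3 analogue), matching the expected confusion
  structure among flat profiles.
- VAF regression calibration: under a null with 30 pairs × 20 mutations the
  concordance coefficient rejects at α = 0.05 in ~5.2% of 1000 replicates;
  an injected slope of 3 per unit concordance is recovered with positive
  sign in 100% of 200 replicates.
- Problem sizes in the test suite and acceptance script (e.g. 10-pair
  truth-recovery cohorts, 1000–2500 germline sites in unit fixtures) are
  chosen to keep the full suite in seconds while leaving every statistical
  check well-powered; the simulator runs the full 30 × 20 000 study scale
  in a few seconds when asked.
- Truth-recovery checks disable QC (`QCThresholds.disabled()`): with noise
  off, the discordant set then equals the truth PZM set exactly for any
  seed. With QC on, a handful of true PZMs are legitimately lost (e.g. an
  observed alt fraction below 10% for a true VAF-0.25 mutation), which is
  the intended behaviour of the filters, not an error.
- Degenerate inputs: empty spectra cannot be scored (n = 0 raises); an empty
  low-concordance stratum raises with instructions to skip the artefact
  correction (the pipeline then substitutes a uniform background); an
  all-zero profile cannot be zero-complemented; concordance is undefined
  (error) when a pair has no non-(RR,RR) sites.

## Known limitations

Germline-database contamination filtering is exact-key only; population
VCFs with normalized multi-allelic representation should be decomposed
before loading. The exonic classifier is region-level, not
transcript-aware. The pipeline assumes confirmed monozygosity — it performs
no kinship or zygosity estimation. Signature attribution reports the single
best signature, not a mixture decomposition (no NMF / de novo extraction).
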