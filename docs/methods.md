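# Methods

## Scope and data model

The package analyses *annotated* screening data: it consumes a gene panel,
a curated variant catalogue (transcript-level HGVS, QC fields, population
allele frequencies, ACMG evidence codes, provenance flags) and a genotype
table, and produces filter audits, classifications, carrier/couple calls
and frequency estimates. Read alignment, variant calling and annotation
(BWA/GATK/VEP-class tools) are upstream and out of scope; so are CNV and
repeat-expansion disorders (SMN1-type deletions, fragile X), which
short-read panel screens do not reliably detect.

Catalogues are keyed by `variant_id` (`GENE:cHGVS`), not genomic
coordinates: published variant tables cite transcript HGVS, and nothing in
the analysis needs positions. Genomic fields appear only in the synthetic
VCF, on one pseudo-contig per gene.

## Consequence typing from HGVS

The consequence classes that matter to the retention filter are coarse:
missense, nonsense, in-frame indel, splice region (with intronic offset),
other. They are derived from the HGVS strings by a small total classifier:
protein-level evidence wins (substitution → missense/nonsense; in-frame
del/dup/ins → in-frame indel; frameshift → other), otherwise an intronic
cDNA offset `c.###±N` gives splice-region with offset `N`; anything
unparseable is `other` with a logged warning, never an exception. Both
canonical (`c.1001G>T`) and spaced table typography (`c.1001G > T`) are
accepted, since printed tables are not canonical HGVS. No
reference-sequence validation is attempted.

## Retention filters

Defaults: require `PASS`; 1000 Genomes MAF strictly `< 0.05` (the sources
consulted are configurable and ordered; a variant absent from every
consulted source counts as rare — missing evidence must not suppress a
rare allele); consequence exonic or splice-region; depth strictly `> 10`;
then the curated exclusion list. Failure is attributed to the *first*
failing rule in that fixed order, making audit logs reproducible and
order-independent.

Two deliberate choices:

* **Splice window.** "Canonical splice site" (±1/±2) would reject a
  functionally validated acceptor-region variant at −6 that the screen
  reported; the window is therefore a parameter, `max_intronic_offset`,
  defaulting to 8 bases, wide enough for validated near-splice variants
  while still excluding deep-intronic noise. Values below 2 are rejected.
* **Curated exclusions, not a local-frequency rule.** A coding variant at
  0.5% local allele frequency passes the numeric MAF filter; when review
  judges it a population polymorphism it is removed via an explicit
  exclusion list, and `flag_local_common` (local or gnomAD-SAS AF ≥ 0.5%)
  only *marks* candidates for that review. Automating the drop would hide
  a judgment call inside a threshold.

## ACMG/AMP combination

The engine consumes evidence codes as given (assignment is upstream
curation) and combines tier counts by the standard rules; it is
symmetric within tiers by construction and total. Duplicated specific
codes are rejected rather than double-counted — no published set repeats a
code, and silent double-counting would inflate classifications. When a
pathogenic rule and a benign rule are simultaneously satisfied the result
is VUS (the guideline's conflicting-evidence disposition); no published
set exercises this, so it is covered by constructed tests. The test suite
checks the engine against an independently written rule table over every
realizable tier-count vector, and asserts monotonicity: with no benign
codes, adding pathogenic evidence never demotes the classification.

## Carrier and couple calling

One call per (individual, gene) over reportable (P/LP) variants only.
Category rules: AR het → carrier; AR hom or two distinct het variants in
one gene → affected-risk (possible compound heterozygote; phase is not
resolved); XL het female → carrier, XL hemi male → affected-risk (a
hemizygous pathogenic genotype implies affected status, not carrier
status), XL het male → validation error (males are hemizygous on X outside
the PAR, so a het call there is a data defect, not biology); AD/AR het →
affected-risk, kept out of carrier-frequency tables so those tables retain
pure recessive-carrier semantics. Couple screening matches at gene level
by default — partners carrying different deafness genes are not an at-risk
couple, consistent with locus heterogeneity — with disorder-level matching
as an option. Residual risk is a plain Bayes update; the detection rate is
a user input, as screening sensitivity depends on panel and population.

## Frequency estimation

Wilson score intervals, with `z = 1.96` exactly at 95% (the convention of
published screening tables; other levels use the normal quantile). The
`n = 0` lower bound and `n = N` upper bound are set to exactly 0 and 1,
where the algebraic solution has floating-point residue. Displayed
rounding is configurable; tests compare unrounded values (tolerance 5e-4
on the percent scale). The frequency table groups by gene, with an
optional disorder-level view (the four deafness genes combine to 12
carriers, about one in 17, in the reference cohort).

Two published reference rows — the total row (52/200, printed 19.9–31.9
where the Wilson formula gives 20.4–32.5) and the 5/200 row (printed
0.78–5 where Wilson gives 1.07–5.72) — do not reproduce under the stated
method and are treated as errata; the formula is not adjusted to match
them, and they are excluded from acceptance checks.

## The reference cohort

The bundled fixture reconstructs the screen the package validates against:
200 individuals (88 couples — members `P001`–`P176` — plus 24 singletons;
101 male / 99 female), an 88-gene panel (72 AR, 7 XL, 9 AD/AR), and 47
catalogued P/LP variants observed 57 times in 52 carriers. Published
sources give per-variant occurrence counts and marginal totals but not the
person-level assignment, so the genotype table is an arbitrary
*deterministic* choice preserving every printed marginal: the five
two-disorder carriers are singletons `P177`–`P181` with fixed gene pairs
(CFTR+SLC26A4, CFTR+GJB2, GAA+SLC26A4, TMPRSS3+MMAA, GALT+OCA2), and each
remaining observation goes to the first member of a distinct couple, in
catalogue order. Placing the double carriers outside couples makes the
zero-at-risk-couples outcome structural rather than assignment-dependent.

Per-variant QC values and allele frequencies were not published; the
catalogue carries synthetic but consistent values (all `PASS`, depths
38–92 matching the reported ">30 on review", small AFs). The panel file is
explicitly a synthetic stand-in beyond the ~38 recoverable genes (catalogue
genes, the named X-linked disorders, familial hypercholesterolemia); filler
rows exist only to give the panel its documented mode composition and carry
placeholder transcript/OMIM identifiers (`ENST000009000xx`, `9000xx`).
One source discrepancy is resolved in the catalogue's favour: the
junctional epidermolysis bullosa observations sit in *LAMB3* (per the
variant table) although the frequency table printed the *LAMC2* label;
both genes are on the panel.

## Synthetic cohorts

The simulator emulates the screening *data*, not the sequencing: each
individual is independently a heterozygous carrier of gene *g* with
probability `per_gene_carrier_freq[g]` (independent Bernoulli per gene;
Hardy–Weinberg mating structure, linkage and population stratification are
ignored — adequate at rare-allele carrier frequencies, and documented as
an approximation), drawing the allele from the catalogue weighted by
reference occurrence counts. Distractor loads are Poisson per individual
per class: `common` (AF uniform 0.05–0.5), `non_pass`, `low_depth`
(depth 0–10), `vus_evidence` (`PM2 + PP3`), `benign_evidence`
(`BS1 + BS2`); defaults (2.0, 0.3, 0.3, 0.5, 0.5) give a realistic
annotated-variant load of a few per individual after upstream filtering.
Each distractor is constructed to fail for exactly its planted defect, so
the audit log is checkable. Study-scale defaults are a cohort of 200 with
88% enrolled as couples.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seed and package version give byte-identical outputs (the analysis path
itself is seed-free). Passing tests on synthetic data show the pipeline's
bookkeeping and statistics are correct under the generator's assumptions;
they do not validate upstream annotation quality, phasing, or real
population structure.

## Problem sizes and numerical checks

The exhaustive ACMG oracle comparison enumerates every realizable
tier-count vector (~21,600 combinations). Wilson endpoints are verified as
roots of the score equation to 1e-10 and against bisection for all
0 ≤ n ≤ N ≤ 50, and against an independent library implementation to the
precision allowed by the pinned z. Interval calibration uses 100 seeded
cohorts of N = 2000 at a planted carrier frequency of 0.05, requiring
coverage in ≥ 90 runs (nominal ~95%; the bound is loose for binomial noise
in the count of covering runs). These sizes keep the full suite under half
a minute while exercising every code path.

## Known limitations

* No phasing or cis/trans resolution: two het variants in one AR gene are
  flagged affected-risk conservatively.
* No automated evidence assignment (PVS1 decision trees, PM2 lookups) and
  no Bayesian point-based variant of the classification guideline.
* Consequence typing trusts HGVS strings; a malformed description demotes
  a variant to `other` (and thus to a consequence-filter failure) rather
  than guessing.
* The bundled panel beyond the recoverable genes is representative filler;
  per-gene results for filler genes are meaningless by construction.
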