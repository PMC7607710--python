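# carrierscreen

Analysis toolkit for NGS-based **expanded carrier screening**: given a gene
panel, a curated variant catalogue and per-individual genotypes, it applies
the variant-retention filters, combines ACMG/AMP evidence codes into the
five-tier classification, calls carriers and at-risk couples, and estimates
per-gene carrier frequencies with Wilson score intervals. A seeded
synthetic-cohort simulator with known ground truth, and a deterministic
reference cohort — an expanded carrier screen of 200 North Indian
individuals (88 couples) over an 88-gene panel, with its catalogue of 47
pathogenic / likely pathogenic variants — are bundled for validation.

It is written for analysts reproducing or extending carrier-frequency
studies in populations whose pathogenic variant spectra are poorly
represented in Western panels, where full-exon screening and careful
variant curation (rather than targeted genotyping of known alleles) are
required.

## Methods at the core

**Variant retention.** A variant is kept iff its VCF filter is `PASS`, its
population MAF is `< 0.05` (1000 Genomes by default; absent record = rare),
its consequence is exonic (missense / nonsense / in-frame indel) or within
the splice region (intronic offset ≤ 8 by default), and read depth is
`> 10`. A curated exclusion list removes judged polymorphisms that pass
every numeric rule; every variant gets an auditable first-fail reason.

**ACMG/AMP combination.** Evidence codes PVS1, PS1–4, PM1–6, PP1–5 (and
BA1, BS1–4, BP1–7) combine by the standard rules, e.g. Pathogenic for
1 PVS + ≥1 PS, or ≥2 PS, or 1 PS + ≥3 PM …; Likely pathogenic for
1 PS + 1–2 PM, ≥3 PM, 2 PM + ≥2 PP, 1 PM + ≥4 PP …; conflicting
pathogenic/benign rules give VUS. Only P/LP findings are reportable;
VUS are suppressed.

**Carrier statistics.** A carrier frequency n/N is reported as a percent,
as "1 in N/n", and with the Wilson score interval

```
( p̂ + z²/2N  ±  z·√( p̂(1−p̂)/N + z²/4N² ) ) / ( 1 + z²/N ),   z = 1.96 at 95%
```

which stays well-behaved at the small counts (n = 1…9 of 200) typical of
rare recessive carrier states. Residual (post-negative-test) carrier risk
is the Bayes update `f(1−d) / (f(1−d) + (1−f))` for prior `f` and
detection rate `d`.

## Worked example

```python
from carrierscreen import reference_cohort, run_pipeline, render_report

ref = reference_cohort()
run = run_pipeline(ref.panel, ref.catalogue, ref.individuals, ref.genotypes)
print(render_report(run, "text"))
```

prints (abridged):

```
COHORT
individuals: 200; carriers: 52 (26%); carrier calls: 57; at-risk couples: 0
carriers by number of disorders: 1: 47, 2: 5

CARRIER FREQUENCIES
label   n   N   pct   1 in      ci_lower_pct  ci_upper_pct
CFTR    9   200 4.5   22.2222   2.38523       8.32976
SLC26A4 5   200 2.5   40        1.07246       5.71791
GAA     3   200 1.5   66.6667   0.511415      4.31665
...
total   52  200 26    3.84615   20.4137       32.4909
```

Reading it: 52 of the 200 screened individuals (26%) carry at least one
reportable P/LP variant — 47 for a single disorder, 5 for two. Cystic
fibrosis (*CFTR*) is the most frequent single-gene finding at 9/200 =
4.5%, i.e. one carrier in 22, with Wilson 95% CI 2.4–8.3%; the four
deafness genes together account for 12 carriers (one in 17). No couple
shares a gene, so no at-risk couples are reported.

The numbered drivers under `analysis/` run the same computations as
narrative steps and write their tables to `results/`:
`01_classify_catalogue.py` (filter audit + ACMG classification of the 47
catalogued variants), `02_reference_cohort.py` (the full screen above),
`03_synthetic_cohorts.py` (seeded simulation: exact truth recovery and
Wilson-interval calibration over 100 cohorts of N = 2000).

## Layout

- `src/carrierscreen/` — library: `panel`, `catalogue`, `hgvs`, `filters`,
  `acmg`, `carriers`, `stats`, `simulate`, `reference`, `pipeline`
- `src/carrierscreen/data/` — bundled panel (partly synthetic filler; see
  module docs) and the 47-variant catalogue
- `analysis/` — numbered narrative drivers writing to `results/`
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
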