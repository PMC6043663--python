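# Methods

## Scope and data model

`epitriage` operates downstream of read alignment and variant calling: its
inputs are a VCF 4.x (or an equivalent combined variant table), an
ANNOVAR-style annotation TSV, a per-patient phenotype TSV, and optionally a
6-column PED file with a companion per-variant carrier-genotype table. Read
trimming, alignment, calling, and the computation of SIFT / PolyPhen-2 /
MutationTaster / CADD scores and population allele counts are consumed as
annotations, never recomputed.

All joins use one canonical variant key: VCF 1-based coordinates with
left-aligned, minimal alleles. ANNOVAR-style `-` alleles and VCF anchored
indels normalize to the same key, so a duplication written `c.649dupC`
(position 29825024, `-`→`C`) and its anchored VCF spelling join correctly.
Conservation is enforced at every stage boundary: input = joined + rejected,
and unannotated variants land in a reject log rather than disappearing.

## The filtering cascade

Stages run in a fixed order — QC, consequence, population, prediction — and
the first failure excludes the record with a named reason. Tunables live in
`QcThresholds`; defaults:

| parameter | default | meaning |
|---|---|---|
| `min_mapping_quality` | 30 | phred; below fails QC |
| `min_base_quality` | 20 | phred |
| `min_depth` | 20 | reads; boundary value passes |
| `strand_bias_p` | 1e-3 | two-sided Fisher exact on (ref_fwd, ref_rev; alt_fwd, alt_rev) |
| `cluster_window_bp` / `cluster_min_count` | 10 / 3 | ≥3 same-sample calls in 10 bp flags the cluster |
| CADD cutoff | 20 | phred, boundary inclusive |

Decisions where the procedure was genuinely open:

- **Strand bias** and **variant clustering** have no universal definition in
  amplicon pipelines; the Fisher-exact formulation and the 3-in-10-bp window
  mirror common artifact heuristics and are fully configurable.
- **Missing QC metrics pass with a warning** (absence of a metric is not
  evidence of a failing call); a `strict` mode fails instead. This matters
  because curated variant tables often carry no per-call QC at all.
- **Boundary semantics are inclusive on the passing side**: depth 20, MQ 30,
  BQ 20 and CADD 20.0 all pass. Population cutoffs are exclusive on the
  passing side: ≤1 ExAC allele and ≤5 gnomAD alleles pass, one more fails.
  ExAC/gnomAD hits are interpreted as allele counts (the carrier-count
  reading would be slightly more permissive for hom-alt carriers).
- **The consensus vote is ≥3 of 4 programs**, with PolyPhen-2 "possibly
  damaging" (P) counting as a damaging vote and absent predictors
  abstaining. A strict "more than three" reading (=4 of 4) would reject
  validated variants with one abstention; ≥3 reproduces the worked example
  under either PolyPhen reading.
- **Null variants (nonsense, frameshift, canonical splice, start-loss)
  bypass the prediction stage.** Missense predictors do not score
  truncations; requiring votes they cannot cast would silently discard the
  highest-impact class.

## Classification

The decision tree (rules R1–R6 in the README) is a pure function of an
assembled `EvidenceProfile`; repeated evaluation is identical, and the rule
trace records every rule consulted. Priority order is fixed, but for the
packaged worked example the pathogenic-or-likely-pathogenic *set* is
invariant under any permutation of R1–R5 (tested); only the P/LP split can
shift with priorities.

- **De novo** requires both parents genotyped non-carriers; a single tested
  negative parent yields `unknown`, not `de novo`.
- **Segregation** is deliberately asymmetric: an affected tested relative
  without the variant demotes phenotype-dependent calls (R3–R5) to VUS,
  while consistent segregation is recorded but never upgrades a class —
  inherited ultra-rare missense variants in multiplex families stay likely
  pathogenic. Unaffected carriers are tolerated (incomplete penetrance, e.g.
  *PRRT2*).
- **Female restriction**: for *PCDH19*-type X-linked female-restricted
  genes, mechanism- and phenotype-based rules (R2–R5) require a female
  proband or an explicit override; the disease-database rule R1 is exempt.
- **start_loss** counts as a null consequence although the worked example
  contains none.
- `in_disease_db` and `functional_evidence` are curator-supplied columns;
  the pipeline does not query HGMD/ClinVar/LOVD or assess function.

## Panel model

The shipped panel covers the 21 screened genes with transcript, a
loss-of-function-mechanism flag (licensing R2), an inheritance mode, and a
phenotype spectrum over a flat controlled vocabulary of 18 epilepsy
syndrome/localization tags. Spectra are literature-derived defaults meant to
be edited per site — phenotype matching is data-driven, not hard-coded — and
the matcher is monotone: adding patient tags can only create matches. A flat
tag vocabulary (rather than an HPO-style ontology) is sufficient for
spectrum-intersection matching; ontology integration is out of scope.

## Cohort statistics

Yields are recomputed from raw counts everywhere; JSON reports carry full
precision and only the human-readable table rounds. Two yield flavours are
reported: variant-based (P/LP variants / cohort n, the headline figure) and
carrier-based (distinct P/LP patients / n); they differ when one patient
carries two reportable variants.

Stratifiers must partition the cohort. The family-history partition maps
`unknown` to sporadic. The syndromic partition assigns patients with a
specific-syndrome tag ({DRAVET, GEFS_PLUS, EFMR, GLUT1_DS, LGS, EAS}) or an
intellectual-disability flag to the syndromic stratum. Under this map the
packaged 593-patient table yields a 39-patient syndromic stratum with 5
carriers (12.8%) — and a non-syndromic complement of 6/554 (1.08%). The
published split prints 7/554 for the complement, which cannot be reconciled
with 11 total carriers split 5 + 6; the package reports the internally
consistent computed value and does not force agreement.

The Fisher exact test is two-sided with the point-probability convention
(sum of hypergeometric probabilities ≤ the observed table's), delegated to
`scipy.stats.fisher_exact`; the test suite checks it against a
full-enumeration oracle for every 2×2 table with N ≤ 30. The odds ratio is
the sample estimate ad/bc (∞ when bc = 0 with ad > 0). No multiple-testing
correction is applied: the pipeline makes one planned comparison.

## Synthetic cohorts

The generator's defaults are the study conditions: 593 patients, familial
fraction 99/593, syndromic fraction 39/593, and per-patient planting rates
chosen so a default cohort carries ≈1800–1900 variants with an expected P/LP
rate of 1.9 per 100 patients (`ultra_rare_match` 0.007 + `null_lof` 0.008 +
`db_known` 0.004 per patient), matching the observed diagnostic yield;
`out_of_spectrum` at 0.027 matches the observed VUS rate, and common (2.2),
QC-failing (0.35) and synonymous (0.5) classes supply the bulk that the
cascade must discard.

Each planted class realizes its fate by construction: common variants get
gnomAD counts > 5, QC failures get a sub-threshold metric, ultra-rare
in-spectrum variants get four damaging predictor calls (CADD uniform on
[20, 45]) in a gene whose spectrum intersects the carrier's tags, null
variants land in loss-of-function-mechanism genes, and out-of-spectrum
variants in genes disjoint from the carrier's phenotype. Positions are drawn
uniformly in fixed per-gene windows, globally unique and ≥ 11 bp from any
same-sample variant so nothing trips the cluster filter by accident.
Everything is deterministic in the seed, down to byte-identical VCFs.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: predictor scores are parametric draws, not real
SIFT/PolyPhen behavior; positions are well-formed but not real exon
coordinates; there is no genotyping error, no multi-allelic complexity
beyond what the reader is tested on separately, and planted classes are
unambiguous by design, whereas real variants sit on the boundaries. The
synthetic suite validates the *plumbing and the rules*, not the clinical
sensitivity of the rubric. Raw-sequencing figures (mean depth, fraction of
target covered ≥ 20×) depend on read data the pipeline never sees and are
not reproduced.

## Problem sizes used in the test and acceptance runs

The default suite simulates cohorts of 12–593 patients (the full-size run
carries ≈1850 variants), checks threshold monotonicity under 100 randomized
perturbations of the full-size cohort, verifies the Fisher implementation
exhaustively for all 2×2 tables with N ≤ 30, and averages realized yield
over 200 seeds at n = 150. The complete suite runs in well under a minute on
one CPU.
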