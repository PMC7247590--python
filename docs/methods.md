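# Methods

## Model and procedure

`gvburden` implements a four-stage pipeline.

**1. Score normalization and variant retention.**  Six in-silico
deleteriousness predictors are supported.  SIFT is already oriented
lower-is-deleterious on [0, 1] and passes through unchanged.
MutationTaster and both PolyPhen-2 models are bounded on [0, 1] with
higher-is-deleterious orientation and are flipped affinely (x → 1 − x).
phyloP and GERP++ are unbounded conservation scores; they are min–max
scaled over the raw scores observed in the annotation table and then
flipped, so every variant has a single normalized score cohort-wide
(per-individual scaling would make burdens incomparable across
individuals).  A variant is retained when it is nonsynonymous coding and
its normalized score is ≤ 0.7 (boundary included).  The cutoff is applied
to every method's normalized score, not only SIFT's, behind a
configuration switch: the retention rule is stated for SIFT and the other
five methods are put through the same validation path after
normalization, so the package treats the cutoff as part of that shared
path.  Variants lacking a raw score for a method are simply absent from
that method's burden (no imputation).

**2. Burden aggregation.**  The gene-level burden of gene *j* for one
individual is the geometric mean of the normalized scores of the retained
variants the individual carries in the gene, and 1 when it carries none;
the drug-level burden is the geometric mean of the drug's PK/PD gene
burdens.  Zygosity is collapsed to presence/absence: the burden is defined
over carried variant *sets*, and genotype dosage is deliberately not
modeled.  Genes appearing under several relation types for one drug
(e.g. both enzyme and target) are deduplicated before the mean, and
relation types never weight the mean.

**3. Gold standards.**  Coding associations are removed from the
variant–drug catalog first, so no drug is ever scored against the variants
that produced its burden.  An individual's gold standard is the set of
drugs whose remaining (noncoding) catalog variants it carries.  In
ethnicity-specific mode the association's OMB label must equal the
individual's label under an editable superpopulation→OMB table (default:
AFR→African-American, EAS/SAS→Asian, EUR→Caucasian; AMR unmapped, because
admixed American panels have no single OMB label).  Records without an
ethnicity label are excluded from ethnicity-specific gold standards by
default (their group cannot be asserted) and included in non-specific
ones; both behaviours are configurable.  Individuals whose
superpopulation is unmapped are flagged and excluded from
ethnicity-specific evaluation rather than silently dropped.

**4. Evaluation.**  Drugs are ranked ascending by burden (most
deleterious first).  The ROC sweep moves the rank threshold over the
*distinct* burden values, so drugs tied on burden — and most drugs sit at
burden exactly 1 — enter the predicted-positive set as one block; the
trapezoidal AUC then equals all-pairs concordance with ties counted ½ and
does not depend on input order.  AUC is computed per individual and then
aggregated (mean ± SD), never pooled across individuals; SD uses the
n − 1 convention, and single-individual strata report SD 0 with a
degeneracy flag.  Individuals with an empty gold standard are excluded
from aggregation (the statistic is undefined), and strata where every
individual is empty are reported with n = 0 and flagged.  ATC strata
restrict both the drug universe and the gold standard to the anatomical
main group's drugs before the sweep.  The gene-category comparison uses a
one-sided Mann–Whitney U test (alternative: the named category's
cohort-mean burdens are shifted lower); the test choice is the package's
own, as burden distributions are far from normal.

## Numerical choices

Geometric means are computed in log space with `math.fsum`; a score of
exactly 0 short-circuits to burden 0 with no epsilon flooring, matching
the declared score range.  Min–max normalization with all observed raw
scores equal is rejected as a degenerate scale.  Unaffected genes are not
materialized: profiles store only (individual, gene) pairs with at least
one retained carried variant and report 1 elsewhere.  Variant identity is
the rsID when present on a biallelic record, else `chrom:pos:ref:alt`
with 1-based VCF coordinates; decomposed multiallelic ALT alleles always
use coordinate keys, since one rsID cannot distinguish two ALT alleles of
the same record.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not any real dataset:

* **Cohort** — individuals apportioned to populations by largest
  remainder (default 200 individuals over three populations:
  YRI/AFR 0.34, CHB/EAS 0.33, CEU/EUR 0.33).
* **Coding background** — default 30 genes with Poisson(6) variants each
  (75% nonsynonymous).  Benign variants draw carrier frequencies from
  Beta(0.4, 3) (mean 0.12); deleterious variants from the thin-tailed
  Beta(1, 30) (mean 0.032) — purifying selection keeps strongly damaging
  alleles consistently rare, which is the premise of burden collapsing.
  Frequencies are jittered per population on the logit scale (SD 0.5).
* **Scores** — one latent deleteriousness per variant: Beta(1.2, 20)
  (mass near 0) with probability 0.3, Beta(12, 1.5) (mass near 1)
  otherwise.  Each method observes a monotone distortion of an
  independently noised copy (SD 0.03) mapped to its native range and
  orientation, so cross-method rank agreement is high but not perfect;
  5% of non-SIFT scores are dropped as missing.  Noncoding variants carry
  no scores.
* **Core pharmacogenes** — 8 of the 30 genes get a 3× deleterious
  fraction and 2× variant count (core pharmacogenes are highly
  polymorphic), planting a reliably low-burden gene category.
* **Drugs** — default 60 drugs with 1 + Poisson-distributed gene sets
  (mean 2), relation types drawn roughly in the proportions of large
  drug databases (71% target, 18% enzyme, 9% transporter, 2% carrier),
  one random ATC main-group letter each.
* **Planted associations** — 15 drugs receive a noncoding marker
  (carrier frequency 0.35) plus a deleterious nonsynonymous variant in
  one of the drug's genes; a marker carrier also carries the coding
  variant with probability `linkage_fidelity`, and by default nobody
  else carries it, so fidelity 0 makes planted and noise associations
  exactly exchangeable.  Ethnicity-specific plantings elevate the marker
  only in one target population (frequency 0.05 elsewhere) and operate
  the linkage only there, mirroring population-specific linkage
  disequilibrium; the association is labeled with the target
  population's OMB group.  10 noise associations reference noncoding
  markers with no coding linkage; 5 coding associations exercise the
  noncoding filter.

Marker–causal linkage is simulated directly as a carrier-copy probability
rather than via haplotype recombination: the analysis consumes only
carrier sets, so haplotype machinery would add nothing observable.
Identical seeds produce byte-identical output files (VCF, sample sheet,
annotation, drug–gene map, catalog, truth set, manifest).

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real data: realistic site-frequency spectra,
recombination maps or LD decay, demographic history, transcript-level
annotation ambiguity, correlated missingness between predictors, the
empirical score distributions of the six methods, evidence levels or
curation biases of real association catalogs, and genotype dosage
effects.  Results on synthetic cohorts demonstrate that the pipeline
recovers the signal it is designed to detect when that signal is present
in the stated form, and stays at chance when it is absent.

## Problem sizes used in the test and acceptance runs

Cohort-level checks run at 200 individuals, 30 genes and 60 drugs; the
chance-calibration check averages 20 seed replicates and the
fidelity-sweep and ethnicity checks 10 and 5 replicates respectively.
The gene-category comparison runs at 120 genes with 24 core genes: the
Mann–Whitney test across gene categories gains its power from the number
of *genes*, and 30-gene universes leave the comparison dominated by
between-gene variance regardless of the planted effect.  These sizes are
the package's chosen operating points; all of them complete in seconds.

## Known limitations

* Burdens ignore dosage, phasing and compound heterozygosity; a
  homozygous carrier counts the same as a heterozygous one.
* The ≤ 0.7 retention cutoff for non-SIFT methods is an interpretation
  (see stage 1); turning it off changes those methods' burdens.
* Min–max scaling of unbounded scores depends on the observed annotation
  table: adding variants can rescale every normalized phyloP/GERP++
  score.
* Per-individual AUC with small gold standards is noisy; aggregates over
  few individuals (flagged degenerate strata) should not be
  over-interpreted.
* The ethnicity-specific machinery assumes association labels and the
  cohort's superpopulation→OMB mapping are correct; mislabeled records
  silently dilute the specific gold standard.
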