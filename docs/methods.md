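# Methods

## The problem

TP53 lesions in myeloid neoplasia (MDS, AML, MDS/MPN) carry very different
prognoses depending on whether *both* alleles are inactivated in the same
cell. Bulk sequencing reports only variant allele frequencies (VAFs), and
lesion counting ("single hit" vs "double hit") cannot distinguish a truly
biallelic clone from subclonal mosaicism of two independent monoallelic
clones — nor can it see a small cryptic biallelic subclone hiding inside a
case that looks monoallelic. This package implements a VAF-arithmetic
resolution of the allelic configuration, a survival-guided search for the
VAF cutoff that separates the ambiguous cases, and a clonal-architecture
simulator that generates ground-truthed cohorts on which every stage is
testable end to end.

## Classification model

Let v₁ … v_k be the VAFs (fractions) of a patient's TP53 mutations and
V = min(Σvᵢ, 1) their combined VAF. In diploid cells a fully clonal
heterozygous mutation has VAF 0.5, so the following configurations cannot
be explained without cells carrying two inactivated alleles
(*obligatory biallelic*), tested in order:

1. any single vᵢ > 0.5 (homozygosity via copy-neutral LOH, or hemizygosity);
2. V > 0.5 with mutations assumed in trans (compound heterozygous);
3. V + c > 0.5, where c is the measured clonality of a 17p deletion.

Below these bounds the bulk signal is ambiguous, and mutated patients are
split at a cutoff t (default 0.23): V > t → *probable biallelic*,
V ≤ t → *probable monoallelic*. All inequalities are strict. Patients with
no mutation are WT, or *del17p-only* when only the deletion is present
(the mutation classes do not apply to them). 17p UPD does not promote a
call by itself: UPD doubles the mutant VAF, so rules 1–2 already contain
that evidence; UPD enters only the traditional double-hit count. A
deletion with unquantified clonality skips rule 3 and flags the call
(`clonality_unknown`) rather than imputing a value. With more than two
mutations all VAFs are summed; trans phase is assumed because cis phasing
is unobservable in bulk data.

The traditional comparator counts lesions: one mutation or an isolated
del17p is a single hit; a mutation plus any of {second mutation, del17p,
17p UPD} is a double hit.

## Cutoff search

The cutoff is chosen by treating survival as a surrogate for the
unobservable allelic state. The procedure is the identifiable core of a
single-covariate survival tree: the root-node split maximising the
two-sample log-rank statistic between {V ≤ c} and {V > c}, restricted to
candidates (midpoints of consecutive distinct VAFs, or a fixed 1–49% grid)
leaving at least `min_node` (default 15) patients per side. With one
covariate, forest aggregation adds only resampling variation, which two
explicit layers reproduce:

* **bootstrap split stability** — `subsamples` (default 1000) size-n
  resamples with replacement; the winning split is tallied per resample;
* **cross-validated selection** — `cv_runs` (default 30) random 80/20
  train/test partitions; for each candidate c the classification rule
  (which has no free parameters beyond c) is applied to the held-out test
  fold, patients are scored on the ordinal risk scale WT = 0 (including
  del17p-only), probable monoallelic = 1, probable biallelic = 2,
  obligatory biallelic = 3, and Harrell's C is computed on that fold. The
  selected cutoff is the argmax of the mean test C; exact ties break
  toward the smaller cutoff everywhere (the conservative direction:
  more patients labelled probable biallelic).

The ordinal score is the minimal encoding consistent with the expected
survival ordering of the classes; any strictly monotone transform leaves
the concordance unchanged (asserted in tests). Obligatory-biallelic and
WT/del17p-only patients are unaffected by the candidate cutoff, which the
implementation exploits by precomputing those features once per cohort;
a test asserts bit-equality of this fast path with per-patient
classification at every candidate.

## Survival estimators

All estimators are implemented in-package and cross-checked in the test
suite against lifelines / explicit enumeration:

* Kaplan–Meier product-limit curves; the median is the smallest event time
  with S(t) ≤ 0.5, absent when never reached. Reported dispersion is the
  IQR of observed event times (matching how the source cohort summarised
  medians), not a CI.
* k-sample log-rank test, chi-square reference with k−1 df; a scalar
  U²/V fast path serves the split search.
* Harrell's C: pairs are comparable when times differ and the earlier
  subject died; tied risk scores count 0.5; undefined (hard error) without
  comparable pairs.
* Univariate Cox partial likelihood with Breslow tie handling,
  Newton–Raphson from β = 0, Wald 95% CI; degenerate covariates are
  rejected, non-convergence raises carrying the last iterate. Breslow was
  chosen as the simplest scheme for heavily tied month-scale data; Efron
  is the noted alternative.
* 2×2 odds ratio: cross-product with Haldane–Anscombe 0.5 correction when
  any cell is zero, Woolf log-scale CI, and an `unstable` flag for zero
  rows/columns.

p-values come from the asymptotic chi-square reference; no permutation
option in this version.

## Simulator

A patient is a mixture of cell states (clones); a state has a TP53 locus
copy number (1 in del17p cells, 2 otherwise), mutant copy counts per
mutation, and a cell fraction. A cell is biallelic when mutant copies plus
lost copies reach 2 — compound heterozygous, UPD-homozygous, or hemizygous
mutant. Observables derive from the architecture:

* expected bulk VAF of mutation m: Σᵢ fᵢ·mutᵢₘ / Σᵢ fᵢ·copiesᵢ;
  sequencing draws binomial reads at Poisson-distributed depth (default
  mean 500); variants observed below 1% VAF are dropped as uncalled.
* del17p is reported only when the deleted-cell fraction reaches the
  assay's detection floor (default 20%, the sensitivity limit of
  SNP-array-class methods); reported clonality adds N(0, 0.02) noise,
  clipped to [floor, 1]. Smaller deletions are *cryptic*. UPD is flagged
  under the same floor.
* survival is exponential with stratum medians 42 (WT) / 29 (monoallelic)
  / 14 (biallelic-containing) months — the printed medians of the cohorts
  this model emulates. A patient enters the biallelic stratum as soon as
  the true biallelic cell fraction exceeds 2% (default): presence of the
  clone, not its size, drives the hazard; the 2% default makes a 6%
  biallelic subclone (the validated cryptic case) hazard-relevant. The
  hazard-vs-clone-size relationship is a declared simplification — the
  source quantifies presence only.
* censoring is independent uniform: C ~ Uniform(0, u) with u solved from
  (1 − e⁻ˣ)/x = censor_rate (default 0.2), keeping the product-limit
  estimator unbiased for the stratum medians.
* single-cell genotyping samples cells multinomially from the state
  fractions; each physical allele is observed independently with
  probability 1 − ado_rate (default 0.1). Truth flags are computed before
  dropout. Doublets and dropout asymmetry are not modelled.

The default cohort mixes architecture families as WT 30% and, within the
mutated 70%: monoallelic 19%, cryptic-biallelic 24%, dominant-biallelic
40%, del17p-involving 17% — the published class shares among mutated
patients (57/24/19, with the obligatory 57% split by the ~17% del17p
rate). The WT share is held at 30% rather than the source cohorts' 86% so
a desk-scale cohort (n ≈ 1000–2000) retains usable per-class counts.
Cryptic-biallelic architectures (3–10% UPD-homozygous subclone inside a
small heterozygous clone) are constructed so their combined VAF stays
below the 23% cutoff: the bulk classifier calls them probable monoallelic
while they carry the biallelic hazard. This is the central discordance the
simulator must produce, and it also means the *observed* probable-biallelic
share among mutated patients (~8%) is smaller than the cryptic family's
24% plant — the generator encodes architecture ratios, not observed-label
shares. Disease subtypes, mutation effects (missense 74% / truncated 15% /
other 11%) and canonical-hotspot protein labels are drawn from the
published frequencies and are carried, never interpreted.

A second generator plants a hazard change-point on the VAF axis: mutated
patients receive a true VAF uniform on (0.02, 0.48); above the
change-point (default 0.25) the architecture is UPD-homozygous (biallelic
hazard), below it heterozygous (monoallelic hazard). Every VAF stays below
50%, so the entire signal sits where the cutoff search must find it. Its
`null=True` variant gives all mutated patients the same hazard regardless
of VAF — the no-signal reference for stability checks.

## Numerical choices and edge cases

* VAFs are fractions internally; every file interface speaks percent.
  The double conversion (×100 then /100) is identity to 1 ulp, which is
  the round-trip contract; readers use pandas' round-trip float parser.
* Combined VAF above 1 is capped at 1 with a logged warning.
* Log-rank uses a pseudoinverse for the quadratic form (guards degenerate
  covariance); times with a single subject at risk contribute no variance.
* Cox stops when the Newton step falls below 1e-9 (max 100 iterations).
* `best_split` ties and `crossval_cutoff` ties resolve to the smallest
  cutoff (first argmax index on an increasing grid).
* Bootstrap resamples with an infeasible candidate grid are recorded as
  "no split" and excluded from the frequency table; CV test folds without
  comparable pairs are skipped for that candidate and counted.
* Empty survival input, empty groups, constant Cox covariates and
  undefined concordance are hard errors, not silent defaults.

## Problem sizes used by the test and acceptance runs

Grid checks use ~8×10⁴ rule configurations; brute-force oracle comparisons
use 100 random cohorts (n ≤ 200) for the split search and 100 censored
datasets (n ≤ 50) for concordance; cutoff recovery uses 20 replicates of
n = 1000 with 30 CV runs each; null stability uses 20 seeds at n = 600;
simulator consistency uses depth 500 and 2000 cells. These sizes give the
Monte-Carlo bounds stated in each test while keeping the default suite
fast.

## What passing tests do and do not show

The simulator reproduces the *structure* of the real problem — VAF
arithmetic, detection floors, survival ordering, cryptic discordance — not
the real cohorts: purity and genome-wide copy number are not modelled,
hazards are exponential with three strata, co-mutations and subtype-
specific effects are absent, and VAFs are taken at face value (no
purity/CN adjustment, matching the source's own limitation). Recovery of a
planted cutoff therefore validates the machinery, not the clinical value
23% itself, which was estimated on ~7400 unavailable patient records.
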