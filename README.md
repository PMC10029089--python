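# tp53allelic

Resolving the allelic configuration of TP53 mutations in myeloid neoplasia
from bulk sequencing.

Whether a TP53-mutated MDS/AML clone has lost *both* alleles in the same
cell is one of the strongest prognostic facts about it — and one that bulk
sequencing does not report directly. Counting lesions ("single hit" vs
"double hit") conflates true biallelic clones with subclonal mosaicism and
misses small cryptic biallelic subclones inside cases that look
monoallelic. This package is for biostatisticians and computational
hematologists who want that distinction made explicit, testable, and
reproducible.

## What it does

**Classification.** For a patient with mutation VAFs v₁…v_k (combined
V = min(Σvᵢ, 1)) and optional 17p-deletion clonality c, the allelic call is
the first matching rule:

| rule | condition | label |
|---|---|---|
| 1 | any vᵢ > 0.5 | obligatory biallelic |
| 2 | V > 0.5 (mutations in trans) | obligatory biallelic |
| 3 | V + c > 0.5 | obligatory biallelic |
| 4 | V > t (cutoff, default 0.23) | probable biallelic |
| 5 | otherwise | probable monoallelic |

plus WT / del17p-only for unmutated patients, alongside the traditional
single/double-hit comparator and a reclassification cross-table.

**Cutoff search.** The cutoff t is chosen by survival: a log-rank
split-point search with a minimum node size of 15, bootstrap
split-stability profiling, and selection by Harrell's C on held-out test
folds over repeated 80/20 splits (ordinal risk score WT=0 < probable
monoallelic=1 < probable biallelic=2 < obligatory biallelic=3).

**Survival toolkit.** Self-contained Kaplan–Meier, k-sample log-rank,
Harrell's concordance, univariate Breslow Cox, and 2×2 odds ratios —
cross-checked against independent implementations in the test suite.

**Simulator.** Ground-truthed cohorts built from explicit clonal
architectures (heterozygous, UPD-homozygous, compound heterozygous,
hemizygous del17p, cryptic biallelic subclones): binomial read sampling,
a 20% cytogenetic detection floor, stratum-specific exponential survival
(medians 42/29/14 months for WT/monoallelic/biallelic), and single-cell
genotype matrices with allelic dropout. See `docs/methods.md` for the
model and its limits.

## Worked example

```bash
tp53allelic simulate --n 400 --seed 11 --out-prefix sim_
tp53allelic run-all --patients sim_patients.tsv --variants sim_variants.tsv \
    --cyto sim_cyto.tsv --cutoff 23 --seed 11
```

prints (abridged):

```
cohort: 400 patients

traditional hit classes:
  WT                     125
  single_hit             108
  double_hit             167
allelic-configuration classes:
  WT                     125
  obligatory_biallelic   159
  probable_biallelic     22
  probable_monoallelic   94
  del17p_only            0

survival by allelic class (median OS months [IQR of event times]):
  WT                     n=125   events=99    median=51.6 [21-67]
  probable_monoallelic   n=94    events=77    median=20.8 [7-33]
  probable_biallelic     n=22    events=19    median=25.0 [10-39]
  obligatory_biallelic   n=159   events=129   median=15.4 [5-22]

univariate Cox vs WT:
  obligatory_biallelic vs WT                    HR=4.38 [3.17-6.04]
  probable_biallelic vs WT                      HR=2.63 [1.57-4.38]
  probable_monoallelic vs WT                    HR=2.19 [1.61-2.99]
```

Reading it: 400 simulated patients, of whom 159 carry VAF arithmetic that
*forces* a biallelic call (rules 1–3). The probable-monoallelic group's
median OS (20.8 months) sits well below the WT group's (51.6) because this
simulated cohort deliberately hides cryptic biallelic subclones below the
23% cutoff — the exact discordance the method exists to expose; their
truth labels are in `sim_truth.tsv`. The same workflow runs on any real
cohort supplied as the three TSV tables (`patients.tsv`, `variants.tsv`,
`cyto.tsv`; VAFs in percent — see `tp53allelic --help` and the column
contracts in `src/tp53allelic/core_io.py`).

The cutoff search is its own subcommand:

```bash
tp53allelic optimize-cutoff --patients sim_patients.tsv --variants sim_variants.tsv \
    --cyto sim_cyto.tsv --runs 30 --seed 7 --out cutoff.json
```

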