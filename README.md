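# tmburden

Tumor mutational burden (TMB) — the count of protein-altering somatic
mutations per megabase of coding sequence — is an FDA-approved biomarker
(TMB-high: >= 10 mutations/Mb) for checkpoint-inhibitor therapy. When no
patient-matched germline sample is sequenced, somatic mutations are
identified by removing variants found in public population catalogs,
optionally above an allele-frequency threshold tau. Because those catalogs
over-represent European ancestry, this tumor-only shortcut inflates TMB,
and inflates it *more* for patients from under-represented groups — a
racially disparate bias in treatment selection.

`tmburden` is a pipeline for quantifying that bias. It computes
per-patient TMB under four filtering criteria —

* `TMB_Germline` — subtract the patient-matched germline call set (gold standard)
* `TMB_DB0` — exclude any variant reported in any database
* `TMB_DB0.001` / `TMB_DB0.01` — exclude variants with frequency >= tau
  (0.1% / 1%) in **any** database

— over a 75 Mb whole-exome region and a 1059-gene (7 Mb) cancer panel,
then compares groups: mean (SE) tables, pooled-variance t-tests, the
two-way ANOVA `TMB ~ group + criterion + group:criterion` whose
interaction term is the disparity statistic, cross-criterion Pearson
correlations, and TMB-high discordance (patients called TMB-H tumor-only
but not by the gold standard).

Real cohorts of this design are controlled-access, so the package includes
a first-class synthetic-cohort generator: Balding–Nichols
population-differentiated allele frequencies (FST-parameterized),
population-private variants, Hardy–Weinberg genotypes, gamma-Poisson
somatic counts, and a public database built by finite binomial sampling
with unequal ancestry composition (default: 60,000 individuals, 54.9%
European / 8.6% African). See `docs/methods.md` for the model and its
limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort shaped like the real one (575 White / 126 Black patients):

```bash
python analysis/01_simulate_cohort.py --seed 1   # writes results/tmb_table.tsv
python analysis/02_group_summaries.py
python analysis/03_interaction_and_correlations.py
python analysis/04_tmb_high.py
python analysis/05_db_representation_sweep.py
```

With seed 1 this prints, for the exome region:

```
TMB (mutations/Mb), mean (SE) — exome:
group                  Black          White
criterion
TMB_Germline   5.660 (0.216)  5.747 (0.107)
TMB_DB0        5.662 (0.216)  5.748 (0.107)
TMB_DB0.001    6.026 (0.215)  5.791 (0.107)
TMB_DB0.01    11.419 (0.215)  6.547 (0.107)

exome: interaction F(3,2796) = 94.86, p = 1.83e-58

TMB-H threshold: >= 10.0 mutations/Mb (exome)
  Black  TMB_DB0.01  : 81 patients TMB-H under tumor-only filtering but not under paired germline
  White  TMB_DB0.01  : 17 patients TMB-H under tumor-only filtering but not under paired germline
```

Reading: under the gold standard the two groups have statistically
indistinguishable TMB (t-test p = 0.73), but with 1%-threshold tumor-only
filtering the Black group's mean is inflated by 5.8 mutations/Mb versus
0.8 in the White group — a strongly significant group:criterion
interaction — and 81 of 126 Black patients (vs 17 of 575 White patients)
would be wrongly classified TMB-high. The dose-response sweep
(`05_db_representation_sweep.py`) shows the inflation gap shrinking from
17.3 to 0.3 mutations/Mb as the database's African-ancestry sample grows
from 64 to 3,294 individuals: the disparity is a database-representation
effect.

## Library and CLI

All computation lives in `src/tmburden/` (`variant_core`,
`somatic_filtering`, `tmb_calculator`, `cohort_stats`,
`synthetic_cohort`, `experiments`, `pipeline`). A thin `tmburden` CLI
wraps it:

```bash
tmburden fixture  --out fx/                      # 3-patient micro-cohort
tmburden tmb      --mode vcf --metadata fx/cohort_metadata.tsv \
                  --frequency-table fx/frequency_table.tsv \
                  --panel-genes fx/panel_genes.txt --out out/
tmburden report   --tmb-table out/tmb_table.tsv
tmburden simulate --seed 7 --out cohort/         # emit VCFs + TSVs
tmburden compare  --tmb-table out/tmb_table.tsv --out cmp/
```

Criterion specs are `germline`, `db:0`, `db:0.001`, `db:0.01`, or any
`db:<float>`. Exit codes: 0 success, 2 config error, 3 data error. Every
run writes a `manifest.json` with the config echo, seed, version and
input/output checksums; identical config + seed reproduces byte-identical
TMB tables.

VCF input is standard v4.2 with per-record `IMPACT`
(HIGH/MODERATE/LOW/MODIFIER) and `GENE` INFO keys (key names
configurable); frequency tables are TSV with columns
`CHROM POS REF ALT DB AF [AC AN]`, one row per (variant, database).

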