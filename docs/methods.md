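# Methods

## Problem and model

Tumor mutational burden (TMB) is the number of protein-altering somatic
mutations per megabase of sequenced coding region. When a patient-matched
germline sample is available, somatic status is decided by subtracting the
germline call set from the tumor call set (the gold standard). In
tumor-only sequencing, somatic status is instead approximated by removing
tumor variants that appear in public population catalogs (1000 Genomes,
ExAC, ESP6500, ...), either any reported variant (tau = 0) or variants
whose catalog frequency reaches a threshold tau (here 0.1% and 1%). Because
those catalogs over-represent European ancestry, rare and
population-private germline variants carried by patients from
under-represented groups are less likely to be filtered, so tumor-only TMB
is inflated more for those patients. This package computes per-patient TMB
under both filtering families and quantifies the differential inflation
between self-reported groups.

The four criteria, in the order used everywhere:

| label        | rule                                                        |
|--------------|-------------------------------------------------------------|
| TMB_Germline | exclude tumor variants present in the matched germline set   |
| TMB_DB0      | exclude variants reported in any database                    |
| TMB_DB0.001  | exclude variants with frequency >= 0.001 in any database     |
| TMB_DB0.01   | exclude variants with frequency >= 0.01 in any database      |

Exclusion is at frequency **>= tau** (a variant at exactly tau is removed),
the boundary the criteria's verbal definitions imply; retained sets are
therefore nested in tau, which forces per-patient TMB_DB0 <= TMB_DB0.001 <=
TMB_DB0.01. The database rule is a logical OR over named catalogs, not a
pooled frequency. Database frequencies are used as alternate-allele
frequencies, unfolded; a `fold` option compares min(af, 1-af) instead for
workflows whose annotations are true minor-allele frequencies. A catalog
entry with allele count 0 counts as unreported. Variant identity is exact
(chrom, pos, ref, alt); inputs are assumed pre-normalized and
multi-allelic records are decomposed on read. Only PASS/unfiltered VCF
records enter the analysis. Impact categories HIGH and MODERATE count as
protein-altering; LOW and MODIFIER never count. Counting regions are
configured constants — a 75 Mb whole-exome region and a 7 Mb panel of 1059
cancer genes — with an optional BED override that sums merged half-open
intervals. Variants without a gene annotation count toward the exome but
cannot be attributed to the panel.

## Synthetic cohorts

Real cohorts of this design are controlled-access, so the package ships a
generator that reproduces the *statistical structure* the analysis needs.

**Germline sites.** `n_sites` biallelic sites with ancestral frequencies
p ~ Beta(`sfs_alpha`, `sfs_beta`); defaults Beta(0.15, 8), a rare-skewed
frequency spectrum. Population frequencies follow the Balding–Nichols
model, p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F), so E[p_k] = p and
Var[p_k] = F·p(1-p); F = 0 degenerates to a point mass (no draws
consumed), F >= 1 is rejected. A fraction of sites is private to one
population (frequency fixed at 0 elsewhere); defaults 5% European-private
and 15% African-private, reflecting the larger private variation of
African-ancestry genomes relative to European-centric catalogs.

**Public database.** Allele counts are binomial draws from 2N chromosomes
per population, summed; an = 2·ΣN; sites with zero sampled copies are
absent from the table. Default composition: 60,000 individuals of which
54.9% European and 8.6% African — the documented ancestry makeup of the
large exome catalogs. Database individuals are simulated separately from
cohort patients.

**Patients.** Genotypes are Hardy–Weinberg Binomial(2, p_k) draws.
Detected germline variants enter the tumor and germline call sets
independently with probability `germline_sensitivity` (default 1.0 — the
guarantee that paired-germline TMB <= database-filtered TMB per patient
requires every tumor-borne germline variant to also be seen in the
germline sample; lower sensitivity is an exposed option that breaks that
bound realistically). Somatic counts are Poisson with a
gamma-distributed patient rate (mean 8 mutations/Mb, shape 5, i.e. CV ~
0.45 — chosen so germline-paired counted TMB has the ~5.5 ± 2.5
mutations/Mb scale of a newly diagnosed myeloma cohort). Somatic mutations
are placed at positions disjoint from the germline panel by default
(`collision_rate` relaxes this); positions are bookkeeping identities only
— no linkage, hotspots, signatures, copy number or subclonality are
modeled. Impact labels: MODERATE/HIGH with probability 0.7 (HIGH 20% of
those), else LOW. Genes are uniform over 11,346 equal-length gene slots,
with the panel being the first 1,059 — the same 7/75 fraction of the
exome as the configured region sizes.

**Scale.** `n_sites` defaults to 200,000 — a deliberate ~35x scale-down of
the several-million-site catalogs, giving each patient roughly 7,000
carried coding variants. Consequently absolute inflation values are
smaller than a full-scale catalog would produce; the qualitative structure
(near-zero inflation at tau = 0, growing with tau, larger in the
under-represented group, shrinking as that group's database representation
rises) is the object of study and is insensitive to the scale-down.

**Reproducibility.** All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawn keys: `(0,)` site panel, `(1,)`
database, `(2, i)` patient i — so any patient regenerates independently.
A vectorized counting path (`simulate_cohort_tmb`) consumes exactly the
same draws as the object path (`simulate_cohort` + filters) and is tested
for record-for-record equality; replicate studies use it.

## Statistics

Group cells are summarized as mean and SE = sd/sqrt(n) (n-1 denominator;
single-patient cells report a missing SE). Between-group comparisons use
the pooled-variance Student t-test (Welch is exposed but off by default,
matching the named method); zero pooled variance with equal means yields
t = 0, p = 1, with unequal means it is rejected as degenerate. The
group:criterion interaction is the model-comparison F between
`tmb ~ group + criterion` and the model with the interaction added —
equivalent to the interaction term tested last under any sums-of-squares
type, hence well-defined for unbalanced groups; the reported SS table is
sequential (group, criterion, interaction, residual). Pearson correlations
of per-patient TMB across criteria are reported per region; zero-variance
columns give missing entries. TMB-high status is tmb >= threshold
(inclusive; default 10 mutations/Mb), and discordance counts patients
TMB-H under a database criterion but not under paired germline. No
multiple-testing correction is applied (raw p-values are reported; the run
manifest records the number of tests).

**Known limitation (deliberate).** The ANOVA treats each patient's four
TMB values as independent rows although they are repeated measures sharing
the patient's somatic count. The analysis reproduces that model as
published rather than switching to a mixed model. The consequence is a
*conservative* interaction test on cohort data: under an
exchangeable-groups null the patient effect cancels exactly in interaction
contrasts while still inflating the residual MSE, so the realized type-I
rate falls far below the nominal level (0/500 replicates at alpha = 0.05
in the packaged check) — the test's rejections are therefore trustworthy,
but its nominal calibration is not attained on cohort data. On independent
observations the implementation is correctly calibrated (additive-truth
simulations recover the 5% level) and the F statistic matches an
independent nested least-squares oracle to 1e-9.

## Replicate studies and problem sizes

The packaged experiments use a scaled-down disparity scenario — 160 + 40
patients, a 6,000-individual database at the 54.9%/8.6% composition,
FST 0.1, 10% African-private sites, zero European-private sites, equal
somatic rates — and an exchangeable null scenario (100 + 100 patients,
equal FST, no private-site asymmetry, equal database sampling of 1,500
individuals per population, 20,000 sites). Equal group sizes in the null
scenario keep the F-test's behavior from being confounded by cell-size
imbalance; the type-I property under exchangeability does not depend on
cohort asymmetry. Mechanism checks run 20 replicates, power checks 100,
calibration checks 500. The dose-response sweep varies the African-ancestry
database sample over {64, 516, 3294} individuals with the European sample
fixed.

## What passing tests do and do not show

The generator reproduces population-differentiated germline variation,
finite-sample database ascertainment, and somatic count dispersion; it does
not model linkage disequilibrium, sequencing error, caller artifacts,
mutation signatures, tumor purity, or the correlation between ancestry and
tumor biology. Passing tests therefore demonstrate that the *filtering
arithmetic and inference machinery* behave as specified and that
database under-representation alone is sufficient to produce the observed
disparity pattern — not that real cohorts are free of additional sources
of bias, nor that the simulated magnitudes equal those of any particular
real cohort.
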