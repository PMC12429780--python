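# Methods

## Cohort model

An analyzable individual carries a group label (pMN / sMN / control),
two resolved HLA-DQ haplotypes (a DQA1 + DQB1 allele each, as linked
typing provides them — no phasing or imputation is attempted), an
rs4664308 genotype, and optional immunostaining/serology phenotypes
(defaulting to `not_done`). Allele names are normalized to two-field
colon form ("05:01"); legacy concatenated-digit names (0501, 030201,
05010101) are split into 2-digit fields and truncated to two. Serotype
identity is a protein-level property, so synonymous and noncoding
fields carry no information here and truncation loses nothing the
analysis uses. Genotypes are stored in canonical alphabetical order
(AG); the file reader rejects "GA" rather than silently reordering, so
data-entry irregularities surface. Ethnicity is accepted as passthrough
metadata and never used in computation. The file dialect is fixed
(TSV, UTF-8, "." for missing optionals) so that equal cohorts always
serialize to byte-identical files.

## Serotype engine

Two haplotypes contribute up to two distinct alpha and two distinct
beta chains; every alpha x beta pairing is enumerated unconditionally
(free pairing, no stability filter), giving 1, 2 or 4 dimers — exactly
(distinct alphas) x (distinct betas). A pairing present on a single
input chromosome is cis; otherwise trans. When cis and trans would
produce the same allele pair the dimer is kept once and flagged cis,
since the proteins are indistinguishable.

The dimer → serotype map is shipped as data
(`src/dqrisk/data/serotype_table.tsv`), not code. Patterns are exact
two-field names or a bare allele-group field (e.g. alpha "03" matching
03:01 and 03:02, as DQ8 is conventionally defined); exact entries take
precedence over group patterns, then first match wins, and unmatched
dimers get "other". The default table contains only the serotypes this
analysis names — DQ2.5 (05:01 with 02:01 or 02:02), DQ2.2, DQ7.5,
DQ6.2, DQ8.1 — deliberately minimal rather than a full nomenclature
dictionary; users with finer typing supply their own TSV.

Combinations are keyed two ways: `haplotype_pair` (default), the
unordered pair of cis haplotype labels ("DQ2.5/DQ8.1", sort-stable
under haplotype swap), and `serotype_set`, the sorted set of all
serotypes the individual's dimers realize. The pair mode treats the
genotype as the unit; the set mode follows the dimer-level reading of
"serotype combination". Both are deterministic.

## Association tests

Counting is per chromosome: feature + complement = 2N in every group
(A-allele dose is 2/1/0 for AA/AG/GG). Pairwise 2x2 tables
(pMN–control, pMN–sMN, sMN–control) are tested with a two-sided Fisher
exact test in the minimum-likelihood convention: conditioning on all
margins, p is the sum of hypergeometric probabilities of every table no
more probable than the observed one. Probabilities are computed in log
space via log-gamma; a relative tolerance of 1e-7 treats
floating-point-tied tables as ties; accumulated p within 1e-12 of 1
snaps to 1 (the full support sums to exactly 1 in exact arithmetic).
Degenerate tables (a zero margin) return p = 1 and are flagged. The
kernel is validated in the test suite against exact-rational
enumeration (Fractions over binomial coefficients) and against an
independent library implementation.

The three-group omnibus comparison uses the same minimum-likelihood
rule generalized to 3x2 tables by full enumeration with fixed margins
(Freeman–Halton style); at this cohort's scale the enumeration is a few
thousand tables.

Multiplicity: the three pairwise tests use a Bonferroni threshold of
alpha/m kept unrounded (0.05/3 = 0.01666…, not 0.016 or 0.017), with
strict `p < threshold` significance — so p = 0.034 on the pMN–sMN
allele comparison is reported non-significant.

## Risk score

For each combination, rs4664308 genotype frequencies are computed among
the combination's carriers within the pMN and control groups (carrier =
the individual's combination key matches; an individual carrying a
serotype via several dimers counts once), and

    score = f(pMN_AA) + 2 f(pMN_AG) − 2 f(control_AA) − f(control_AG)

Bounds [−2, 2] follow from the frequencies being sub-distributions; +2
requires all pMN carriers AG and no control AA/AG carriers, −2 the
mirror image. sMN individuals never enter the score. Zero carriers in
both groups makes a combination undefined (excluded from the ranking);
zero in exactly one group leaves that group's terms 0 and flags the
result low-confidence. Ranking is by descending score with
lexicographic tie-break, so output order is reproducible. The carrier
denominator is the default; a whole-group denominator is available
behind `denominator="group"` as an alternative sample-size
normalization, since both readings are defensible.

A property worth knowing: under a null in which both groups draw
genotypes from one shared distribution (P(AA)=a, P(AG)=h), the score's
expectation is h − a, not 0 — the formula weights AA and AG
asymmetrically between groups. The score is therefore unbiased under
neutrality exactly when a = h, which holds under Hardy–Weinberg at
A-allele frequency 2/3. The neutral test fixture uses (0.4, 0.4, 0.2)
for this reason; with other baselines, score differences between
combinations remain meaningful but the zero point shifts.

No statistical test is attached to the scores: at realistic cohort
sizes most combinations have too few carriers, which is also why the
package reports carrier counts alongside every score.

## Synthetic cohorts

`generate_cohort` draws, per individual, two haplotypes independently
from the group's pool (no linkage or population structure between an
individual's chromosomes — nothing in the analysis models it), then a
genotype from the group's baseline distribution unless an effect
override matches the individual's combination. Genotype is otherwise
independent of HLA, which makes the scoring null true by construction.
One integer seed drives a single `numpy` generator stream consumed in
fixed order (groups pMN, sMN, control; per individual hap1, hap2,
genotype), so equal seeds give byte-identical cohort files across
platforms.

The default configuration emulates the study conditions: group sizes
52 / 15 / 77; per-group DQ2.5 haplotype frequencies 27/104, 11/30,
18/154; Hardy–Weinberg genotypes at per-group A-allele frequencies
81/104, 17/30, 94/154. The rest of the haplotype pool (DQ7.5, DQ6.2,
DQ8.1, DQ2.2 and two unnamed haplotypes) uses fixed plausible European
relative weights, chosen once — the published marginals constrain only
DQ2.5.

`table1_fixture` is deterministic: it reproduces every published count
exactly. Genotype splits are resolved from the published allele totals
by maximizing the AG count (pMN 29 AA / 23 AG, sMN 2 / 13, control
17 / 60) since per-group genotype counts are not published.
Staining/serology follow the printed positivity: 30 pMN stained with 24
positive (80%), 17 pMN serology-tested with 13 positive (76.5%), all
tested sMN negative. The sources disagree on whether 30 or 31 pMN
patients were stained; the fixture follows the percentages (24/30).
Because DQ2.5 haplotypes, AA genotypes and positive phenotypes are all
assigned from the start of each group, the fixture's score ranking is
an artifact of that deterministic layout — the fixture validates
counting and testing, not score semantics.

The neutral and implant fixtures use a two-haplotype pool (DQ2.5 and
DQ7.5 at 0.5 each), so every combination has ≥ ~13 expected carriers
per group. This is deliberate: with singleton carriers a single AG
patient saturates the score at ±2 and top-rank recovery is not
identifiable — the same small-sample limit that precludes statistics on
rare combinations in real cohorts. The implant effect is maximal (risk:
all pMN carriers of DQ2.5/DQ2.5 are AG; protective: all control
carriers AA), and is recovered at the top/bottom rank in ≈97–99% of
seeded replicates (the validation threshold is 95% over 200 seeds).

## Pipeline

`run_pipeline` chains serotype-table load, cohort acquisition (file or
synthetic), association, crosstab and scoring, then writes a bundle
(cohort echo, count table, test results as TSV + JSON, score ranking,
crosstab, rendered markdown report, and a manifest with package
version, seed and SHA-256 input hashes). Failures abort with a
stage-named error and remove partial outputs. All outputs are
deterministic functions of the inputs and seed; no timestamps are
written, so reruns are byte-identical.

## Problem sizes used in validation

The exact-test kernel is checked on 1000+ random tables with totals
≤ 40 against exact-rational enumeration (1e-10), and pmf normalization
at the cohort's actual margins (n = 258). Dimer combinatorics are
checked on 10,000 random haplotype pairs. Score bounds use 1e5 random
frequency-vector pairs; the neutral-score and implant-recovery
properties use 500 and 2 x 200 generated cohorts of 144 individuals.

## Known limitations

- The serotype dictionary is minimal by design; haplotypes outside it
  collapse into "other", which can merge biologically distinct
  combinations.
- The generator draws haplotypes independently within and between
  individuals: no Hardy–Weinberg deviation, linkage disequilibrium
  between haplotypes, or HLA–SNP correlation beyond explicit overrides.
  Passing tests therefore demonstrate correctness of the machinery
  under the stated model, not robustness to population structure in
  real data.
- Phenotype fields are carried and cross-tabulated but not modelled;
  synthetic cohorts leave them `not_done` except in dedicated fixtures.
- Combinations observed in only one group get one-sided scores
  (flagged low-confidence); interpreting them as risk or protective
  rests on sparse evidence.
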