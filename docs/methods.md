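# Methods

## Scope and data model

The unit of analysis is one annotated variant observed in one proband: gene,
dbSNP identity (or the novelty marker `New`), cDNA/protein change,
consequence class (missense, nonsense, frameshift, splice, in-frame indel),
in-silico predictor annotations, reference allele frequency with its
population scope, zygosity, chromosome class, and gene-panel assignment.
Raw reads and VCFs are out of scope: all annotations (SIFT, PolyPhen2,
MutationAssessor, CADD PHRED, LoF-Tool, gnomAD frequencies) arrive as input
columns.  The packaged fixtures transcribe the study's four printed panel
tables (14 + 31 + 13 + 19 rows); inconsistencies in the source are
preserved and surfaced, not corrected (see *Known source inconsistencies*).

Table dialect: frequencies accept both `3.95e-4` and `3.95 × 10^-4`
notation; a trailing asterisk marks a *global* frequency used where no
Latino/Admixed-American stratum value exists; `New` marks a novel variant
(no frequency by definition); `NF` marks the one known variant whose
frequency the reference does not report.  Statistics use the frequency as
given regardless of scope — the source mixes scopes without renormalizing —
but the scope is carried into every output.

## Deleteriousness classification

* **Missense**: deleterious iff ≥ 2 abnormal predictors among SIFT,
  PolyPhen2, MutationAssessor — or ≥ 1 for a novel variant.  SIFT is
  abnormal on label `D`; when only a score is available, score < 0.05.  The
  printed label wins over a contradicting score (the fixtures contain a
  `D (0.085)` case); the conflict is recorded in the call's notes.
  PolyPhen2's HumDiv and HumVar sub-models count as **one** predictor,
  OR-combined: counting them separately would make almost every variant
  reach two abnormalities and contradict the novel-rule example in the
  fixtures.  MutationAssessor is abnormal at medium or high impact.
* **Splice / nonsense / frameshift / in-frame indel**: deleterious iff
  CADD PHRED ≥ 20 (inclusive); when CADD is absent, a LoF-Tool `PD` label
  is trusted (no numeric LoF-Tool cutoff is imposed — the score is stored
  but not thresholded).  The novel-variant relaxation applies to missense
  only.
* A variant with no usable predictor raises an explicit
  insufficient-annotation error rather than defaulting to benign.

Panel filtering keeps every non-synonymous variant in the
previously-TGA-associated panel regardless of clinical tier, and only
VUS / likely-pathogenic / pathogenic variants in the three cilia panels.
"Possibly pathogenic" in the source vocabulary is mapped to the standard
likely-pathogenic tier.  Because the printed cilia tables do not carry
clinical tiers, fixture rows are assigned VUS (likely-pathogenic for the
ClinVar-classified PIBF1 c.1214G>A), and the TGA-panel rows `unclassified`
— that panel's filter ignores the tier by construction.

## Allele aggregation

Carrier dose is 1 (het), 2 (hom), 1 (hemi); the denominator is
2 × patients = 22 for autosomes and 2 × females + males = 13 for the X in
the 9 M / 2 F study cohort.  The source never states its X denominator —
all its printed n = 22 statistics are autosomal — so the 2F + M rule
affects only new analyses.  The same variant observed twice in one patient
is an input error, never double-counted; panels overlap, so cohort-level
computations deduplicate by (patient, gene, cDNA change) first.

The headline statistic is the binomial **point** probability
C(n,k) p^k (1−p)^(n−k), evaluated in log space (gammaln), because the
source's printed 0.2184 for 2/22 at p = 0.053 equals the point mass — the
upper tail at k ≥ 2 is ≈ 0.327.  The point mass is *not* a calibrated
p-value and is labelled "point probability" in all outputs; the upper tail
Pr(K ≥ k) is always computed alongside and is the quantity whose null
rejection rate is verified to be ≤ nominal in the synthetic calibration.
Novel variants (and the `NF` case) yield an explicit not-computable result
carrying (k, n) and a reason.

The sex-difference test is the two-sided Fisher exact test under the
probability-ordering convention: all tables with the observed margins whose
hypergeometric probability is ≤ the observed one (relative tolerance 1e-7,
guarding round-off at ties) contribute.  Degenerate margins give p = 1.
Both statistics are authored here and cross-checked in the tests against
scipy and against brute-force enumeration oracles (all 2^n sequences for
the pmf, n ≤ 10; all margin-constrained tables for Fisher, totals ≤ 40).

## Interaction clustering and enrichment

Edge lists arrive in STRING protein-links dialect (integer combined scores
0–999, divided by 1000) or unit-scale TSV; self-edges are dropped and
symmetric duplicates keep the maximum confidence.

**MCL**: transition matrix = column-normalized adjacency (confidences as
weights, unit self-loops); iterate expansion (matrix power, default 2) and
inflation (elementwise power, default 2.0, then column renormalization)
until the maximum entry change < 1e-6 or 100 iterations.  Clusters are the
weakly connected components of the limit matrix's support (entries > tol);
components of the input graph can therefore never merge.  Cluster ids are
assigned by lowest-ordered member over lexicographically sorted nodes, so
the partition is deterministic; non-convergence returns the current
partition flagged `converged=False`.  Raising inflation empirically does
not decrease cluster count on the packaged synthetic fixtures (asserted
there only — MCL has no strict theorem here).

**Enrichment**: the external database's analytic enrichment p-value is
replaced by a documented permutation test — observed edges within the gene
set versus the same count after degree-preserving double-edge-swap
randomization of the whole graph (10 × |E| swaps per permutation; the swap
can saturate on near-complete graphs, in which case the achieved swaps are
kept — degrees are preserved regardless and asserted per permutation), with
the add-one correction p = (1 + #{null ≥ obs}) / (1 + N).  Reproducible
for a fixed seed; the seed is part of the result record.

Per-patient subnetworks are induced on the proband's deleterious genes at a
confidence tier (0.15 / 0.40 / 0.70 / 0.90 by convention, any value in
[0, 1] accepted); genes without retained interactions — including genes
absent from the background network — stay as singletons, since they are
real findings that are merely unconnected at that tier.

## Synthetic data

The generator defines the study-like conditions under which the pipeline is
validated: 11 patients, 9 male / 2 female by default, so the 22 / 13
denominators arise naturally.  Genotypes follow Hardy–Weinberg sampling —
autosomal dose ~ Binomial(2, AF); X-linked females Binomial(2, AF), males
Bernoulli(AF) recorded as hemizygous.  Predictor profiles are drawn
conditional on a ground-truth deleterious label (deleterious missense:
SIFT U(0, 0.05)/`D`, PolyPhen2 U(0.9, 1)/`PD`, MutationAssessor M or H;
benign: U(0.2, 1)/`T`, U(0, 0.3)/`B`, N or L; loss-of-function classes CADD
U(25, 45) vs U(5, 15)), with a 10% default discordance rate that flips one
predictor to exercise the 2-of-3 logic.  Graphs follow a planted-partition
model with confidences U(0.4, 0.95).  A single root seed derives
independent sub-streams per stage, and identical seeds give byte-identical
outputs.

What the generator does **not** emulate: linkage disequilibrium between
variants, realistic predictor-score correlation structure (real predictors
disagree in correlated, gene-dependent ways), annotation errors, and the
topology of real protein-interaction databases.  Passing the synthetic
checks therefore demonstrates internal correctness and statistical
calibration of the machinery, not performance on real exomes.

Validation problem sizes were chosen to be decisive yet quick: 200
replicates for both null calibrations (3·SE band at nominal 0.05), 100
permutations per enrichment replicate on 30-node background graphs, 1000
permutations for the planted-clique check, and 3 × 10-node blocks
(0.9 / 0.05 edge probabilities) for MCL recovery.

## Known source inconsistencies (preserved, surfaced)

* A female proband is printed hemizygous for OFD1; the fixture keeps the
  label and the consistency report flags it.
* The non-motile and trafficking tables disagree on the heterozygous
  PIBF1 c.1214G>A carrier (T180101 vs T180201); the union therefore counts
  6 alleles, while the trafficking table alone gives the reported
  two-homozygote + one-heterozygote configuration (5 of 22).  Both numbers
  are printed by the aggregation driver.
* One known variant (MNS1 c.605delA) has frequency `NF`; it is modelled as
  an explicit not-found marker rather than relaxing novelty bookkeeping.
* The prose and tables disagree on one OFD1 cDNA change; fixtures follow
  the tables.
* A discussion-section probability for PIBF1 (6.02e-3) cannot be derived
  from any (k, n, p) combination in the tables and is deliberately not
  reproduced; likewise the sex-stratified exact-test value requires
  reference sex counts that are not part of the data, so only the generic
  operation is provided.

## Limitations

* The packaged interaction network is synthetic; global network statistics
  (fraction of genes networked, number of clusters) depend on external
  database content and are not comparable.
* The binomial model treats cohort alleles as independent draws at the
  reference frequency; it ignores relatedness, population substructure, and
  winner's-curse effects of scanning many variants.
* The composite classifier inherits the biases of its constituent
  predictors and the printed labels; it recomputes nothing from sequence.
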