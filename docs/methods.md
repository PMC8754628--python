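# Methods

## Score composition

A variant's tissue-specific score is the product of two forest
probabilities, `S_t = G · T_t`.

The **generic stage** `G` is a 500-tree random forest
(`sklearn.RandomForestClassifier`, raw vote fractions, no probability
recalibration) over 15 features extracted against the union of all
biosample annotations: seven binaries (eQTL membership; TF ChIP-seq peak;
matched TF motif — a motif hit for a TF whose peak also covers the
variant; matched DNase footprint — footprint and DNase peak
co-occurrence; DNase peak; any TF motif; any DNase footprint) and eight
numerics (maximum |ΔIC| over motif hits; median, 95th percentile and
sample standard deviation of per-dataset ChIP-seq signal at the position;
the same three for DNase signal; and one externally supplied
functional-significance column, defaulting to 0 when absent — it is an
input, never computed here).  The exact feature roster lives behind a
named `FeatureSchema` so it can be re-pointed without code changes.

The **tissue stage** `T_t` averages six per-cell-line forests (unweighted
mean, order-invariant), each trained with `class_weight="balanced"` on
seven binary features of one biosample: DNase peak, DNase footprint, and
the five widely assayed histone marks H3K27ac, H3K4me1, H3K4me3,
H3K36me3, H3K27me3.  Per-cell-line models may add H3K4me2 via
`TISSUE_SCHEMA_8`; the cross-tissue ensemble keeps the five-mark schema
because those marks cover most tissues.  Positives for a cell line's
model are its ASB variants; controls are all other training variants.
Both forest stages use 500 trees; the tissue count mirrors the generic
stage for symmetry.  Since `mean(G·T) = G·mean(T)`, averaging member
probabilities before or after multiplying by `G` is equivalent; the
implementation averages first.

Organ-specific scores evaluate `S` on an `OrganBundle`: the set union of
every member biosample's intervals, so each binary organ feature is the
OR of the member features.  Because the forest is not monotone, the organ
*score* need not dominate the member tissue scores — only the feature
aggregation is guaranteed, and that is what the tests assert.  Organs
without both histone and DNase data are refused by name rather than
silently scored zero.  Only chromosomes 1–22 and X are scored at organ
level.

## ASB training labels

Allelic imbalance at a heterozygous site is tested against a symmetric
beta-binomial null: ref count `k ~ BetaBinomial(n, α, α)` with
`α = (1/ρ − 1)/2`, so ρ is the standard overdispersion `1/(2α+1)` and
ρ = 0 reduces to Binomial(n, ½).  The two-sided p-value is
`min(1, 2·min(P(X ≤ k), P(X ≥ k)))`, which at ρ = 0 equals the exact
binomial two-sided p.  ρ is estimated by pooled method of moments from
`E[(k/n − ½)²] = (1 + (n−1)ρ)/(4n)`, clamped to [0, 0.99], and requires
at least 50 sites with depth ≥ 6 (otherwise supply a configured default).

Calling proceeds by: removing sites inside copy-number-variable regions
(read-depth ratio < 0.5 or > 1.5); testing only sites whose reads fall in
the same dataset's binding peaks and whose depth reaches a configurable
minimum (default 6 — the protocol this mirrors does not publish the
value, so it is a parameter, not an assertion); Benjamini–Hochberg
correction across all tests at FDR 0.05.  A variant is positive when
significant in at least one dataset.  "Non-allelic" means exactly equal
read counts on the two alleles at a tested site.

The negative set combines three sublists with equal total weight (each
sums to 1/3, positives sum to 1, so classes balance): non-allelic
variants; for each positive its nearest same-chromosome variant outside
all peaks (deduplicated; positives with no peak-free neighbour are
logged and skipped); and a seeded random sample of variants with no
functional-annotation hits.

## Motif features

PWMs are pseudocount-smoothed (default 10⁻³) position frequency matrices
parsed from JASPAR or MEME-minimal text via `Bio.motifs`.  Scanning
slides every window of a motif that covers the variant, on both strands,
against a uniform 0.25 background; a window is a hit when its log-odds
score reaches 0.8 of the motif's maximum attainable score (a fixed,
transparent rule — the upstream database this emulates uses its own
precomputed calls).  Forward/reverse hits on one window deduplicate to a
single hit; minus-strand ΔIC complements the alleles before the
frequency lookup.  `IC(pos) = 2 + Σ_b f log₂ f ≤ 2` bits, so |ΔIC| ≤ 2.

## Significance and enrichment

Significance: `σ = −log₁₀(max(#{background > s}/N, 1/(N+1)))` against the
organ scores of the GWAS catalog LD-expanded at R² ≥ 0.6.  The comparison
is strictly greater (background ties favour the query), and the add-one
floor is the minimal fix for the transform being infinite when the query
tops the background.

Enrichment eligibility: a trait needs ≥ 20 catalog SNVs and ≥ 5% of its
R² ≥ 0.8 LD-expanded members with generic score ≥ 0.8.  Each of 100
iterations samples an equal-size background from the union of all
traits' SNVs without replacement (a trait's own SNVs are not excluded),
LD-expands both sets at 0.8 (single hop, symmetric closure, no
transitive expansion), prunes both per organ so retained SNVs are
pairwise > 1 Mb apart (greedy in decreasing score order, ties broken by
ascending chromosome and position), and runs a one-sided Mann–Whitney U
test per organ.  The U test enumerates rank assignments exactly while
`C(n₁+n₂, n₁) ≤ 20 000` (midranks handle ties) and otherwise uses the
tie-corrected normal approximation with continuity correction.

Per iteration, `−ln p` values are standardized across organs with
population mean/sd (z-scores sum to zero by construction; the log base
cancels in standardization).  Correction is Holm–Šidák at 5% via
`statsmodels.multipletests`, applied within each iteration across all
trait × organ tests; a pair is reported when its mean z over iterations
is positive **and** the corrected decision is a rejection in the
majority of iterations (the aggregation of 100 per-pair p-values into
one decision is not pinned down by any single convention, so both the
correction family and the majority rule are config surface).  The top
organ per trait is the argmax of mean z.  Ward-linkage clustering of the
organ columns of the mean-z matrix is provided purely as an output
ordering.

## Synthetic data

The generators emulate the statistical structure the method assumes —
positives enriched in functional annotations, allelic imbalance at het
sites, one trait's SNVs concentrated in one organ's active regions —
not the peak-length or LD-decay distributions of real data.  Passing the
planted-recovery checks therefore demonstrates that the pipeline
recovers the effects it models, not that real-data performance matches
any published figure.

Default study conditions (all overridable in `SimulationConfig`, all
randomness from one seed through named CRC-keyed sub-streams so adding a
generator never perturbs existing outputs):

* genome: 8 chromosomes × 4 Mb — large enough that 1 Mb pruning retains
  ~10–15 SNVs per set while keeping runtimes in minutes;
* annotations: 4 organs × 2 biosamples, 40 planted active regions of
  2 kb per biosample, assays active over a region with probability 0.9,
  background peaks of 300 bp at 5 × 10⁻⁶ per bp;
* training: 2 000 variants, half positive (planted inside active
  regions), eQTL membership at 4:1 odds for positives (0.2 vs 0.05);
* ASB: 2 000 sites, 200 planted at allelic ratio 0.9, depth
  6 + Poisson(34) ≈ 40×, null ρ = 0;
* cell lines: six biosamples with disjoint active regions, 120 planted
  ASB variants each;
* GWAS: 400 SNVs, traits of 30 SNVs (one planted into liver, two null),
  LD blocks of 2 at R² = 0.9 with partners within 5 kb.

Chromosome sequences are generated only when `with_sequence` is set
(motif features need them and are zero otherwise); the large-coordinate
GWAS simulations run without sequence.

## Numerical choices

* Coordinates: variants 1-based (VCF), intervals 0-based half-open
  (BED); the conversion `pos − 1` happens in exactly two point-query
  methods.  Chromosome names normalize to the `chr` prefix on read.
  Strand is ignored except that motif scanning covers both strands.
* Signal quantiles use linear interpolation; spread is the sample
  standard deviation (0 with fewer than two tracks); positions without
  track coverage read 0.0.
* Beta-binomial tail sums come from `scipy.stats.betabinom` (no closed
  form needed at the depths involved).
* Forest training uses a fixed seed end to end and is bit-reproducible;
  a stratified 20% hold-out provides the AUROC/AUPR diagnostics, and a
  repeated 4:1 random-partition evaluator (1 000 replicates by default,
  configurable) is exposed for benchmark-style comparisons.
* Degenerate inputs: empty interval sets overlap nothing; an empty
  in-peak set yields empty ASB calls with a warning; organs with no
  data are skipped (enrichment) or refused (scoring) explicitly.

## Limitations

* The 15-feature generic roster is a reconstruction of the published
  feature *classes*; per-assay-class signal statistics (TF ChIP vs
  DNase) are used rather than per-mark statistics.
* eQTL membership is a generic-level binary; no tissue-specific eQTL
  annotation is modelled.
* Indels and structural variants are out of scope (SNVs only), as are
  read alignment, genotype calling and mapping-bias correction — allelic
  count tables are consumed as input.
* Raw forest vote fractions are reported without calibration; scores
  are comparable within a run, not across differently trained models.
* Organ aggregation is a plain union; no normalization for unequal data
  availability across organs is attempted.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the default conditions
above: oracle equivalence over all binomial outcomes with n ≤ 50 and all
U-test splits with n₁+n₂ ≤ 10; 10 000 null U tests for the rejection
rate; 1 000 sites per overdispersion regime; 2 000 training variants;
720 cell-line ASB variants; 100 enrichment iterations for the planted
trait and 20 × 20-iteration reruns for the null traits.
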