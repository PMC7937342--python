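# Methods

## Depurination detection at the sarcin–ricin loop

**Model.** A RIP-attacked 28S rRNA molecule carries an abasic site at the
SRL target adenine. In cDNA-based sequencing, reverse transcriptase
preferentially inserts an adenine opposite the abasic site, which reads out
as T at that position on the rRNA sense strand. The per-molecule lesion
probability *d* is therefore estimated by the non-adenine (principally T)
fraction among reads overlapping the site; with a per-base sequencing error
rate ε (uniform over the three alternatives) the expected adenine fraction
is (1−d)(1−ε).

**Read retention.** A read contributes only if its alignment fully covers
the 13-mer motif span; this anchors the measurement and excludes edge
artifacts. Two input modes share the same counting core: external SAM/BAM
alignments (coordinates converted to 0-based half-open on read), or raw
reads anchored by exact match of the motif with the target position
wildcarded, in the read or its reverse complement. In alignment mode,
reads with more than `max_mismatch_fraction` (default 0.02) substitutions
over aligned columns are dropped — the target column is exempt, because
the signal being measured must not count against retention. Reads gapped
at the target are tallied separately and excluded from base fractions; an
N at the target counts as `other` (it is evidence of neither base).
Every dropped read is tallied by reason, so retained + dropped = input.

**Estimation and QC.** The adenine fraction gets a Wilson 95% score
interval, which remains sensible at the 0/1 boundaries where uninfected
samples sit (a Wald interval collapses there). Replicates with fewer than
10 retained reads are flagged and excluded from group tests.

**Group test.** Replicate (non-A, A) counts are modelled by a binomial
GLM on group with independent Gaussian (ridge) penalties: prior sd 2.5 on
group coefficients, 10 on the intercept, applied within IRLS. The penalty
exists for complete separation — treatments with zero non-A reads — where
the unpenalized MLE diverges; it leaves well-identified fits essentially
untouched (the reported deviance χ², the difference in *unpenalized*
binomial deviance between the null and group fits at the penalized
estimates, matches the plain likelihood-ratio statistic to <1% at ≥500
reads/replicate with proportions in [0.05, 0.95]). df = groups − 1. For
two groups an exact two-sided Fisher test on pooled counts is reported as
a secondary check, and `unpenalized_lrt` gives the classical statistic
for comparison. Multiple contrasts are reported unadjusted (each contrast
answers its own question); a Bonferroni option exists but is off by
default.

## Interaction set logic

**Contrasts.** blue = S⁻W⁻ vs S⁺W⁻, red = S⁻W⁻ vs S⁻wasp, green =
S⁻wasp vs S⁺wasp; fold-changes are second treatment over first. DE calls
use |log2FC| ≥ 0.58 and BH-FDR < 0.05; genes below 1 CPM in every
replicate of a pair are removed before testing.

**Direction-stratified Venn.** Up- and down-regulated sets get separate
partitions into the seven regions of a three-set diagram. This is the only
reading under which a "restored" gene can be simultaneously exclusively
down in green and exclusively up in red; region disjointness and coverage
are property-tested against brute-force set algebra.

**Group calls.** Expression patterns are assessed on treatment means of
per-gene z-scores of TMM-normalized CPM across all samples of the time
point (genes with zero variance get z = 0, so ties break toward
`unclassified`). Group A: green-exclusive-down ∧ red-exclusive-up.
Group B: green-exclusive-up ∧ red-exclusive-down; up-regulated blue∩green
genes matching the restored shape are annotated `B-like` rather than
merged, since their blue membership leaves the attribution ambiguous.
Group C: up in green (exclusive or shared with red) with the S⁺wasp mean
exceeding every other treatment mean by ≥ δ while those three means span
≤ ε. Male-gonad pattern: control − wasp ≥ δ, wasp − max(S⁺ treatments) ≥ δ,
|S⁺W⁻ − S⁺wasp| ≤ ε. Defaults δ = 0.5, ε = 0.75 z-units, both
configurable: the original pattern calls were made by eye from heatmap
clusters, which is not a testable contract, so explicit thresholds replace
visual clustering; the chosen defaults separate the planted patterns from
nulls on the synthetic data without being tuned to any single dataset.

**Normalization.** TMM follows the published algorithm exactly: reference
sample by the 75th-percentile rule, M/A values on library-scaled counts,
double trim (30% of M, 5% of A per tail), inverse asymptotic-variance
weights, factors rescaled to geometric mean 1. Agreement with edgeR
4.0.16 `calcNormFactors` is asserted to 1e-6 on a composition-bias
fixture (oracle values frozen from an edgeR run).

**Built-in DE.** External DE tables are first-class input; the built-in
test exists so the pipeline runs end-to-end without external software. It
is a per-gene NB likelihood-ratio test with one common dispersion shared
by all genes, estimated by the pooled Pearson moment equation
Σ(y−μ̂)²/(μ̂+φμ̂²) = residual df (bisection; floored at 0 for
under-dispersed data). A per-gene moment median was rejected: at 4
replicates it underestimates φ by ~25%, inflating false positives exactly
where planted genes live. Group means are fitted by vectorized Newton
iteration on log abundance with TMM effective library sizes as offsets;
fold-changes add 0.5 pseudo-reads per side to stay finite at zero counts.
This deliberately omits gene-wise dispersion shrinkage and robust
quasi-likelihood — it is calibration plumbing, not a replacement for a
production DE tool.

## Power

Log-scale count variance is approximated by 1/depth + cv², Poisson
counting noise plus biological variability (cv = √ of the NB common
dispersion). A two-sided two-sample normal test then gives
power = Φ(√(n·ln²Δ / (2(1/depth+cv²))) − z₁₋α/₂) and the inverse
n = 2(z₁₋α/₂+z_power)²(1/depth+cv²)/ln²Δ. The replicate report rounds to
the *nearest* integer (half away from zero), not the ceiling: the target
power (0.93) is itself a rounded figure, and nearest-integer reporting is
what reproduces the standard replicate-requirement quadruple (5, 8, 7, 10)
at the (100X, 20X) × (0.3, 0.4) corners. `power_at` and `required_n` are
mutual inverses to 1e-9 (property-tested). The module also carries the
design-math helper `all_female_probability` (0.5³ = 12.5% for a 3-larva
pool at a 1:1 sex ratio).

## qPCR ΔCt

An amplicon with fractional efficiency E multiplies by (1+E) per cycle,
so corrected Ct = Ct·log₂(1+E) puts cycles on the perfect-doubling scale;
E = 1 is the identity. ΔCt = corrected Ct(reference) − corrected
Ct(target) increases with target expression. A "literal" mode computing
Ct·log₂(E) is kept behind a flag for auditing alternative conventions; it
degenerates to 0·Ct at E = 1, which is why it is never the default. RIP1
defaults to its measured efficiency 0.995 when none is given. Group
statistics on ΔCt (factorial models, post-hoc tests) are out of scope:
the module emits tidy tables any stats tool consumes. Rows of
nucleotide-identical genes (RIP3/4/5) are summed under one label by
`interaction.aggregate_identical_genes` before expression reporting.

## Synthetic data: what it emulates and what it does not

**Reads.** 125 bp single-end stranded reads, uniform starts over a 400 nt
fragment carrying the SRL motif exactly once at position 180 (the flanks
are synthetic random sequence — only the 13-mer context is assay-defined).
Depurination is planted as a T at the target with probability d (an option
plants a small C/G fraction for robustness testing); errors are
independent per base at rate ε (default 1e-3), uniform over alternatives,
sparing the target of depurinated reads (the signature is a deterministic
consequence of the lesion, not an error). Default d = 0.15 in the
symbiont + susceptible-wasp treatment and 0 elsewhere: clearly detectable
but sub-saturating. Not emulated: positional quality profiles, indel
errors, GC/fragment-length bias, rRNA secondary-structure coverage bias.
Passing tests therefore validate the counting/estimation logic, not
robustness to real library artifacts — which is why external alignments
are accepted as input.

**Counts.** Gamma–Poisson draws with variance μ + bcv²μ² (default
BCV 0.35), four treatments × 4 replicates, per-sample relative depths
uniform in 1 ± 0.2. Planted classes (sizes in parentheses): male-biased
(150; baseline ×0.02 under the symbiont — male transcripts vanish with
the males), wasp-responsive up/down (60+60), symbiont-responsive down
(80), Group A (20; wasp ×4, restored under co-infection), Group B (20;
wasp ×¼, restored), Group C (20; ×4 only under symbiont+wasp), male-gonad
ordering (30; multipliers 1, 0.02, 0.4, 0.02), remainder null. Planted
effects are 4-fold (log2FC = 2), within the regime the design has high
power to detect at n = 4; planted baselines are drawn from 2^U(5,9)
expected counts so recovery measures the classifier rather than the
expression floor. Class sizes are larger than the handful of genes such
patterns produce in practice, purely to stabilize the recovery fraction
as a Monte-Carlo estimate. Not emulated: gene-wise dispersion variation,
gene–gene correlation, outlier replicates, batch structure.

**Ct tables.** Raw Cts are back-computed through the efficiency
correction from requested ΔCt values plus Gaussian replicate noise, so
noise-free tables round-trip exactly.

**Reproducibility.** All draws come from numpy's PCG64;
per-replicate/per-purpose sub-streams are seeded with
`SeedSequence((seed, stream))`, making outputs byte-identical for a fixed
seed and independent of execution order.

## Validation experiment sizes

The statistical checks (in `ripseq.experiments`, exercised by both the
acceptance tests and `scripts/acceptance.py`) use: estimator
bias/coverage — 200 replicates × 2000 reads at each of four depurination
rates, coverage pooled over rates (per-rate MC error ≈ 1.5 pp would make
a per-rate band check noise-dominated; pooled, it is ≈ 0.8 pp); GLM size —
1000 null simulations (MC se ≈ 0.7 pp against a ±2 pp band) and 200
alternative simulations; pattern recovery — pooled over 4 independent
default datasets (360 planted pattern genes; misses at this design are
dominated by genuine 4-replicate sampling noise: occasional spurious blue
calls breaking region exclusivity and z-gaps falling under δ); Venn
oracle — 100 random instances, exact region equality.

## Known limitations

* The alignment-mode mismatch fraction counts substitutions over aligned
  columns; indels affect coverage and gap calls but not the mismatch cap.
* The built-in DE's single common dispersion under-serves genes with
  atypical dispersion; use external DE tables for real analyses.
* Group C / male-gonad thresholds (δ, ε) are explicit stand-ins for
  by-eye clustering; different settings shift the precision/recall
  balance, and an average-linkage heatmap view is advisable for
  borderline genes.
* The power formula is a normal approximation; it is accurate in the
  regimes exercised here but is not an exact NB test power.
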