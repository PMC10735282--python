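# Methods

## Data model and conventions

An exon is identified across datasets by its genomic coordinates
(chromosome, start, end, strand); gene symbols and exon numbers are
annotation labels used for display and input validation only, since
user-supplied labels are the field most often wrong (the `validate`
subcommand proposes corrections by coordinate lookup). Internally all
intervals are 0-based half-open; the tab-separated exon tables are
1-based inclusive (the convention of the annotation tables they derive
from) and BED files are 0-based half-open, both converted at the readers.
ΔPSI is carried on a −100..100 percent scale. Genome builds are a per-
dataset tag; queries against a registry of a different build are refused
rather than lifted over.

A dataset stores only exons passing the significance filter
|ΔPSI| ≥ 10 (percent) and adjusted p ≤ 0.05, both comparisons inclusive.
These thresholds are the registry's construction rule and the default for
user queries, but are configurable per run.

## Mode 1: correlation query

Over the exon-identity intersection of query and dataset, the Pearson
correlation of ΔPSI is computed. The null model is "randomly associated
exons": the pairing between query and dataset ΔPSI values is permuted
(one side shuffled), preserving both marginal distributions. With B
permutations the one-sided empirical p-value is

    p_pos = max(#{r_perm >= r_obs}, 1) / B        (p_neg analogously)

ties counted as extreme and the value floored at 1/B — the resolution of
the test (10⁻⁴ at the default B = 10⁴). Both tails are reported because a
query can match a knockdown signature either directly or inverted (e.g. a
factor's overexpression vs its depletion). Each directional Score pairs
the matching tail with the two overlap fractions:

    Score = (1 − p + percent.sig.input/100 + percent.sig.SF/100) / 3

Datasets are ranked by max(score_pos, score_neg), ties broken by dataset
id. Computation requires at least `min_shared` = 10 shared exons and
non-degenerate ΔPSI on both sides; datasets failing this are reported
flagged, never dropped. Each dataset draws from an independent child
stream of the run seed, so results are bit-reproducible and independent
of registry order.

An alternative null (resampling ΔPSI from the whole registry rather than
permuting the pairing) was considered and rejected as default: label
permutation is the minimal null that leaves both marginals untouched.

## Mode 2: overlap randomization

For a coordinate-only query E and dataset S, the observed count N of
query exons in S is referred to the distribution of the same count over
random control sets of size |E| drawn uniformly without replacement from
the exon universe (default: the union of identities across registry
datasets; an annotation-wide universe can be supplied). The count of a
uniform without-replacement draw is exactly hypergeometric, so control
counts are sampled directly from that law — equivalent to materializing
each control set, and verified against exhaustive enumeration of all
C(12,4) control sets on a tiny universe in the test suite. The two-sided
empirical p-value is

    P_emp = (min(k, l) + 1) / (B + 1)

with k = #{control count ≥ N}, l = #{≤ N} (both inclusive, so k + l ≥ B).
BH correction is applied across all datasets of the run; the
enriched/depleted direction label compares N to the control median, which
the formula itself does not encode.

**Calibration note.** This minimum-tail form is *not* doubled, so for a
smooth null its level at threshold α lies between α and 2α; its actual
level is pulled back toward α only by the discreteness of the count
distribution. The calibration test therefore uses a deliberately discrete
regime (universe 300, dataset 60, input 15), whose exact level at α = 0.05
is 0.048 by direct hypergeometric computation; users testing very large,
smooth configurations should expect the uncorrected P_emp to be mildly
anti-conservative.

## CLIP-peak enrichment

Peaks from all experiments targeting one SF are merged (sorted sweep;
abutting intervals coalesce). Regulated classes per SF are the unions of
significantly more-included (up) and more-skipped (down) exons across
that SF's samples; exons regulated in opposite directions in different
samples are removed from every class, and SFs with fewer than 100 exons
in either class are discarded. Control exons are all other detected
exons. For the exon body and three consecutive 100-nt windows on each
side (oriented 5′→3′ on the exon's strand, truncated at chromosome
bounds, fully-truncated windows excluded from the denominator), overlap
is any-basepair intersection, and

    R = log2((P_reg + 0.01) / (P_ctrl + 0.01))

The 0.01 pseudocount bounds |R| by log2(1.01/0.01) ≈ 6.66. Significance
is a two-sided Wald test on the class coefficient of a binomial GLM
(logistic regression of overlap on class, fitted on the aggregated 2×2
table — a saturated model, so the scale is fixed at 1), with Fisher's
exact test as fallback whenever a contingency cell is zero (separation).
BH is applied across all (SF × class × region) cells of a run. Windows
are purely distance-based and may fall in neighbouring features; no
intron-identity check is made.

## Motif enrichment and the V statistic

Regulated-exon sequences extended ±200 nt (reverse-complemented for
minus-strand exons) are compared to control sequences (all other detected
exons minus the SF's regulated set). The enrichment engine is a
sequence-level Fisher exact test on the contains/does-not-contain 2×2
table, one-sided; the impoverishment p-value P_i swaps the roles of the
two sets. The engine sits behind a stable (P_e, P_i) interface so an
external enrichment program could be substituted. Matching is exact-IUPAC
consensus (regex) or PWM log-odds against a 0-order background estimated
from the control set, thresholded at the score whose background
exceedance rate is 10⁻³ per nucleotide (configurable). RNA alphabets are
mapped to DNA at read time; MEME minimal motif files are parsed via
Biopython.

The combined statistic is V = (1 − min(P_e, P_i)) × s with s = −1 if
P_i < P_e, +1 otherwise (+1 with an "ambiguous" flag at the tie). The
min-of-complements form min(1−P_e, 1−P_i) × s is also available
(`variant="as_printed"`) but is not the default: with one-sided
near-complementary p-values it collapses toward 0 exactly when the
evidence is strongest, contradicting the |V| > 0.95 display rule. Cells
with |V| > 0.95 display red (enriched) or blue (depleted), others grey,
and classes under 100 exons white (untested). Because |V| > 0.95
corresponds to a one-sided p < 0.05, roughly 5–10 % of truly null cells
will cross the display threshold; the test suite measures this null rate
directly.

## Synthetic data

The generator emulates the statistical structure of knockdown registries,
not their biology: synthetic chromosomes carry non-overlapping exons of
50–300 nt with inter-exon gaps ≥ 700 nt (so flanking windows of
neighbouring exons never collide), ΔPSI magnitudes are uniform in a
configurable range (default 10–60, signs balanced), and adjusted p-values
uniform below 0.05 — every generated record passes the significance
filter by construction. Pairwise exon sharing between datasets is planted
by drawing from earlier datasets (preferring exons exclusive to the pair
so other overlaps are not inflated); ΔPSI correlation on shared exons is
induced by additive Gaussian noise whose scale is calibrated by bisection
*after* clipping back into the significant range, keeping the realized
Pearson r within ±0.05 of target (±2 % for sharing fractions). CLIP
fixtures give each exon a covering peak with a class-specific
probability; motif fixtures plant a consensus at a uniform position
within the extended region at class-specific rates in an otherwise
uniform-ACGT genome. Everything is deterministic under a seed and
realized quantities are recorded as ground truth.

What passing tests on these fixtures do **not** show: performance on real
data with correlated significance calls, non-uniform ΔPSI shapes, GC- or
length-biased control exons, clustered CLIP peaks, or motif occurrence
statistics of real genomes (the planted-recovery tests use
high-information 10-nt consensi so background matches are negligible;
real RBP motifs are shorter and noisier, and their null behaviour is
characterized separately by the null-calibration tests).

## Problem sizes and defaults

Defaults follow the registry construction rules: thresholds (10, 0.05),
10⁴ permutations / control sets, minimum class size 100, display
threshold 0.95, window size 100 nt, flank 200 nt, min_shared 10. The test
suite and the acceptance script run on desk-scale configurations chosen
as the smallest sizes at which the statistical properties under test are
well-resolved: registries of 1–4 datasets with 99–1000 exons over
universes of 100–4000, 300–50 000 permutations depending on the precision
the comparison needs, 1000 replicates for calibration checks, and 50–100
seeded trials for recovery rates.

## Known limitations

- No liftOver: cross-build comparisons are refused, not converted.
- Control sets are not GC/length-matched (not part of the method; a
  future sampling option).
- The mode-2 P_emp is anti-conservative for smooth nulls (see above).
- Motif matching is presence/absence per sequence; hit counts and
  positional weighting are out of scope.
- The up/down breakdown percentages are relative to the query's full
  up/down subset sizes, and exons with ΔPSI exactly 0 are excluded from
  both direction classes and counted separately.
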