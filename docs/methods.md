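# Methods

This note documents the models, rules and numerical choices implemented in
svmosaic, the parameters that matter, what the synthetic-data generator does
and does not emulate, and the design decisions taken where the design was
genuinely open.

## Coordinate conventions and domain types

All internal coordinates are 0-based half-open; the VCF and GFF3 readers and
writers convert at the boundary. The VCF dialect is pinned: `POS` is the
first affected base (1-based) and `END` the last, so `END − POS + 1` equals
the event length and `|SVLEN|`; deletion `SVLEN` is stored positive
internally and written negative. The reader is cyvcf2 because it exposes the
raw `INFO/END` field; record writing is plain text because htslib's VCF 4.4
semantics re-derive the record end from `SVLEN` for symbolic ALTs, which is
one base off from this dialect — the text writer also makes outputs
byte-deterministic under a fixed seed.

An insertion is modelled as a point event (`start == end`) carrying the
inserted-sequence length. Reciprocal overlap is therefore undefined for
insertions, and every insertion comparison in the package uses positional
distance instead. SVs are treated as unstranded. The minimum event length is
10 bp (`MIN_SV_LENGTH`); shorter variants belong to indel callers.

Size bins for benchmarking are A 50–150 bp, B 151–500, C 501–5000,
D 5001–50 000, E 50 001–250 000, F 250 001–1 000 000. The B/C boundary is
resolved with 500 in B and C starting at 501, so the bins partition
[50, 10^6] exactly; lengths outside that range carry an `unbinned` sentinel
and are excluded from binned scoring but not from clustering.

## Benchmark matching

A prediction *p* matches a truth event *S* of the same type when
`RO(p,S) ≥ 0.9` and `e(p,S) < min(10, 0.1·(len(p)+len(S)))` bp. The
fractional error rule is combined by `min` deliberately: under a plain OR
the 10 % rule would loosen the cap for large events and never tighten it
for small ones, the opposite of its purpose of demanding less error from
small events. The plain-OR reading remains available as
`MatchCriteria(combine_rule="or")`. The error cap is strictly `< 10` in
benchmarking but inclusively `≤ 10` in the clustering graph rule — both
thresholds are kept as stated by their respective rules rather than
harmonised. Duplications use `RO ≥ 0.7` with no error constraint, because
short-read duplication breakpoints are poorly resolved. Insertion matching
is positional (site distance ≤ 10 bp), mirroring the insertion clustering
radius, since interval overlap is undefined for point events.

Assignment is greedy and one-to-one over candidate pairs ordered by
descending RO, then ascending error, then coordinates (ascending site
distance for insertions). Greedy was chosen over optimal assignment for
determinism and speed; on instances of ≤ 8 calls per side the test suite
verifies that the greedy TP count equals the exhaustive maximum-cardinality
matching. False positives are binned by predicted length, false negatives
and true positives by truth length. Cells with a zero denominator report a
missing sensitivity/precision, never zero by convention.

## Within-sample merging

Retention rules, applied per sample to all types except insertions: (a) all
anchor-caller calls with FILTER PASS ("QUAL = PASS" is read as the FILTER
column, matching Pindel/MetaSV semantics); (b) all inversions from the
keep-all caller (LUMPY), deduplicated against anchor inversions; (c) any
other call supported by at least two distinct callers under pairwise RO,
with the threshold 0.7 when the relaxed caller (LUMPY) is in the pair and
0.9 otherwise, and not already represented by a retained call at those
thresholds. Support is counted per pairwise RO against the candidate (star
topology), the simplest reading of "supported by at least two callers".
Anchor non-PASS calls are excluded entirely, including from support
counting. Each retained multi-caller group is emitted once with breakpoints
from the highest-priority caller present (anchor first — it was selected
for breakpoint precision) and the full supporting-caller set recorded on
the representative; recording provenance is what makes the merge
idempotent. Insertion sites chain by single linkage within 10 bp; each
chain emits the leftmost site with the longest assembled sequence, and
unchained insertions from either caller are kept.

## Cross-sample clustering

Per SV type and chromosome: (1) transitive grouping of calls overlapping by
≥ 1 bp, by a sweep over sorted intervals; (2) within each group, a graph
with edges where `RO ≥ 0.9`, or `RO ≥ 0.7` and `e ≤ 10` bp — the weak rule
admits small events with large relative but tiny absolute boundary
differences; (3) connected components; (4) complete-linkage agglomeration
within each component on `d(a,b) = e(a,b)/(len(a)+len(b))`, cutting the
tree at height 0.1, inclusive. Normalising by the *sum* of the two lengths
is consistent with the benchmark's `len(p)+len(S)` normalisation; the
mean-length alternative (which differs only by a factor of two) is exposed
as `ClusterParams(length_norm="mean")`. Insertions chain by single linkage
on site distance ≤ 10 bp, matching the within-sample insertion rule.

Each final cell becomes one allelic event. Representative breakpoints are
per-side medians (floored for even counts) — robust to jittered outliers.
Tightness is the mean over members of `(|Δstart| + |Δend|)` against the
representative, divided by twice the representative length, i.e. the mean
per-side breakpoint deviation as a fraction of the event length; for
insertions the site deviation plays both sides' role. Allele frequency is
the carrier count over the panel size.

Determinism: members are canonically sorted before the distance matrix is
built, so the partition is invariant to input order. scipy's
complete-linkage implementation performs the agglomeration; a from-scratch
naive agglomerator exists only in the test suite as an independent oracle,
and equality of partitions is asserted over hundreds of random instances.

## Synthetic data

The generators work at the call level: caller behaviour is emulated
directly by breakpoint jitter (integer Gaussian noise per side, clipped to
keep positive extent), false-negative dropout (independent Bernoulli) and
false-positive injection (bin-matched lengths, uniform placement), instead
of simulating reads and running external callers. The short-read design
constants of the study this emulates (83-bp reads, 500-bp inserts with SD
50, 2 % error) are recorded in `SimConfig.read_design` for provenance but
are not used computationally. Consequences: passing benchmarks validate the
*comparison and scoring machinery*, not any real caller's error profile;
alignment artefacts, repeat-mediated mis-calls and coverage effects are out
of scope.

Truth sets place non-overlapping events with lengths uniform within each
size bin (the within-bin distribution is not otherwise constrained);
default counts are 1000 per type for bins A–D and 200/100 for E/F, on a
coordinate-only genome of 12 × 100 Mb (no sequence is materialised, so
memory is flat). Placement is rejection-sampled largest-first; an
infeasible packing raises an error naming the bin. Insertion sites reserve
a 100-bp reference footprint so neighbouring sites stay unambiguous under
10-bp matching.

Panels plant allelic events spaced with a 50 %-of-length margin; each event
is carried by `Binomial(panel_size, freq)` samples with per-sample,
per-side jitter of SD `0.02 × length` by default — chosen so that realised
cluster tightness sits near the ~2 % of event length regime a large rice
panel shows. Carrier frequencies default to Uniform(0.4, 1.0): with a
20-sample panel this keeps planted events at several carriers, so the
similarity graph of a planted event stays connected under jitter and
recovery is exact; rare-variant regimes can be simulated by widening the
range, at the cost of occasional two-carrier events whose single pairwise
edge can fail. The half-normal expectation of the tightness statistic under
this jitter is ≈ 1.6 % of the event length, and measured values land near
1.5 %.

Annotation simulation produces gene models with a fixed 5′UTR / 3-exon CDS
/ 3′UTR layout on alternating strands, TE tracks with superfamily labels,
TFBS intervals around the TSS, promoter deletions with a configurable
TFBS-avoidance strength, and random sequence with optional microsatellite
insets for complexity fixtures. For statistical calibration there is a
direct indicator-level generator (`simulate_indicator_tracks`) producing
iid per-gene, per-position Bernoulli fields, with
`P(SV | TFBS) = p_sv·(1 − avoidance)`.

## Annotation statistics

TE classification: `strict_te` when some TE record has ≥ 80 % reciprocal
overlap with the event; otherwise `repeat_associated` when the union of
TE/repeat records covers ≥ 50 % of the event; otherwise `none`. The best
label is the class of the maximum-RO record. Insertions carry no reference
extent: with an inserted sequence present they are compared by length ratio
(≥ 80 %) against TEs in a one-length neighbourhood of the site — a
heuristic stand-in for sequence matching — otherwise they classify `none`.

Feature assignment uses the precedence CDS > 5′UTR > 3′UTR > intron >
promoter > intergenic over all overlapping genes, mirroring functional
severity for events spanning several features. The promoter is the 500 bp
immediately upstream of the TSS, strand-aware (higher coordinates for
minus-strand genes); 500 bp matches the extracted regulatory region, and
the length is configurable because long-deletion density peaks a few
hundred bp upstream.

TSS profiles count, per position in ±1000 bp around the TSS (strand-flipped
so negative is always upstream), the genes whose position is covered by an
event, binary per gene, split at 40 bp into short and long tracks and
normalised by a per-position denominator that truncates genes near contig
edges.

Deleted genes: a gene is deleted in a sample when the union of the deletion
intervals that sample carries covers every CDS base — strict full coverage,
so 99 % coverage does not count. The rule is monotone in added deletions.
Variety-group sharing tables are restricted to genes deleted in ≥ 5
samples by default.

Density windows: 100-kb windows sliding by 50 kb; a variant is counted in
every window containing its start position (start-position assignment
avoids double counting within one window while keeping the sliding
smoothing); windows with count ≥ 2 × the track mean are flagged; two tracks
are compared by Pearson correlation over aligned windows. Cluster counts
(not raw call counts) are the default unit, with calls available by passing
them instead.

## Regulatory statistics

The TFBS–SV table computes, per position *x* over genes,
`P_x(TFBS)`, `P_x(SV)`, `P_x(TFBS ∩ SV)`, the conditional
`P_x(SV | TFBS) = P_x(TFBS ∩ SV)/P_x(TFBS)` (missing where no gene has a
TFBS), the association sign from the 2×2 determinant, and an independence
p-value. The default test is the exact two-sided Fisher test. Exactness
comes at a price: with a few hundred genes the hypergeometric null is
discrete and the test is conservative (empirical type-I error ≈ 0.044 at
nominal 0.05 for 500 genes with TFBS/SV rates 0.4/0.3). Two calibrated
alternatives are provided: the Fisher mid-p variant (`method="midp"`,
half-weighting the observed table; empirical type-I ≈ 0.049) and the
asymptotic chi-square without continuity correction (`method="chi2"`,
≈ 0.049; the Yates correction was rejected as it over-corrects to ≈ 0.039).
Calibration assertions in the test suite use the mid-p variant; raw
p-values are reported by default with optional Benjamini–Hochberg
adjustment across positions.

Linguistic complexity of a window of size N over alphabet size K is
`CL = (Σᵢ Vᵢ)/(Σᵢ Vmaxᵢ)` for word sizes i = 1..N, with Vᵢ the number of
distinct substrings of length i and `Vmaxᵢ = min(Kⁱ, N − i + 1)`. Defaults
N = 10, K = 4; windows containing non-alphabet characters are masked to
NaN; profiles over multiple equal-length sequences average position-wise
(NaN-aware). The homopolymer closed form is CL = 10/49 ≈ 0.204.

Enrichment uses the hypergeometric upper tail: the probability of at least
`list_hits` category genes when drawing `list_total` from `pop_total`
containing `pop_hits`, with the sample odds ratio from the 2×2 table. Zero
margins give p = 1 and an undefined (NaN) odds ratio. Benjamini–Hochberg
adjustment is applied across categories when a table is supplied.

## Problem sizes and tolerances

The standard validation conditions, as run by the test suite and
`scripts/acceptance.py`: the full-design self-benchmark uses all four SV
types at 1000/1000/1000/1000/200/100 events per bin (17 200 events);
dropout recovery uses 200 bin-A deletions × 100 seeds and a 3-standard-
error band; clustering oracle equivalence uses 200 random instances of up
to 30 calls; planted-partition recovery uses 50 events × 20 samples;
independence-test calibration uses 500 genes × 101 positions × 100 seeds;
the enrichment oracle checks 50 random tables at relative tolerance 1e-9.
Probabilistic assertions use 3-SE bands around their binomial expectations;
identity assertions (conditional-probability product, oracle partitions,
self-benchmark rates) are exact.

## Known limitations

Translocations and read-depth CNV genotyping are out of scope (the
clustering pipeline cannot distinguish events inside translocated regions).
Caller emulation is statistical, not mechanistic: it cannot reproduce
caller-specific biases such as repeat-driven false positives. Insertion
clustering uses position only; inserted-sequence similarity is not
compared. TE classification of insertions without sequence is not
attempted. The merge step is quadratic per sample in the number of
candidate calls, which is ample for per-sample call sets but would need an
interval index for pathological inputs.
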