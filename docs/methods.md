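# Methods

## Enzymatic model

The three libraries measure per-site cut activity of HpaII, MspI and
MspI after beta-GT glucosylation. For a site whose alleles are
fractions u (unmodified), m (5-mC) and h (5-hmC), u + m + h = 1, the
expected cut weights are

    w_HpaII = u          w_MspI = 1          w_GT+MspI = u + m

HpaII is modeled as blocked by **both** 5-mC and 5-hmC. Its documented
property is methylation sensitivity; we extend the block to 5-hmC
because the enzyme does not cut hydroxymethylated CCGG either, and the
calling rule itself presumes HpaII ≈ 0 at hmC loci (the GT > HpaII
criterion). This is a model assumption of the simulator, stated here
rather than buried in code. Glucosylation is complete by default; the
`gt_efficiency` parameter (default 1.0) scales the protection of the h
term (`w_GT = u + m + (1−eff)·h`) for exploring partial enzymatic
efficiency, for which no calibrating measurement exists.

## Counting

A tag's 5'-most genomic coordinate must equal the site's expected tag
start: `pos+1` for plus-strand tags (the fragment downstream of the
C^CGG cut), `pos+2` for minus-strand tags (the upstream fragment read
leftward), matching the enzymes' 5'-CG overhang chemistry. `slop`
(default 0, max 5) relaxes the match by ±slop bases; strand-agnostic
matching is available behind a flag.

Filters: mismatches ≤ 2 (from the alignment's edit-distance field; a
missing field is treated as 0 and logged, or rejected under the
`error` policy) and reported locations ≤ 10. Multiplicity n is taken
from the alignment record's hit-count tag when present, otherwise from
counting records per read name in the file. Each kept location adds
1/n to its matched site; off-site locations contribute nothing but
still divide the read's weight, exactly as the fractional-count formula
states — so a read whose locations are all on-site contributes total
weight 1, and never more otherwise.

Normalization divides each site's fractional count by the library's
total count over all sites, partial counts included — not by the number
of sequenced reads — making the per-library table a probability vector
over sites and the angle comparison depth-independent.

## Scoring and calling

Angle = `atan2(y_sensitive, x_MspI)` in degrees, on normalized counts.
Both axes zero means the site is uncovered: it carries no calls, since
an MspI dropout is an absence of data, not a biological state.

Calls use strict inequalities: 5-mC at HpaII/MspI angle < 20°; 5-hmC at
GT/MspI angle < 50° **and** normalized GT strictly greater than
normalized HpaII **and** (default) a 5-mC call at the site. The
methylation precondition is a flag (`require_methylated`) because the
written procedure lists only the first two criteria while the results
describe hmC loci as methylated; both behaviors are reachable.

A consequence of the thresholds as published: a fully methylated site
(h = 0) has GT tracking MspI, so its GT angle sits near 45° — inside
the < 50° cutoff — and GT > HpaII = 0 holds, so it satisfies every
5-hmC criterion. The rule is implemented exactly as stated rather than
silently corrected; users wanting hmC calls that exclude such sites can
lower `t_hmc`. The simulator's truth calls apply the identical rule to
noiseless weights, so pipeline-vs-truth agreement is unaffected.

The 0–100 display score is the affine map `100·(1 − angle/90)` (0 = no
modification, 100 = complete modification). Thresholds stay in degrees;
the display map is a presentation choice and never enters calling. An
optional pseudocount (default 0) can be added to raw counts before
normalization for very shallow libraries.

## Annotation

Promoters are the 2 kb windows centered on the strand-aware TSS (for a
minus-strand gene the TSS is the rightmost transcribed base, end−1,
which keeps the window symmetric in genomic coordinates). The partition
is exhaustive and exclusive with precedence promoter > exon > intron >
intergenic; the precedence is our tie-break (promoter biology is the
analysis's focus), as the category definitions alone leave overlaps
ambiguous. Promoter windows are clipped at contig bounds when lengths
are known.

CpG shores are the 2000 bp flanks on each side of an island, measured
from island edges, strand-free, with island taking precedence over
shore. Sites are classified at their motif start coordinate.

The between-sample test is the pooled two-sample z-test for
proportions, two-sided (delegated to statsmodels); per-category tables
carry raw p-values plus an optional Benjamini–Hochberg column, since
the per-category stars in typical figures do not state a correction.
Degenerate tables with zero events on both sides are reported as z = 0,
p = 1.

Sample clustering is agglomerative average linkage (scipy) on pairwise
distances over sites covered in every sample; Euclidean by default,
1 − Pearson selectable. Only the linkage is prescribed by the
procedure; the metric is our choice and is exposed.

## Expression integration

Expression bins use linear-interpolation percentiles,
boundary-inclusive: decile mode labels genes ≤ 10th percentile "low"
and ≥ 90th "high"; quartile mode assigns Q1–Q4 at the 25/50/75
boundaries. An all-equal expression table degenerates to empty
low/high bins with a warning rather than an error.

Metaprofiles average a per-site value in half-open 10-bp bins over
[−window, window) around the TSS or TES, strand-oriented (upstream
negative). The aggregated value defaults to the 0–100 display score and
can be switched to the binary call indicator — the per-site quantity
behind published "hmC level" profiles is not pinned down, so it is
configurable. The 95% CI per bin is 1.96·SEM; empty bins are reported
with n = 0.

Regression is OLS of the per-gene mean site value (over covered sites
in the region; genes with no covered site are dropped) on expression X,
untransformed by default with an optional log2(X+1) flag. The
"proximal" region is TSS ± 1 kb; "intragenic" is the TSS-to-TES span.
At least 3 covered genes and non-constant X are required. The reported
coefficient is a regression slope and is labeled as such.

qPCR fold enrichment is `2^(Input−Pulldown)_sample /
2^(Input−Pulldown)_control`, total on finite Ct values.

## Simulator

The default configuration is the package's reference study condition:
one 500 kb contig at GC 0.45 with CCGG planted every 100 bp (~5000
sites), state mixture 80% (1,0,0), 10% (0,1,0), 10% (0,0.3,0.7), mean
depth 1000 tags per site, 27 bp tags. The mixture covers the three
informative regimes — no call, 5-mC-only, and genuine mixed-allele
hmC — and the depth is deep enough that sampled normalized counts sit
within a fraction of a degree of their expectations.

Spurious CCGGs arising in the random background are scrubbed (one C
mutated to A, which cannot create a new motif), so the catalog equals
the planted grid and per-site truth is unambiguous. `multimap_fraction`
pairs sites into twins by copying the full tag-bearing context
(±30 bp plus the read length) so emitted tags map to exactly two
locations (NH = 2) and fractional counting assigns 1/2 to each twin.

Counts are multinomial per library over sites with probabilities
proportional to cut weights, total = mean_depth × n_sites — a site-level
depth model. Fragment-length effects, PCR bias, the ~125 bp product
size selection and adapter chemistry are **not** modeled; tags are
error-free by default (a uniform substitution rate is available and is
recorded in the emitted alignments' edit-distance field). Tag strand is
a fair coin and does not affect site-level recovery. Consequently,
passing tests demonstrate the correctness of the counting, scoring,
calling and statistical machinery under the stated enzymatic model;
they do not demonstrate robustness to alignment artifacts, coverage
biases or incomplete digestion in real libraries.

All randomness flows through the single config seed: two runs with the
same configuration are bit-identical, end to end.

## Numerical and testing choices

Coordinates are 0-based half-open internally, BED dialect on disk.
Angles are computed with `atan2` and compared against an independent
`atan`-ratio oracle to 1e-9 in tests. Acceptance-level checks run at
reduced problem sizes chosen for statistical validity: the truth-
recovery check uses the full 5000-site/depth-1000 reference condition;
SAM-level round trips use ~300-site genomes; the null-calibration arms
use 10,000 replicates (proportion test) and 1000 replicates
(regression), at which the asserted ±1 and ±2 percentage-point bands
are several standard errors wide. Library-backed steps (linkage,
proportion z-test, OLS) are verified against hand-coded brute-force
oracles rather than trusted.
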