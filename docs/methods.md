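# Methods

## Scope and data model

`promotif` analyses one upstream promoter window per species (≤ 1000 bp,
uppercase A/C/G/T/N) together with a binary per-species phenotype
(telomerase `active`/`inactive` in the motivating application) and a set
of position count matrices. Coordinates are 1-based negative *upstream
offsets*: −1 is the base immediately 5′ of the translation start, a
promoter of length L spans −L..−1, and a window of length w starting at
offset v occupies v..v+w−1 on the forward strand. Internally string
index i of a length-L sequence is offset i − L. Minus-strand hits are
reported at the forward-strand offset of their 5′-most base, so
positional summaries are strand-agnostic.

Metadata is the single source of phenotype truth; FASTA headers carry
only the species id, and study assembly enforces a bijection between
promoters and metadata rows so labels cannot drift silently.

## Similarity scoring

For a matrix with pseudocount-adjusted frequencies f(i,b) the
information vector is

    I(i) = Σ_b f(i,b) · ln(4 f(i,b)),   0·ln 0 ≡ 0,

ranging from 0 (uniform position) to ln 4 (fully conserved). A window w
of matrix length scores

    MSS = (Current − Min) / (Max − Min),
    Current = Σ_i I(i) f(i, w_i),
    Min = Σ_i I(i) min_b f(i,b),   Max = Σ_i I(i) max_b f(i,b).

MSS is 1.0 *exactly* on a per-position argmax window and 0.0 exactly on
a per-position argmin window (the implementation sums Current, Min and
Max in identical position order so these endpoints are exact in floating
point, not merely close). The core similarity CSS applies the same
normalised form to the *core*: the run of min(5, L) consecutive
positions maximising Σ I(i), leftmost on ties (a ≤ 1e−12 slack treats
exactly-tied floating sums as ties). All-uniform matrices have Max = Min
and are rejected at load.

Two filter dialects share this kernel:

* `match` — require CSS ≥ core_cutoff (default 1.0) and MSS ≥
  mss_cutoff (default 0.94);
* `tfbind` — require MSS ≥ mss_cutoff (default 0.9), no core filter.

The named tools these dialects emulate publish cut-offs but not complete
formulas; implementing both as one audited information-weighted kernel
keeps them testable and mutually comparable. Whether the original
analyses scanned both strands is not documented, so `both_strands` is a
flag (default on, the standard convention for double-stranded promoter
motifs).

Default pseudocount is 0 with the 0·ln 0 convention, configurable per
matrix load; reshaping user matrices silently was deliberately avoided.
Windows containing N are skipped and counted to the log, not scored: any
score for an ambiguous base would require an ambiguity model the scoring
scheme does not define.

## Group statistics

**Three-hypothesis bootstrap.** For one matrix, per-species hit counts
are split by phenotype. Each of B replicates (default 10,000) resamples
both groups with replacement, each to its own size, and compares the
resampled group means; the replicate is tallied into exactly one of
{inactive > active, inactive = active, inactive < active}. The tallies
divided by B are the reported probabilities of the three hypotheses; a
small value marks that hypothesis as failed. Because every replicate
lands in one bin of a single run, the three probabilities sum to 1
exactly (as rationals n/B). Mean comparison uses integer
cross-multiplication (sum_inactive·n_active vs sum_active·n_inactive), so
"equal" is an exact integer event, never a floating tolerance. The
bootstrap runs on raw counts by default; a presence (0/1) switch exists
because either convention is defensible for near-binary data.

**Fisher presence test.** Presence = count ≥ 1 yields a 2×2 table
(phenotype × present/absent). The two-tailed p follows the standard
sum-of-small-p rule — the total conditional hypergeometric probability
of all tables with the observed margins no more probable than the
observed one — computed with exact rational arithmetic (`math.comb` +
`Fraction`), so it agrees with brute-force enumeration identically
rather than to rounding. Degenerate margins (site present in every
species or in none) return p = 1 with a logged note. No multiple-testing
correction is applied by default, matching the per-matrix raw-p
reporting convention of small comparative studies; Benjamini–Hochberg
q-values are available behind a flag.

**Significance flag.** A matrix is flagged when the two approaches
agree at α = 0.05: min(p_greater, p_less) < α *and* Fisher p < α. The
directional tallies alone are not a calibrated test — exact resample
ties inflate p_equal and deflate both directional tallies (constant
counts give p_greater = p_less = 0) — so the conjunction rule is what
the calibration guarantee attaches to. On null studies the flag fires
well below 5% (exact discrete tests are conservative); this is verified
by simulation in the test suite.

## Clustering and PCA

Features are 0/1 presence indicators for the selected matrices plus one
phenotype indicator; binary columns share a scale, so no standardisation
is applied by default (a flag exists). k-means (Lloyd's algorithm,
scikit-learn, random initial centers, one initialisation per restart)
is run for a configurable number of restarts; each result is
canonicalised by renaming clusters in order of first occurrence, so
label permutations compare equal, and distinct clusterings are returned
ranked by within-cluster sum of squares. Selecting *the* clustering
(e.g. the one best matching an external grouping) is an editorial act,
not a computational one, so the package returns all distinct solutions
plus a label-homogeneity score (mean within-cluster majority fraction)
to support the choice. PCA centers columns (no scaling) and projects
onto the leading right singular vectors with a fixed sign convention
(each component's largest-magnitude loading positive), making output
deterministic.

## Positional histograms

Hits are binned by 5′-most-base offset into fixed-width bins
partitioning −1000..−1 and stratified by phenotype;
counts_all = counts_active + counts_inactive per bin by construction.
The default width of 50 bp makes "−200 to −151" a single bin, the
granularity at which promoter-proximal site concentrations are usually
described. No statistical test is attached: positional structure is
summarised, not scored.

## Synthetic studies

The generator emulates the study design the statistics assume: two
groups of species (default 14 + 14, the size at which the Fisher
enumeration is still exhaustive and realistic for cross-species promoter
collections), 1000-bp promoters drawn i.i.d. from a configurable
background composition (default uniform), and per-matrix planting: with
a group-specific probability, an instance sampled position-wise from the
matrix frequencies is written over the background at an offset drawn
from a rounded, truncated Gaussian (default mean −175, sd 15 bp, so
~90% of plants fall within one 50-bp bin, emulating a promoter-proximal
site cluster; a uniform option exists), on a uniformly random strand.
Plants overwrite background rather than insert, preserving promoter
length and offset arithmetic; plants never overlap each other (rejection
sampling with a retry cap that errors loudly naming the species and
matrix). Chance background hits remain possible by design — real
promoters contain spurious matches too — and every planted instance is
recorded with its own-matrix MSS/CSS so sub-threshold plants are
identifiable for any cut-off. All randomness flows from one seed; output
is byte-stable per seed.

The bundled example matrices are synthetic constructions shaped like
familiar motif families (ETS GGAA core, E-box, GATA), not database
matrices: 12 positions of which 8 (including the whole 5-position core)
are deterministic and 4 flanks are soft. The deterministic octamer makes
the chance background rate ≈ 4⁻⁸ per window (~0.01 hits per 1-kb
promoter per matrix, both strands) while sampled instances always pass
both dialects' cut-offs; the soft flanks give instances realistic score
variation. The four octamers are pairwise distinct in both orientations,
so planted instances of one matrix are not hit by another. An earlier
8-position sketch with only the core deterministic produced ~1.6 chance
hits per promoter-matrix pair — enough to drown presence statistics —
which motivated this design.

`five_group_study` builds a 28-species study with five site/state
patterns (two groups of inactive promoters carrying a far-upstream
E-box, one inactive group with ELK1+GATA3-like sites, and two active
groups, one with the GABPA-like motif concentrated near −175) for
exercising the clustering and positional stages on data with known
structure.

What the generator does **not** emulate: phylogenetic correlation among
species (promoters are independent draws, whereas real species share
ancestry), non-uniform or Markov background composition beyond a single
base-frequency vector, motif co-occurrence constraints, and
insertions/deletions. Passing tests on synthetic data therefore
demonstrate the correctness and calibration of the *computations*, not
that any particular biological promoter set will show the same effect
sizes.

## Problem sizes and numerical conventions

Simulation-based checks in the test suite use 500 null studies and 200
effect studies at B = 2,000 bootstrap replicates, and B = 100,000 when
comparing against the exhaustive resample enumeration for tiny groups;
the acceptance script uses 200 null and 100 effect replicates at
B = 2,000 and B = 10,000 for the flagship study. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bounds.
Further conventions: hit ordering is (matrix, species, offset, strand
with + before −); hit TSVs print scores with round-trip float precision;
k-means restart seeds and per-matrix bootstrap streams are spawned
deterministically from the user seed (all derived seeds < 2³¹); Fisher
p-values are exact rationals converted to float only for reporting.

## Known limitations

* The two dialects are this package's documented reconstruction of
  Match-style and TFbind-style filtering; the original TFbind scoring
  may differ in detail, so absolute hit lists from the historical tools
  are not guaranteed to be reproduced — the cut-off semantics and the
  relative comparisons are.
* The bootstrap's three probabilities come from one resampling run; a
  workflow that estimated each hypothesis in an independent run would
  produce probabilities summing only approximately to 1.
* Binary presence features discard site multiplicity for clustering
  (a counts option exists but is not the default).
* No per-hit background-model p-values; the cut-off filter is the only
  per-hit significance notion.
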