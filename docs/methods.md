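# Methods

## Structure model and decomposition

A secondary structure is a set of base pairs (i, j), i < j, over 1-based
nucleotide positions, with each position in at most one pair. All analyses
require the structure to be pseudoknot-free: no two pairs (i, j), (k, l) with
i < k < j < l. Crossing pairs are detected exhaustively; by default they are
a hard error, and an explicit stripping mode removes the later-opening pair
of each crossing greedily until none remain.

The decomposition follows the standard region vocabulary. Stems are maximal
runs of consecutively nested pairs; a stem of s pairs encloses s − 1 stem
regions. Every stem's innermost pair closes exactly one loop, classified by
the stems and unpaired runs on its far side: no inner stem → hairpin; one
inner stem with one non-empty unpaired run → bulge, with two → interior
loop; two or more inner stems → multiloop. Everything outside all top-level
stems is the opening region. Loop groups are the maximal non-empty runs of
unpaired positions between consecutive stem attachment points around a loop.

Degenerate and edge cases are handled deliberately:

* A run of zero unpaired nucleotides between abutting stems is **not**
  counted as a loop group. No worked example in the field's usage exhibits a
  size-0 group, and the Q recursion's group factor x^k + z presumes k ≥ 1;
  omitting empty runs keeps that reading consistent. This is a genuine
  convention choice and the one place the decomposition is not forced.
* A structure with zero pairs decomposes to a single opening-region loop;
  its type-1/3 tree is a lone root and its polynomial is x (the leaf rule
  takes precedence for a childless root — the recursion must be total, and
  early transcription-step prefixes are exactly this case).
* Lonely pairs (stems of one base pair) are legal stems and contribute no
  stem-region vertices.
* The two sides of an interior loop enter the trees as an unordered group
  multiset; children are unordered everywhere, matching the invariance of
  the polynomials under child permutation.

These conventions are locked in by the conservation identity
2·Σ stem sizes + Σ loop sizes = length, by the tree identity
#loops = #stems + 1, and by the property tests that assert both on every
generator draw.

## Trees and polynomials

The eight tree types share the loop-stem skeleton (vertex per loop, edge per
stem, root at the opening region) and differ in decoration: stem-size types
(3, 4, 6, 8) expand each stem edge into a path of stem-region vertices;
loop-size types (2, 4, 5, 6) attach one unpaired-nucleotide leaf per
unpaired position; group types put artificial group vertices either between
the loop and its leaves (2, 4) or as bare leaves (7, 8). Types 7 and 8
record group counts only, so they conflate group count with hairpin
presence and add little discriminating power — a known property, not a bug.
The exact shapes of types 5–8 are reconstructions from the feature checklist
and are pinned down by contraction tests: contracting the decoration
vertices of a richer type must reproduce the poorer type exactly
(3→1, 6→5, 8→7, 2→5, 4→2, 5→1, 7→1).

P and Q are computed by one shared bottom-up pass (iterative postorder, so
recursion depth never binds) over sparse exponent-map polynomials with exact
arbitrary-precision integer coefficients. Exactness is not optional:
coefficient sums grow exponentially with the number of bubbles in linear
branches and overflow fixed-width integers on realistic 200-nt windows.
Dense coefficient tensors are materialised only on demand (object-dtype
arrays, again to protect big integers). Memoization of repeated subtrees is
possible but not enabled; profiling showed the plain pass is fast enough for
every problem size used here.

The completeness of P (equal polynomials iff isomorphic rooted trees) is
verified exhaustively over all 486 rooted trees with at most 9 vertices
against an independently generated canonical nested-tuple enumeration; the
AHU canonical form incorporates vertex classes so the same oracle covers the
class-labelled trees.

## Distances and clustering

The distance between two same-type polynomials sums the relative coefficient
difference κ(b, c) = |b − c|/(b + c) over the union of the two supports;
out-of-support cells contribute κ(0, 0) = 0, so the dense (n+1)³ tensor is
never built. Accumulation uses exact rationals (coefficient magnitudes can
exceed float range) and converts to float only on output; tests compare at
1e−12. κ is a bounded per-cell metric, so the sum is a metric on coefficient
maps; one consequence worth noting is saturation — once two polynomials have
disjoint supports every cell contributes 1 and further divergence no longer
increases the distance. The synthetic-family monotonicity test therefore
probes the unsaturated regime.

k-medoids is a hand-written PAM: k-medoids++-style seeding from the given
generator, alternating nearest-medoid assignment (ties to the lowest index;
a medoid always anchors its own cluster) and per-cluster medoid update,
iteration cap 300, convergence on an unchanged medoid set. The algorithm is
a heuristic, so family-recovery experiments repeat it over consecutive seeds
(base_seed + r for repeat r) and report the mean majority-rule
misclassification rate. Majority ties within a cluster break to the
lexicographically smallest family name and are recorded; empty clusters
contribute no misclassifications. Both tie rules are our choices — the
majority rule itself does not dictate them.

## R-loop pipeline

Given an amplicon of n nt and window length m (default 200, the length at
which co-transcriptional folding of every window remains practical), the
n − m + 1 windows are folded independently — no cross-window reconciliation,
consistent with treating the windows' nascent structures as mutually
independent. The structure grid s(i, j) holds the coefficient sum of the
chosen tree type for the step-j prefix structure of window i; overlapping
sums use an O(n) sliding difference and are tested against a brute-force
window-assignment oracle. Normalization divides by the column maximum using
exact rational division; an all-zero column yields zeros with a warning
rather than an error. The scaled sum multiplies the normalized overlapping
sum by the maximum of the experimental probability track, so the two tracks
share their peak value by construction. Pearson correlation excludes
undefined positions pairwise and reports NaN (with a warning) for constant
tracks. Cross-step selection (the best PCC among the last ten transcription
steps) is an explicit reporting operation that returns every per-step PCC
alongside the maximiser, never a silent choice. PCC includes amplicon edge
positions with partial window coverage; the trapezoidal coverage profile is
itself oracle-tested.

The external-folder adapter reads one file per window of per-step candidate
structures; when several structures coexist at a step it keeps the
highest-occupancy one by default, with a minimum-free-energy alternative
behind a flag, and records the rule in provenance — folding tools do not
dictate a unique per-step representative, so both readings are available.

## Synthetic data

The generator emits pseudoknot-free dot-bracket strings by construction
(branches are nested strings, so pairs cannot cross). Defaults model the
regimes relevant to the coefficient-sum analysis: 200-nt windows, stems of
2–4 bp, hairpins of 3–5 nt, bulges of 1–2 nt, interior loops of 1–2 nt per
side, a Poisson(2) number of bubbles per linear branch (capped at 3),
multiloop branching with probability 0.3 up to depth 3. A branch (or a
multiloop sub-branch) is only started while the worst-case linear branch
still fits the remaining length budget, so no size draw is ever truncated
and the realised stem/loop marginals follow the requested distributions
exactly (verified by seeded chi-square at n = 2000, α = 0.01); leftover
positions stay unpaired in the opening region, giving exactly the requested
length. All randomness flows from one explicit seed per call.

Family sets share a fixed topology template per family with member-level
jitter on loop sizes only, mirroring the empirical pattern that loop sizes
vary within a structure family while the loop-stem relation is conserved.
Two modes exist: families differing in topology (hairpin-branch count; the
feature type 1 records) and families differing only in loop size (the
feature type 1 is blind to) — the second mode underlies the test that a
feature-recording type clusters at least as well as a feature-blind type on
data built to differ in exactly that feature.

The mock co-transcriptional folder is a deterministic toy: scanning 5′→3′,
each nucleotide pairs with the innermost open position that is complementary
(Watson–Crick or GU), at least 4 nt upstream, and accepted by a seeded hash
(3/4 acceptance); skipped-over positions stay unpaired, so structures are
nested and step j always has exactly j nucleotides. It reproduces the
interface and invariants of a kinetic folding program, not its energetics:
passing pipeline tests demonstrates the correctness of the windowing,
summing, scaling and correlation machinery on folder-shaped input, not that
the mock structures resemble thermodynamic folds. Likewise the synthetic
probability track is a noisy affine image of a computed normalized
overlapping sum (peak 0.5, Gaussian noise σ = 0.01, clipped to [0, 1]), so
the end-to-end recovery test checks the pipeline's self-consistency, not
biological predictive power.

## Problem sizes

The default test suite and the acceptance script use a 150-nt mock amplicon
with 40-nt windows (4,440 structures), 500 random trees for the Q → P
reduction sweep, 36 structures across three synthetic families with 50–100
clustering repeats, and the exhaustive ≤ 9-vertex tree enumeration — sizes
chosen so the whole battery completes in seconds while every check remains
exact or statistically stable under its fixed seeds.

## Known limitations

* Pseudoknots are out of scope end to end; stripping is a preprocessing
  convenience, not a representation.
* Tree representations are unordered: structures differing only in the
  arrangement of stems around a multiloop (or in a 5′/3′ swap) share a tree
  and hence a polynomial.
* The clustering MMR and pipeline PCC values on real datasets depend on
  external data (curated structure databases, folding-tool output,
  footprinting tracks) and are not reproduced here; the procedures are.
* Plasmid topology (supercoiling state) is carried as metadata only and
  never enters the computation.
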