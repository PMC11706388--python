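# treepoly

Tree-polynomial analysis of RNA secondary structures, with applications to
non-coding RNA family clustering and co-transcriptional R-loop propensity
scoring.

## The problem

A pseudoknot-free RNA secondary structure decomposes uniquely into **stems**
(maximal runs of nested base pairs) and **loops** — hairpin loops, bulges,
interior loops, multiloops and the opening region holding the 5′/3′ ends.
The stems attached to a loop split its unpaired nucleotides into **loop
groups**. This package encodes a structure as one of **eight rooted trees**,
each recording the loop–stem relation plus a chosen combination of three
quantitative features:

| type | polynomial | loop size | stem size | loop group |
|------|------------|-----------|-----------|------------|
| 1    | P          |           |           |            |
| 2    | Q          | ✓         |           | ✓          |
| 3    | P          |           | ✓         |            |
| 4    | Q          | ✓         | ✓         | ✓          |
| 5    | P          | ✓         |           |            |
| 6    | P          | ✓         | ✓         |            |
| 7    | P          |           |           | ✓          |
| 8    | P          |           | ✓         | ✓          |

Type 1 is the classical loop-stem tree; type 6 is the arc tree. Loop size is
recorded as one leaf per unpaired nucleotide, stem size by expanding a stem
of *s* base pairs into a path of *s − 1* stem-region vertices, and loop
group via artificial group vertices (internal in types 2/4, leaves in 7/8).

Each tree *T* is identified by a **complete polynomial invariant**, computed
bottom-up from the leaves to the root *r*:

* **P(T, x, y)**: a leaf vertex gets *x*; an internal vertex with children
  *u₁…u_k* gets *y + ∏ᵢ P(uᵢ, x, y)*. Two rooted trees are isomorphic iff
  their P polynomials are equal.
* **Q(T, x, y, z)**: as P, but an artificial group vertex gets
  *z + ∏ᵢ Q(uᵢ)* instead of *y + ∏ᵢ Q(uᵢ)*, so the loop-group feature is
  carried by its own variable. Substituting *z := y* in Q recovers P.

The polynomials are interpretable: the x-degree counts leaves (hairpins for
type 1, unpaired nucleotides for types 2/4/5/6), the z-degree of Q counts
loop groups, and the coefficient of the linear *y* term of Q(·,·,·,1) counts
loops (plus stem regions for type 4). Structures are compared with a
coefficient-wise Canberra distance

d(S, T) = Σ κ(b⁽ⁱʲᵏ⁾, c⁽ⁱʲᵏ⁾),  κ(b, c) = |b − c| / (b + c)  (κ(0,0) = 0),

summed over the coefficient tensors of the two polynomials. Distance
matrices feed a seeded PAM k-medoids clusterer scored by majority-rule
misclassification (MMR over repeated runs).

The **R-loop pipeline** scans a transcript with an *m*-nt sliding window
(*n − m + 1* windows over *n* nt), obtains one secondary structure per
transcription step *j = 1…m* of every window from a co-transcriptional
folder (an external tool via the adapter, or the built-in deterministic mock
folder), and computes the coefficient sum *s(i, j)* of the chosen
tree-polynomial for every structure. Per step, the per-nucleotide
**overlapping sum** (each window adds *s(i, j)* to the positions it covers),
its max-normalization, and the **scaled sum** (rescaled to the maximum of an
experimental R-loop probability track) are compared with the experimental
track by Pearson correlation. Structures rich in *bubbles* — bulges and
interior loops separating short stems along linear branches — contribute a
factor *x + ℓy* per branch with ℓ bubbles, so coefficient sums grow
exponentially with bubble count; those regions dominate the scaled-sum
profile.

## Worked example

The 41-nt structure `.(((.((.((...))....((.((....)))).)).)))..` has one
3-bp stem and four 2-bp stems; its loops are the opening region (3 nt,
groups 1+2), an interior loop (2 nt, groups 1+1), a multiloop (6 nt, groups
1+4+1), a 1-nt bulge, and hairpins of 3 and 4 nt:

```sh
$ treepoly parse --db '.(((.((.((...))....((.((....)))).)).)))..'
region  kind       size  groups  stems
loop    opening    3     1,2     0
loop    interior   2     1,1     0,1
loop    multiloop  6     1,4,1   1,2,3
loop    hairpin    3     3       2
loop    bulge      1     1       3,4
loop    hairpin    4     4       4
stem    stem       3             0
...
```

Its type-1 tree has 6 vertices (one per loop) and 5 edges (one per stem):

```sh
$ treepoly poly --db '.(((.((.((...))....((.((....)))).)).)))..' --type 1
x^2 + x*y + 3*y
coefficient_sum 5
```

The term *x²* says the tree has two leaves (two hairpin loops); the *3y*
collects the three internal vertices on single-child chains. The type-4
polynomial Q of the same structure has coefficient sum 5165, its z-degree is
10 (ten loop groups in total) and the linear-y coefficient of Q(·,·,·,1) is
12 (6 loops + 6 stem regions).

A clustering run over synthetic families and a mock R-loop pipeline run:

```sh
treepoly synth --mode families --seed 5 --count 20 --out fam/
treepoly dist --in fam/families.dbn --type 1 --out fam/dm.tsv
treepoly cluster --dist fam/dm.tsv --labels fam/labels.tsv --k 3 --repeats 1000 --seed 1
# -> {"mmr_percent": 0.0, ...}

treepoly synth --mode amplicon --seed 5 --length 150 --window 40 --out amp/
treepoly rloop --fasta amp/amplicon.fa --amplicon 1:150 --window 40 \
    --tree-type 1 --prob amp/probability.tsv --mock-fold 5 --out rloop/
# -> {"best_step": 40, "best_pcc": 0.997...}
```

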