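# Methods

`prefixome` serves binned, filtered, normalized views of pairwise
nucleic-acid interaction data (Hi-C-like DNA-DNA contacts, RADICL-/GRID-seq
style RNA-DNA contacts) in time that does not depend on the number of
stored interactions, the genome size or the bin size.  All
parameter-dependent work happens at query time against a
parameter-independent index, so filters and normalizations can be changed
freely without re-running a pipeline.

## The sparse prefix-sum index

The prefix sum of a coordinate `q` is the number of records at or before
`q` in every dimension.  The count in any axis-aligned range follows by
inclusion-exclusion over the `2^d` corners of the range, each corner one
prefix evaluation; corners with a `-1` component lie before all data and
cost nothing.  Interactions are points in a multi-dimensional space: x and
y position (in units of the *base resolution*, the constant divisor applied
to bp positions; default 1000 bp, the finest queryable bin size), and one
coordinate per filter.

**Quality filter.** Each interaction carries the lower of its two partners'
mapping qualities (SAM's "unavailable" value 255 is mapped to 0 so it can
never pass a filter).  The quality axis is stored *inverted*
(`255 - mapq`), so high-quality interactions sit at the bottom: a
"keep mapq >= m" filter moves only the top face of the queried cube, the
bottom face stays below all data, and a 3-D filtered query costs 4 lookups
instead of 8.

**Multimapper rescue.** An interaction whose partner aligns to several
loci is stored as the smallest rectangle enclosing all its candidate loci.
At query time a rectangle counts toward a bin only if the bin fully
encloses it (the read's true locus is then known to be in the bin, whatever
it is).  Counting enclosed rectangles uses the identity, valid once
rectangles wider than the bin are removed through per-dimension *width*
coordinates,

    enclosed = prod_j ( I[end_j <= b_j] - I[start_j <= a_j - 1] ),

whose expansion is a sum of `2^k` signed prefix-style counts; overlapping
rectangles use `prod_j (I[start_j <= b_j] - I[end_j <= a_j - 1])` without
the width restriction.  No expansion term ever bounds a rectangle's start
and end in the same dimension, so the store is sharded into `2^k` point
sub-indices (one per start/end combination, each over k corner
coordinates, k widths and the filter coordinates).  This sharding is what
keeps the sparse storage tractable: a single joint space over starts,
ends and widths multiplies the non-empty-slice counts of strongly
correlated axes and grows explosively.  Both counting formulas are
validated against brute-force enumeration over random rectangle sets in
1-5 dimensions; that oracle, not a derivation, is the correctness
authority for the d-dimensional generalization.

**Annotation filter.** Two 0/1 dimensions per annotation type (x overlap,
y overlap) let queries keep or drop interactions by whether *any* candidate
locus overlaps an annotation of that type on that axis.

**Sparsity and boxes.** Storing prefix sums densely is impossible (the
cross product of all axes is astronomically large).  The data space is
divided into an even grid of boxes.  Each box stores an *internal* prefix
grid over the cross product of its non-empty slices (one sorted coordinate
list and one dense lookup table per dimension) plus one lower-dimensional
*overlay* prefix grid per dimension counting the records that precede the
box in that dimension (and not in any earlier one).  The overlays
partition everything before a query point but outside its box, so one
prefix evaluation reads `d + 1` cells — constant, whatever the data.
Empty slices are never materialised; per-contig-pair matrices keep dense
cis pairs from inflating sparse trans pairs; disabled filters collapse
their dimension to a single default coordinate.

**Size prediction.** Index size depends on the data distribution, so the
best box count is found empirically: candidate grids are scored by probing
up to 1000 random boxes (seeded, without replacement), computing their
exact sparse-cell and lookup-table sizes, and extrapolating (8 bytes per
prefix cell, 4 per LUT entry).  Probing every box reproduces the
materialised size exactly; ties go to fewer boxes.

## Views, bins, coordinates

Heatmaps keep a roughly constant number of displayed bins (default budget
2500, i.e. 50 per axis): zooming out grows the bins, not their number.
Genomic bins are the smallest base-resolution multiple meeting the budget;
bin grids restart at contig boundaries, so a bin never spans two contigs.
In *annotation coordinates* each bin covers `ceil(A / target)` consecutive
annotations (e.g. gene bodies); a bin's query range runs from its first
annotation's start to its last annotation's end, and the annotation-overlap
filter is forced on for that axis so interactions in the void space between
the annotations are excluded.

Virtual 4C fixes a viewpoint range on one axis and emits one filtered
count per opposite-axis bin — a single range count per bin regardless of
the viewpoint width.  Tracks are exactly additive over viewpoint
partitions for point-like interactions; under enclosed-mode multimapper
rescue a rectangle straddling the partition boundary counts toward the
joint viewpoint but toward neither part, so the joint track can exceed
the parts' sum — by design, not error.  Two heatmaps on identical grids can be compared by
subtraction or division (pseudocount, default 1, in both numerator and
denominator); both raw and normalized inputs are accepted.

## Ploidy correction

Assemblies whose contig copy number differs from the physical chromosome
number (aneuploidy, or collapsed homozygous cores next to split
heterozygous haplotypes) over- or under-represent interactions.  Each
n-ploid contig is displayed as n *instances*; counts are redistributed
with weights that always sum to one: evenly (`1/(n_a n_b)`) across
instance pairs of different contigs; within a contig, all weight on the
diagonal instance pairs (`1/n` each) under the intra-instance assumption;
and when named instance *groups* (haplotypes spanning contigs) exist, only
intra-group instance pairs receive weight whenever at least one pair is
intra-group.  Weights are exact `Fraction`s, so total heatmap mass is
conserved to the last unit.

## Normalizing partial matrices

Only the visible bins are ever computed, so full-matrix normalizations are
approximated by adding a small set of sampled out-of-view bins:

* **Iterative correction** uses two bias vectors (rows and columns), since
  a visible sub-rectangle of a symmetric matrix need not be symmetric.
  Biases are updated by the bias-corrected marginal sums, renormalized to
  unit mean over non-empty rows/columns each iteration
  (tolerance 1e-5 on the marginal deviation, at most 200 iterations);
  empty rows/columns are masked.  On a symmetric matrix this reproduces
  classical single-bias IC (asserted to within 10x the tolerance).
  Samples are evenly spaced concentric rings between the view edge and the
  genome edge; each ring decomposes into bin-sized strips matching the
  view's rows and columns, adding at most two rows and two columns
  (clipped or coinciding radii add fewer; ring radii are
  `ceil(i * margin / (n+1))`).  Sample bins are used for fitting only and
  discarded afterwards.
* **Distance-dependent decay** records each bin's signed distance to the
  diagonal (the sign distinguishes the two sides, which matters for
  asymmetric data).  Per contig pair and distance, same-size bins are
  sampled evenly spaced parallel to the diagonal (seeded phase), the top
  and bottom `x`-th percentile are trimmed (default 10, configurable) and
  the rest averaged — a mean rather than a median, because sparse data
  would make a median flip between 0 and 1.  Bins whose distance has no
  defined expectation, or expectation 0, are masked.
* **Associated Slices** (RNA-DNA) first calls chromatin-associated gene
  bodies from an evenly spaced subsample of gene bodies: a gene's average
  RNA reads per kbp (one whole-contig query per contig, divided by the
  total assembly length in kbp) and its maximal DNA reads in a 1 kbp-binned
  genome.  The maximum is found by heap-ordered halving: whole contigs are
  queried, the region with the largest count is split and re-queried until
  the largest region reaches the target size — exact, because counts are
  monotone under refinement.  Thresholds on the two properties are
  required configuration (the calling direction for the DNA maximum is
  configurable, default >=).  Each visible RNA slice is then divided by
  its summed *trans* contacts with the associated bodies (one query per
  body and slice; zero divisors mask the slice).
* **Binomial test** (RNA-DNA) scores each bin against a uniform-coverage
  null: the RNA of row `r` produced `N_r` interactions genome-wide (one
  prefix query per row, even for a partial view) and a bin of width `w_j`
  collects `Binomial(N_r, w_j / genome span)` of them.  Upper-tail
  p-values are Benjamini-Hochberg corrected; sampled rows above and below
  the view (preserving the columns) widen the BH family toward the
  full-matrix one without being reported.  The output is `-log10(q)` with
  non-significant bins masked.  The exact null parameters inherited from
  the RADICL-seq literature are not printed anywhere; the uniform-null,
  genome-wide-total choice here is the package's documented stand-in, and
  the null calibration test (significant fraction <= alpha on simulated
  null data) pins its behavior.

Default sample counts — 300 (IC), 1000 (Associated Slices), 100
(Binomial), 200 (DDD) — balance accuracy against query cost and are
overridable everywhere.

### Evaluating the sampling approximation

`windowed_deviation` quantifies the error the sampling introduces: a full
binned matrix is split into evenly sized diagonal windows, each window is
normalized separately with `n` samples, the windows are concatenated and
compared with the matrix normalized in its entirety.  Both results are
rescaled to unit mean over the compared (unmasked) bins before taking the
mean absolute difference, since normalized scales are arbitrary.  The
suite runs this over 20 replicate simulations with n in {10, 100, 1000}
and requires, per normalization, a significant sign-test majority of
seeds with decreasing deviation — a trend check, deliberately not a
reproduction of any published curve (those were measured on external
sequencing data).  These experiments run on matrices binned directly from
the simulated interaction lists; a separate end-to-end test asserts that
this binning equals unfiltered index queries.

## Synthetic data

The generator emulates the statistical structure the methods assume: cis
contacts with `P(s) ~ (s+1)^-gamma` (default gamma = 1, Hi-C-like;
distance drawn first, pair then placed inside the contig so the decay law
is exact), uniform trans background, multimappers whose extra candidate
loci are geometrically displaced (such partners get mapping quality 0), a
mapping-quality mixture with mass at 0, uniform-length gene annotations,
optional aneuploidy and zygosity groups, and a separate uniform null for
the Binomial calibration.  Outputs are byte-identical per seed.  A truth
table (one row per interaction and touched contig pair, with bounding
rectangle and effective mapq) backs the brute-force reference
computations.  What the generator does *not* model — TADs, loops,
compartments, restriction-site bias, PCR duplicates — bounds what the
tests show: they validate counting, filtering and the sampling
approximations, not biological discovery on real data.

## Numerical and scale choices

Coordinates are non-negative integers with inclusive `[low, high]`
intervals (half-open external formats are converted on read: BED ends
subtract 1, GFF3 starts subtract 1).  Prefix cells are 64-bit.  Stable
input order breaks sorting ties.  Test problem sizes (genomes of a few
hundred kbp, thousands of interactions, base resolutions of 1-10 kbp)
keep full-suite runs fast; index storage grows steeply with the number of
distinct coordinates per dimension, which is the known cost of
constant-time queries — coarser base resolutions or deactivated filters
shrink it, as does the box-grid optimizer.

## Known limitations

Indices are immutable after build (no updates).  Strand is parsed but
unused.  Bins truncate at contig boundaries rather than spanning them.
The interaction input is a package-defined TSV dialect because no standard
pairs format carries candidate-locus lists.  Out-of-core storage,
eigenvector/compartment analysis, KR balancing and interactive rendering
are out of scope.
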