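# prefixome

On-the-fly analysis of nucleic-acid interactome data — Hi-C-style DNA-DNA
contacts and RADICL-/GRID-seq-style RNA-DNA contacts — on a sparse
N-dimensional prefix-sum index.

Interactome pipelines bake filtering, binning and normalization parameters
in at processing time; exploring a dataset then means re-running hours of
pipeline per parameter set.  `prefixome` instead preprocesses a dataset
*once*, parameter-free, into an index of prefix sums, after which any
heatmap — arbitrary region, bin size, mapping-quality window, multimapper
handling, annotation filter, normalization, ploidy correction — is served
by a constant number of lookups per displayed bin, independent of the
number of interactions and the genome size.  It is a library plus a small
CLI, aimed at people analyzing contact data from organisms with modest
genomes (parasites, yeasts, bacteria) where repeats, aneuploidy and
uncertain parameters make one-shot pipelines painful.

## The core idea

The prefix sum `P(q)` is the number of interactions at or before `q` in
every dimension.  Any bin count is an alternating sum over the bin's
corners: in 1-D, `count(a, b] = P(b) − P(a)`; in d dimensions, `2^d`
corners.  Filters become extra dimensions: an inverted mapping-quality
axis (stored as `255 − min(mapq_x, mapq_y)`, so quality thresholds touch
only the cube face that requires lookups), two 0/1 overlap dimensions per
annotation type, and per-axis width dimensions for multimapping reads,
which are stored as the smallest rectangle enclosing their candidate loci
and counted toward a bin only when the bin fully encloses the rectangle:

    enclosed(bin) = Σ over start/end choices (−1)^(#starts) · P(chosen corners, widths ≤ bin, filters)

Storage is a grid of boxes, each keeping prefix sums only over its
non-empty slices; the box count is chosen by seeded random probing to
minimise predicted size.  Partial-matrix normalizations — two-bias
iterative correction, distance-dependent decay, Associated Slices and a
Binomial test with Benjamini-Hochberg correction — approximate their
full-matrix counterparts by sampling out-of-view bins (concentric rings,
diagonal-parallel bins, gene-body subsamples, extra rows).  Ploidy
correction redistributes counts over chromosome instances with exact
fractional weights.  See `docs/methods.md` for the full model.

## Worked example

```
$ prefixome simulate --seed 3 --out-dir sim
$ prefixome index --chrom-sizes sim/genome.chrom.sizes \
    --interactions sim/interactions.tsv --annotations sim/genes.gff3 \
    --base-resolution 10000 --boxes 4 --out idx.h5
stored 5000 incidences in 16 contig-pair matrices
predicted size: 22027104 bytes, materialized: 22027104 bytes
$ prefixome query --index idx.h5 --bins 900 --out heatmap.tsv
wrote 29x29 heatmap, mass 4871
$ prefixome query --index idx.h5 --bins 900 --mapq-min 1 --norm ic --samples 50 --out ic.tsv
wrote 29x29 heatmap, mass 2591
$ prefixome v4c --index idx.h5 --viewpoint chr1:100000-140000 --bins 100 --out v4c.bedgraph
wrote 55 bins, total 156
```

The simulated dataset holds 5000 interactions on four contigs; `index`
builds one rectangle index per touched contig pair (16 pairs) and reports
its probe-predicted byte size next to the materialised one (identical
here because the probe count exceeds the box count, making the
prediction exhaustive).  The first query counts all 5000 incidences into
a 29×29 whole-genome heatmap — mass 4871 rather than 5000 because, at
20 kb bins, 129 multimapper rectangles span a bin boundary and are
(correctly) not rescued.  The second keeps only the 2591 pairs with
effective mapping quality ≥ 1 and balances them by iterative correction
with 50 ring samples (the unit-mean biases redistribute counts across
bins while conserving the total); the virtual-4C track sums, per 20 kb
bin, the interactions linking the bin to the 40 kb viewpoint on
chromosome 1.

The same operations are available as library calls
(`build_interactome_index`, `query_heatmap`, `virtual_4c`,
`ic_normalized_heatmap`, `apply_ploidy`, ...), which is the more
convenient interface from notebooks.

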