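"""Normalization of partial (visible-region) matrices.

A heatmap served from the index shows only the bins of the current view,
but classic normalizations are defined on the full contact matrix.  Each
method here therefore augments the visible matrix with a small set of
*sampled* out-of-view bins chosen so that, with enough samples, the
result approaches the full-matrix normalization:

* iterative correction (IC): evenly spaced concentric rings around the
  view, each ring contributing up to two extra rows and two extra
  columns (the matrix must stay rectangular and gap-free for balancing);
* distance-dependent decay (DDD): per signed diagonal distance, evenly
  spaced same-size bins parallel to the diagonal, averaged after trimming
  the top and bottom percentiles (average, not median: sparse data would
  make a median flip between 0 and 1);
* Associated Slices (RNA-DNA): chromatin-associated gene bodies are
  called from an evenly spaced subsample of gene bodies, then each
  visible RNA slice is divided by its summed trans contacts with the
  associated bodies;
* Binomial test (RNA-DNA): per-RNA-row binomial upper-tail p-values
  against a uniform-coverage null, Benjamini-Hochberg corrected; sampled
  rows above and below the view (preserving the columns) extend the BH
  family toward the full-matrix one.

Default sample counts: 300 (IC), 1000 (Associated Slices), 100
(Binomial), 200 (DDD).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import Genome
from .query import Bin, FilterSettings, Heatmap

__all__ = [
    "DEFAULT_SAMPLES",
    "SampleScheme",
    "BiasVectors",
    "DDDProfile",
    "ChromAssocCall",
    "sample_rings",
    "ic_partial",
    "ic_normalized_heatmap",
    "ddd_profile",
    "ddd_normalize",
    "trimmed_mean",
    "max_bin_count",
    "find_chromatin_associated",
    "assoc_slices_normalize",
    "binomial_normalize",
    "binomial_normalized_heatmap",
    "sample_rows",
]

DEFAULT_SAMPLES = {"ic": 300, "assoc": 1000, "binom": 100, "ddd": 200}


@dataclass
class SampleScheme:
    """Out-of-view sample bins added before normalization.

    ``rows``/``cols`` are global-bp strip starts (strips are bin-sized);
    clipped or deduplicated rings contribute fewer than two strips.
    """

    kind: str
    rows: list[int] = field(default_factory=list)
    cols: list[int] = field(default_factory=list)
    bin_width: int = 0
    bin_height: int = 0
    n_samples: int = 0


@dataclass
class BiasVectors:
    row_bias: np.ndarray
    col_bias: np.ndarray
    iterations: int
    residual: float


@dataclass
class ChromAssocCall:
    name: str
    contig: str
    start: int
    end: int
    avg_rna_per_kbp: float
    max_dna_1kbp: int
    is_associated: bool


# ---------------------------------------------------------------------------
# ring sampling for IC


def sample_rings(view_x, view_y, bin_w, bin_h, genome: Genome, n_samples: int) -> SampleScheme:
    """Concentric ring samples around a genomic view.

    ``view_x``/``view_y`` are half-open global-bp spans of the visible
    area; sample strips are one bin wide and evenly spaced between the
    view edge and the genome edge on each side.  Strips outside the
    genome are omitted and coinciding radii are deduplicated, so a
    clipped ring adds fewer (never more) than 2 rows and 2 columns.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    total = genome.total_length

    def side_strips(view_lo, view_hi, size, lower: bool):
        margin = view_lo - 0 if lower else total - view_hi
        starts = []
        for i in range(1, n_samples + 1):
            r = math.ceil(i * margin / (n_samples + 1))
            s = view_lo - r - size if lower else view_hi + r
            if s < 0 or s + size > total:
                continue
            # keep strips outside the view (tiny margins can push them in)
            if s + size > view_lo and s < view_hi:
                continue
            starts.append(s)
        return sorted(set(starts))

    scheme = SampleScheme("rings", bin_width=bin_w, bin_height=bin_h, n_samples=n_samples)
    scheme.rows = side_strips(view_y[0], view_y[1], bin_h, True) + side_strips(
        view_y[0], view_y[1], bin_h, False
    )
    scheme.cols = side_strips(view_x[0], view_x[1], bin_w, True) + side_strips(
        view_x[0], view_x[1], bin_w, False
    )
    return scheme


# ---------------------------------------------------------------------------
# iterative correction


def ic_partial(matrix, visible_rows=None, visible_cols=None, max_iter=200, tol=1e-5):
    """Two-bias iterative correction of a (possibly asymmetric) matrix.

    Alternately rescales row and column biases by the bias-corrected
    marginal sums (renormalized to unit mean over non-empty rows/columns)
    until every unmasked marginal is within ``tol`` of the common mean.
    On a symmetric matrix this reduces to classical single-bias IC.

    Returns ``(BiasVectors, corrected)`` where ``corrected`` is restricted
    to ``visible_rows``/``visible_cols`` (sample bins are only used for
    fitting).  All-zero rows and columns are masked (NaN).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if np.any(M < 0):
        raise ValueError("negative entries cannot be balanced")
    row_ok = M.sum(axis=1) > 0
    col_ok = M.sum(axis=0) > 0
    if not row_ok.any() or not col_ok.any():
        raise ValueError("nothing to balance: matrix has no non-zero rows/columns")
    br = np.ones(M.shape[0])
    bc = np.ones(M.shape[1])
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        S = M / np.outer(br, bc)
        rs = S[:, col_ok].sum(axis=1)
        upd = rs[row_ok] / rs[row_ok].mean()
        br[row_ok] *= upd
        S = M / np.outer(br, bc)
        cs = S[row_ok, :].sum(axis=0)
        updc = cs[col_ok] / cs[col_ok].mean()
        bc[col_ok] *= updc
        residual = max(np.abs(upd - 1).max(), np.abs(updc - 1).max())
        if residual < tol:
            break
    corrected = M / np.outer(br, bc)
    corrected[~row_ok, :] = np.nan
    corrected[:, ~col_ok] = np.nan
    br_out = np.where(row_ok, br, np.nan)
    bc_out = np.where(col_ok, bc, np.nan)
    if visible_rows is not None:
        corrected = corrected[np.asarray(visible_rows)]
    if visible_cols is not None:
        corrected = corrected[:, np.asarray(visible_cols)]
    return BiasVectors(br_out, bc_out, it, float(residual)), corrected


def _strip_bins(starts, size, genome):
    bins = []
    for s in starts:
        for contig, lo, hi in genome.spans(s, s + size):
            bins.append(Bin(contig, lo, hi))
    return bins


def ic_normalized_heatmap(iidx, heatmap: Heatmap, filters=None, n_samples=None,
                          max_iter=200, tol=1e-5):
    """IC-normalize a visible heatmap using ring samples around it.

    The visible bins are extended with sampled rows and columns queried
    from the index; the extended rectangular matrix is balanced and the
    sample bins are then discarded.
    """
    from .query import _bin_units  # local import to avoid a cycle at import time

    filters = filters or FilterSettings()
    if n_samples is None:
        n_samples = DEFAULT_SAMPLES["ic"]
    genome = iidx.genome
    res = iidx.config.base_resolution

    def gspan(bins):
        lo = genome.global_start(bins[0].contig) + bins[0].start
        hi = genome.global_start(bins[-1].contig) + bins[-1].end
        return lo, hi

    bw = max(b.width for b in heatmap.x_bins)
    bh = max(b.width for b in heatmap.y_bins)
    scheme = sample_rings(gspan(heatmap.x_bins), gspan(heatmap.y_bins), bw, bh, genome, n_samples)
    extra_rows = _strip_bins(scheme.rows, bh, genome)
    extra_cols = _strip_bins(scheme.cols, bw, genome)
    rows = list(heatmap.y_bins) + extra_rows
    cols = list(heatmap.x_bins) + extra_cols
    M = np.zeros((len(rows), len(cols)))
    kw = dict(mapq_min=filters.mapq_min, mapq_max=filters.mapq_max,
              ann_required=filters.ann_required())
    nvr, nvc = len(heatmap.y_bins), len(heatmap.x_bins)
    M[:nvr, :nvc] = heatmap.values
    for yi, rb in enumerate(rows):
        ylo, yhi = _bin_units(rb, res)
        for xi, cb in enumerate(cols):
            if yi < nvr and xi < nvc:
                continue
            xlo, xhi = _bin_units(cb, res)
            M[yi, xi] = iidx.count(cb.contig, rb.contig, (xlo, ylo), (xhi, yhi),
                                   mode=filters.multimapper_mode, **kw)
    bias, corrected = ic_partial(M, visible_rows=np.arange(nvr),
                                 visible_cols=np.arange(nvc),
                                 max_iter=max_iter, tol=tol)
    return Heatmap(heatmap.x_bins, heatmap.y_bins, corrected,
                   provenance=dict(heatmap.provenance, norm="ic", ic_samples=n_samples))


# ---------------------------------------------------------------------------
# distance-dependent decay


class DDDProfile:
    """Per contig pair: signed diagonal distance (index units) -> expected count."""

    def __init__(self, bin_w_units, bin_h_units, trim):
        self.bin_w = bin_w_units
        self.bin_h = bin_h_units
        self.trim = trim
        self.expected: dict[tuple[str, str, int], float] = {}

    def get(self, cx, cy, dist):
        return self.expected.get((cx, cy, dist))


def trimmed_mean(values, trim_pct):
    """Mean after dropping the top and bottom ``trim_pct`` percent of values."""
    if not 0 <= trim_pct < 50:
        raise ValueError("trim percentile must be in [0, 50)")
    v = np.sort(np.asarray(values, dtype=float))
    k = int(len(v) * trim_pct / 100)
    core = v[k : len(v) - k] if len(v) > 2 * k else v
    return float(core.mean())


def ddd_profile(iidx, heatmap: Heatmap, n_samples=None, trim_pct=10.0,
                filters=None, seed=0) -> DDDProfile:
    """Expected counts per signed diagonal distance, from sampled bins.

    For every distance present in the view (distance of a bin = x start -
    y start, in index units, per contig pair; the sign separates the two
    sides of the diagonal), ``n_samples`` bins of the same size are placed
    at that distance, evenly spaced parallel to the diagonal with a
    seeded phase, and their counts averaged after percentile trimming.
    """
    from .query import _bin_units

    filters = filters or FilterSettings()
    if n_samples is None:
        n_samples = DEFAULT_SAMPLES["ddd"]
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    res = iidx.config.base_resolution
    rng = np.random.default_rng(seed)
    bw = max(b.width for b in heatmap.x_bins) // res
    bh = max(b.width for b in heatmap.y_bins) // res
    prof = DDDProfile(bw, bh, trim_pct)
    kw = dict(mapq_min=filters.mapq_min, mapq_max=filters.mapq_max,
              ann_required=filters.ann_required())
    dists = set()
    for yb in heatmap.y_bins:
        for xb in heatmap.x_bins:
            dists.add((xb.contig, yb.contig, _bin_units(xb, res)[0] - _bin_units(yb, res)[0]))
    for cx, cy, dist in sorted(dists):
        nx = -(-iidx.genome.lengths[cx] // res)
        ny = -(-iidx.genome.lengths[cy] // res)
        # valid x starts t with bins [t, t+bw-1] x [t-dist, t-dist+bh-1] in range
        t_lo = max(0, dist)
        t_hi = min(nx - bw, ny - bh + dist)
        if t_hi < t_lo:
            continue  # distance beyond the contig pair: expected undefined
        avail = t_hi - t_lo + 1
        n = min(n_samples, avail)
        phase = float(rng.random())
        ts = np.unique(((np.arange(n) + phase) * avail / n).astype(int) + t_lo)
        counts = [
            iidx.count(cx, cy, (int(t), int(t - dist)),
                       (int(t) + bw - 1, int(t - dist) + bh - 1),
                       mode=filters.multimapper_mode, **kw)
            for t in ts
        ]
        prof.expected[(cx, cy, dist)] = trimmed_mean(counts, trim_pct)
    return prof


def ddd_normalize(heatmap: Heatmap, profile: DDDProfile) -> Heatmap:
    """Divide each bin by the expected count at its diagonal distance."""
    from .query import _bin_units

    vals = np.full(heatmap.values.shape, np.nan)
    res = heatmap.provenance.get("base_resolution", 1)
    for yi, yb in enumerate(heatmap.y_bins):
        ylo = yb.start // res
        for xi, xb in enumerate(heatmap.x_bins):
            xlo = xb.start // res
            exp = profile.get(xb.contig, yb.contig, xlo - ylo)
            if exp:
                vals[yi, xi] = heatmap.values[yi, xi] / exp
    return Heatmap(heatmap.x_bins, heatmap.y_bins, vals,
                   provenance=dict(heatmap.provenance, norm="ddd"))


# ---------------------------------------------------------------------------
# Associated Slices


def max_bin_count(iidx, contigs, viewpoint=None, target_bp=1000, filters=None,
                  rna_axis="y"):
    """Maximal count over target-size bins, by heap-ordered halving.

    Whole contigs are queried first; the region with the highest count is
    repeatedly popped, halved (at base-resolution-aligned midpoints) and
    re-queried, until the popped region is at most ``target_bp`` wide.
    Counts are monotone under region refinement, so the first such pop is
    the exact maximum over the halving tree's leaf bins.  ``viewpoint``
    optionally fixes the other (RNA) axis to a (contig, start, end) span.
    """
    filters = filters or FilterSettings()
    if not contigs:
        raise ValueError("empty contig set")
    res = iidx.config.base_resolution
    if target_bp < res:
        raise ValueError("target bin size below the base resolution")
    kw = dict(mapq_min=filters.mapq_min, mapq_max=filters.mapq_max,
              ann_required=filters.ann_required())

    def count(contig, s_bp, e_bp):
        lo, hi = s_bp // res, (e_bp - 1) // res
        if viewpoint is None:
            n = 0
            for other in contigs:
                no = -(-iidx.genome.lengths[other] // res)
                if rna_axis == "y":
                    n += iidx.count(contig, other, (lo, 0), (hi, no - 1),
                                    mode=filters.multimapper_mode, **kw)
                else:
                    n += iidx.count(other, contig, (0, lo), (no - 1, hi),
                                    mode=filters.multimapper_mode, **kw)
            return n
        vc, vs, ve = viewpoint
        vlo, vhi = vs // res, (ve - 1) // res
        if rna_axis == "y":
            return iidx.count(contig, vc, (lo, vlo), (hi, vhi),
                              mode=filters.multimapper_mode, **kw)
        return iidx.count(vc, contig, (vlo, lo), (vhi, hi),
                          mode=filters.multimapper_mode, **kw)

    heap = []
    tie = 0
    for c in contigs:
        e = iidx.genome.lengths[c]
        heapq.heappush(heap, (-count(c, 0, e), tie, c, 0, e))
        tie += 1
    while heap:
        negn, _, c, s, e = heapq.heappop(heap)
        if e - s <= target_bp:
            return (c, s, e), -negn
        half = -(-((e - s) // 2) // res) * res
        mid = min(s + max(half, res), e)
        for lo, hi in ((s, mid), (mid, e)):
            if hi > lo:
                heapq.heappush(heap, (-count(c, lo, hi), tie, c, lo, hi))
                tie += 1
    raise AssertionError("heap exhausted")


def find_chromatin_associated(iidx, gene_type, n_samples, rna_per_kbp_threshold,
                              max_dna_threshold, dna_cmp="ge", rna_axis="y",
                              filters=None, target_bp=None):
    """Call chromatin-associated gene bodies from a gene-body subsample.

    Every ``ceil(G / n_samples)``-th gene (in sorted order) is evaluated:
    average RNA reads per kbp (total reads with RNA in the gene body,
    divided by the assembly size in kbp) and the maximal DNA reads of the
    gene's RNA in a ``target_bp``-binned genome (via :func:`max_bin_count`).
    A gene is associated when the RNA average reaches
    ``rna_per_kbp_threshold`` and the DNA maximum compares to
    ``max_dna_threshold`` as ``dna_cmp`` (">=" or "<=") requires.
    """
    filters = filters or FilterSettings()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if dna_cmp not in ("ge", "le"):
        raise ValueError("dna_cmp must be 'ge' or 'le'")
    if iidx.annotations is None or gene_type not in iidx.annotations.types:
        return []
    if target_bp is None:
        # 1 kbp DNA binning unless the index is coarser than that
        target_bp = max(1000, iidx.config.base_resolution)
    df = iidx.annotations.frame(gene_type)
    if df.empty:
        return []
    step = -(-len(df) // n_samples)
    genome_kbp = iidx.genome.total_length / 1000.0
    res = iidx.config.base_resolution
    kw = dict(mapq_min=filters.mapq_min, mapq_max=filters.mapq_max,
              ann_required=filters.ann_required())
    calls = []
    for i in range(0, len(df), step):
        g = df.iloc[i]
        glo, ghi = int(g.start) // res, int(g.end) // res
        tot = 0
        for other in iidx.genome.names:
            no = -(-iidx.genome.lengths[other] // res)
            if rna_axis == "y":
                tot += iidx.count(other, g.contig, (0, glo), (no - 1, ghi),
                                  mode=filters.multimapper_mode, **kw)
            else:
                tot += iidx.count(g.contig, other, (glo, 0), (ghi, no - 1),
                                  mode=filters.multimapper_mode, **kw)
        avg = tot / genome_kbp
        _, mx = max_bin_count(
            iidx, iidx.genome.names,
            viewpoint=(g.contig, int(g.start), int(g.end) + 1),
            target_bp=target_bp, filters=filters, rna_axis=rna_axis,
        )
        dna_ok = mx >= max_dna_threshold if dna_cmp == "ge" else mx <= max_dna_threshold
        calls.append(ChromAssocCall(
            g["name"], g.contig, int(g.start), int(g.end), avg, int(mx),
            bool(avg >= rna_per_kbp_threshold and dna_ok),
        ))
    return calls


def assoc_slices_normalize(heatmap: Heatmap, calls, iidx, rna_axis="y",
                           filters=None) -> Heatmap:
    """Divide each bin by the trans coverage of associated gene bodies.

    For every visible RNA slice the divisor is the summed count of
    interactions linking the slice to any chromatin-associated gene body
    on a *different* contig (cis contacts are excluded); slices with a
    zero divisor are masked.
    """
    from .query import _bin_units

    filters = filters or FilterSettings()
    bodies = [c for c in calls if c.is_associated]
    if not bodies:
        raise ValueError("no chromatin-associated gene bodies")
    res = iidx.config.base_resolution
    kw = dict(mapq_min=filters.mapq_min, mapq_max=filters.mapq_max,
              ann_required=filters.ann_required())
    slices = heatmap.y_bins if rna_axis == "y" else heatmap.x_bins
    div = np.zeros(len(slices))
    for si, sl in enumerate(slices):
        slo, shi = _bin_units(sl, res)
        for b in bodies:
            if b.contig == sl.contig:
                continue  # trans only
            blo, bhi = b.start // res, b.end // res
            if rna_axis == "y":
                div[si] += iidx.count(b.contig, sl.contig, (blo, slo), (bhi, shi),
                                      mode=filters.multimapper_mode, **kw)
            else:
                div[si] += iidx.count(sl.contig, b.contig, (slo, blo), (shi, bhi),
                                      mode=filters.multimapper_mode, **kw)
    vals = np.full(heatmap.values.shape, np.nan)
    for si in range(len(slices)):
        if div[si] > 0:
            if rna_axis == "y":
                vals[si, :] = heatmap.values[si, :] / div[si]
            else:
                vals[:, si] = heatmap.values[:, si] / div[si]
    return Heatmap(heatmap.x_bins, heatmap.y_bins, vals,
                   provenance=dict(heatmap.provenance, norm="assoc"))


# ---------------------------------------------------------------------------
# Binomial test


def sample_rows(view_y, bin_h, genome: Genome, n_samples: int, seed=0):
    """Evenly spaced sample-row starts above and below a view (seeded phase)."""
    rng = np.random.default_rng(seed)
    total = genome.total_length
    out = []
    halves = ((0, view_y[0], n_samples - n_samples // 2), (view_y[1], total, n_samples // 2))
    for lo, hi, want in halves:
        avail = (hi - lo) // bin_h if bin_h else 0
        n = min(want, avail)
        if n <= 0:
            continue
        phase = float(rng.random())
        ks = np.unique(((np.arange(n) + phase) * avail / n).astype(int))
        out.extend(int(lo + k * bin_h) for k in ks)
    return sorted(set(out))


def binomial_normalize(values, col_widths, alpha=0.05, sample_values=None,
                       row_totals=None, sample_row_totals=None, total_width=None):
    """Binomial-test significance scores for a count matrix.

    The RNA of row ``r`` produced ``N_r`` interactions genome-wide; under
    the uniform null a bin in column ``j`` receives
    ``Binomial(N_r, p_j)`` counts with ``p_j`` the column's width fraction
    of ``total_width`` (the genome-wide span).  ``row_totals`` supplies
    the genome-wide ``N_r`` (one prefix query per row suffices even for a
    partial view); by default the visible row sums are used and
    ``total_width`` is the summed column width.  Upper-tail p-values are
    BH-corrected jointly over the visible bins and the ``sample_values``
    rows — the samples widen the testing family toward the full-matrix
    one but are not reported.  Returns ``(-log10(q)`` with
    non-significant bins masked, q-value matrix)``.
    """
    V = np.asarray(values, dtype=np.int64)
    w = np.asarray(col_widths, dtype=float)
    p = w / (total_width if total_width else w.sum())
    blocks = [(V, row_totals)]
    if sample_values is not None and len(sample_values):
        blocks.append((np.asarray(sample_values, dtype=np.int64), sample_row_totals))
    pvals = []
    for block, totals in blocks:
        if totals is None:
            N = block.sum(axis=1, keepdims=True)
        else:
            N = np.asarray(totals, dtype=np.int64).reshape(-1, 1)
        pv = stats.binom.sf(block - 1, N, p[None, :])
        pv[N[:, 0] == 0] = 1.0
        pvals.append(pv)
    flat = np.concatenate([pv.ravel() for pv in pvals])
    rej, qvals, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    nvis = V.size
    q = qvals[:nvis].reshape(V.shape)
    sig = rej[:nvis].reshape(V.shape)
    scores = np.where(sig, -np.log10(np.maximum(q, 1e-300)), np.nan)
    return scores, q


def binomial_normalized_heatmap(iidx, heatmap: Heatmap, filters=None,
                                n_samples=None, alpha=0.05, seed=0) -> Heatmap:
    """Binomial-test normalization of a visible heatmap with sampled rows."""
    from .query import _bin_units

    filters = filters or FilterSettings()
    if n_samples is None:
        n_samples = DEFAULT_SAMPLES["binom"]
    genome = iidx.genome
    res = iidx.config.base_resolution
    bh = max(b.width for b in heatmap.y_bins)
    ylo = genome.global_start(heatmap.y_bins[0].contig) + heatmap.y_bins[0].start
    yhi = genome.global_start(heatmap.y_bins[-1].contig) + heatmap.y_bins[-1].end
    starts = sample_rows((ylo, yhi), bh, genome, n_samples, seed)
    extra = _strip_bins(starts, bh, genome)
    kw = dict(mapq_min=filters.mapq_min, mapq_max=filters.mapq_max,
              ann_required=filters.ann_required())
    def row_total(rb):
        rlo, rhi = _bin_units(rb, res)
        tot = 0
        for other in genome.names:
            no = -(-genome.lengths[other] // res)
            tot += iidx.count(other, rb.contig, (0, rlo), (no - 1, rhi),
                              mode=filters.multimapper_mode, **kw)
        return tot

    S = np.zeros((len(extra), len(heatmap.x_bins)), dtype=np.int64)
    for ri, rb in enumerate(extra):
        rlo, rhi = _bin_units(rb, res)
        for xi, cb in enumerate(heatmap.x_bins):
            xlo, xhi = _bin_units(cb, res)
            S[ri, xi] = iidx.count(cb.contig, rb.contig, (xlo, rlo), (xhi, rhi),
                                   mode=filters.multimapper_mode, **kw)
    widths = [b.width for b in heatmap.x_bins]
    totals = [row_total(rb) for rb in heatmap.y_bins]
    sample_totals = [row_total(rb) for rb in extra]
    scores, q = binomial_normalize(heatmap.values, widths, alpha, S,
                                   row_totals=totals, sample_row_totals=sample_totals,
                                   total_width=genome.total_length)
    return Heatmap(heatmap.x_bins, heatmap.y_bins, scores,
                   provenance=dict(heatmap.provenance, norm="binom", alpha=alpha,
                                   binom_samples=n_samples))
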