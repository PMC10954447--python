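"""Windowed-deviation evaluation of sampling-based normalization.

The partial-matrix normalizations approximate their full-matrix
counterparts through sampling.  To quantify the approximation error, a
full binned matrix is subdivided into evenly sized diagonal windows; each
window is normalized separately (with ``n_samples`` out-of-window
samples), the windows are concatenated, and the result is compared with
the same matrix normalized in its entirety.  The reported *mean
deviation* is the mean absolute difference of bin values after each
normalized matrix has been rescaled to unit mean over the compared bins,
so matrices on arbitrary output scales are comparable.  With enough
samples the deviation approaches zero (the Binomial test approaches it
more slowly: its windowed column span never equals the global one).

Everything here operates on plain matrices; binning a simulated dataset
into such a matrix is equivalent to unfiltered index queries (asserted by
the end-to-end oracle tests), which keeps many-replicate experiments fast.
"""

from __future__ import annotations

import math

import numpy as np

from .norm import binomial_normalize, ic_partial, trimmed_mean

__all__ = ["windowed_deviation", "matrix_from_records"]


def matrix_from_records(records, genome, bin_bp):
    """Bin interactions (first candidate locus per partner) into a dense matrix."""
    n = -(-genome.total_length // bin_bp)
    M = np.zeros((n, n))
    for it in records:
        cx, px = it.loci_x[0]
        cy, py = it.loci_y[0]
        x = (genome.global_start(cx) + px) // bin_bp
        y = (genome.global_start(cy) + py) // bin_bp
        M[y, x] += 1
    return M


def _windows(n, w):
    return [(a, min(a + w, n)) for a in range(0, n, w)]


def _even_sample(rng, lo, hi, n):
    """n evenly spaced integers in [lo, hi) with a random phase; deduplicated."""
    avail = hi - lo
    if avail <= 0 or n <= 0:
        return np.empty(0, dtype=int)
    n = min(n, avail)
    phase = float(rng.random())
    return np.unique(((np.arange(n) + phase) * avail / n).astype(int) + lo)


def _ring_rows(rng, a, b, n, total):
    """Sample strip indices above and below window [a, b): up to 2 per ring."""
    rows = []
    for i in range(1, n + 1):
        r_top = math.ceil(i * a / (n + 1))
        if r_top >= 1 and a - r_top >= 0:
            rows.append(a - r_top)
        r_bot = math.ceil(i * (total - b) / (n + 1))
        if r_bot >= 1 and b - 1 + r_bot < total:
            rows.append(b - 1 + r_bot)
    return np.unique(rows).astype(int)


def _deviation(windowed, global_, windows):
    sel = np.zeros(global_.shape, dtype=bool)
    for a, b in windows:
        sel[a:b, a:b] = True
    ok = sel & np.isfinite(windowed) & np.isfinite(global_)
    w = windowed[ok]
    g = global_[ok]
    if w.size == 0 or abs(w.mean()) < 1e-300 or abs(g.mean()) < 1e-300:
        return float("nan")
    return float(np.abs(w / w.mean() - g / g.mean()).mean())


def _ic(M, n_samples, windows, rng, tol, max_iter):
    _, global_ = ic_partial(M, tol=tol, max_iter=max_iter)
    out = np.full(M.shape, np.nan)
    n = M.shape[0]
    for a, b in windows:
        rows = _ring_rows(rng, a, b, n_samples, n)
        idx = np.concatenate([np.arange(a, b), rows]).astype(int)
        sub = M[np.ix_(idx, idx)]
        try:
            _, corr = ic_partial(sub, visible_rows=np.arange(b - a),
                                 visible_cols=np.arange(b - a),
                                 tol=tol, max_iter=max_iter)
        except ValueError:
            continue
        out[a:b, a:b] = corr
    return out, global_


def _ddd(M, n_samples, windows, rng, trim):
    n = M.shape[0]

    def diag_vals(d):
        return np.diagonal(M, offset=d)

    global_exp = {}
    out_g = np.full(M.shape, np.nan)
    for d in range(-(n - 1), n):
        v = diag_vals(d)
        global_exp[d] = trimmed_mean(v, trim)
    r, c = np.indices(M.shape)
    exp_g = np.vectorize(lambda d: global_exp[d])(c - r)
    with np.errstate(divide="ignore", invalid="ignore"):
        out_g = np.where(exp_g > 0, M / exp_g, np.nan)

    out_w = np.full(M.shape, np.nan)
    for a, b in windows:
        for d in range(-(b - a) + 1, b - a):
            v = diag_vals(d)
            ks = _even_sample(rng, 0, len(v), n_samples)
            exp = trimmed_mean(v[ks], trim)
            rows = np.arange(max(a, a - d), b)
            rows = rows[(rows + d >= a) & (rows + d < b)]
            if exp > 0:
                out_w[rows, rows + d] = M[rows, rows + d] / exp
    return out_w, out_g


def _assoc_calls(M, gene_bins, contig_of, rna_thr, dna_thr, dna_cmp, sel=None):
    assoc = []
    idx = range(len(gene_bins)) if sel is None else sel
    for gi in idx:
        lo, hi = gene_bins[gi]
        rows = M[lo:hi, :]
        avg = rows.sum() / M.shape[1]
        mx = rows.sum(axis=0).max()
        ok = mx >= dna_thr if dna_cmp == "ge" else mx <= dna_thr
        if avg >= rna_thr and ok:
            assoc.append(gi)
    return assoc


def _assoc(M, n_samples, windows, rng, gene_bins, contig_of, rna_thr, dna_thr, dna_cmp):
    def normalized(assoc):
        div = np.zeros(M.shape[0])
        for gi in assoc:
            lo, hi = gene_bins[gi]
            for r in range(M.shape[0]):
                if contig_of[r] == contig_of[lo]:
                    continue  # trans only
                div[r] += M[r, lo:hi].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(div[:, None] > 0, M / div[:, None], np.nan)

    out_g = normalized(_assoc_calls(M, gene_bins, contig_of, rna_thr, dna_thr, dna_cmp))
    step = -(-len(gene_bins) // max(1, n_samples))
    phase = int(rng.integers(0, step)) if step > 1 else 0
    sel = list(range(phase, len(gene_bins), step))
    out_w = np.full(M.shape, np.nan)
    sub = normalized(_assoc_calls(M, gene_bins, contig_of, rna_thr, dna_thr, dna_cmp, sel))
    for a, b in windows:
        out_w[a:b, a:b] = sub[a:b, a:b]
    return out_w, out_g


def _binom(M, n_samples, windows, rng, alpha):
    n = M.shape[0]
    full_totals = M.sum(axis=1).astype(np.int64)

    def qscore(values, totals, sample_values=None, sample_totals=None):
        _, q = binomial_normalize(
            values, np.ones(values.shape[1]), alpha, sample_values,
            row_totals=totals, sample_row_totals=sample_totals, total_width=n,
        )
        return -np.log10(np.maximum(q, 1e-300))

    out_g = qscore(M.astype(np.int64), full_totals)
    out_w = np.full(M.shape, np.nan)
    for a, b in windows:
        outside = np.concatenate([np.arange(0, a), np.arange(b, n)])
        rows = _even_sample(rng, 0, len(outside), n_samples)
        S = M[outside[rows]][:, a:b].astype(np.int64) if len(rows) else None
        St = full_totals[outside[rows]] if len(rows) else None
        out_w[a:b, a:b] = qscore(M[a:b, a:b].astype(np.int64),
                                 full_totals[a:b], S, St)
    return out_w, out_g


def windowed_deviation(matrix, window_bp, bin_bp, n_samples, normalization,
                       seed=0, trim_pct=10.0, alpha=0.05, tol=1e-5, max_iter=200,
                       gene_bins=None, contig_of=None,
                       rna_thr=None, dna_thr=None, dna_cmp="ge"):
    """Mean deviation between windowed and global normalization.

    ``matrix`` is a full square binned matrix at ``bin_bp`` resolution;
    windows are ``window_bp // bin_bp`` bins wide, tiled along the
    diagonal.  ``normalization`` is one of ``ic``, ``ddd``, ``assoc``,
    ``binom``; the Associated-Slices variant additionally needs
    ``gene_bins`` (bin ranges of gene bodies), ``contig_of`` (contig label
    per bin) and the two association thresholds.  Deterministic for a
    given seed (the seed sets the phase of all even-spaced sampling).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    w = window_bp // bin_bp
    if w < 1 or window_bp % bin_bp:
        raise ValueError("window size must be a positive multiple of the bin size")
    windows = _windows(M.shape[0], w)
    rng = np.random.default_rng(seed)
    if normalization == "ic":
        out_w, out_g = _ic(M, n_samples, windows, rng, tol, max_iter)
    elif normalization == "ddd":
        out_w, out_g = _ddd(M, n_samples, windows, rng, trim_pct)
    elif normalization == "assoc":
        if gene_bins is None or contig_of is None or rna_thr is None or dna_thr is None:
            raise ValueError("assoc needs gene_bins, contig_of and both thresholds")
        out_w, out_g = _assoc(M, n_samples, windows, rng, gene_bins, contig_of,
                              rna_thr, dna_thr, dna_cmp)
    elif normalization == "binom":
        out_w, out_g = _binom(M, n_samples, windows, rng, alpha)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return _deviation(out_w, out_g, windows)
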