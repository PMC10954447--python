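"""Views, bin grids, heatmaps and virtual 4C.

A :class:`View` describes a rectangular query region on genomic or
annotation coordinates together with a display budget
(``target_bin_count`` total bins, kept roughly constant across zoom
levels: zooming out grows the bins, not their number).  Bin grids restart
at every contig boundary, so a bin never spans two contigs and the last
bin of a contig may be truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .build import InteractomeIndex
from .genome import AnnotationSet, Genome

__all__ = [
    "View",
    "FilterSettings",
    "Bin",
    "Heatmap",
    "make_axis_bins",
    "make_bins",
    "annotation_to_genomic",
    "query_heatmap",
    "virtual_4c",
    "compare",
]


@dataclass(frozen=True)
class Bin:
    """One axis bin: a single-contig bp span, optionally a run of annotations."""

    contig: str
    start: int  # bp, inclusive
    end: int  # bp, exclusive
    annotations: tuple[str, ...] = ()

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class View:
    """Query region: per-axis span lists plus a total bin budget.

    ``x_region``/``y_region`` are lists of (contig, start bp, end bp)
    half-open spans.  ``coordinate_mode`` per axis is ``"genomic"`` or
    ``("annotation", type)``; in annotation mode each bin covers a fixed
    number of consecutive annotations instead of a fixed bp span.
    """

    x_region: list[tuple[str, int, int]]
    y_region: list[tuple[str, int, int]]
    target_bin_count: int = 2500
    x_mode: object = "genomic"
    y_mode: object = "genomic"

    def __post_init__(self):
        if self.target_bin_count < 1:
            raise ValueError("target_bin_count must be >= 1")

    @property
    def bins_per_axis(self) -> int:
        return max(1, math.isqrt(self.target_bin_count))


@dataclass
class FilterSettings:
    mapq_min: int = 0
    mapq_max: int = 255
    multimapper_mode: str = "enclosed"  # enclosed | overlap | count-all
    annotation_filter_x: tuple[str, int] | None = None  # (type, required flag)
    annotation_filter_y: tuple[str, int] | None = None

    def __post_init__(self):
        if not 0 <= self.mapq_min <= self.mapq_max <= 255:
            raise ValueError("need 0 <= mapq_min <= mapq_max <= 255")
        if self.multimapper_mode not in ("enclosed", "overlap", "count-all"):
            raise ValueError(f"unknown multimapper mode {self.multimapper_mode!r}")

    def ann_required(self):
        req = {}
        if self.annotation_filter_x:
            req[(self.annotation_filter_x[0], "x")] = self.annotation_filter_x[1]
        if self.annotation_filter_y:
            req[(self.annotation_filter_y[0], "y")] = self.annotation_filter_y[1]
        return req


@dataclass
class Heatmap:
    x_bins: list[Bin]
    y_bins: list[Bin]
    values: np.ndarray  # shape (len(y_bins), len(x_bins))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.shape != (len(self.y_bins), len(self.x_bins)):
            raise ValueError("heatmap shape does not match bin lists")

    @property
    def mass(self) -> float:
        return float(np.nansum(self.values))


def make_axis_bins(region, target, base_resolution, mode="genomic", annotations=None):
    """Bin one axis.

    Genomic mode: bin size is the smallest multiple of the base
    resolution giving at most ``target`` bins over the region; span
    starts are snapped down to the base resolution and bins are truncated
    at span (contig) ends.  Annotation mode: each bin covers
    ``ceil(A / target)`` consecutive annotations of the requested type
    within the region; empty bins cannot arise.
    """
    if mode == "genomic":
        total = 0
        spans = []
        for contig, s, e in region:
            s = (s // base_resolution) * base_resolution
            if e <= s:
                raise ValueError(f"empty span on {contig}")
            spans.append((contig, s, e))
            total += e - s
        size = base_resolution * max(1, -(-total // (target * base_resolution)))
        bins = []
        for contig, s, e in spans:
            pos = s
            while pos < e:
                bins.append(Bin(contig, pos, min(pos + size, e)))
                pos += size
        return bins
    ann_type = mode[1]
    if annotations is None:
        raise ValueError("annotation-mode bins need an AnnotationSet")
    df = annotations.frame(ann_type)
    rows = []
    for contig, s, e in region:
        sub = df[(df.contig == contig) & (df.end >= s) & (df.start < e)]
        rows.extend(sub.itertuples(index=False))
    if not rows:
        return []
    per_bin = -(-len(rows) // target)
    bins = []
    for i in range(0, len(rows), per_bin):
        chunk = rows[i : i + per_bin]
        # a bin spanning a contig break is split (one bin per contig)
        j = 0
        while j < len(chunk):
            k = j
            while k < len(chunk) and chunk[k].contig == chunk[j].contig:
                k += 1
            part = chunk[j:k]
            bins.append(
                Bin(
                    part[0].contig,
                    int(part[0].start),
                    int(max(a.end for a in part)) + 1,
                    tuple(a.name for a in part),
                )
            )
            j = k
    return bins


def make_bins(view: View, genome: Genome, annotations=None, base_resolution=1):
    t = view.bins_per_axis
    xb = make_axis_bins(view.x_region, t, base_resolution, view.x_mode, annotations)
    yb = make_axis_bins(view.y_region, t, base_resolution, view.y_mode, annotations)
    return xb, yb


def annotation_to_genomic(bin_: Bin):
    """Genomic range of an annotation bin plus the implied overlap filter.

    The range runs from the start of the first to the end of the last
    annotation in the bin; because it also covers the void space between
    the annotations, any query over it must require overlap flag 1 on
    this axis to exclude interactions from the gaps.
    """
    if not bin_.annotations:
        raise ValueError("bin contains no annotations")
    return (bin_.contig, bin_.start, bin_.end), 1


def _bin_units(bin_: Bin, res):
    """Inclusive index-unit bounds of a bp bin."""
    return bin_.start // res, (bin_.end - 1) // res


def _bin_filters(filters: FilterSettings, xbin=None, ybin=None, x_mode="genomic", y_mode="genomic"):
    req = filters.ann_required()
    if x_mode != "genomic" and xbin is not None:
        req[(x_mode[1], "x")] = 1
    if y_mode != "genomic" and ybin is not None:
        req[(y_mode[1], "y")] = 1
    return dict(mapq_min=filters.mapq_min, mapq_max=filters.mapq_max, ann_required=req)


def query_heatmap(iidx: InteractomeIndex, view: View, filters: FilterSettings | None = None) -> Heatmap:
    """Count interactions per bin with on-the-fly filtering.

    Multimapper handling per bin: ``enclosed`` counts a stored rectangle
    only when the bin fully contains it (widths are filtered first, so a
    rectangle larger than the bin can never sneak in); ``overlap`` and the
    diagnostic alias ``count-all`` count a rectangle once for every bin it
    touches.
    """
    filters = filters or FilterSettings()
    res = iidx.config.base_resolution
    xb, yb = make_bins(view, iidx.genome, iidx.annotations, res)
    values = np.zeros((len(yb), len(xb)), dtype=np.int64)
    for yi, byin in enumerate(yb):
        ylo, yhi = _bin_units(byin, res)
        for xi, bxin in enumerate(xb):
            xlo, xhi = _bin_units(bxin, res)
            kw = _bin_filters(filters, bxin, byin, view.x_mode, view.y_mode)
            values[yi, xi] = iidx.count(
                bxin.contig, byin.contig, (xlo, ylo), (xhi, yhi),
                mode=filters.multimapper_mode, **kw,
            )
    return Heatmap(
        xb, yb, values,
        provenance={
            "filters": vars(filters).copy(),
            "x_mode": str(view.x_mode),
            "y_mode": str(view.y_mode),
            "base_resolution": res,
        },
    )


def virtual_4c(iidx, viewpoint, opposite_bins, filters=None, viewpoint_axis="y"):
    """1-D track: filtered counts between a fixed viewpoint and each bin.

    ``viewpoint`` is a list of (contig, start bp, end bp) spans; thanks to
    prefix sums one query per (viewpoint span, bin) suffices no matter how
    wide the viewpoint is.
    """
    filters = filters or FilterSettings()
    res = iidx.config.base_resolution
    track = np.zeros(len(opposite_bins), dtype=np.int64)
    kw = dict(mapq_min=filters.mapq_min, mapq_max=filters.mapq_max,
              ann_required=filters.ann_required())
    for i, b in enumerate(opposite_bins):
        blo, bhi = _bin_units(b, res)
        for vc, vs, ve in viewpoint:
            if ve <= vs:
                continue
            vlo, vhi = vs // res, (ve - 1) // res
            if viewpoint_axis == "y":
                cx, cy, low, high = b.contig, vc, (blo, vlo), (bhi, vhi)
            else:
                cx, cy, low, high = vc, b.contig, (vlo, blo), (vhi, bhi)
            track[i] += iidx.count(cx, cy, low, high,
                                   mode=filters.multimapper_mode, **kw)
    return track


def compare(a: Heatmap, b: Heatmap, op="subtract", pseudocount=1.0) -> Heatmap:
    """Compare two heatmaps on identical bin grids by subtraction or division."""
    if a.x_bins != b.x_bins or a.y_bins != b.y_bins:
        raise ValueError("heatmaps have different bin grids")
    if op == "subtract":
        vals = a.values.astype(float) - b.values.astype(float)
    elif op == "divide":
        vals = (a.values + pseudocount) / (b.values + pseudocount)
    else:
        raise ValueError(f"unknown comparison op {op!r}")
    return Heatmap(a.x_bins, a.y_bins, vals, provenance={"op": op, "pseudocount": pseudocount})
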