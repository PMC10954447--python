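"""Sparse N-dimensional prefix-sum index with constant-time range counts.

The index answers "how many records lie at or before coordinate ``q`` in
every dimension" with a fixed number of array reads, independent of the
number of records, the extent of the data space, or the size of the
queried range.  Range counts over axis-aligned hyperrectangles follow by
inclusion-exclusion over the ``2**d`` corners of the range; corners with a
``-1`` component are known to be zero and cost nothing.

Storage is a regular grid of boxes.  Each box keeps

* an *internal* prefix grid over the records inside the box, stored only
  at the box's non-empty slices (one sorted coordinate list plus one
  dense lookup table per dimension), and
* one *overlay* prefix grid per dimension ``j`` counting the records that
  precede the box in dimension ``j`` (and start at or after the box in
  all dimensions before ``j``).  The overlays partition every record that
  lies before a query point but outside the box, so a prefix query is the
  internal cell plus one cell of each overlay: ``d + 1`` array reads.

Two record kinds are supported.  A *point* index stores integer
coordinates with multiplicities.  A *rectangle* index stores axis-aligned
hyperrectangles (used for multimapping interactions, where a read pair is
represented by the smallest rectangle enclosing all candidate loci).
Fully-enclosed and overlapping rectangles are counted by signed
combinations of prefix counts that bound, per spatial dimension, either
the rectangle's start or its end (never both at once), restricted by its
width.  The rectangle store therefore shards into ``2**k`` point
sub-indices — one per start/end choice combination — each over only
``k`` corner coordinates, ``k`` widths and the filter dimensions, which
keeps the sparse cross product per box small (see
:meth:`RectangleIndex.count_enclosed`).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataSpace",
    "PointRecord",
    "RectRecord",
    "PrefixSumIndex",
    "RectangleIndex",
    "build_point_index",
    "build_rect_index",
    "rect_space",
    "predict_index_size",
    "choose_box_count",
    "save_index",
    "load_index",
]

_PSUM_BYTES = 8  # one 64-bit prefix sum per sparse cell
_LUT_BYTES = 4  # one 32-bit entry per lookup-table slot


@dataclass(frozen=True)
class DataSpace:
    """Integer coordinate space of an index.

    ``extent[j]`` is the exclusive upper bound of coordinates in dimension
    ``j``.  ``inverted[j]`` marks dimensions whose stored coordinate is
    ``extent - 1 - value`` in natural units (e.g. mapping quality, stored
    inverted so that high-quality records sit at the bottom of the axis and
    quality filters touch only the cheap top face of the queried cube).
    The flag is metadata: the index stores whatever coordinates it is
    handed, and :meth:`PrefixSumIndex.range_count_filtered` refuses filter
    bounds on non-inverted axes.
    """

    extent: tuple[int, ...]
    inverted: tuple[bool, ...] = ()

    def __post_init__(self):
        if len(self.extent) < 1:
            raise ValueError("a data space needs at least one dimension")
        if any(e < 1 for e in self.extent):
            raise ValueError(f"extents must be >= 1, got {self.extent}")
        if not self.inverted:
            object.__setattr__(self, "inverted", (False,) * len(self.extent))
        elif len(self.inverted) != len(self.extent):
            raise ValueError("inverted flags must match dimension count")

    @property
    def d(self) -> int:
        return len(self.extent)


@dataclass(frozen=True)
class PointRecord:
    coord: tuple[int, ...]
    multiplicity: int = 1


@dataclass(frozen=True)
class RectRecord:
    """Axis-aligned hyperrectangle with inclusive corners.

    ``low``/``high`` are the spatial corners; ``filter_coord`` holds extra
    non-spatial coordinates (inverted mapping quality, annotation-overlap
    flags, ...).  A degenerate rectangle with ``low == high`` behaves
    exactly like a point.
    """

    low: tuple[int, ...]
    high: tuple[int, ...]
    filter_coord: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.low) != len(self.high):
            raise ValueError("low/high dimension mismatch")
        if any(l > h for l, h in zip(self.low, self.high)):
            raise ValueError(f"rectangle corners out of order: {self.low} > {self.high}")


class _Overlay:
    """Prefix grid (over all dims but one) of the records preceding a box."""

    __slots__ = ("dims", "lists", "luts", "grid")

    def __init__(self, dims, lists, luts, grid):
        self.dims = dims  # dimensions the grid spans (all but the skipped one)
        self.lists = lists
        self.luts = luts
        self.grid = grid


class _Box:
    __slots__ = ("grid_pos", "start", "width", "lists", "luts", "psum", "overlays")

    def __init__(self, grid_pos, start, width, lists, luts, psum, overlays):
        self.grid_pos = grid_pos
        self.start = start
        self.width = width
        self.lists = lists  # per dim: sentinel + sorted non-empty slice coords
        self.luts = luts  # per dim: local coord -> index of largest list entry <= coord
        self.psum = psum  # internal prefix grid, int64
        self.overlays = overlays

    def cell_count(self) -> int:
        n = int(self.psum.size)
        for ov in self.overlays:
            n += int(ov.grid.size)
        return n

    def lut_entries(self) -> int:
        n = sum(int(l.size) for l in self.luts)
        for ov in self.overlays:
            n += sum(int(l.size) for l in ov.luts)
        return n


def _as_coord_array(records, d):
    """Normalise point records to (coords[n, d] int64, mult[n] int64)."""
    if isinstance(records, np.ndarray):
        coords = np.asarray(records, dtype=np.int64)
        if coords.ndim != 2 or coords.shape[1] != d:
            raise ValueError(f"expected an (n, {d}) coordinate array")
        return coords, np.ones(len(coords), dtype=np.int64)
    coords = np.empty((len(records), d), dtype=np.int64)
    mult = np.empty(len(records), dtype=np.int64)
    for i, rec in enumerate(records):
        if isinstance(rec, PointRecord):
            c, m = rec.coord, rec.multiplicity
        else:
            c, m = rec, 1
        if len(c) != d:
            raise ValueError(f"record {i} has {len(c)} coordinates, expected {d}")
        if m < 1:
            raise ValueError("multiplicity must be >= 1")
        coords[i] = c
        mult[i] = m
    return coords, mult


def _check_bounds(coords, space):
    if len(coords) == 0:
        return
    ext = np.asarray(space.extent, dtype=np.int64)
    bad = np.where((coords < 0) | (coords >= ext))
    if len(bad[0]):
        i, j = int(bad[0][0]), int(bad[1][0])
        raise ValueError(
            f"coordinate {int(coords[i, j])} of record {i} outside "
            f"[0, {space.extent[j]}) in dimension {j}"
        )


def _box_widths(space, boxes_per_dim):
    if isinstance(boxes_per_dim, int):
        boxes_per_dim = (boxes_per_dim,) * space.d
    boxes_per_dim = tuple(int(b) for b in boxes_per_dim)
    if len(boxes_per_dim) != space.d or any(b < 1 for b in boxes_per_dim):
        raise ValueError(f"invalid boxes_per_dim {boxes_per_dim} for d={space.d}")
    widths = tuple(-(-e // b) for e, b in zip(space.extent, boxes_per_dim))
    return boxes_per_dim, widths


def _box_layout(coords, mult, space, widths, grid_pos, sizes_only=False):
    """Internal + overlay layout of one box.

    Shared between the builder and the size predictor so that exhaustive
    probing reproduces the materialised size exactly.
    Returns (lists, psum, overlays) or, with ``sizes_only``,
    (cell_count, lut_entries).
    """
    d = space.d
    start = [g * w for g, w in zip(grid_pos, widths)]
    end = [min(s + w, e) for s, w, e in zip(start, widths, space.extent)]
    in_range = [(coords[:, j] >= start[j]) & (coords[:, j] < end[j]) for j in range(d)]

    cells = 0
    lut_n = 0

    # internal grid: records strictly inside the box
    inside = np.ones(len(coords), dtype=bool)
    for j in range(d):
        inside &= in_range[j]
    lists = []
    for j in range(d):
        uniq = np.unique(coords[inside, j]) if inside.any() else np.empty(0, np.int64)
        lists.append(np.concatenate(([start[j] - 1], uniq)))
    shape = tuple(len(l) for l in lists)
    if sizes_only:
        cells += int(np.prod(shape))
        lut_n += sum(end[j] - start[j] for j in range(d))
        psum = None
        luts = None
    else:
        psum = np.zeros(shape, dtype=np.int64)
        if inside.any():
            idx = tuple(
                np.searchsorted(lists[j], coords[inside, j], side="left") for j in range(d)
            )
            np.add.at(psum, idx, mult[inside])
            for ax in range(d):
                np.cumsum(psum, axis=ax, out=psum)
        luts = [
            np.searchsorted(lists[j], np.arange(start[j], end[j]), side="right").astype(
                np.int32
            )
            - 1
            for j in range(d)
        ]

    # overlay grids: records preceding the box, partitioned by the first
    # dimension in which they fall before the box start
    overlays = []
    before = [coords[:, j] < start[j] for j in range(d)]
    for j in range(d):
        sel = before[j].copy()
        for i in range(j):
            sel &= in_range[i]
        dims = tuple(i for i in range(d) if i != j)
        pts = coords[sel]
        pmult = mult[sel]
        olists = []
        for i in dims:
            if len(pts):
                vals = pts[:, i]
                uniq = np.unique(vals[(vals >= start[i]) & (vals < end[i])])
            else:
                uniq = np.empty(0, np.int64)
            olists.append(np.concatenate(([start[i] - 1], uniq)))
        oshape = tuple(len(l) for l in olists)
        if sizes_only:
            cells += int(np.prod(oshape))
            lut_n += sum(end[i] - start[i] for i in dims)
            continue
        if not dims:  # 1-D index: the overlay is a single scalar count
            grid = np.zeros((), dtype=np.int64)
            grid[()] = int(pmult.sum())
        else:
            grid = np.zeros(oshape, dtype=np.int64)
            if len(pts):
                keep = np.ones(len(pts), dtype=bool)
                idx = []
                for k, i in enumerate(dims):
                    pos = np.searchsorted(olists[k], pts[:, i], side="left")
                    keep &= pos < len(olists[k])
                    idx.append(np.minimum(pos, len(olists[k]) - 1))
                if keep.any():
                    np.add.at(grid, tuple(ix[keep] for ix in idx), pmult[keep])
                    for ax in range(len(dims)):
                        np.cumsum(grid, axis=ax, out=grid)
        oluts = [
            np.searchsorted(olists[k], np.arange(start[i], end[i]), side="right").astype(
                np.int32
            )
            - 1
            for k, i in enumerate(dims)
        ]
        overlays.append(_Overlay(dims, olists, oluts, grid))

    if sizes_only:
        return cells, lut_n
    return _Box(grid_pos, tuple(start), tuple(widths), lists, luts, psum, overlays)


class PrefixSumIndex:
    """Grid-of-boxes sparse prefix-sum store over integer coordinates.

    Build with :func:`build_point_index` or :func:`build_rect_index`.
    ``lookups`` counts prefix evaluations that actually touched
    materialised data (queries with a ``-1`` component are free); it is
    exposed so tests can assert the constant-lookup contract.
    """

    def __init__(self, space, boxes_per_dim, boxes, total, kind="point"):
        self.space = space
        self.boxes_per_dim = boxes_per_dim
        self.box_widths = tuple(-(-e // b) for e, b in zip(space.extent, boxes_per_dim))
        self.boxes = boxes  # dict grid_pos -> _Box
        self.total = int(total)
        self.kind = kind
        self.lookups = 0

    # -- prefix machinery -------------------------------------------------

    def reset_lookups(self):
        self.lookups = 0

    def prefix_at(self, coord) -> int:
        """Number of records at or before ``coord`` in every dimension.

        Components equal to ``-1`` mean "before everything" and short-circuit
        to 0 without touching the index; components ``>= extent`` are clamped
        to ``extent - 1``.
        """
        d = self.space.d
        if len(coord) != d:
            raise ValueError(f"expected {d} coordinates, got {len(coord)}")
        q = []
        for j, c in enumerate(coord):
            c = int(c)
            if c <= -1:
                if c < -1:
                    raise ValueError(f"coordinate {c} below -1 in dimension {j}")
                return 0
            q.append(min(c, self.space.extent[j] - 1))
        g = tuple(c // w for c, w in zip(q, self.box_widths))
        box = self.boxes[g]
        self.lookups += 1
        local = [c - s for c, s in zip(q, box.start)]
        total = int(box.psum[tuple(box.luts[j][local[j]] for j in range(d))])
        for ov in box.overlays:
            total += int(ov.grid[tuple(ov.luts[k][local[i]] for k, i in enumerate(ov.dims))])
        return total

    def range_count(self, low, high) -> int:
        """Records with ``low <= coord <= high`` componentwise (inclusive).

        Computed by inclusion-exclusion over the corners of the range; only
        dimensions with ``low > 0`` contribute a second (subtracted) corner,
        so a query with ``m`` two-sided dimensions costs ``2**m`` prefix
        evaluations, bounded by ``2**d``.
        """
        d = self.space.d
        low = [int(x) for x in low]
        high = [int(x) for x in high]
        if len(low) != d or len(high) != d:
            raise ValueError("bound dimension mismatch")
        if any(l > h for l, h in zip(low, high)):
            return 0
        two_sided = [j for j in range(d) if low[j] > 0]
        total = 0
        for picks in itertools.product((False, True), repeat=len(two_sided)):
            corner = list(high)
            sign = 1
            for pick, j in zip(picks, two_sided):
                if pick:
                    corner[j] = low[j] - 1
                    sign = -sign
            total += sign * self.prefix_at(corner)
        return total

    def range_count_filtered(self, low_spatial, high_spatial, filter_bounds) -> int:
        """Range count with per-filter-dimension maxima on inverted axes.

        ``filter_bounds[i]`` is the largest kept *stored* coordinate of the
        ``i``-th trailing dimension, which must have been built inverted: the
        filter then only moves the top face of the queried hyperrectangle and
        the bottom face stays below all data (prefix 0, no lookup).
        """
        k = len(low_spatial)
        m = self.space.d - k
        if len(filter_bounds) != m:
            raise ValueError(f"expected {m} filter bounds, got {len(filter_bounds)}")
        for i in range(m):
            if not self.space.inverted[k + i]:
                raise ValueError(
                    f"dimension {k + i} was not built inverted; "
                    "a one-sided filter bound is only meaningful on an inverted axis"
                )
        low = list(low_spatial) + [0] * m
        high = list(high_spatial) + [int(b) for b in filter_bounds]
        return self.range_count(low, high)

    # -- sizing ------------------------------------------------------------

    def materialized_size_bytes(self) -> int:
        cells = sum(b.cell_count() for b in self.boxes.values())
        luts = sum(b.lut_entries() for b in self.boxes.values())
        return cells * _PSUM_BYTES + luts * _LUT_BYTES


def build_point_index(points, space, boxes_per_dim=1) -> PrefixSumIndex:
    """Build a point index; ``points`` may be PointRecords, tuples, or an (n, d) array."""
    coords, mult = _as_coord_array(points, space.d)
    _check_bounds(coords, space)
    return _build(coords, mult, space, boxes_per_dim, kind="point")


def rect_space(axis_extents, filter_extents=(), filter_inverted=()) -> DataSpace:
    """Data space of one rectangle sub-index: corner coords, widths, filters."""
    ext = tuple(axis_extents) * 2 + tuple(filter_extents)
    inv = (False,) * (2 * len(axis_extents)) + tuple(
        filter_inverted or (False,) * len(filter_extents)
    )
    return DataSpace(ext, inv)


def _rect_corner_coords(rects, k, space, use_end):
    """Coordinates of one sub-index: per dim the start or end corner, then widths, filters."""
    coords = np.empty((len(rects), space.d), dtype=np.int64)
    m = space.d - 2 * k
    for i, r in enumerate(rects):
        if len(r.low) != k:
            raise ValueError(f"rectangle {i} has {len(r.low)} spatial dims, expected {k}")
        if len(r.filter_coord) != m:
            raise ValueError(
                f"rectangle {i} has {len(r.filter_coord)} filter coords, expected {m}"
            )
        for j in range(k):
            coords[i, j] = r.high[j] if use_end[j] else r.low[j]
            coords[i, k + j] = r.high[j] - r.low[j]
        for j in range(m):
            coords[i, 2 * k + j] = r.filter_coord[j]
    return coords


class RectangleIndex:
    """Prefix-sum store of axis-aligned hyperrectangles.

    Enclosed and overlapping counting expand into ``2**k`` signed terms,
    each bounding per spatial dimension *either* the rectangle start or
    its end, together with the widths and filter coordinates.  One point
    sub-index per start/end combination answers its terms; sharding this
    way keeps each sub-index at ``2k + m`` dimensions instead of
    ``3k + m``, which is what makes the sparse storage tractable.
    """

    kind = "rect"

    def __init__(self, space, k_spatial, subs, total):
        self.space = space  # space of each sub-index
        self.k_spatial = k_spatial
        self.subs = subs  # dict use_end tuple -> PrefixSumIndex
        self.total = int(total)

    @property
    def lookups(self) -> int:
        return sum(s.lookups for s in self.subs.values())

    def reset_lookups(self):
        for s in self.subs.values():
            s.reset_lookups()

    def _filter_ranges(self, filter_ranges):
        k = self.k_spatial
        m = self.space.d - 2 * k
        if filter_ranges is None:
            filter_ranges = [(0, self.space.extent[2 * k + i] - 1) for i in range(m)]
        if len(filter_ranges) != m:
            raise ValueError(f"expected {m} filter ranges, got {len(filter_ranges)}")
        return filter_ranges

    def _signed_terms(self, bin_low, bin_high, filter_ranges, widths_bounded):
        k = self.k_spatial
        a = [int(x) for x in bin_low]
        b = [int(x) for x in bin_high]
        if len(a) != k or len(b) != k:
            raise ValueError(f"expected {k} spatial bounds")
        if any(x > y for x, y in zip(a, b)):
            return 0
        ext = self.space.extent
        total = 0
        for use_end in itertools.product((False, True), repeat=k):
            low = [0] * self.space.d
            high = [0] * self.space.d
            sign = 1
            for j in range(k):
                if use_end[j]:
                    # enclosed: I[end_j <= b_j]; overlap: -I[end_j <= a_j - 1]
                    high[j] = b[j] if widths_bounded else a[j] - 1
                    if not widths_bounded:
                        sign = -sign
                else:
                    # enclosed: -I[start_j <= a_j - 1]; overlap: I[start_j <= b_j]
                    high[j] = a[j] - 1 if widths_bounded else b[j]
                    if widths_bounded:
                        sign = -sign
                if high[j] < 0:
                    sign = 0
                    break
                high[k + j] = b[j] - a[j] if widths_bounded else ext[k + j] - 1
            if sign == 0:
                continue
            for i, (fl, fh) in enumerate(filter_ranges):
                low[2 * k + i] = int(fl)
                high[2 * k + i] = int(fh)
            total += sign * self.subs[use_end].range_count(low, high)
        return total

    def count_enclosed(self, bin_low, bin_high, filter_ranges=None) -> int:
        """Rectangles fully enclosed by the bin (rescued multimappers).

        With rectangles wider than the bin removed through the width
        dimensions, the enclosure indicator factorises per dimension as
        ``I[end_j <= b_j] - I[start_j <= a_j - 1]``; the expanded product
        is a sum of ``2**k`` signed prefix-style range counts.
        """
        filter_ranges = self._filter_ranges(filter_ranges)
        return self._signed_terms(bin_low, bin_high, filter_ranges, widths_bounded=True)

    def count_overlapping(self, bin_low, bin_high, filter_ranges=None) -> int:
        """Rectangles intersecting the bin in every spatial dimension.

        ``intersect_j = I[start_j <= b_j] - I[end_j <= a_j - 1]``; no width
        filter applies, rectangles larger than the bin still overlap it.
        """
        filter_ranges = self._filter_ranges(filter_ranges)
        # note the sign convention: the negative term is the end-bounded one
        return self._signed_terms(bin_low, bin_high, filter_ranges, widths_bounded=False)

    def materialized_size_bytes(self) -> int:
        return sum(s.materialized_size_bytes() for s in self.subs.values())


def build_rect_index(rects, space, boxes_per_dim=1, k_spatial=None) -> RectangleIndex:
    """Build a rectangle index over a space produced by :func:`rect_space`."""
    if k_spatial is None:
        if rects:
            k_spatial = len(rects[0].low)
        else:
            raise ValueError("k_spatial required for an empty rectangle index")
    rects = list(rects)
    subs = {}
    for use_end in itertools.product((False, True), repeat=k_spatial):
        coords = _rect_corner_coords(rects, k_spatial, space, use_end)
        _check_bounds(coords, space)
        mult = np.ones(len(coords), dtype=np.int64)
        subs[use_end] = _build(coords, mult, space, boxes_per_dim, kind="point")
    total = len(rects)
    return RectangleIndex(space, k_spatial, subs, total)


def _build(coords, mult, space, boxes_per_dim, kind):
    boxes_per_dim, widths = _box_widths(space, boxes_per_dim)
    boxes = {}
    for g in itertools.product(*(range(b) for b in boxes_per_dim)):
        boxes[g] = _box_layout(coords, mult, space, widths, g)
    return PrefixSumIndex(space, boxes_per_dim, boxes, int(mult.sum()), kind=kind)


# -- size prediction -------------------------------------------------------


def _coord_sets(points_or_rects, space):
    """Record coordinate arrays: one per sub-index for rectangles, else one."""
    if isinstance(points_or_rects, np.ndarray):
        return [np.asarray(points_or_rects, dtype=np.int64)]
    points_or_rects = list(points_or_rects)
    if points_or_rects and isinstance(points_or_rects[0], RectRecord):
        k = len(points_or_rects[0].low)
        return [
            _rect_corner_coords(points_or_rects, k, space, use_end)
            for use_end in itertools.product((False, True), repeat=k)
        ]
    coords, _ = _as_coord_array(points_or_rects, space.d)
    return [coords]


def predict_index_size(
    points_or_rects, space, boxes_per_dim, n_probes=1000, seed=0
) -> float:
    """Estimate the materialised index size in bytes by probing random boxes.

    ``n_probes`` boxes are drawn without replacement (seeded); their sparse
    cell counts and lookup-table sizes are computed exactly and the mean is
    extrapolated to the full grid (8 bytes per prefix cell, 4 per LUT
    entry).  Probing every box reproduces the built index's
    ``materialized_size_bytes`` exactly.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    coord_sets = _coord_sets(points_or_rects, space)
    boxes_per_dim, widths = _box_widths(space, boxes_per_dim)
    all_boxes = list(itertools.product(*(range(b) for b in boxes_per_dim)))
    n_boxes = len(all_boxes)
    if n_probes >= n_boxes:
        probed = all_boxes
    else:
        rng = np.random.default_rng(seed)
        probed = [all_boxes[i] for i in rng.choice(n_boxes, size=n_probes, replace=False)]
    total = 0.0
    for coords in coord_sets:
        mult = np.ones(len(coords), dtype=np.int64)
        cells = 0
        luts = 0
        for g in probed:
            c, l = _box_layout(coords, mult, space, widths, g, sizes_only=True)
            cells += c
            luts += l
        total += (cells * _PSUM_BYTES + luts * _LUT_BYTES) * (n_boxes / len(probed))
    return total


def choose_box_count(
    points_or_rects, space, candidate_counts, n_probes=1000, seed=0
):
    """Candidate grid minimising the predicted index size (ties: fewer boxes)."""
    if not candidate_counts:
        raise ValueError("candidate list must be non-empty")
    best = None
    for cand in candidate_counts:
        b, _ = _box_widths(space, cand)
        size = predict_index_size(points_or_rects, space, cand, n_probes, seed)
        key = (size, int(np.prod(b)))
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]


# -- persistence ------------------------------------------------------------


def save_index(index, h5group):
    """Write a point or rectangle index into an open h5py group (bit-exact round trip)."""
    if isinstance(index, RectangleIndex):
        header = {
            "version": 1,
            "kind": "rect",
            "extent": list(index.space.extent),
            "inverted": [bool(x) for x in index.space.inverted],
            "k_spatial": index.k_spatial,
            "total": index.total,
        }
        h5group.attrs["header"] = json.dumps(header)
        for use_end, sub in index.subs.items():
            name = "sub_" + "".join("e" if u else "s" for u in use_end)
            save_index(sub, h5group.create_group(name))
        return
    header = {
        "version": 1,
        "extent": list(index.space.extent),
        "inverted": [bool(x) for x in index.space.inverted],
        "boxes_per_dim": list(index.boxes_per_dim),
        "total": index.total,
        "kind": index.kind,
    }
    h5group.attrs["header"] = json.dumps(header)
    for g, box in index.boxes.items():
        bg = h5group.create_group("box_" + "_".join(map(str, g)))
        for j, (lst, lut) in enumerate(zip(box.lists, box.luts)):
            bg.create_dataset(f"list{j}", data=lst)
            bg.create_dataset(f"lut{j}", data=lut)
        bg.create_dataset("psum", data=box.psum)
        for ov in box.overlays:
            og = bg.create_group(f"overlay{[j for j in range(index.space.d) if j not in ov.dims][0]}")
            og.attrs["dims"] = list(ov.dims)
            for k, i in enumerate(ov.dims):
                og.create_dataset(f"list{k}", data=ov.lists[k])
                og.create_dataset(f"lut{k}", data=ov.luts[k])
            og.create_dataset("grid", data=ov.grid)


def load_index(h5group):
    header = json.loads(h5group.attrs["header"])
    if header.get("version") != 1:
        raise ValueError(f"unsupported index container version {header.get('version')!r}")
    space = DataSpace(tuple(header["extent"]), tuple(header["inverted"]))
    if header["kind"] == "rect":
        subs = {}
        for name, sg in h5group.items():
            if not name.startswith("sub_"):
                continue
            use_end = tuple(ch == "e" for ch in name[4:])
            subs[use_end] = load_index(sg)
        return RectangleIndex(space, header["k_spatial"], subs, header["total"])
    boxes_per_dim = tuple(header["boxes_per_dim"])
    widths = tuple(-(-e // b) for e, b in zip(space.extent, boxes_per_dim))
    boxes = {}
    for name, bg in h5group.items():
        if not name.startswith("box_"):
            continue
        g = tuple(int(x) for x in name[4:].split("_"))
        start = tuple(gi * w for gi, w in zip(g, widths))
        lists = [bg[f"list{j}"][...] for j in range(space.d)]
        luts = [bg[f"lut{j}"][...] for j in range(space.d)]
        psum = bg["psum"][...]
        overlays = []
        for j in range(space.d):
            og = bg.get(f"overlay{j}")
            if og is None:
                continue
            dims = tuple(int(x) for x in og.attrs["dims"])
            olists = [og[f"list{k}"][...] for k in range(len(dims))]
            oluts = [og[f"lut{k}"][...] for k in range(len(dims))]
            overlays.append(_Overlay(dims, olists, oluts, og["grid"][...]))
        overlays.sort(key=lambda ov: [j for j in range(space.d) if j not in ov.dims][0])
        boxes[g] = _Box(g, start, widths, lists, luts, psum, overlays)
    return PrefixSumIndex(space, boxes_per_dim, boxes, header["total"], kind=header["kind"])
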