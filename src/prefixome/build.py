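"""Building the interactome index from parsed inputs.

Each contig pair with at least one interaction becomes its own rectangle
index (storing contig pairs separately keeps dense cis pairs from
inflating the sparse space of trans pairs).  The per-pair dimensions are

* x start/end, y start/end and per-axis widths, all in units of the base
  resolution (bp // base_resolution),
* inverted effective mapping quality (``255 - min(mapq_x, mapq_y)``), so
  high-quality interactions sit at the bottom of the axis and quality
  filters only move the cheap top face of the queried hyperrectangle,
* two 0/1 dimensions per enabled annotation type (x overlap, y overlap);
  a multimapper overlaps a type if any of its candidate loci does.

Disabled filters place every record at coordinate 0 in the corresponding
dimension, which shrinks the index without changing unfiltered results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import sparse
from .genome import AnnotationSet, Genome

__all__ = ["IndexConfig", "InteractomeIndex", "build_interactome_index"]

MAPQ_EXTENT = 256


@dataclass
class IndexConfig:
    """Index build parameters.

    ``base_resolution`` is the constant dividend applied to genomic
    positions before indexing; it is the finest queryable bin size in bp.
    """

    base_resolution: int = 1000
    mapq_filter: bool = True
    annotation_types: tuple[str, ...] = ()
    boxes_per_axis: int = 1

    def __post_init__(self):
        if self.base_resolution < 1:
            raise ValueError("base_resolution must be >= 1")
        self.annotation_types = tuple(self.annotation_types)


def _axis_extent(genome, contig, res):
    return -(-genome.lengths[contig] // res)


class InteractomeIndex:
    """Per-contig-pair rectangle indices plus build metadata."""

    def __init__(self, genome: Genome, config: IndexConfig, annotations: AnnotationSet | None):
        self.genome = genome
        self.config = config
        self.annotations = annotations
        self.pairs: dict[tuple[str, str], sparse.PrefixSumIndex] = {}

    @property
    def total(self) -> int:
        """Number of stored (interaction, contig-pair) incidences."""
        return sum(ix.total for ix in self.pairs.values())

    def pair_space(self, cx, cy) -> sparse.DataSpace:
        res = self.config.base_resolution
        nx = _axis_extent(self.genome, cx, res)
        ny = _axis_extent(self.genome, cy, res)
        n_ann = len(self.config.annotation_types)
        return sparse.rect_space(
            (nx, ny),
            (MAPQ_EXTENT,) + (2,) * (2 * n_ann),
            (True,) + (False,) * (2 * n_ann),
        )

    def filter_ranges(self, mapq_min=0, mapq_max=255, ann_required=None):
        """Stored-coordinate ranges for the non-spatial dimensions.

        ``ann_required`` maps (annotation type, axis 'x'|'y') -> required
        overlap flag (0 or 1); unconstrained annotation dimensions span
        [0, 1].  The mapq range is expressed on the inverted axis.
        """
        if mapq_min > mapq_max:
            raise ValueError("mapq_min > mapq_max")
        ranges = [(255 - int(mapq_max), 255 - int(mapq_min))]
        ann_required = ann_required or {}
        for t in self.config.annotation_types:
            for axis in ("x", "y"):
                req = ann_required.get((t, axis))
                ranges.append((0, 1) if req is None else (int(req), int(req)))
        return ranges

    def count(self, cx, cy, low, high, mode="enclosed", **filter_kw):
        """Filtered count for an inclusive bin (index units) on one contig pair."""
        ix = self.pairs.get((cx, cy))
        if ix is None:
            return 0
        franges = self.filter_ranges(**filter_kw)
        if mode == "enclosed":
            return ix.count_enclosed(low, high, franges)
        if mode in ("overlap", "count-all"):
            return ix.count_overlapping(low, high, franges)
        raise ValueError(f"unknown multimapper mode {mode!r}")

    # -- persistence --------------------------------------------------------

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "prefixome-index"
            f.attrs["version"] = 1
            f.attrs["genome"] = json.dumps(
                {"names": self.genome.names, "lengths": self.genome.lengths}
            )
            f.attrs["config"] = json.dumps(
                {
                    "base_resolution": self.config.base_resolution,
                    "mapq_filter": self.config.mapq_filter,
                    "annotation_types": list(self.config.annotation_types),
                    "boxes_per_axis": self.config.boxes_per_axis,
                }
            )
            if self.annotations is not None:
                ann = {
                    t: self.annotations.frame(t).to_dict("records")
                    for t in self.annotations.types
                }
                f.attrs["annotations"] = json.dumps(ann)
            for (cx, cy), ix in self.pairs.items():
                sparse.save_index(ix, f.create_group(f"pair/{cx}\t{cy}"))

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "prefixome-index":
                raise ValueError(f"{path}: not a prefixome index container")
            if f.attrs.get("version") != 1:
                raise ValueError(f"{path}: unsupported container version")
            g = json.loads(f.attrs["genome"])
            genome = Genome(g["names"], g["lengths"])
            c = json.loads(f.attrs["config"])
            config = IndexConfig(
                base_resolution=c["base_resolution"],
                mapq_filter=c["mapq_filter"],
                annotation_types=tuple(c["annotation_types"]),
                boxes_per_axis=c["boxes_per_axis"],
            )
            annotations = None
            if "annotations" in f.attrs:
                annotations = AnnotationSet(genome)
                for t, rows in json.loads(f.attrs["annotations"]).items():
                    for r in rows:
                        annotations.add(t, r["contig"], r["start"], r["end"], r["name"])
            out = cls(genome, config, annotations)
            if "pair" in f:
                for key, grp in f["pair"].items():
                    cx, cy = key.split("\t")
                    out.pairs[(cx, cy)] = sparse.load_index(grp)
        return out


def derive_rect_records(interactions, annotations, config):
    """Per-contig-pair rectangle records with derived filter coordinates."""
    res = config.base_resolution
    for t in config.annotation_types:
        if annotations is None or t not in annotations.types:
            raise ValueError(f"annotation type {t!r} enabled but not provided")
    per_pair: dict[tuple[str, str], list[sparse.RectRecord]] = {}
    for it in interactions:
        mq = it.effective_mapq if config.mapq_filter else 0
        ann_flags = []
        for t in config.annotation_types:
            fx = int(any(annotations.overlaps(t, c, p, p) for c, p in it.loci_x))
            fy = int(any(annotations.overlaps(t, c, p, p) for c, p in it.loci_y))
            ann_flags += [fx, fy]
        for (cx, cy), (x0, x1), (y0, y1) in it.contig_pairs():
            rec = sparse.RectRecord(
                (x0 // res, y0 // res),
                (x1 // res, y1 // res),
                (255 - mq, *ann_flags),
            )
            per_pair.setdefault((cx, cy), []).append(rec)
    return per_pair


def build_interactome_index(
    interactions, genome: Genome, annotations: AnnotationSet | None, config: IndexConfig
) -> InteractomeIndex:
    """Derive filter coordinates and build one rectangle index per contig pair."""
    per_pair = derive_rect_records(interactions, annotations, config)
    out = InteractomeIndex(genome, config, annotations)
    for (cx, cy), rects in per_pair.items():
        space = out.pair_space(cx, cy)
        b = config.boxes_per_axis
        boxes = (b, b, 1, 1, 1) + (1,) * (2 * len(config.annotation_types))
        out.pairs[(cx, cy)] = sparse.build_rect_index(rects, space, boxes, k_spatial=2)
    return out
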