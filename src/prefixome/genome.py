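"""Genome tables and genomic annotations.

Internally every interval is 0-based with *inclusive* ends, mirroring the
inclusive-integer convention of the prefix-sum index.  BED input (0-based,
half-open) and GFF3 input (1-based, inclusive) are both converted on read,
so the BED line ``chr1  10  20`` and the GFF3 line with start=11, end=20
denote the same internal interval (10, 19).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = ["Genome", "read_chrom_sizes", "write_chrom_sizes", "AnnotationSet", "read_annotations"]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


@dataclass
class Genome:
    """Ordered contigs with lengths in bp and cumulative offsets."""

    names: list[str]
    lengths: dict[str, int]
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate contig names")
        off = 0
        self.offsets = {}
        for n in self.names:
            if self.lengths[n] < 1:
                raise ValueError(f"contig {n} has non-positive length")
            self.offsets[n] = off
            off += self.lengths[n]
        self.total_length = off

    def __contains__(self, name):
        return name in self.lengths

    def global_start(self, contig: str) -> int:
        return self.offsets[contig]

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Contig and local bp offset of a global (concatenated) position."""
        if not 0 <= global_pos < self.total_length:
            raise ValueError(f"global position {global_pos} outside genome")
        for n in self.names:
            if global_pos < self.offsets[n] + self.lengths[n]:
                return n, global_pos - self.offsets[n]
        raise AssertionError

    def spans(self, gstart: int, gend: int):
        """Split a half-open global bp range into per-contig (contig, start, end) spans."""
        gstart = max(0, gstart)
        gend = min(self.total_length, gend)
        out = []
        for n in self.names:
            s, e = self.offsets[n], self.offsets[n] + self.lengths[n]
            lo, hi = max(gstart, s), min(gend, e)
            if lo < hi:
                out.append((n, lo - s, hi - s))
        return out


def read_chrom_sizes(path) -> Genome:
    """Read a UCSC-style two-column chrom.sizes file (contig, length)."""
    names, lengths = [], {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns")
            name = parts[0]
            if name in lengths:
                raise ValueError(f"{path}:{ln}: duplicate contig {name!r}")
            try:
                length = int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer length {parts[1]!r}") from None
            names.append(name)
            lengths[name] = length
    if not names:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return Genome(names, lengths)


def write_chrom_sizes(genome: Genome, path):
    with open(path, "w") as fh:
        for n in genome.names:
            fh.write(f"{n}\t{genome.lengths[n]}\n")


class AnnotationSet:
    """Per-type sorted annotation arrays plus interval trees for overlap tests."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self._frames: dict[str, pd.DataFrame] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    @property
    def types(self):
        return sorted(self._frames)

    def add(self, ann_type: str, contig: str, start: int, end: int, name: str = "."):
        """Add one annotation (0-based inclusive coordinates)."""
        if start > end:
            raise ValueError(f"annotation {name!r}: start {start} > end {end}")
        if contig not in self.genome:
            logger.warning("skipping annotation %r on unknown contig %r", name, contig)
            return
        rows = self._frames.setdefault(ann_type, [])
        rows.append((contig, int(start), int(end), name))
        self._trees.pop((ann_type, contig), None)

    def frame(self, ann_type: str) -> pd.DataFrame:
        """Sorted array of one annotation type: contig order, then start."""
        rows = self._frames.get(ann_type, [])
        df = pd.DataFrame(rows, columns=["contig", "start", "end", "name"])
        rank = {n: i for i, n in enumerate(self.genome.names)}
        df["_rank"] = df["contig"].map(rank)
        df = df.sort_values(["_rank", "start", "end"], kind="stable").drop(columns="_rank")
        return df.reset_index(drop=True)

    def _tree(self, ann_type, contig):
        key = (ann_type, contig)
        if key not in self._trees:
            t = IntervalTree()
            for c, s, e, _ in self._frames.get(ann_type, []):
                if c == contig:
                    t.addi(s, e + 1)  # tree is half-open
            self._trees[key] = t
        return self._trees[key]

    def overlaps(self, ann_type: str, contig: str, start: int, end: int) -> bool:
        """Does [start, end] (inclusive) overlap any instance of the type?"""
        if ann_type not in self._frames:
            return False
        return self._tree(ann_type, contig).overlaps(start, end + 1)


def read_annotations(path, fmt=None, genome=None, bed_type="annotation") -> AnnotationSet:
    """Read GFF3 or BED into an :class:`AnnotationSet`.

    GFF3 rows are grouped by their feature-type column; a BED file yields a
    single type named ``bed_type``.  Annotations on contigs absent from the
    genome are skipped with a warning; ``start > end`` is an error.
    """
    if genome is None:
        raise ValueError("a Genome is required to validate annotation contigs")
    path = str(path)
    if fmt is None:
        base = path[:-3] if path.endswith(".gz") else path
        fmt = "gff3" if base.endswith((".gff", ".gff3")) else "bed"
    out = AnnotationSet(genome)
    if fmt == "gff3":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=range(9),
            names=["contig", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
            dtype={"contig": str, "type": str},
        )
        for row in df.itertuples(index=False):
            name = "."
            for kv in str(row.attrs).split(";"):
                if kv.startswith(("ID=", "Name=")):
                    name = kv.split("=", 1)[1]
                    break
            # GFF3 is 1-based inclusive
            out.add(row.type, row.contig, int(row.start) - 1, int(row.end) - 1, name)
    elif fmt == "bed":
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
        for row in df.itertuples(index=False):
            name = str(row[3]) if len(row) > 3 else "."
            # BED is 0-based half-open
            out.add(bed_type, str(row[0]), int(row[1]), int(row[2]) - 1, name)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return out
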