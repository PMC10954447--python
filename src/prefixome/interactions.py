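"""Interaction ("pairs"-like) file parsing.

No standard pairs dialect carries candidate-locus lists for multimapping
reads, so the package defines a small TSV dialect (gzip transparent):

    read_id <TAB> loci_x <TAB> mapq_x <TAB> loci_y <TAB> mapq_y

where each ``loci`` field is a semicolon-separated list of
``contig:pos`` or ``contig:pos:strand`` candidate alignments (0-based bp,
5' coordinate) and mapq is an integer 0-255 per partner.  Lines starting
with ``#`` are headers/comments.  Strand is parsed and ignored: no
operation downstream depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Genome, _open_text

__all__ = ["Interaction", "read_interactions", "write_interactions"]

COLUMNS = ("read_id", "loci_x", "mapq_x", "loci_y", "mapq_y")


@dataclass
class Interaction:
    """One read pair with candidate mapping loci per partner.

    ``loci_x``/``loci_y`` are non-empty lists of (contig, position-bp).
    The effective mapping quality of the pair is the lower of the two
    partner qualities; a SAM "unavailable" value of 255 is treated as 0 so
    that it can never pass a quality filter.
    """

    read_id: str
    loci_x: list[tuple[str, int]]
    mapq_x: int
    loci_y: list[tuple[str, int]]
    mapq_y: int

    @property
    def effective_mapq(self) -> int:
        mx = 0 if self.mapq_x == 255 else self.mapq_x
        my = 0 if self.mapq_y == 255 else self.mapq_y
        return min(mx, my)

    def contig_pairs(self):
        """Touched (contig_x, contig_y) pairs with per-pair bounding rectangles.

        A multimapper whose candidate loci span several contigs is
        replicated into each touched contig pair; within one pair the
        rectangle is the smallest one enclosing the pair's loci.
        Yields ((cx, cy), (min_x, max_x), (min_y, max_y)) in bp.
        """
        by_x: dict[str, list[int]] = {}
        for c, p in self.loci_x:
            by_x.setdefault(c, []).append(p)
        by_y: dict[str, list[int]] = {}
        for c, p in self.loci_y:
            by_y.setdefault(c, []).append(p)
        for cx, xs in by_x.items():
            for cy, ys in by_y.items():
                yield (cx, cy), (min(xs), max(xs)), (min(ys), max(ys))


def _parse_loci(field: str, genome: Genome, path, ln):
    loci = []
    for tok in field.split(";"):
        parts = tok.split(":")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: malformed locus {tok!r}")
        contig = parts[0]
        try:
            pos = int(parts[1])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer position in {tok!r}") from None
        if contig not in genome:
            raise ValueError(f"{path}:{ln}: unknown contig {contig!r}")
        if not 0 <= pos < genome.lengths[contig]:
            raise ValueError(
                f"{path}:{ln}: position {pos} beyond contig {contig} "
                f"(length {genome.lengths[contig]})"
            )
        loci.append((contig, pos))
    return loci


def _parse_mapq(field: str, path, ln):
    try:
        q = int(field)
    except ValueError:
        raise ValueError(f"{path}:{ln}: non-integer mapq {field!r}") from None
    if not 0 <= q <= 255:
        raise ValueError(f"{path}:{ln}: mapq {q} outside 0-255")
    return q


def read_interactions(path, genome: Genome):
    """Stream :class:`Interaction` records from an interaction TSV."""
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            yield Interaction(
                read_id=parts[0],
                loci_x=_parse_loci(parts[1], genome, path, ln),
                mapq_x=_parse_mapq(parts[2], path, ln),
                loci_y=_parse_loci(parts[3], genome, path, ln),
                mapq_y=_parse_mapq(parts[4], path, ln),
            )


def write_interactions(interactions, path):
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(COLUMNS) + "\n")
        for it in interactions:
            lx = ";".join(f"{c}:{p}" for c, p in it.loci_x)
            ly = ";".join(f"{c}:{p}" for c, p in it.loci_y)
            fh.write(f"{it.read_id}\t{lx}\t{it.mapq_x}\t{ly}\t{it.mapq_y}\n")
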