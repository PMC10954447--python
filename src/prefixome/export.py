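"""TSV heatmap and bedGraph track export.

Heatmap TSVs carry a provenance header (``#key=value`` lines), then the
bin boundary lines and the matrix rows, so any output can be reproduced
from its own header.  Masked bins are written as ``nan``.
"""

from __future__ import annotations

import numpy as np

from .query import Bin, Heatmap

__all__ = ["write_heatmap_tsv", "read_heatmap_tsv", "write_bedgraph"]


def _fmt_bin(b: Bin) -> str:
    s = f"{b.contig}:{b.start}-{b.end}"
    if b.annotations:
        s += "[" + ",".join(b.annotations) + "]"
    return s


def _parse_bin(tok: str) -> Bin:
    ann = ()
    if tok.endswith("]"):
        tok, rest = tok[:-1].split("[", 1)
        ann = tuple(rest.split(","))
    contig, span = tok.rsplit(":", 1)
    s, e = span.split("-")
    return Bin(contig, int(s), int(e), ann)


def write_heatmap_tsv(hm: Heatmap, path):
    with open(path, "w") as fh:
        for k, v in sorted(hm.provenance.items()):
            fh.write(f"#{k}={v}\n")
        fh.write("#xbins\t" + "\t".join(_fmt_bin(b) for b in hm.x_bins) + "\n")
        fh.write("#ybins\t" + "\t".join(_fmt_bin(b) for b in hm.y_bins) + "\n")
        for row in hm.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_heatmap_tsv(path) -> Heatmap:
    prov = {}
    xb = yb = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#xbins\t"):
                xb = [_parse_bin(t) for t in line.split("\t")[1:]]
            elif line.startswith("#ybins\t"):
                yb = [_parse_bin(t) for t in line.split("\t")[1:]]
            elif line.startswith("#"):
                k, _, v = line[1:].partition("=")
                prov[k] = v
            elif line:
                rows.append([float(t) for t in line.split("\t")])
    if xb is None or yb is None:
        raise ValueError(f"{path}: missing bin boundary header lines")
    return Heatmap(xb, yb, np.array(rows), provenance=prov)


def write_bedgraph(bins, values, path, track_name="track"):
    """Write a 1-D track (virtual 4C, coverage overlay) as bedGraph."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for b, v in zip(bins, values):
            fh.write(f"{b.contig}\t{b.start}\t{b.end}\t{float(v):g}\n")
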