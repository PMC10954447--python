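"""Ploidy correction.

Assemblies often collapse an n-ploid chromosome into a single contig (or
split a heterozygous region into one contig per haplotype), so the contig
count does not match the physical chromosome count and interaction counts
are over- or under-estimated.  The correction makes an n-ploid contig
appear as n *instances* and redistributes counts among instance pairs:

* inter-contig pairs share evenly, ``1 / (n_a * n_b)`` each;
* intra-contig interactions are assumed intra-instance: only diagonal
  instance pairs (A-A, B-B, ...) receive weight, ``1 / n`` each;
* named *groups* of instances spanning contigs (e.g. the A-haplotype
  subtelomeres and core of one chromosome) take precedence: if any
  instance pair of a contig pair is intra-group, only intra-group pairs
  share the weight.

Weights always sum to exactly one, so total heatmap mass is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import yaml

from .query import Bin, Heatmap

__all__ = ["PloidyMap", "read_ploidy", "ploidy_weights", "apply_ploidy"]


@dataclass
class PloidyMap:
    """Contig -> ordered instance names, plus instance groups.

    Contigs absent from ``instances`` are implicitly haploid with a single
    instance named like the contig itself.
    """

    instances: dict[str, list[str]]
    groups: list[set[str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for contig, names in self.instances.items():
            if not names:
                raise ValueError(f"contig {contig!r} has an empty instance list")
            for n in names:
                if n in seen:
                    raise ValueError(f"duplicate instance name {n!r}")
                seen.add(n)
        self.groups = [set(g) for g in self.groups]
        known = seen
        for g in self.groups:
            missing = g - known
            if missing:
                raise ValueError(f"group members {sorted(missing)} are not instances")

    def instances_of(self, contig: str) -> list[str]:
        return self.instances.get(contig, [contig])

    def share_group(self, inst_a: str, inst_b: str) -> bool:
        return any(inst_a in g and inst_b in g for g in self.groups)


def read_ploidy(path) -> PloidyMap:
    """Read a YAML ploidy file: ``contigs: {name: [instances]}; groups: [[...]]``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return PloidyMap(doc.get("contigs", {}), [set(g) for g in doc.get("groups", [])])


def ploidy_weights(contig_a: str, contig_b: str, pmap: PloidyMap):
    """Instance-pair weights for one contig pair; exact fractions summing to 1."""
    insts_a = pmap.instances_of(contig_a)
    insts_b = pmap.instances_of(contig_b)
    if contig_a == contig_b:
        w = Fraction(1, len(insts_a))
        return [((ia, ia), w) for ia in insts_a]
    pairs = [(ia, ib) for ia in insts_a for ib in insts_b]
    intra = [p for p in pairs if pmap.share_group(*p)]
    chosen = intra if intra else pairs
    w = Fraction(1, len(chosen))
    return [(p, w) for p in chosen]


def apply_ploidy(heatmap: Heatmap, pmap: PloidyMap) -> Heatmap:
    """Redistribute a contig-space heatmap onto instance axes.

    Every bin must lie within a single contig (the bin grids produced by
    this package guarantee that).  Each contig-pair block is replicated
    once per instance pair and scaled by its weight; total mass is
    conserved because weights sum to one.
    """

    def expand_axis(bins):
        out_bins, src, contig_of = [], [], []
        for i, b in enumerate(bins):
            for inst in pmap.instances_of(b.contig):
                out_bins.append(Bin(inst, b.start, b.end, b.annotations))
                src.append(i)
                contig_of.append((b.contig, inst))
        return out_bins, src, contig_of

    xb, xsrc, xinst = expand_axis(heatmap.x_bins)
    yb, ysrc, yinst = expand_axis(heatmap.y_bins)
    values = np.zeros((len(yb), len(xb)), dtype=float)
    cache: dict[tuple[str, str], dict] = {}
    for yi, (cy, iy) in enumerate(yinst):
        for xi, (cx, ix) in enumerate(xinst):
            key = (cx, cy)
            if key not in cache:
                cache[key] = {p: float(w) for p, w in ploidy_weights(cx, cy, pmap)}
            w = cache[key].get((ix, iy), 0.0)
            values[yi, xi] = w * heatmap.values[ysrc[yi], xsrc[xi]]
    return Heatmap(xb, yb, values, provenance=dict(heatmap.provenance, ploidy=True))
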