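"""Deterministic synthetic interactome data.

The generator emulates the statistical structure the methods assume
without requiring any sequencing data: cis contacts with a power-law
distance decay ``P(s) ~ (s + 1)**(-gamma)`` (gamma = 1 is Hi-C-like),
uniform trans background, a configurable multimapper fraction whose extra
candidate loci are displaced by a geometric spread, a mapping-quality
distribution with a low-quality mass at 0, gene annotations, and an
optional aneuploidy specification.  Outputs are byte-identical for equal
seeds, and a truth table records every interaction so tests can compare
index queries against direct enumeration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import Genome, write_chrom_sizes
from .interactions import Interaction, write_interactions

__all__ = ["SimConfig", "simulate_interactome", "simulate_null_rna_dna"]


@dataclass
class SimConfig:
    """Synthetic dataset parameters (all randomness flows from ``seed``)."""

    seed: int
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 500_000, "chr2": 300_000, "chr3": 200_000, "chr4": 100_000,
        }
    )
    n_interactions: int = 5000
    cis_fraction: float = 0.7
    gamma: float = 1.0  # distance-decay exponent of cis contacts
    multimapper_fraction: float = 0.15
    multimapper_spread_bp: int = 2000  # geometric mean displacement of extra loci
    multimapper_max_loci: int = 4
    mapq_values: tuple[int, ...] = (0, 1, 10, 30, 60)
    mapq_weights: tuple[float, ...] = (0.15, 0.05, 0.15, 0.25, 0.40)
    n_genes: int = 40
    gene_length_bp: tuple[int, int] = (2000, 10000)  # uniform range
    aneuploidy: dict[str, list[str]] = field(default_factory=dict)
    zygosity_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for frac in (self.cis_fraction, self.multimapper_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if len(self.contig_lengths) < 2 and self.cis_fraction < 1:
            raise ValueError(
                "trans interactions requested but the genome has a single contig"
            )

    @property
    def genome(self) -> Genome:
        return Genome(list(self.contig_lengths), dict(self.contig_lengths))


def _decay_distance(rng, max_dist, gamma):
    """Draw a cis distance with P(s) ~ (s + 1)**(-gamma), truncated."""
    if gamma == 0:
        return int(rng.integers(0, max_dist + 1))
    # inverse-CDF on a discretised power law; gamma == 1 handled via log
    u = rng.random()
    if abs(gamma - 1) < 1e-9:
        return int(np.expm1(u * np.log1p(max_dist)))
    a = 1.0 - gamma
    top = (max_dist + 1.0) ** a
    return int(((u * (top - 1.0) + 1.0) ** (1.0 / a)) - 1.0)


def _simulate_records(config: SimConfig):
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    names = genome.names
    lens = np.array([genome.lengths[n] for n in names], dtype=float)
    pweights = lens / lens.sum()
    mq_w = np.asarray(config.mapq_weights, dtype=float)
    mq_w = mq_w / mq_w.sum()

    records = []
    for i in range(config.n_interactions):
        is_cis = rng.random() < config.cis_fraction
        cx = names[rng.choice(len(names), p=pweights)]
        px = int(rng.integers(0, genome.lengths[cx]))
        if is_cis:
            # draw the distance first, then place the pair inside the contig,
            # so the realised distance distribution is exactly the decay law
            cy = cx
            d = _decay_distance(rng, genome.lengths[cx] - 1, config.gamma)
            t = int(rng.integers(0, genome.lengths[cx] - d))
            px, py = (t, t + d) if rng.random() < 0.5 else (t + d, t)
        else:
            others = [n for n in names if n != cx]
            w = np.array([genome.lengths[n] for n in others], dtype=float)
            cy = others[rng.choice(len(others), p=w / w.sum())]
            py = int(rng.integers(0, genome.lengths[cy]))
        mqx = int(rng.choice(config.mapq_values, p=mq_w))
        mqy = int(rng.choice(config.mapq_values, p=mq_w))
        loci_x = [(cx, px)]
        loci_y = [(cy, py)]
        for loci, contig, mm in ((loci_x, cx, "x"), (loci_y, cy, "y")):
            if rng.random() < config.multimapper_fraction:
                extra = int(rng.integers(1, config.multimapper_max_loci))
                for _ in range(extra):
                    disp = int(rng.geometric(1.0 / config.multimapper_spread_bp))
                    p = loci[0][1] + (disp if rng.random() < 0.5 else -disp)
                    loci.append((contig, int(min(max(p, 0), genome.lengths[contig] - 1))))
                if mm == "x":
                    mqx = 0
                else:
                    mqy = 0
        records.append(Interaction(f"read{i}", loci_x, mqx, loci_y, mqy))
    return records


def _simulate_genes(config: SimConfig, rng):
    genome = config.genome
    names = genome.names
    lens = np.array([genome.lengths[n] for n in names], dtype=float)
    rows = []
    for i in range(config.n_genes):
        c = names[rng.choice(len(names), p=lens / lens.sum())]
        glen = int(rng.integers(config.gene_length_bp[0], config.gene_length_bp[1] + 1))
        glen = min(glen, genome.lengths[c] - 1)
        start = int(rng.integers(0, genome.lengths[c] - glen))
        rows.append((c, start, start + glen - 1, f"gene{i:03d}"))
    return rows


def simulate_interactome(config: SimConfig, out_dir):
    """Write chrom.sizes, interaction TSV, GFF3 genes and a ploidy file.

    Returns a dict of file paths plus ``truth``: a DataFrame with one row
    per (interaction, contig pair) incidence holding the bounding
    rectangle in bp, the effective mapq and per-partner locus counts,
    suitable for brute-force reference binning in tests.
    """
    os.makedirs(out_dir, exist_ok=True)
    genome = config.genome
    records = _simulate_records(config)
    rng = np.random.default_rng(config.seed + 1)
    genes = _simulate_genes(config, rng)

    chrom_path = os.path.join(out_dir, "genome.chrom.sizes")
    write_chrom_sizes(genome, chrom_path)
    inter_path = os.path.join(out_dir, "interactions.tsv")
    write_interactions(records, inter_path)
    gff_path = os.path.join(out_dir, "genes.gff3")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c, s, e, name in genes:  # GFF3 is 1-based inclusive
            fh.write(f"{c}\tsim\tgene\t{s + 1}\t{e + 1}\t.\t+\t.\tID={name}\n")
    ploidy_path = os.path.join(out_dir, "ploidy.yaml")
    with open(ploidy_path, "w") as fh:
        yaml.safe_dump(
            {"contigs": config.aneuploidy, "groups": config.zygosity_groups},
            fh, sort_keys=True,
        )

    truth_rows = []
    for i, it in enumerate(records):
        for (cx, cy), (x0, x1), (y0, y1) in it.contig_pairs():
            truth_rows.append(
                (it.read_id, cx, cy, x0, x1, y0, y1, it.effective_mapq,
                 len(it.loci_x), len(it.loci_y))
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "cx", "cy", "x0", "x1", "y0", "y1",
                 "mapq", "n_loci_x", "n_loci_y"],
    )
    return {
        "chrom_sizes": chrom_path,
        "interactions": inter_path,
        "gff3": gff_path,
        "ploidy": ploidy_path,
        "truth": truth,
        "records": records,
    }


def simulate_null_rna_dna(config: SimConfig, out_path, row_bin_bp=1000,
                          mean_row_total=20.0):
    """Null RNA-DNA interactions: per RNA row, DNA partners uniform genome-wide.

    RNA positions are uniform within their row bin; row totals are Poisson
    with mean ``mean_row_total``.  Under this null every heatmap bin count
    follows ``Binomial(N_row, p_col)``, the calibration target of the
    Binomial-test normalization.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    records = []
    i = 0
    for contig in genome.names:
        n_rows = genome.lengths[contig] // row_bin_bp
        totals = rng.poisson(mean_row_total, size=n_rows)
        for r, total in enumerate(totals):
            for _ in range(int(total)):
                py = int(r * row_bin_bp + rng.integers(0, row_bin_bp))
                gpos = int(rng.integers(0, genome.total_length))
                cx, px = genome.locate(gpos)
                records.append(
                    Interaction(f"null{i}", [(cx, px)], 60, [(contig, py)], 60)
                )
                i += 1
    write_interactions(records, out_path)
    return records
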