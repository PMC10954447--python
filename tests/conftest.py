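import numpy as np
import pytest

from prefixome import (
    AnnotationSet,
    Genome,
    IndexConfig,
    Interaction,
    SimConfig,
    build_interactome_index,
    read_annotations,
    read_chrom_sizes,
    read_interactions,
    simulate_interactome,
)


@pytest.fixture(scope="session")
def small_genome():
    return Genome(["chr1", "chr2"], {"chr1": 100_000, "chr2": 60_000})


@pytest.fixture(scope="session")
def gene_set(small_genome):
    ann = AnnotationSet(small_genome)
    ann.add("gene", "chr1", 10_000, 19_999, "geneA")
    ann.add("gene", "chr1", 60_000, 69_999, "geneB")
    ann.add("gene", "chr2", 5_000, 14_999, "geneC")
    return ann


def make_interactions(genome, n=400, seed=0, multimapper_fraction=0.3):
    """Random interactions with mapq spread and same-contig multimappers."""
    rng = np.random.default_rng(seed)
    names = genome.names
    out = []
    for i in range(n):
        cx, cy = rng.choice(names), rng.choice(names)
        px = int(rng.integers(0, genome.lengths[cx]))
        py = int(rng.integers(0, genome.lengths[cy]))
        mqx = int(rng.choice([0, 5, 30, 60]))
        mqy = int(rng.choice([0, 5, 30, 60]))
        loci_x = [(cx, px)]
        if rng.random() < multimapper_fraction:
            spread = int(rng.integers(1, 20_000))
            loci_x.append((cx, int(min(max(px + spread, 0), genome.lengths[cx] - 1))))
            mqx = 0
        out.append(Interaction(f"r{i}", loci_x, mqx, [(cy, py)], mqy))
    return out


@pytest.fixture(scope="session")
def interactions(small_genome):
    return make_interactions(small_genome)


@pytest.fixture(scope="session")
def iidx(small_genome, gene_set, interactions):
    cfg = IndexConfig(base_resolution=1000, annotation_types=("gene",), boxes_per_axis=4)
    return build_interactome_index(interactions, small_genome, gene_set, cfg)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    cfg = SimConfig(
        seed=11,
        contig_lengths={"chr1": 120_000, "chr2": 90_000, "chr3": 60_000},
        n_interactions=1500,
        n_genes=25,
        aneuploidy={"chr1": ["chr1_A", "chr1_B"]},
    )
    out = simulate_interactome(cfg, tmp_path_factory.mktemp("sim"))
    out["config"] = cfg
    return out


@pytest.fixture(scope="session")
def sim_index(sim_dataset):
    genome = read_chrom_sizes(sim_dataset["chrom_sizes"])
    ann = read_annotations(sim_dataset["gff3"], genome=genome)
    inters = list(read_interactions(sim_dataset["interactions"], genome))
    cfg = IndexConfig(base_resolution=2000, annotation_types=("gene",), boxes_per_axis=4)
    return build_interactome_index(inters, genome, ann, cfg)
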