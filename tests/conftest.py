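"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from beemeth import pipeline, refmodel, simulate
from beemeth.refmodel import Gene, Genome, Transcript


@pytest.fixture(scope="session")
def toy_gene_genome():
    """A 1 kb genome with one plus-strand two-exon gene at known coordinates."""
    rng = np.random.default_rng(123)
    seq = list("".join(rng.choice(list("ACGT"), size=1000, p=[0.3, 0.2, 0.2, 0.3])))
    # canonical GT...AG intron between exons [100,200) and [300,400)
    seq[200], seq[201] = "G", "T"
    seq[298], seq[299] = "A", "G"
    genome = Genome({"chr1": "".join(seq)})
    gene = Gene(
        "g1",
        "chr1",
        "+",
        (Transcript("g1.t1", ((100, 200), (300, 400)), ((100, 200), (300, 400))),),
    )
    return genome, [gene]


@pytest.fixture(scope="session")
def small_sim():
    """100 kb simulated study at modest coverage, reused across tests."""
    cfg = simulate.SimConfig(seed=11, genome_length=100_000, n_genes=10, coverage=12)
    genome, genes = simulate.simulate_genome(cfg)
    index = refmodel.build_region_index(genes, genome, flank=cfg.flank)
    truth = simulate.plant_methylome(genome, genes, cfg, index)
    return cfg, genome, genes, index, truth


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Reads mapped and called for the small simulated study."""
    cfg, genome, genes, index, truth = small_sim
    from beemeth import bsalign, bscall

    reads = simulate.simulate_bs_reads(genome, truth, cfg)
    alignments = bsalign.map_bs_reads(genome, reads)
    pile = bscall.build_pileup(alignments, genome)
    calls = bscall.call_all(pile, genome, bscall.CallModelParams(conv_fail=cfg.conv_fail))
    return dict(
        config=cfg,
        genome=genome,
        genes=genes,
        index=index,
        truth=truth,
        reads=reads,
        alignments=alignments,
        pileup=pile,
        calls=calls,
    )
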