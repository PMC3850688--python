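"""Simulator contracts: determinism, planted rates, channel statistics."""

import numpy as np
import pytest
from scipy import stats

from beemeth import refmodel, simulate
from beemeth.refmodel import CTX_CG, CTX_CHH, Genome, compute_oe, context_code_arrays
from beemeth.simulate import HMC, MC, MethylomeTruth, SimConfig


def _zero_rates():
    return {k: {"5mC": 0.0, "5hmC": 0.0} for k in simulate.ehb_like_rates()}


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=1, genome_length=100_000, n_genes=10)
        g1, genes1 = simulate.simulate_genome(cfg)
        g2, genes2 = simulate.simulate_genome(cfg)
        assert g1["chr1"] == g2["chr1"]
        assert [g.id for g in genes1] == [g.id for g in genes2]
        assert genes1[3].transcripts[0].exons == genes2[3].transcripts[0].exons

    def test_no_genes_degenerate(self):
        cfg = SimConfig(seed=2, genome_length=10_000, n_genes=0)
        genome, genes = simulate.simulate_genome(cfg)
        assert genes == []
        assert len(genome["chr1"]) == 10_000

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError):
            simulate.simulate_genome(SimConfig(seed=3, genome_length=5_000, n_genes=50))

    def test_oe_distribution_is_bimodal(self):
        cfg = SimConfig(seed=4, genome_length=400_000, n_genes=40)
        genome, genes = simulate.simulate_genome(cfg)
        oe = np.array(list(compute_oe(genes, genome).values()))
        low, high = oe[oe < 0.9], oe[oe >= 0.9]
        # two separated modes near the configured targets, half the genes each
        assert len(low) == len(high) == 20
        assert abs(low.mean() - cfg.oe_low) < 0.15
        assert abs(high.mean() - cfg.oe_high) < 0.15

    def test_splice_motifs_are_canonical(self):
        cfg = SimConfig(seed=5, genome_length=100_000, n_genes=10)
        genome, genes = simulate.simulate_genome(cfg)
        seq = genome["chr1"]
        for g in genes:
            for tr in g.transcripts:
                for a, b in tr.introns:
                    if g.strand == "+":
                        assert seq[a : a + 2] == "GT" and seq[b - 2 : b] == "AG"
                    else:
                        assert seq[b - 2 : b] == "AC" and seq[a : a + 2] == "CT"


class TestPlantMethylome:
    def test_all_zero_rates_give_empty_truth(self):
        cfg = SimConfig(seed=6, genome_length=20_000, n_genes=2, rates=_zero_rates())
        genome, genes = simulate.simulate_genome(cfg)
        truth = simulate.plant_methylome(genome, genes, cfg)
        assert len(truth.sites()) == 0

    def test_forced_rate_marks_every_exon_cg(self):
        rates = _zero_rates()
        rates[("Exon", "CG")] = {"5mC": 1.0}
        cfg = SimConfig(seed=7, genome_length=50_000, n_genes=5, rates=rates)
        genome, genes = simulate.simulate_genome(cfg)
        index = refmodel.build_region_index(genes, genome)
        truth = simulate.plant_methylome(genome, genes, cfg, index)
        plus, minus = context_code_arrays(genome, "chr1")
        for strand, ctx in (("+", plus), ("-", minus)):
            pos = np.flatnonzero(ctx == CTX_CG)
            pos = pos[index.mask("chr1", "Exon", pos)]
            assert (truth.state_array("chr1", strand)[pos] == MC).all()

    def test_planted_fraction_within_binomial_bounds(self):
        rate = 0.0626
        rates = _zero_rates()
        rates[("Intergenic", "CHH")] = {"5mC": rate}
        cfg = SimConfig(seed=8, genome_length=300_000, n_genes=0, rates=rates)
        genome, genes = simulate.simulate_genome(cfg)
        truth = simulate.plant_methylome(genome, genes, cfg)
        plus, minus = context_code_arrays(genome, "chr1")
        tot = mod = 0
        for strand, ctx in (("+", plus), ("-", minus)):
            pos = np.flatnonzero(ctx == CTX_CHH)
            tot += len(pos)
            mod += int((truth.state_array("chr1", strand)[pos] > 0).sum())
        assert tot > 5e4
        sd = np.sqrt(rate * (1 - rate) / tot)
        assert abs(mod / tot - rate) < 3 * sd

    def test_cg_symmetric_fraction_near_configured(self, small_sim):
        _, genome, _, _, truth = small_sim
        plus, minus = context_code_arrays(genome, "chr1")
        sp, sm = truth.state_array("chr1", "+"), truth.state_array("chr1", "-")
        src = np.flatnonzero((plus == CTX_CG) & (sp > 0))
        src = src[src + 1 < len(sp)]
        frac = float((sm[src + 1] > 0).mean())
        assert abs(frac - 0.21) < 0.06

    def test_missing_rate_key_is_reported(self):
        rates = _zero_rates()
        del rates[("Intron", "CHH")]
        cfg = SimConfig(seed=9, genome_length=50_000, n_genes=5, rates=rates)
        genome, genes = simulate.simulate_genome(cfg)
        with pytest.raises(KeyError, match="Intron"):
            simulate.plant_methylome(genome, genes, cfg)

    def test_truth_invariant_state_level_consistency(self, small_sim):
        _, _, _, _, truth = small_sim
        df = truth.sites()
        assert (df["level"] > 0).all()
        assert set(df["level"].unique()) <= {0.5, 1.0}


class TestSimulateBsReads:
    def test_full_conversion_removes_interrogated_base(self):
        cfg = SimConfig(
            seed=10, genome_length=5_000, n_genes=0, coverage=2, conv_fail=0.0,
            seq_error=0.0, rates=_zero_rates(),
        )
        genome, genes = simulate.simulate_genome(cfg)
        truth = simulate.plant_methylome(genome, genes, cfg)
        # every cytosine of the molecule's own strand converts, so no read
        # retains a C (minus-strand reads keep G at plus-strand C positions,
        # which is their complement, not a retained cytosine)
        for read in simulate.simulate_bs_reads(genome, truth, cfg):
            assert "C" not in read.sequence

    def test_full_protection_at_level_one_site(self):
        g = Genome({"c": "A" * 200 + "CAA" + "A" * 197})
        truth = MethylomeTruth(g)
        truth.set_site("c", 200, "+", MC, 1.0)
        cfg = SimConfig(
            seed=11, genome_length=400, coverage=30, read_length=50,
            conv_fail=0.0, seq_error=0.0,
        )
        reads = simulate.simulate_bs_reads(g, truth, cfg)
        n_cover = 0
        for r in reads:
            _, chrom, start, strand = r.name.split("|")
            start = int(start)
            if strand == "+" and start <= 200 < start + 50:
                n_cover += 1
                assert r.sequence[200 - start] == "C"
        assert n_cover > 0

    def test_nonconversion_rate_recovered(self):
        # all-unmodified genome: retained C fraction estimates conv_fail
        g = Genome({"c": "AC" * 5_000})
        truth = MethylomeTruth(g)
        cfg = SimConfig(
            seed=12, genome_length=10_000, coverage=40, read_length=76,
            conv_fail=0.005, seq_error=0.0,
        )
        reads = simulate.simulate_bs_reads(g, truth, cfg)
        n_c = n_sites = 0
        for r in reads:
            if r.name.split("|")[3] == "+":
                n_c += r.sequence.count("C")
                n_sites += r.sequence.count("C") + r.sequence.count("T")
        assert n_sites > 9e4
        sd = np.sqrt(0.005 * 0.995 / n_sites)
        assert abs(n_c / n_sites - 0.005) < 3 * sd

    def test_read_too_long_raises(self):
        g = Genome({"c": "ACGT" * 10})
        cfg = SimConfig(seed=13, read_length=100)
        with pytest.raises(ValueError):
            simulate.simulate_bs_reads(g, MethylomeTruth(g), cfg)

    def test_deterministic(self, small_sim):
        cfg, genome, _, _, truth = small_sim
        r1 = simulate.simulate_bs_reads(genome, truth, cfg)
        r2 = simulate.simulate_bs_reads(genome, truth, cfg)
        assert r1 == r2


class TestSimulatePvuDigestion:
    def test_no_hmc_no_records(self):
        g = Genome({"c": "ACGT" * 100})
        cfg = SimConfig(seed=14, pvu_background_cut_rate=0.0)
        cuts = simulate.simulate_pvu_digestion(g, MethylomeTruth(g), cfg)
        assert len(cuts) == 0

    def test_fixed_offset_forced_cuts(self):
        g = Genome({"c": "A" * 1000 + "CAA" + "A" * 997})
        truth = MethylomeTruth(g)
        truth.set_site("c", 1000, "+", HMC, 1.0)
        cfg = SimConfig(seed=15, pvu_offsets_top=(12,), pvu_mean_frags=5.0)
        cuts = simulate.simulate_pvu_digestion(g, truth, cfg)
        assert (cuts["pos"] == 1012).all()
        assert (cuts["strand"] == "+").all()
        assert len(cuts) > 0

    def test_offset_distribution_uniform(self):
        g = Genome({"c": "A" * 1000 + "CAA" + "A" * 997})
        truth = MethylomeTruth(g)
        truth.set_site("c", 1000, "+", HMC, 1.0)
        cfg = SimConfig(seed=16, pvu_offsets_top=(11, 12, 13), pvu_mean_frags=10_000.0)
        cuts = simulate.simulate_pvu_digestion(g, truth, cfg)
        observed = cuts["pos"].value_counts().reindex([1011, 1012, 1013]).to_numpy()
        assert stats.chisquare(observed).pvalue > 0.01


class TestSimulateDipFragments:
    def test_empty_without_modified_sites(self):
        g = Genome({"c": "ACGT" * 500})
        cfg = SimConfig(seed=17, dip_background_rate=0.0)
        frags = simulate.simulate_dip_fragments(g, MethylomeTruth(g), cfg)
        assert len(frags) == 0

    def test_fragments_contain_site_with_valid_lengths(self):
        g = Genome({"c": "A" * 2000 + "CAA" + "A" * 1997})
        truth = MethylomeTruth(g)
        truth.set_site("c", 2000, "+", HMC, 1.0)
        cfg = SimConfig(seed=18, dip_mean_frags=1000.0)
        frags = simulate.simulate_dip_fragments(g, truth, cfg, target_state="5hmC")
        lengths = (frags["end"] - frags["start"]).to_numpy()
        assert len(frags) > 500
        assert lengths.min() >= 300 and lengths.max() <= 600
        assert ((frags["start"] <= 2000) & (frags["end"] > 2000)).all()
        # uniform lengths on [300, 600]: mean 450, sd ~ 301/sqrt(12)
        sd = (600 - 300) / np.sqrt(12) / np.sqrt(len(frags))
        assert abs(lengths.mean() - 450) < 3 * sd + 0.5
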