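"""Summary tables, metagene binning, splice junctions and gene panels."""

import math

import numpy as np
import pandas as pd
import pytest

from beemeth import summarize
from beemeth.refmodel import Gene, Genome, RegionIndex, Transcript, build_region_index
from beemeth.summarize import (
    PanelSpec,
    classify_genes_by_oe,
    metagene_profile,
    splice_junction_methylation,
    summarize_by_region,
    summarize_intervals_by_region,
)
from beemeth.util import percent, round_half_up


def _calls(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "level"])
    df["pass"] = True
    return df


class TestSummarizeByRegion:
    def test_toy_counts_and_percent(self):
        index = RegionIndex({("c", "Exon"): [(0, 100)]}, {"c": 200})
        rows = [("c", p, "+", "CG", 1.0 if p < 3 else 0.0) for p in range(10)]
        out = summarize_by_region(_calls(rows), index, contexts=("CG",))
        row = out[(out.Type == "Exon") & (out.Context == "CG")].iloc[0]
        assert (row["Analyzed"], row["Methylated"], row["Methylated %"]) == (10, 3, 30.0)

    def test_zero_analyzed_percent_is_na(self):
        index = RegionIndex({("c", "Exon"): [(0, 10)], ("c", "Intron"): [(50, 60)]}, {"c": 100})
        rows = [("c", 1, "+", "CG", 0.0)]
        out = summarize_by_region(_calls(rows), index, contexts=("CG",))
        intron = out[out.Type == "Intron"].iloc[0]
        assert intron["Analyzed"] == 0 and math.isnan(intron["Methylated %"])

    def test_site_counts_once_per_label(self):
        index = RegionIndex(
            {("c", "Exon"): [(0, 10)], ("c", "Gene"): [(0, 10)]}, {"c": 100}
        )
        rows = [("c", 2, "+", "CHH", 1.0)]
        out = summarize_by_region(_calls(rows), index, contexts=("CHH",))
        assert (out["Analyzed"] == 1).all()

    def test_failing_calls_excluded(self):
        index = RegionIndex({("c", "Exon"): [(0, 10)]}, {"c": 100})
        df = _calls([("c", 1, "+", "CG", 1.0), ("c", 2, "+", "CG", 1.0)])
        df.loc[1, "pass"] = False
        out = summarize_by_region(df, index, contexts=("CG",))
        assert out.iloc[0]["Analyzed"] == 1

    def test_rounding_is_half_up(self):
        assert percent(1, 16) == 6.25
        assert percent(5, 2000) == 0.25
        assert percent(1, 800) == 0.13  # 0.125 rounds up, not to even
        assert round_half_up(0.125, 2) == 0.13


class TestSummarizeIntervals:
    def _index(self):
        return RegionIndex(
            {
                ("c", "Exon"): [(100, 200)],
                ("c", "Intron"): [(200, 300)],
                ("c", "Intergenic"): [(0, 100), (300, 1000)],
            },
            {"c": 1000},
        )

    def test_all_in_introns(self):
        iv = pd.DataFrame({"chrom": "c", "start": [210, 220], "end": [250, 260]})
        out = summarize_intervals_by_region(iv, self._index())
        row = out[out.Type == "Intron"].iloc[0]
        assert row["Count"] == 2 and row["Percent"] == 100.0

    def test_empty_input(self):
        out = summarize_intervals_by_region(pd.DataFrame(columns=["chrom", "start", "end"]), self._index())
        assert len(out) == 0

    def test_midpoint_assignment_matches_manual_tally(self):
        iv = pd.DataFrame(
            {
                "chrom": "c",
                "start": [90, 150, 195, 500],
                "end": [130, 170, 215, 560],
            }
        )
        # midpoints: 109 (exon), 159 (exon), 204 (intron), 529 (intergenic)
        out = summarize_intervals_by_region(iv, self._index()).set_index("Type")
        assert out.loc["Exon", "Count"] == 2
        assert out.loc["Intron", "Count"] == 1
        assert out.loc["Intergenic", "Count"] == 1
        assert out["Count"].sum() == 4


class TestMetageneProfile:
    def _uniform_gene(self, length=600, mod_every=2):
        g = Gene("g", "c", "+", (Transcript("g.t", ((1000, 1000 + length),)),))
        rows = [
            ("c", 1000 + i, "+", "CG", 1.0 if i % mod_every == 0 else 0.0)
            for i in range(length)
        ]
        return g, _calls(rows)

    def test_uniform_modification_gives_flat_profile(self):
        gene, calls = self._uniform_gene()
        prof = metagene_profile(calls, [gene], nbins=30, min_covered=100)
        ex = prof["exon"]
        assert (ex["analyzed"] == 20).all()
        assert np.allclose(ex["ratio"], 0.5)

    def test_low_coverage_gene_excluded(self):
        gene, calls = self._uniform_gene(length=99)
        prof = metagene_profile(calls, [gene], min_covered=100)
        assert prof["exon"]["analyzed"].sum() == 0
        prof2 = metagene_profile(calls, [gene], min_covered=99)
        assert prof2["exon"]["analyzed"].sum() == 99

    def test_bin_totals_preserve_site_count(self):
        gene, calls = self._uniform_gene(length=451)  # not divisible by 30
        prof = metagene_profile(calls, [gene], min_covered=10)
        assert prof["exon"]["analyzed"].sum() == 451
        assert prof["exon"]["modified"].sum() == (calls["level"] > 0).sum()

    def test_minus_strand_bins_run_against_genome_coordinates(self):
        length = 300
        rows = [
            ("c", 1000 + i, "+", "CG", 1.0 if i < 30 else 0.0) for i in range(length)
        ]
        calls = _calls(rows)
        plus = Gene("gp", "c", "+", (Transcript("t", ((1000, 1000 + length),)),))
        minus = Gene("gm", "c", "-", (Transcript("t", ((1000, 1000 + length),)),))
        p_plus = metagene_profile(calls, [plus], nbins=10, min_covered=10)["exon"]
        p_minus = metagene_profile(calls, [minus], nbins=10, min_covered=10)["exon"]
        assert p_plus["ratio"].iloc[0] == 1.0 and p_plus["ratio"].iloc[-1] == 0.0
        assert p_minus["ratio"].iloc[-1] == 1.0 and p_minus["ratio"].iloc[0] == 0.0
        assert np.allclose(p_minus["ratio"].to_numpy(), p_plus["ratio"].to_numpy()[::-1])


class TestSpliceJunctions:
    def _genome_plus(self):
        # exon [0,10) GTAAG...AG intron [10,30) exon [30,40)
        seq = "AAAAACAAAA" + "GTAAG" + "A" * 13 + "AG" + "CAAAAAAAAA"
        g = Genome({"c": seq})
        gene = Gene("g", "c", "+", (Transcript("t", ((0, 10), (30, 40)),),))
        return g, gene

    def test_modified_donor_template_c(self):
        g, gene = self._genome_plus()
        # template C opposite the sense G at intron start 10 (minus strand)
        calls = _calls([("c", 10, "-", "CHH", 1.0)])
        records, summary = splice_junction_methylation(calls, [gene], g)
        assert len(records) == 1
        rec = records.iloc[0]
        assert rec["junction"] == "donor"
        assert rec["motif_sense"] == "GT" and rec["motif_template"] == "AC"
        don = summary[summary.junction == "donor"].iloc[0]
        assert don["modified"] == 1 and don["canonical"] == 1

    def test_modified_acceptor_template_c(self):
        g, gene = self._genome_plus()
        calls = _calls([("c", 29, "-", "CHH", 1.0)])  # opposite sense G at e-1
        records, _ = splice_junction_methylation(calls, [gene], g)
        assert records.iloc[0]["junction"] == "acceptor"
        assert records.iloc[0]["motif_sense"] == "AG"
        assert records.iloc[0]["motif_template"] == "CT"

    def test_minus_strand_gene_mirrored(self):
        # sense GT on a minus-strand gene is reference AC at the intron's
        # right edge; the template C sits on the plus strand
        seq = "AAAAAAAAAA" + "CT" + "A" * 16 + "AC" + "AAAAAAAAAA"
        g = Genome({"c": seq})
        gene = Gene("g", "c", "-", (Transcript("t", ((0, 10), (30, 40)),),))
        calls = _calls([("c", 29, "+", "CHH", 1.0)])
        records, _ = splice_junction_methylation(calls, [gene], g)
        assert records.iloc[0]["junction"] == "donor"
        assert records.iloc[0]["motif_sense"] == "GT"

    def test_no_modified_sites_empty(self):
        g, gene = self._genome_plus()
        records, summary = splice_junction_methylation(_calls([]), [gene], g)
        assert len(records) == 0
        assert math.isnan(summary.iloc[0]["canonical_fraction"])

    def test_non_canonical_junction_still_recorded(self):
        seq = "AAAAACAAAA" + "GGAAG" + "A" * 13 + "AG" + "CAAAAAAAAA"
        g = Genome({"c": seq})
        gene = Gene("g", "c", "+", (Transcript("t", ((0, 10), (30, 40)),),))
        calls = _calls([("c", 10, "-", "CHH", 1.0)])
        records, summary = splice_junction_methylation(calls, [gene], g)
        assert records.iloc[0]["motif_sense"] == "GG"
        don = summary[summary.junction == "donor"].iloc[0]
        assert don["modified"] == 1 and don["canonical"] == 0


class TestGenePanels:
    def _setup(self):
        gene = Gene("g", "c", "+", (Transcript("t", ((0, 100), (200, 300)),),))
        oe = {"g": 0.7}
        return gene, oe

    def test_zero_percent_panel_with_minimum_sites(self):
        gene, oe = self._setup()
        rows = [("c", p, "+", "CG", 0.0) for p in range(12)]
        sel = classify_genes_by_oe(
            _calls(rows), [gene], oe, PanelSpec("p0", "CG", "exon", "=", 0.0, min_sites=10)
        )
        assert list(sel.genes["gene_id"]) == ["g"]
        rows9 = rows[:9]
        sel9 = classify_genes_by_oe(
            _calls(rows9), [gene], oe, PanelSpec("p0", "CG", "exon", "=", 0.0, min_sites=10)
        )
        assert len(sel9.genes) == 0  # below the motif-count minimum

    def test_threshold_panel(self):
        gene, oe = self._setup()
        # 20 intron CHH sites, 3 modified -> 15% > 10%
        rows = [("c", 100 + p, "+", "CHH", 1.0 if p < 3 else 0.0) for p in range(20)]
        sel = classify_genes_by_oe(
            _calls(rows), [gene], oe, PanelSpec("p10", "CHH", "intron", ">", 10.0)
        )
        assert list(sel.genes["gene_id"]) == ["g"]
        assert sel.genes.iloc[0]["percent"] == pytest.approx(15.0)
        assert sel.genes.iloc[0]["oe"] == 0.7

    def test_unknown_region_or_context_errors(self):
        gene, oe = self._setup()
        with pytest.raises(ValueError):
            classify_genes_by_oe(_calls([]), [gene], oe, PanelSpec("x", "CXX", "exon", ">", 1))
        with pytest.raises(ValueError):
            classify_genes_by_oe(_calls([]), [gene], oe, PanelSpec("x", "CG", "flank", ">", 1))
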