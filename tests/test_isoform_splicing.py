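"""Isoform-CR correlation screen, biotype enrichment, splice-completeness
counting and intron lengths."""

import math

import numpy as np
import pandas as pd
import pytest

from sfae import isoform_splicing as isp
from sfae import simulate as sim
from sfae.types import Gene, GeneModels, ReadBlockSketch, Transcript


def brute_force_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def small_panel(ratio1):
    """Two-isoform single-gene panel with the given isoform-1 ratios."""
    n = len(ratio1)
    cols = [f"CL{i}" for i in range(n)]
    cr = pd.DataFrame([np.linspace(0.3, 0.9, n)], index=["g1"], columns=cols)
    gene_tpm = np.full(n, 10.0)
    iso = pd.DataFrame(
        [ratio1 * gene_tpm, (1 - np.asarray(ratio1)) * gene_tpm],
        index=["g1.T1", "g1.T2"], columns=cols)
    gene = pd.DataFrame([gene_tpm], index=["g1"], columns=cols)
    gmap = pd.Series({"g1.T1": "g1", "g1.T2": "g1"})
    return cr, iso, gene, gmap


class TestIsoformCRCorrelation:
    def test_linear_coupling_gives_r_one(self):
        cr, iso, gene, gmap = small_panel(np.linspace(0.2, 0.8, 8))
        out = isp.isoform_cr_correlation(cr, iso, gmap)
        assert out.loc["g1.T1", "r"] == pytest.approx(1.0)
        assert out.loc["g1.T2", "r"] == pytest.approx(-1.0)

    def test_two_isoform_ratios_are_anticorrelated(self):
        rng = np.random.default_rng(0)
        cr, iso, gene, gmap = small_panel(
            np.clip(0.5 + 0.3 * rng.normal(size=11), 0.05, 0.95))
        out = isp.isoform_cr_correlation(cr, iso, gmap)
        assert out.loc["g1.T1", "r"] == pytest.approx(-out.loc["g1.T2", "r"])

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        ratios = np.clip(0.5 + 0.2 * rng.normal(size=11), 0.05, 0.95)
        cr, iso, gene, gmap = small_panel(ratios)
        out = isp.isoform_cr_correlation(cr, iso, gmap)
        expected = brute_force_pearson(cr.loc["g1"], ratios)
        assert out.loc["g1.T1", "r"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_cell_lines_reported_missing(self):
        cr, iso, gene, gmap = small_panel(np.linspace(0.2, 0.8, 3))
        out = isp.isoform_cr_correlation(cr, iso, gmap)
        assert np.isnan(out.loc["g1.T1", "r"])
        assert "fewer than 4" in out.loc["g1.T1", "reason"]

    def test_constant_target_reported_missing(self):
        cr, iso, gene, gmap = small_panel(np.full(6, 0.5))
        out = isp.isoform_cr_correlation(cr, iso, gmap)
        assert np.isnan(out.loc["g1.T1", "r"])
        assert out.loc["g1.T1", "reason"] == "constant vector"


class TestScreen:
    @pytest.mark.parametrize(
        "r_strength,same_sign,med_tpm,should_pass",
        [
            (0.99, False, 5.0, True),
            (0.99, False, 1.0, False),  # fails expression threshold
        ],
    )
    def test_threshold_logic(self, r_strength, same_sign, med_tpm, should_pass):
        rng = np.random.default_rng(2)
        n = 11
        latent = np.linspace(0.2, 0.8, n)
        noise = rng.normal(0, 0.02, n)
        ratio1 = np.clip(latent * r_strength + noise, 0.02, 0.98)
        cols = [f"CL{i}" for i in range(n)]
        cr = pd.DataFrame([np.linspace(0.3, 0.9, n)], index=["g1"], columns=cols)
        gene_tpm = np.full(n, med_tpm)
        iso = pd.DataFrame([ratio1 * gene_tpm, (1 - ratio1) * gene_tpm],
                           index=["g1.T1", "g1.T2"], columns=cols)
        gene = pd.DataFrame([gene_tpm], index=["g1"], columns=cols)
        gmap = pd.Series({"g1.T1": "g1", "g1.T2": "g1"})
        out = isp.screen_switch_genes(cr, iso, gene, gmap)
        assert bool(out.loc["g1", "passes"]) == should_pass

    def test_median_threshold_is_inclusive(self):
        cr, iso, gene, gmap = small_panel(np.linspace(0.2, 0.8, 9))
        gene.loc["g1"] = 3.0  # median exactly at the threshold
        out = isp.screen_switch_genes(cr, iso, gene, gmap)
        assert bool(out.loc["g1", "passes"])

    def test_exported_is_positively_correlated_isoform(self):
        cr, iso, gene, gmap = small_panel(np.linspace(0.2, 0.8, 9))
        out = isp.screen_switch_genes(cr, iso, gene, gmap)
        assert out.loc["g1", "exported_isoform"] == "g1.T1"
        assert out.loc["g1", "retained_isoform"] == "g1.T2"

    def test_planted_panel_sensitivity_and_specificity(self):
        sens, fps = [], []
        for seed in range(3):
            iso, gene, cr, gmap, truth = sim.simulate_isoform_panel(
                n_genes=500, n_cell_lines=11, n_switch=25, effect=0.95,
                seed=seed)
            out = isp.screen_switch_genes(cr, iso, gene, gmap)
            passed = set(out.index[out["passes"]])
            planted = truth.planted_switch_genes
            sens.append(len(passed & planted) / len(planted))
            null_genes = set(out.index) - planted
            fps.append(len(passed & null_genes) / len(null_genes))
        assert np.mean(sens) >= 0.95
        assert np.mean(fps) <= 0.05


class TestBiotypeEnrichment:
    def make_screen(self, rows):
        df = pd.DataFrame(
            rows, columns=["gene_id", "exported_isoform", "retained_isoform"])
        df["passes"] = True
        return df.set_index("gene_id")

    def test_diagonal_table_p_one_third(self):
        screen = self.make_screen(
            [("g1", "e1", "r1"), ("g2", "e2", "r2")])
        biotypes = {"e1": "protein_coding", "e2": "protein_coding",
                    "r1": "lincRNA", "r2": "lincRNA"}
        table, p = isp.biotype_switch_enrichment(screen, biotypes)
        assert table.loc["exported", "coding"] == 2
        assert table.loc["retained", "noncoding"] == 2
        assert p == pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        rows = [(f"g{i}", f"e{i}", f"r{i}") for i in range(10)]
        biotypes = {}
        for i in range(10):
            biotypes[f"e{i}"] = "protein_coding" if i < 5 else "lincRNA"
            biotypes[f"r{i}"] = "protein_coding" if i < 5 else "lincRNA"
        table, p = isp.biotype_switch_enrichment(self.make_screen(rows), biotypes)
        assert p == pytest.approx(1.0)

    def test_empty_margin_gives_nan_p(self):
        screen = self.make_screen([("g1", "e1", "r1")])
        biotypes = {"e1": "protein_coding", "r1": "protein_coding"}
        table, p = isp.biotype_switch_enrichment(screen, biotypes)
        assert math.isnan(p)
        assert table.to_numpy().sum() == 2


class TestSpliceCompleteness:
    def test_direct_ratio_arithmetic(self, intron_gene_models):
        frags = []
        for i in range(6):  # exon-only
            frags.append(ReadBlockSketch(f"c{i}", [("chr2", 100 + i, 150 + i)]))
        for i in range(3):  # intron-overlapping
            frags.append(ReadBlockSketch(f"i{i}", [("chr2", 1500, 1550)]))
        rows = isp.splice_completeness_ratio(frags, intron_gene_models)
        row = rows["geneI"]
        assert row.incomplete_count == 3 and row.complete_count == 6
        assert row.ratio == pytest.approx(0.5)
        assert row.log_ratio == pytest.approx(math.log(0.5), abs=1e-9)

    def test_intron_block_is_incomplete(self, intron_gene_models):
        frag = ReadBlockSketch("r", [("chr2", 1150, 1160)])
        rows = isp.splice_completeness_ratio([frag], intron_gene_models)
        assert rows["geneI"].incomplete_count == 1

    def test_zero_incomplete_masks_log_ratio(self, intron_gene_models):
        frag = ReadBlockSketch("r", [("chr2", 10, 60)])
        rows = isp.splice_completeness_ratio([frag], intron_gene_models)
        assert rows["geneI"].ratio == 0.0
        assert math.isnan(rows["geneI"].log_ratio)

    def test_fragment_count_conservation(self, two_gene_models):
        rng = np.random.default_rng(3)
        reads = sim.simulate_gene_reads(
            two_gene_models, incomplete_fraction=0.0, n_fragments=50, seed=4)
        rows = isp.splice_completeness_ratio(reads, two_gene_models)
        total = sum(r.incomplete_count + r.complete_count + r.ignored_count
                    for r in rows.values())
        assert total == 100  # every simulated fragment assigned and counted

    def test_read_outside_any_gene_ignored(self, intron_gene_models):
        frag = ReadBlockSketch("r", [("chr9", 10, 60)])
        rows = isp.splice_completeness_ratio([frag], intron_gene_models)
        assert rows == {}


class TestIntronLength:
    def test_single_gap(self):
        t = Transcript("t", exons=[(0, 100), (200, 300)])
        g = Gene("g", "chr1", "+", {"t": t})
        out = isp.summed_intron_length(GeneModels({"g": g}))
        assert out["g"] == 100

    def test_single_exon_gene_zero(self):
        t = Transcript("t", exons=[(0, 500)])
        g = Gene("g", "chr1", "+", {"t": t})
        assert isp.summed_intron_length(GeneModels({"g": g}))["g"] == 0

    def test_union_swallows_gaps(self, two_gene_models):
        out = isp.summed_intron_length(two_gene_models, policy="exon_union")
        assert out["geneA"] == 0  # tx2 exon covers tx1's gap
        assert out["geneB"] == 0

    def test_representative_policy_and_ordering(self, two_gene_models):
        rep = {"geneA": "tx1", "geneB": "tx3"}
        out_rep = isp.summed_intron_length(
            two_gene_models, policy="representative", representative=rep)
        assert out_rep["geneA"] == 300  # tx1 gap [300, 600)
        out_union = isp.summed_intron_length(two_gene_models, policy="exon_union")
        # the union can only remove intronic bases relative to any
        # span-covering representative
        assert (out_union <= out_rep).all()
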