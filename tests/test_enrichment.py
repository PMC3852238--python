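"""Feature labels, chi-square enrichment, metagene binning."""

import numpy as np
import pandas as pd
import pytest

from methyldiff import (
    ClassificationParams,
    ComparativeCallSet,
    GenomeAnnotation,
    GroupDesign,
    assign_features,
    chi_square_2x2,
    feature_contingency,
    metagene_profile,
)
from methyldiff.annotation import Gene
from methyldiff.enrichment import EnrichmentError

from oracles import chi2_textbook

DESIGN = GroupDesign({"domesticated": ["d1", "d2", "d3"],
                      "wild": ["w1", "w2", "w3", "w4"]})


def comparative_from_classes(site_classes):
    rows = [
        {"chrom": c, "pos": p, "strand": s, "m_a": 0, "c_a": 3,
         "m_b": 0, "c_b": 4, "cls": cls}
        for (c, p, s), cls in site_classes.items()
    ]
    return ComparativeCallSet(pd.DataFrame(rows), DESIGN, ClassificationParams())


class TestAssignFeatures:
    def test_cds_plus_te_multilabel(self, toy_annotation):
        # position 3100 is inside gplus exon 1 and we add a TE over it
        ann = toy_annotation
        ann.te_intervals.append(("chr1", 3050, 3150))
        labels = assign_features([("chr1", 3100, "+")], ann)
        row = labels.iloc[0]
        assert row["CDS"] and row["TE"]
        assert not row["intron"] and not row["intergenic"]

    def test_intron_label(self, toy_annotation):
        row = assign_features([("chr1", 3500, "+")], toy_annotation).iloc[0]
        assert row["intron"] and not row["CDS"] and row["TE"]  # TE spans the intron

    def test_flank_boundary_is_exclusive(self, toy_annotation):
        # gplus starts at 3000; 2000-bp flank covers [1000, 3000)
        inside = assign_features([("chr1", 1000, "+")], toy_annotation).iloc[0]
        outside = assign_features([("chr1", 999, "+")], toy_annotation).iloc[0]
        assert inside["upstream"]
        assert not outside["upstream"] and outside["intergenic"]

    def test_empty_annotation_all_intergenic(self):
        ann = GenomeAnnotation(chromosomes={"chr1": 1000})
        labels = assign_features([("chr1", i, "+") for i in (1, 500, 999)], ann)
        assert labels["intergenic"].all()

    def test_smrna_label(self, toy_annotation):
        row = assign_features([("chr1", 550, "+")], toy_annotation).iloc[0]
        assert row["smRNA"] and not row["intergenic"]


class TestContingency:
    def test_constructed_counts(self, toy_annotation):
        classes = {
            ("chr1", 3100, "+"): "DMC_A",   # CDS
            ("chr1", 3105, "+"): "CMC",     # CDS
            ("chr1", 3106, "+"): "CMC",     # CDS
            ("chr1", 3500, "+"): "DMC_B",   # intron
            ("chr1", 3510, "+"): "CMC",     # intron
        }
        comp = comparative_from_classes(classes)
        sites = list(classes)
        labels = assign_features(sites, toy_annotation)
        table = feature_contingency(comp, labels, "intron")
        assert table.table == ((1, 1), (1, 2))  # directions pooled

    def test_empty_row_is_an_error(self, toy_annotation):
        classes = {("chr1", 3100, "+"): "DMC_A", ("chr1", 3105, "+"): "CMC"}
        comp = comparative_from_classes(classes)
        labels = assign_features(list(classes), toy_annotation)
        with pytest.raises(EnrichmentError, match="intron"):
            feature_contingency(comp, labels, "intron")

    def test_feature_equal_reference_rejected(self, toy_annotation):
        comp = comparative_from_classes({("chr1", 3100, "+"): "CMC"})
        labels = assign_features([("chr1", 3100, "+")], toy_annotation)
        with pytest.raises(EnrichmentError):
            feature_contingency(comp, labels, "CDS", "CDS")


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        stat, p = chi_square_2x2([[10, 90], [20, 180]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_under_row_and_column_swap(self):
        table = [[3021, 8731], [1963, 17402]]
        stat, p = chi_square_2x2(table)
        swapped = [[17402, 1963], [8731, 3021]]
        stat2, p2 = chi_square_2x2(swapped)
        assert stat == pytest.approx(stat2, rel=1e-12)
        assert p == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_textbook_formula_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            table = rng.integers(1, 5000, size=(2, 2))
            stat, p = chi_square_2x2(table)
            ref_stat, ref_p = chi2_textbook(table)
            assert stat == pytest.approx(ref_stat, rel=1e-9)
            assert p == pytest.approx(ref_p, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(EnrichmentError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 10]])

    def test_yates_correction_reduces_statistic(self):
        plain, _ = chi_square_2x2([[12, 5], [4, 14]])
        corrected, _ = chi_square_2x2([[12, 5], [4, 14]], yates=True)
        assert corrected < plain


class TestMetagene:
    def gene(self, strand="+"):
        return Gene("g", "chr1", strand, 10_000, 11_000, exons=[(10_000, 11_000)])

    def annotation(self, strand="+"):
        return GenomeAnnotation(chromosomes={"chr1": 30_000}, genes=[self.gene(strand)])

    def test_no_sites_all_zero(self):
        prof = metagene_profile({"CMC": []}, self.annotation())
        assert prof.counts.loc["CMC"].sum() == 0
        assert prof.n_bins == 60

    def test_midpoint_maps_to_body_bin_ten(self):
        # 1000-bp plus gene: midpoint fraction 0.5 -> body bin 10 (0-indexed)
        prof = metagene_profile({"DMC_A": [("chr1", 10_500, "+")]}, self.annotation())
        counts = prof.counts.loc["DMC_A"].to_numpy()
        assert counts.sum() == 1
        assert counts[20 + 10] == 1

    def test_minus_strand_body_runs_from_tss(self):
        # same position, minus gene: fraction measured from the 3' end coordinate
        prof = metagene_profile({"x": [("chr1", 10_999, "-")]}, self.annotation("-"))
        counts = prof.counts.loc["x"].to_numpy()
        assert counts[20 + 0] == 1  # TSS-proximal body bin

    def test_upstream_bin_order_farthest_first(self):
        prof = metagene_profile(
            {"x": [("chr1", 8_001, "+"), ("chr1", 9_999, "+")]}, self.annotation())
        counts = prof.counts.loc["x"].to_numpy()
        assert counts[0] == 1    # 1999 bp upstream -> farthest bin
        assert counts[19] == 1   # 1 bp upstream -> TSS-adjacent bin

    def test_downstream_and_minus_strand_symmetry(self):
        plus = metagene_profile({"x": [("chr1", 11_000, "+")]}, self.annotation())
        minus = metagene_profile({"x": [("chr1", 9_999, "-")]}, self.annotation("-"))
        assert plus.counts.loc["x"].to_numpy()[40] == 1
        assert (plus.counts.loc["x"].to_numpy() ==
                minus.counts.loc["x"].to_numpy()).all()

    def test_uniform_sites_fill_body_bins_uniformly(self):
        rng = np.random.default_rng(12)
        n = 10_000
        sites = [("chr1", int(p), "+") for p in rng.integers(10_000, 11_000, size=n)]
        prof = metagene_profile({"x": sites}, self.annotation())
        body = prof.counts.loc["x"].to_numpy()[20:40]
        assert body.sum() == n
        expected = n / 20
        sd = np.sqrt(n * (1 / 20) * (19 / 20))
        assert (np.abs(body - expected) <= 3 * sd).all()

    def test_counts_conserve_multiplicity_across_neighbour_genes(self):
        g1 = Gene("g1", "chr1", "+", 5_000, 6_000, exons=[(5_000, 6_000)])
        g2 = Gene("g2", "chr1", "+", 7_000, 8_000, exons=[(7_000, 8_000)])
        ann = GenomeAnnotation(chromosomes={"chr1": 20_000}, genes=[g1, g2])
        # 6500 is downstream of g1 AND upstream of g2 -> counted twice
        prof = metagene_profile({"x": [("chr1", 6_500, "+")]}, ann)
        assert prof.counts.loc["x"].sum() == 2

    def test_short_genes_skipped_and_counted(self):
        short = Gene("tiny", "chr1", "+", 100, 110, exons=[(100, 110)])
        ann = GenomeAnnotation(chromosomes={"chr1": 20_000},
                               genes=[short, self.gene()])
        prof = metagene_profile({"x": []}, ann)
        assert (prof.n_genes_used, prof.n_genes_skipped) == (1, 1)

    def test_density_uses_universe_counts(self):
        sites = [("chr1", 10_025, "+")]
        universe = [("chr1", 10_025, "+"), ("chr1", 10_030, "+")]
        prof = metagene_profile({"x": sites}, self.annotation(),
                                universe_sites=universe)
        b = 20 + 0  # both universe sites in first body bin
        assert prof.densities.loc["x"].to_numpy()[b] == pytest.approx(0.5)
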