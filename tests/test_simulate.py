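import math

import numpy as np
import pytest
from scipy import stats as sps

import rhodoscan as rs
from rhodoscan.refdata import AA_ALPHABET
from conftest import four_cluster_community
from test_recruit import revcomp


def single_taxon_spec(genes, read_length=100, error_rate=0.0, bg=0.0, fts="Q"):
    taxa = [rs.TaxonSpec("solo", "SAR11", 1.0, genes, fts_residue=fts)]
    return rs.CommunitySpec(
        taxa, read_length=read_length, error_rate=error_rate, background_fraction=bg
    )


class TestGenerateReferenceSet:
    def test_three_taxon_tree(self):
        spec = four_cluster_community()
        refset = rs.generate_reference_set(spec, divergence=0.05, seed=7)
        assert sorted(refset.tree.leaf_ids) == ["t0", "t1", "t2", "t3"]
        assert set(refset.alignments) == {"PR", "recA"}

    def test_fts_residue_is_forced(self):
        spec = four_cluster_community(fts=("Q", "L", "M", "Q"))
        refset = rs.generate_reference_set(spec, divergence=0.2, seed=7)
        aln = refset.alignments["PR"]
        col = refset.fts_column - 1
        for taxon, want in zip(("t0", "t1", "t2", "t3"), ("Q", "L", "M", "Q")):
            assert aln.row(taxon)[col] == want

    def test_same_seed_identical(self):
        spec = four_cluster_community()
        r1 = rs.generate_reference_set(spec, divergence=0.1, seed=3)
        r2 = rs.generate_reference_set(spec, divergence=0.1, seed=3)
        assert r1.genes == r2.genes
        assert r1.tree.newick == r2.tree.newick

    def test_divergence_limit(self):
        spec = four_cluster_community()
        with pytest.raises(ValueError, match="divergence"):
            rs.generate_reference_set(spec, divergence=0.6)

    def test_single_carrier_gets_ancestor_row(self):
        spec = single_taxon_spec({"recA": rs.GeneSpec(1050)})
        refset = rs.generate_reference_set(spec, divergence=0.1, seed=1)
        assert refset.alignments["recA"].n_rows == 2  # taxon + ancestor
        assert refset.tree is None

    def test_unequal_gene_lengths_rejected(self):
        taxa = [
            rs.TaxonSpec("a", "SAR11", 0.5, {"recA": rs.GeneSpec(900)}),
            rs.TaxonSpec("b", "SAR11", 0.5, {"recA": rs.GeneSpec(1050)}),
        ]
        spec = rs.CommunitySpec(taxa, read_length=100)
        with pytest.raises(ValueError, match="lengths must agree"):
            rs.generate_reference_set(spec, seed=0)


class TestSimulateReads:
    def test_exact_substrings_without_error(self):
        spec = single_taxon_spec({"recA": rs.GeneSpec(1050)})
        refset = rs.generate_reference_set(spec, seed=5)
        gene = refset.genes[("solo", "recA")]
        reads, truth = rs.simulate_reads(spec, refset, 200, "DNA", seed=8)
        for (rid, seq), (_, row) in zip(reads, truth.iterrows()):
            fwd = seq if row["strand"] == "+" else revcomp(seq)
            assert gene[row["start"] : row["start"] + 100] == fwd

    def test_rna_read_ratio_follows_multipliers(self):
        spec = single_taxon_spec(
            {"PR": rs.GeneSpec(750, 26.0), "recA": rs.GeneSpec(1050, 1.0)}
        )
        refset = rs.generate_reference_set(spec, seed=5)
        n = 50_000
        _, truth = rs.simulate_reads(spec, refset, n, "RNA", seed=9)
        counts = truth["source"].value_counts()
        expected_ratio = 26.0 * 750 / 1050
        p_pr = 26.0 * 750 / (26.0 * 750 + 1050)
        se = math.sqrt(p_pr * (1 - p_pr) / n)
        observed_p = counts["PR"] / n
        assert abs(observed_p - p_pr) <= 3 * se
        assert counts["PR"] / counts["recA"] == pytest.approx(expected_ratio, rel=0.05)

    def test_both_strands_sampled(self):
        spec = single_taxon_spec({"recA": rs.GeneSpec(1050)})
        refset = rs.generate_reference_set(spec, seed=5)
        _, truth = rs.simulate_reads(spec, refset, 500, "DNA", seed=10)
        assert set(truth["strand"]) == {"+", "-"}

    def test_seed_reproducibility(self):
        spec = four_cluster_community()
        refset = rs.generate_reference_set(spec, seed=5)
        r1, t1 = rs.simulate_reads(spec, refset, 1000, "DNA", seed=11)
        r2, t2 = rs.simulate_reads(spec, refset, 1000, "DNA", seed=11)
        assert r1 == r2
        assert t1.equals(t2)

    def test_read_count_composition_multinomial(self):
        # chi-square goodness of fit across 20 seeds at alpha=0.001:
        # at most 1 rejection expected
        spec = four_cluster_community(background_fraction=0.5)
        refset = rs.generate_reference_set(spec, seed=5)
        w_pr = 0.25 * 750 * 4
        w_recA = 0.25 * 1050 * 4
        total = w_pr + w_recA
        probs = np.array([0.5, 0.5 * w_pr / total, 0.5 * w_recA / total])
        failures = 0
        n = 50_000
        for seed in range(20):
            _, truth = rs.simulate_reads(spec, refset, n, "DNA", seed=seed)
            counts = truth["source"].value_counts()
            obs = np.array(
                [counts.get("background", 0), counts.get("PR", 0), counts.get("recA", 0)]
            )
            stat, p = sps.chisquare(obs, probs * n)
            if p < 0.001:
                failures += 1
        assert failures <= 1

    def test_invalid_n_reads(self):
        spec = four_cluster_community()
        refset = rs.generate_reference_set(spec, seed=5)
        with pytest.raises(ValueError, match="n_reads"):
            rs.simulate_reads(spec, refset, 0, "DNA")


class TestTruthSummary:
    def test_all_taxa_with_pr(self):
        spec = four_cluster_community()
        t = rs.truth_summary(spec)
        assert t.normalized_abundance["PR"] == pytest.approx(1.0)

    def test_nine_of_ten(self):
        taxa = []
        for i in range(10):
            genes = {"recA": rs.GeneSpec(1050)}
            if i < 9:
                genes["PR"] = rs.GeneSpec(750)
            taxa.append(rs.TaxonSpec(f"t{i}", "SAR11", 0.1, genes, fts_residue="Q"))
        t = rs.truth_summary(rs.CommunitySpec(taxa, read_length=100))
        assert t.normalized_abundance["PR"] == pytest.approx(0.9)

    def test_blue_fraction_even_split(self):
        spec = four_cluster_community(fts=("Q", "L", "Q", "L"))
        t = rs.truth_summary(spec)
        assert t.blue_fraction == pytest.approx(0.5)

    def test_cluster_fractions_sum_to_one(self):
        spec = rs.default_study_community(blue_fraction=0.63)
        t = rs.truth_summary(spec)
        assert sum(t.cluster_gene_fractions.values()) == pytest.approx(1.0)
        assert sum(t.cluster_transcript_fractions.values()) == pytest.approx(1.0)
        assert sum(t.leaf_transcript_fractions.values()) == pytest.approx(1.0)

    def test_no_recA_is_an_error(self):
        taxa = [rs.TaxonSpec("a", "SAR11", 1.0, {"PR": rs.GeneSpec(750)}, "Q")]
        with pytest.raises(ValueError, match="recA"):
            rs.truth_summary(rs.CommunitySpec(taxa, read_length=100))


class TestDefaultStudyCommunity:
    def test_headline_truth_values(self):
        spec = rs.default_study_community(blue_fraction=0.63)
        t = rs.truth_summary(spec)
        assert t.normalized_abundance["PR"] == pytest.approx(0.9, abs=1e-9)
        assert t.rna_dna_ratio["PR"] == pytest.approx(26.2, rel=1e-9)
        assert t.rna_dna_ratio["psaA"] == pytest.approx(11.0, rel=1e-9)
        assert t.rna_dna_ratio["pufM"] == pytest.approx(0.013, rel=1e-9)
        assert t.blue_fraction == pytest.approx(0.63, abs=1e-9)
        assert t.cluster_transcript_fractions["SAR11"] == pytest.approx(0.52, abs=1e-9)

    def test_blue_fraction_is_tunable_without_changing_roster(self):
        a = rs.default_study_community(blue_fraction=0.3)
        b = rs.default_study_community(blue_fraction=0.8)
        assert [t.taxon_id for t in a.taxa] == [t.taxon_id for t in b.taxa]
        assert rs.truth_summary(a).blue_fraction == pytest.approx(0.3, abs=1e-9)
        assert rs.truth_summary(b).blue_fraction == pytest.approx(0.8, abs=1e-9)

    def test_sar11_leaf_evenness_targets(self):
        from rhodoscan.quantify import shannon_evenness

        spec = rs.default_study_community(blue_fraction=0.63)
        t = rs.truth_summary(spec)
        sar11 = [x.taxon_id for x in spec.taxa if x.cluster == "SAR11"]
        gene = shannon_evenness({k: t.leaf_gene_fractions[k] for k in sar11})
        tran = shannon_evenness({k: t.leaf_transcript_fractions[k] for k in sar11})
        assert gene.J == pytest.approx(0.80, abs=0.02)
        assert tran.J == pytest.approx(0.57, abs=0.02)
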