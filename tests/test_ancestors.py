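import numpy as np
import pytest

import gkasr as g
from gkasr.ancestors import (
    AncestralReconstruction,
    ReconstructionError,
    dollo_gene_age,
)
from gkasr.phyloio import AMINO_ACIDS, SiteMask, TreeError

from conftest import brute_force_posterior, random_model


def make_rec(posteriors, threshold=0.20):
    """Assemble an AncestralReconstruction straight from a posterior matrix."""
    posteriors = np.asarray(posteriors, dtype=float)
    from gkasr.ancestors import _best_two

    ml, pp_ml, alt, pp_alt = _best_two(posteriors)
    return AncestralReconstruction(
        node_id="n",
        posteriors=posteriors,
        ml_state=ml,
        pp_ml=pp_ml,
        alt_state=alt,
        pp_alt=pp_alt,
        likely_gap=np.zeros(len(posteriors), dtype=bool),
        threshold=threshold,
    )


def onehot(aa, p=1.0, other=None, q=0.0):
    v = np.zeros(20)
    v[AMINO_ACIDS.index(aa)] = p
    if other is not None:
        v[AMINO_ACIDS.index(other)] = q
    rest = (1.0 - v.sum()) / np.count_nonzero(v == 0)
    v[v == 0] = rest
    return v


class TestMarginalPosteriors:
    def test_conserved_site_high_pp(self, wag):
        tree = g.read_newick("((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);")
        aln = g.AminoAcidAlignment.from_sequences(
            ["A", "B", "C", "D"], ["A", "A", "A", "A"]
        )
        rec = g.marginal_posteriors(aln, tree, wag, tree.root.id)
        assert rec.ml_state[0] == "A"
        assert rec.pp_ml[0] > 0.99

    @pytest.mark.parametrize("k", [1, 2])
    @pytest.mark.parametrize(
        "newick",
        [
            "((A:0.2,B:0.4):0.1,C:0.3);",
            "((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05);",
        ],
    )
    def test_enumeration_oracle(self, newick, k):
        """Marginal posteriors equal brute-force Bayes on small trees."""
        rng = np.random.default_rng(abs(hash((newick, k))) % 2**31)
        model = random_model(rng, n_categories=k, alpha=0.8 if k > 1 else None)
        tree = g.read_newick(newick)
        sim = g.simulate_alignment(tree, model, 3, seed=20)
        for node in tree.internal_nodes():
            rec = g.marginal_posteriors(sim.alignment, tree, model, node.id)
            for site in range(3):
                oracle = brute_force_posterior(
                    sim.alignment, tree, model, node.id, site
                )
                assert np.abs(rec.posteriors[site] - oracle).max() < 1e-10

    def test_posteriors_normalized(self, quartet_tree, wag_gamma):
        sim = g.simulate_alignment(quartet_tree, wag_gamma, 50, seed=21)
        rec = g.marginal_posteriors(
            sim.alignment, quartet_tree, wag_gamma, quartet_tree.root.id
        )
        assert np.abs(rec.posteriors.sum(axis=1) - 1.0).max() < 1e-8
        assert np.all(rec.pp_ml >= rec.pp_alt)

    def test_leaf_node_rejected(self, quartet_tree, wag):
        sim = g.simulate_alignment(quartet_tree, wag, 5, seed=22)
        with pytest.raises(ReconstructionError):
            g.marginal_posteriors(sim.alignment, quartet_tree, wag, "leaf_A")

    def test_unrooted_tree_rejected(self, wag):
        tree = g.read_newick("(A:0.1,B:0.1,C:0.1);")
        aln = g.AminoAcidAlignment.from_sequences(["A", "B", "C"], ["M", "M", "M"])
        with pytest.raises(TreeError):
            g.marginal_posteriors(aln, tree, wag, tree.root.id)

    def test_gap_majority_flagged(self, wag):
        tree = g.read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = g.AminoAcidAlignment.from_sequences(
            ["A", "B", "C", "D"], ["M-", "M-", "MK", "M-"]
        )
        rec = g.marginal_posteriors(aln, tree, wag, tree.root.id)
        assert not rec.likely_gap[0]
        assert rec.likely_gap[1]


class TestSequences:
    def test_ml_sequence_pure(self):
        rec = make_rec([onehot("M"), onehot("M"), onehot("M")])
        assert g.ml_sequence(rec) == "MMM"

    def test_tie_broken_alphabetically(self):
        rec = make_rec([onehot("C", 0.5, "A", 0.5)])
        assert g.ml_sequence(rec) == "A"

    def test_altall_second_best_at_ambiguous_sites(self):
        rec = make_rec([onehot("S", 0.6, "P", 0.35), onehot("M", 0.95)])
        assert g.ml_sequence(rec) == "SM"
        assert g.altall_sequence(rec) == "PM"

    def test_altall_equals_ml_when_unambiguous(self):
        rec = make_rec([onehot("M", 0.95), onehot("K", 0.9)])
        assert g.altall_sequence(rec) == g.ml_sequence(rec)

    def test_altall_hamming_equals_ambiguous_count(self, quartet_tree, wag_gamma):
        sim = g.simulate_alignment(quartet_tree, wag_gamma, 300, seed=23)
        rec = g.marginal_posteriors(
            sim.alignment, quartet_tree, wag_gamma, quartet_tree.root.id
        )
        ml, alt = g.ml_sequence(rec), g.altall_sequence(rec)
        hamming = sum(a != b for a, b in zip(ml, alt))
        assert hamming == rec.n_ambiguous

    def test_bad_threshold_rejected(self):
        rec = make_rec([onehot("M", 0.9)])
        with pytest.raises(ReconstructionError):
            g.altall_sequence(rec, threshold=1.5)


class TestSummarize:
    def test_all_certain(self):
        rec = make_rec([onehot("M"), onehot("K")])
        s = g.summarize(rec)
        assert s.mean_pp == 1.0
        assert s.n_ambiguous == 0
        assert s.expected_errors == 0.0

    def test_arithmetic(self):
        rec = make_rec([onehot("M", 0.9), onehot("K", 0.7, "R", 0.25)])
        s = g.summarize(rec)
        assert abs(s.mean_pp - 0.8) < 1e-12
        assert abs(s.expected_errors - 0.4) < 1e-12
        assert s.n_ambiguous == 1
        assert abs(
            s.expected_errors - s.n_sites_included * (1 - s.mean_pp)
        ) < 1e-8

    def test_mask_restricts_sites(self):
        rec = make_rec([onehot("M", 0.9), onehot("K", 0.5, "R", 0.5)])
        s = g.summarize(rec, SiteMask((0,), 2))
        assert s.n_sites_included == 1
        assert abs(s.mean_pp - 0.9) < 1e-12
        assert s.n_ambiguous == 0

    def test_empty_mask_rejected(self):
        rec = make_rec([onehot("M", 0.9)])
        with pytest.raises(ReconstructionError):
            g.summarize(rec, SiteMask((), 1))


class TestCompareAncestors:
    def test_identical(self):
        assert g.compare_ancestors("MKV", "MKV").count == 0

    def test_two_replacements_with_sites(self):
        rs = g.compare_ancestors("MKV", "MRL")
        assert rs.count == 2
        assert rs.sites_one_based() == (2, 3)
        assert rs.replacements[0] == (1, "K", "R")

    def test_gap_sites_skipped_not_counted(self):
        rs = g.compare_ancestors("M-VK", "MRLX")
        assert rs.count == 1
        assert rs.skipped_sites == (1, 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ReconstructionError):
            g.compare_ancestors("MK", "MKV")


class TestConservedReplacements:
    @pytest.fixture
    def replacement(self):
        return g.compare_ancestors("MSV", "MPV")  # s->P at site 1 (0-based)

    def test_retained_at_90_percent(self, replacement):
        desc = g.AminoAcidAlignment.from_sequences(
            [f"d{i}" for i in range(10)], ["MPV"] * 9 + ["MSV"]
        )
        out = g.conserved_replacements(replacement, desc, {1}, 0.9)
        assert out.count == 1

    def test_dropped_at_80_percent(self, replacement):
        desc = g.AminoAcidAlignment.from_sequences(
            [f"d{i}" for i in range(10)], ["MPV"] * 8 + ["MSV"] * 2
        )
        out = g.conserved_replacements(replacement, desc, {1}, 0.9)
        assert out.count == 0

    def test_empty_region_empty_result(self, replacement):
        desc = g.AminoAcidAlignment.from_sequences(["d0"], ["MPV"])
        assert g.conserved_replacements(replacement, desc, set(), 0.9).count == 0

    def test_gaps_excluded_from_denominator(self, replacement):
        desc = g.AminoAcidAlignment.from_sequences(
            [f"d{i}" for i in range(10)], ["MPV"] * 9 + ["M-V"]
        )
        out = g.conserved_replacements(replacement, desc, {1}, 1.0)
        assert out.count == 1

    def test_coordinate_mismatch_rejected(self, replacement):
        desc = g.AminoAcidAlignment.from_sequences(["d0"], ["MP"])
        with pytest.raises(ReconstructionError):
            g.conserved_replacements(replacement, desc, {2}, 0.9)


class TestDolloGeneAge:
    @pytest.fixture
    def opisthokont_tree(self):
        # ((fungi,(filasterea,(choanos,animals))),outgroup)
        return g.read_newick(
            "((Fungi:1,(Filasterea:1,(Choanoflagellata:0.5,Animalia:0.5)"
            ":0.5):0.5):1,Outgroup:2);"
        )

    def test_single_species_origin_terminal(self, opisthokont_tree):
        age = dollo_gene_age({"Animalia": True}, opisthokont_tree)
        assert age.origin_clade == ("Animalia",)
        assert age.losses == ()

    def test_all_present_origin_at_root(self, opisthokont_tree):
        presence = {
            s: True
            for s in ["Fungi", "Filasterea", "Choanoflagellata", "Animalia", "Outgroup"]
        }
        age = dollo_gene_age(presence, opisthokont_tree)
        assert age.origin_is_root
        assert age.losses == ()

    def test_filozoan_origin(self, opisthokont_tree):
        """Present in animals, choanoflagellates and filastereans but not
        fungi: the origin falls on the Filozoa stem branch."""
        presence = {
            "Animalia": True,
            "Choanoflagellata": True,
            "Filasterea": True,
            "Fungi": False,
            "Outgroup": False,
        }
        age = dollo_gene_age(presence, opisthokont_tree)
        assert set(age.origin_clade) == {
            "Animalia",
            "Choanoflagellata",
            "Filasterea",
        }
        assert not age.origin_is_root
        assert age.losses == ()

    def test_implied_losses_are_maximal_clades(self, opisthokont_tree):
        presence = {
            "Animalia": True,
            "Choanoflagellata": False,
            "Filasterea": True,
            "Fungi": False,
            "Outgroup": False,
        }
        age = dollo_gene_age(presence, opisthokont_tree)
        assert set(age.origin_clade) == {
            "Animalia",
            "Choanoflagellata",
            "Filasterea",
        }
        assert age.losses == (("Choanoflagellata",),)

    def test_no_present_species_rejected(self, opisthokont_tree):
        with pytest.raises(ReconstructionError):
            dollo_gene_age({"Animalia": False}, opisthokont_tree)

    def test_unknown_species_rejected(self, opisthokont_tree):
        with pytest.raises(TreeError):
            dollo_gene_age({"Martian": True}, opisthokont_tree)
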