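import random

import pytest

from paralogon.dating import (UNRESOLVED, annotate_duplications,
                              classify_window, date_gene_tree,
                              family_verdict, lca_map)
from paralogon.trees import SpeciesTree, build_gene_tree, window_of_label

from conftest import random_gene_tree
from oracles import brute_duplications, brute_lca_map

VERT = SpeciesTree.from_newick(
    "(tunicate,((coelacanth,(chicken,human)Amniota)Sarcopterygii,"
    "(gar,(zebrafish,stickleback)Teleostei[wgd=3R])Actinopterygii)"
    "Gnathostomata[wgd=2R-1][wgd=2R-2])Olfactores;")


def date_map(gtree, stree=VERT, **kw):
    return {c.node_id: c for c in date_gene_tree(gtree, stree, **kw)}


class TestLcaMapping:
    def test_two_by_two_topology(self, oracle_species_tree):
        stree = oracle_species_tree
        gtree = build_gene_tree((("A|x", "B|y"), ("A|z", "B|w")))
        mapping = lca_map(gtree, stree)
        names = {nid: stree.name_of(node) for nid, node in mapping.items()}
        assert names["n0"] == "AB" and names["n1"] == "AB"
        assert names["n2"] == "AB"  # the root

    def test_single_tip_maps_to_its_species(self, oracle_species_tree):
        gtree = build_gene_tree("C|only")
        mapping = lca_map(gtree, oracle_species_tree)
        assert oracle_species_tree.name_of(mapping["only"]) == "C"

    def test_unknown_tip_species_is_a_hard_error(self, oracle_species_tree):
        gtree = build_gene_tree(("A|x", "Z|y"))
        with pytest.raises(ValueError, match="'Z'"):
            lca_map(gtree, oracle_species_tree)

    def test_matches_bruteforce_on_random_instances(self,
                                                    oracle_species_tree):
        stree = oracle_species_tree
        rng = random.Random(101)
        for _ in range(120):
            gtree = random_gene_tree(rng, ["A", "B", "C", "D", "E"],
                                     rng.randint(2, 8))
            mapping = lca_map(gtree, stree)
            expected = brute_lca_map(gtree, stree)
            got = {nid: stree.name_of(node) for nid, node in mapping.items()}
            assert got == expected

    def test_mapping_is_monotone_along_the_tree(self, oracle_species_tree):
        stree = oracle_species_tree
        rng = random.Random(5)
        gtree = random_gene_tree(rng, ["A", "B", "C", "D", "E"], 8)
        mapping = lca_map(gtree, stree)
        for node in gtree.internal_nodes():
            for child in node.child_nodes():
                assert stree.is_ancestor_or_equal(
                    mapping[gtree.id_of(node)],
                    mapping[gtree.id_of(child)])


class TestDuplicationFlags:
    def test_two_by_two_has_root_duplication_only(self, oracle_species_tree):
        stree = oracle_species_tree
        gtree = build_gene_tree((("A|x", "B|y"), ("A|z", "B|w")))
        dups = annotate_duplications(gtree, lca_map(gtree, stree), stree)
        assert set(dups) == {"n2"}

    def test_cherry_is_a_tip_branch_duplication(self, oracle_species_tree):
        stree = oracle_species_tree
        gtree = build_gene_tree(("A|x", "A|y"))
        dups = annotate_duplications(gtree, lca_map(gtree, stree), stree)
        assert {nid: stree.name_of(n) for nid, n in dups.items()} == \
            {"n0": "A"}

    def test_matches_bruteforce_on_random_instances(self,
                                                    oracle_species_tree):
        stree = oracle_species_tree
        rng = random.Random(202)
        for _ in range(120):
            gtree = random_gene_tree(rng, ["A", "B", "C", "D", "E"],
                                     rng.randint(2, 8))
            mapping = lca_map(gtree, stree)
            dups = annotate_duplications(gtree, mapping, stree)
            got = {nid: stree.name_of(n) for nid, n in dups.items()}
            assert got == brute_duplications(gtree, brute_lca_map(
                gtree, stree))

    def test_simulator_truth_recovered_exactly_without_loss(self, opsin_scenario):
        stree = opsin_scenario.species_tree
        for family, gtree in opsin_scenario.gene_trees.items():
            mapping = lca_map(gtree, stree)
            dups = annotate_duplications(gtree, mapping, stree)
            assert set(dups) == set(opsin_scenario.duplication_truth[family])


class TestWindowClassification:
    def test_vertebrate_stem_duplication_is_2R(self):
        # copies in every gnathostome, single tunicate outgroup copy
        gtree = build_gene_tree(
            ("tunicate|t",
             ((("coelacanth|c1", ("chicken|g1", "human|h1")),
               ("gar|r1", ("zebrafish|z1", "stickleback|s1"))),
              (("coelacanth|c2", ("chicken|g2", "human|h2")),
               ("gar|r2", ("zebrafish|z2", "stickleback|s2"))))))
        calls = date_map(gtree)
        assert [c.window for c in calls.values()] == ["2R"]

    def test_teleost_stem_duplication_is_3R(self):
        gtree = build_gene_tree(
            (("coelacanth|c", ("chicken|g", "human|h")),
             ("gar|r", (("zebrafish|z1", "stickleback|s1"),
                        ("zebrafish|z2", "stickleback|s2")))))
        calls = date_map(gtree)
        assert sorted(c.window for c in calls.values()) == ["3R"]

    def test_terminal_duplication_in_post_3R_taxon(self):
        gtree = build_gene_tree(
            ("gar|r", (("zebrafish|z1", "zebrafish|z2"), "stickleback|s")))
        calls = date_map(gtree)
        assert [c.window for c in calls.values()] == ["post-3R-local"]

    def test_root_duplication_without_outgroup_is_unresolved(self):
        gtree = build_gene_tree(
            ((("coelacanth|c1", "human|h1"), "gar|r1"),
             (("coelacanth|c2", "human|h2"), "gar|r2")))
        calls = date_map(gtree)
        (call,) = calls.values()
        assert call.window == UNRESOLVED
        assert "2R" in call.candidate_windows

    def test_missing_pre3R_outgroup_still_dates_3R(self):
        # the gar copy is absent: the feasible range spans the ray-finned
        # stem and the teleost stem, and only the latter carries a WGD
        gtree = build_gene_tree(
            (("coelacanth|c", "human|h"),
             (("zebrafish|z1", "stickleback|s1"),
              ("zebrafish|z2", "stickleback|s2"))))
        calls = date_map(gtree)
        dup_calls = [c for c in calls.values() if c.window != "lineage-local"]
        assert sorted(c.window for c in dup_calls) == ["3R"]

    def test_scripted_truth_windows_fully_recovered(self, opsin_scenario):
        stree = opsin_scenario.species_tree
        for family, gtree in opsin_scenario.gene_trees.items():
            calls = date_map(gtree, stree)
            for nid, event in opsin_scenario.duplication_truth[family].items():
                if not event.startswith("wgd:"):
                    continue
                want = window_of_label(event.split(":")[1])
                assert calls[nid].window == want, (family, nid, event)

    def test_collapse_never_creates_new_2R_support(self, opsin_scenario):
        rng = random.Random(77)
        stree = opsin_scenario.species_tree
        for family, gtree in opsin_scenario.gene_trees.items():
            noisy = gtree.copy()
            for node in noisy.internal_nodes():
                if node.parent_node is not None:
                    node.label = str(rng.randrange(0, 100))
            before = {c.node_id for c in date_gene_tree(noisy, stree)
                      if c.window == "2R"}
            after_calls = date_gene_tree(noisy, stree, collapse_below=50)
            if not before:
                assert not any(c.window == "2R" for c in after_calls)


class TestFamilyVerdicts:
    CALL_2R = date_gene_tree(
        build_gene_tree(
            ("tunicate|t",
             (("coelacanth|c1", "gar|r1"), ("coelacanth|c2", "gar|r2")))),
        VERT)
    NO_CALL = []

    def test_supported_by_all(self):
        v = family_verdict("fam", [self.CALL_2R, self.CALL_2R])
        assert v.per_tree == ("2R-consistent", "2R-consistent")
        assert v.aggregate == "supported-by-all"

    def test_supported_by_one(self):
        v = family_verdict("fam", [self.CALL_2R, self.NO_CALL])
        assert v.aggregate == "supported-by-one"

    def test_inconclusive(self):
        v = family_verdict("fam", [self.NO_CALL, self.NO_CALL])
        assert v.aggregate == "inconclusive"

    def test_undated_consistency_flag(self):
        # 2R-pattern quartet but no invertebrate member: root duplication
        # unresolved between the 2R window and older placements
        gtree = build_gene_tree(
            ((("coelacanth|c1", "human|h1"), "gar|r1"),
             (("coelacanth|c2", "human|h2"), "gar|r2")))
        calls = date_gene_tree(gtree, VERT)
        v = family_verdict("fam", [calls])
        assert v.aggregate == "inconclusive"
        assert v.undated_consistent
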