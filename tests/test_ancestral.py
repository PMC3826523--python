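import random

import pytest

from paralogon.ancestral import (build_lineages, dollo_reconstruct,
                                 pre_window_content, scenario_summary)
from paralogon.ancestral import SubtypeLineage
from paralogon.dating import date_gene_tree
from paralogon.loci import LocusTable
from paralogon.trees import SpeciesTree, build_gene_tree

from oracles import brute_min_loss_cover

VERT = SpeciesTree.from_newick(
    "(tunicate,((coelacanth,(chicken,human)Amniota)Sarcopterygii,"
    "(gar,(zebrafish,stickleback)Teleostei[wgd=3R])Actinopterygii)"
    "Gnathostomata[wgd=2R-1][wgd=2R-2])Olfactores;")


def lineages_for(gtree, stree=VERT, table=None):
    calls = {"fam": date_gene_tree(gtree, stree)}
    return build_lineages(calls, {"fam": gtree}, table or LocusTable(),
                          stree)


class TestLineageBuilding:
    def test_family_without_duplications_is_one_lineage(self):
        gtree = build_gene_tree(("human|a", "gar|b"))
        lineages = lineages_for(gtree)
        assert len(lineages) == 1
        assert sorted(lineages[0].members) == ["a", "b"]

    def test_partition_equals_most_recent_dated_duplication_grouping(self):
        # quartet with outgroup: tips grouped by their side of the 2R cut
        gtree = build_gene_tree(
            ("tunicate|t",
             (("coelacanth|c1", "gar|r1"), ("coelacanth|c2", "gar|r2"))))
        lineages = lineages_for(gtree)
        partitions = sorted(sorted(l.members) for l in lineages)
        assert partitions == [["c1", "r1"], ["c2", "r2"], ["t"]]
        cut = [l for l in lineages if "t" not in l.members]
        assert all(l.origin_node == "Gnathostomata" for l in cut)
        assert all(l.origin_window == "2R" for l in cut)

    def test_unresolved_duplication_absorbs_and_flags_members(self):
        # no outgroup: the root duplication is unresolved, so no cut
        gtree = build_gene_tree(
            (("coelacanth|c1", "gar|r1"), ("coelacanth|c2", "gar|r2")))
        lineages = lineages_for(gtree)
        assert len(lineages) == 1
        assert set(lineages[0].flagged_members) == {"c1", "c2", "r1", "r2"}

    def test_opsin_tree_yields_five_2R_lineages(self, opsin_scenario):
        calls = {f: date_gene_tree(t, opsin_scenario.species_tree)
                 for f, t in opsin_scenario.gene_trees.items()}
        lineages = build_lineages(calls, opsin_scenario.gene_trees,
                                  opsin_scenario.locus_table, opsin_scenario.species_tree)
        opsin_2r = [l for l in lineages
                    if l.family == "opsin" and l.origin_window == "2R"]
        assert sorted(l.subtype for l in opsin_2r) == [
            "LWS", "RH1", "RH2", "SWS1", "SWS2"]


class TestDolloReconstruction:
    def _lineage(self, subtype, origin, species, parent=None):
        return SubtypeLineage(
            lineage_id=f"fam.{subtype}", family="fam", subtype=subtype,
            origin_node=origin, origin_window="2R",
            members=tuple(f"{s}_x" for s in species),
            species=tuple(sorted(species)), parent_lineage=parent)

    def test_v1b_pattern_one_loss_on_ray_finned_stem(self):
        lin = self._lineage("V1B", "Gnathostomata",
                            ["coelacanth", "chicken", "human"])
        content, losses = dollo_reconstruct([lin], VERT)
        assert [l.branch for l in losses] == ["Actinopterygii"]
        assert losses[0].n_equally_parsimonious == 1
        assert content.count("Gnathostomata", "fam") == 1
        assert content.count("Teleostei", "fam") == 0

    def test_lineage_present_everywhere_has_no_losses(self):
        lin = self._lineage("X", "Gnathostomata",
                            ["coelacanth", "chicken", "human", "gar",
                             "zebrafish", "stickleback"])
        _content, losses = dollo_reconstruct([lin], VERT)
        assert losses == []

    def test_presence_outside_origin_clade_is_an_error(self):
        lin = self._lineage("X", "Teleostei", ["human"])
        with pytest.raises(ValueError, match="single-origin"):
            dollo_reconstruct([lin], VERT)

    def test_matches_exhaustive_minimal_branch_cover(self):
        rng = random.Random(404)
        species = ["coelacanth", "chicken", "human", "gar", "zebrafish",
                   "stickleback", "tunicate"]
        for _ in range(120):
            origin = rng.choice(["Olfactores", "Gnathostomata",
                                 "Sarcopterygii", "Actinopterygii"])
            pool = sorted(VERT.leaves_under(VERT.node(origin)))
            k = rng.randint(1, len(pool))
            present = rng.sample(pool, k)
            lin = self._lineage("X", origin, present)
            _c, losses = dollo_reconstruct([lin], VERT)
            size, covers = brute_min_loss_cover(VERT, origin, present)
            got = frozenset(l.branch for l in losses)
            assert len(got) == size
            assert got in covers

    def test_invariant_to_lineage_and_tip_order(self):
        lin_a = self._lineage("A", "Gnathostomata", ["human", "gar"])
        lin_b = self._lineage("B", "Gnathostomata",
                              ["chicken", "zebrafish"])
        c1, l1 = dollo_reconstruct([lin_a, lin_b], VERT)
        c2, l2 = dollo_reconstruct([lin_b, lin_a], VERT)
        assert c1.counts == c2.counts
        assert l1 == l2

    def test_unreliable_species_yields_uncertain_not_loss(self):
        # absence only in a flagged assembly: reported uncertain
        lin = self._lineage("RH2", "Gnathostomata",
                            ["coelacanth", "chicken", "gar", "zebrafish",
                             "stickleback"])
        _c, losses = dollo_reconstruct([lin], VERT,
                                       unreliable_species=["human"])
        assert [l.uncertain for l in losses] == [True]
        _c, hard = dollo_reconstruct([lin], VERT)
        assert [l.uncertain for l in hard] == [False]

    def test_tie_counting_around_unreliable_tips(self):
        # absent in chicken (reliable) and human (unreliable): the loss
        # may sit on the amniote stem or the chicken branch
        lin = self._lineage("X", "Gnathostomata",
                            ["coelacanth", "gar", "zebrafish",
                             "stickleback"])
        _c, losses = dollo_reconstruct([lin], VERT,
                                       unreliable_species=["human"])
        (loss,) = losses
        assert loss.n_equally_parsimonious == 2
        assert set(loss.alternatives) == {"Amniota", "chicken"}

    def test_continuation_through_descendant_lineages_is_not_loss(self):
        parent = self._lineage("RH1", "Gnathostomata",
                               ["coelacanth", "chicken", "human"])
        child = SubtypeLineage(
            lineage_id="fam.retro", family="fam", subtype="RH1",
            origin_node="Actinopterygii", origin_window="between-2R-3R",
            members=("gar_y",), species=("gar",),
            parent_lineage="fam.RH1")
        _c, losses = dollo_reconstruct([parent, child], VERT)
        branches = sorted(l.branch for l in losses)
        # the gene survives into ray-finned fishes as the retro lineage;
        # only the teleost absence of that younger lineage is a loss
        assert branches == ["Teleostei"]


class TestContentAndSummaries:
    def test_replay_equivalence_at_every_node(self, opsin_scenario):
        calls = {f: date_gene_tree(t, opsin_scenario.species_tree)
                 for f, t in opsin_scenario.gene_trees.items()}
        lineages = build_lineages(calls, opsin_scenario.gene_trees,
                                  opsin_scenario.locus_table, opsin_scenario.species_tree)
        content, _ = dollo_reconstruct(lineages, opsin_scenario.species_tree)
        families = ("opsin", "GNAT", "GNAI", "OT/VP-R", "CACNA1-L",
                    "ATP2B", "CAMK1")
        for node in ("Olfactores", "Gnathostomata", "Sarcopterygii",
                     "Amniota", "Actinopterygii", "Teleostei",
                     "human", "gar", "zebrafish", "stickleback"):
            snapshot = opsin_scenario.snapshot_counts(node)
            for family in families:
                assert content.count(node, family) == snapshot.get(
                    family, 0), (node, family)

    def test_counts_never_increase_without_new_origins(self, opsin_scenario):
        calls = {f: date_gene_tree(t, opsin_scenario.species_tree)
                 for f, t in opsin_scenario.gene_trees.items()}
        lineages = build_lineages(calls, opsin_scenario.gene_trees,
                                  opsin_scenario.locus_table, opsin_scenario.species_tree)
        content, _ = dollo_reconstruct(lineages, opsin_scenario.species_tree)
        stree = opsin_scenario.species_tree
        for family in ("opsin", "GNAT", "GNAI"):
            origins = {}
            for lin in lineages:
                if lin.family == family:
                    origins[lin.origin_node] = origins.get(
                        lin.origin_node, 0) + 1
            for node in stree.tree.preorder_node_iter():
                parent = node.parent_node
                if parent is None:
                    continue
                name = stree.name_of(node)
                allowed = (content.count(stree.name_of(parent), family)
                           + origins.get(name, 0))
                assert content.count(name, family) <= allowed

    def test_pre_window_multiplicity_from_synteny(self, opsin_results):
        assert opsin_results.repertoire("pre-2R") == {
            "opsin": 2, "GNAT": 1, "GNAI": 1, "OT/VP-R": 2, "CACNA1-L": 1,
            "ATP2B": 1, "CAMK1": 1}

    def test_summary_frame_and_unknown_node(self, opsin_results):
        frame = opsin_results.summary_frame(["Gnathostomata"],
                                              families=["opsin"])
        assert frame["count"].sum() == 5
        with pytest.raises(KeyError):
            opsin_results.summary_frame(["NotANode"])

    def test_absent_family_counts_zero(self, opsin_results):
        assert opsin_results.content.count("Gnathostomata", "TLR") == 0
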