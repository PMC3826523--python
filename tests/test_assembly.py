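import random
from itertools import combinations

import networkx as nx
import pytest

from paralogon.assembly import (assemble_paralogons, build_paralogy_graph,
                                detect_fission, detect_translocations,
                                map_orthologs, orthologs_between)
from paralogon.blocks import define_blocks
from paralogon.dating import date_gene_tree
from paralogon.loci import GeneLocus, LocusTable
from paralogon.trees import SpeciesTree, build_gene_tree

from conftest import fit_opsin_scenario, random_gene_tree
from oracles import brute_lca_map, brute_duplications, brute_ortholog_pairs

VERT = SpeciesTree.from_newick(
    "(tunicate,((coelacanth,(chicken,human)Amniota)Sarcopterygii,"
    "(gar,(zebrafish,stickleback)Teleostei[wgd=3R])Actinopterygii)"
    "Gnathostomata[wgd=2R-1][wgd=2R-2])Olfactores;")


class TestParalogyGraph:
    def test_weights_match_bruteforce_pair_count_on_toy(self):
        # three families over two human blocks; join nodes dated by hand
        table = LocusTable()
        trees = {}
        for fam, (pos1, pos2) in {
            "f1": (1_000_000, 1_000_000),
            "f2": (2_000_000, 2_000_000),
            "f3": (3_000_000, 3_000_000),
        }.items():
            table.add(GeneLocus(f"{fam}a", "human", fam, "s", "1",
                                pos1, pos1 + 1))
            table.add(GeneLocus(f"{fam}b", "human", fam, "s", "2",
                                pos2, pos2 + 1))
            # quartet with a tunicate outgroup -> the join is dated 2R
            trees[fam] = build_gene_tree(
                (f"tunicate|{fam}t",
                 (("coelacanth|" + fam + "c1", f"human|{fam}a"),
                  ("coelacanth|" + fam + "c2", f"human|{fam}b"))))
        anchors = [table.get("f1a"), table.get("f1b")]
        blocks = define_blocks(anchors, 5_000_000, table)
        calls = {f: date_gene_tree(t, VERT) for f, t in trees.items()}
        graph = build_paralogy_graph(blocks, list(trees), calls, trees,
                                     table)
        (b1, b2) = sorted(b.block_id for b in blocks)
        # brute force: count families with a 2R-joined pair spanning blocks
        expected = 0
        for fam, tree in trees.items():
            window_nodes = {c.node_id for c in calls[fam]
                            if c.window == "2R"}
            found = False
            for la in table.filter(family=fam, chromosome="1"):
                for lb in table.filter(family=fam, chromosome="2"):
                    join = tree.id_of(tree.join(la.locus_id, lb.locus_id))
                    if join in window_nodes:
                        found = True
            expected += found
        assert graph[b1][b2]["weight"] == expected == 3

    def test_single_block_graph_has_no_edges(self):
        table = LocusTable([GeneLocus("a", "human", "f", "s", "1", 0, 1)])
        blocks = define_blocks([table.get("a")], 5_000_000, table)
        graph = build_paralogy_graph(blocks, [], {}, {}, table)
        assert graph.number_of_nodes() == 1
        assert graph.number_of_edges() == 0

    def test_chicken_genome_has_four_opsin_anchored_blocks(self, opsin_scenario):
        results = fit_opsin_scenario(opsin_scenario, focal_species="chicken",
                              fission_outgroup=None,
                              rearrangement_outgroup=None)
        assert len(results.blocks) == 4
        assert len(results.main_group().block_ids) == 4

    def test_human_genome_has_five_raw_blocks_in_one_group(
            self, opsin_results):
        assert len(opsin_results.groups) == 1
        assert len(opsin_results.main_group().block_ids) == 5


class TestAssembleParalogons:
    def _demo_graph(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        g.add_edge("a", "b", weight=3)
        g.add_edge("b", "c", weight=1)
        g.add_edge("c", "d", weight=2)
        return g

    def test_min_support_above_weights_gives_singletons(self):
        groups = assemble_paralogons(self._demo_graph(), min_support=5)
        assert [g.block_ids for g in groups] == [
            ("a",), ("b",), ("c",), ("d",)]

    def test_partition_property_for_any_support(self):
        g = self._demo_graph()
        for support in (1, 2, 3, 4):
            groups = assemble_paralogons(g, support)
            blocks = [b for grp in groups for b in grp.block_ids]
            assert sorted(blocks) == sorted(g.nodes)

    def test_raising_support_only_splits_groups(self):
        g = self._demo_graph()
        previous = None
        for support in (1, 2, 3, 4):
            groups = assemble_paralogons(g, support)
            partition = {b: grp.group_id for grp in groups
                         for b in grp.block_ids}
            if previous is not None:
                # refinement: same new group -> same old group
                for x, y in combinations(sorted(partition), 2):
                    if partition[x] == partition[y]:
                        assert previous[x] == previous[y]
            previous = partition


class TestOrthologMapping:
    def test_two_by_two_quartet_pairs(self):
        gtree = build_gene_tree((("human|x", "gar|y"), ("human|z", "gar|w")))
        calls = {"fam": date_gene_tree(gtree, VERT)}
        pairs = map_orthologs({"fam": gtree}, calls)
        assert pairs == {("gar", "human"): [("y", "x"), ("w", "z")]} or \
            pairs == {("gar", "human"): sorted([("y", "x"), ("w", "z")])}

    def test_single_species_family_has_no_pairs(self):
        gtree = build_gene_tree(("human|x", "human|y"))
        calls = {"fam": date_gene_tree(gtree, VERT)}
        assert map_orthologs({"fam": gtree}, calls) == {}

    def test_matches_bruteforce_on_random_instances(self,
                                                    oracle_species_tree):
        stree = oracle_species_tree
        rng = random.Random(303)
        for _ in range(100):
            gtree = random_gene_tree(rng, ["A", "B", "C", "D", "E"],
                                     rng.randint(2, 8))
            calls = {"fam": date_gene_tree(gtree, stree)}
            pairs = map_orthologs({"fam": gtree}, calls)
            got = set()
            for (sa, sb), lst in pairs.items():
                for a, b in lst:
                    got.add(tuple(sorted([(sa, a), (sb, b)])))
            dups = brute_duplications(gtree, brute_lca_map(gtree, stree))
            assert got == brute_ortholog_pairs(gtree, set(dups))

    def test_simulator_truth_same_lineage_loci_are_orthologs(self, opsin_scenario):
        calls = {f: date_gene_tree(t, opsin_scenario.species_tree)
                 for f, t in opsin_scenario.gene_trees.items()}
        pairs = map_orthologs(opsin_scenario.gene_trees, calls)
        human_chicken = orthologs_between(pairs, "human", "chicken")
        table = opsin_scenario.locus_table
        lineage = opsin_scenario.locus_lineage
        human = [l for l in table if l.species == "human"]
        chicken = {lineage[l.locus_id]: l.locus_id for l in table
                   if l.species == "chicken"}
        for locus in human:
            lin = lineage[locus.locus_id]
            if lin in chicken:
                assert human_chicken.get(locus.locus_id) == [chicken[lin]]

    def test_co_orthology_across_3R(self, opsin_scenario):
        calls = {f: date_gene_tree(t, opsin_scenario.species_tree)
                 for f, t in opsin_scenario.gene_trees.items()}
        pairs = map_orthologs(opsin_scenario.gene_trees, calls)
        zf_gar = orthologs_between(pairs, "zebrafish", "gar")
        # both intron-less teleost rhodopsins are co-orthologs of the
        # single gar retrogene
        assert zf_gar["zebrafish_rh1r"] == ["gar_rh1r"]
        assert zf_gar["zebrafish_rh1r.3R"] == ["gar_rh1r"]


class TestFissionHealing:
    def test_human_split_block_healed_by_chicken(self, opsin_results):
        units = opsin_results.ancestral_units()
        assert len(units) == 4
        merged = [u for u in units if u.merged]
        assert len(merged) == 1
        assert set(merged[0].block_ids) == {
            b for b in opsin_results.main_group().block_ids
            if "anc1-p" in b or "anc1-q" in b}

    def test_blocks_on_different_outgroup_chromosomes_not_merged(
            self, opsin_results):
        units = opsin_results.ancestral_units()
        unmerged = [u for u in units if not u.merged]
        assert len(unmerged) == 3
        assert all(len(u.block_ids) == 1 for u in unmerged)


class TestEndToEndStochasticRecovery:
    def test_four_ancestral_units_survive_moderate_loss(self):
        """20 seeded stochastic histories (per-branch loss 0.05, up to two
        cross-unit translocations): the opsin-anchored group always
        resolves to the four ancestral paralogon units after fission
        healing in the non-teleost focal genome."""
        from paralogon.simulate import SimConfig, simulate_random

        for rep in range(20):
            ds = simulate_random(SimConfig(
                seed=5000 + rep, loss_rate=0.05,
                translocation_rate=0.3, max_translocations=2))
            results = fit_opsin_scenario(ds, synteny_override=True)
            assert len(results.ancestral_units()) == 4, rep


class TestTranslocations:
    def _pipeline(self, dataset):
        calls = {f: date_gene_tree(t, dataset.species_tree)
                 for f, t in dataset.gene_trees.items()}
        return map_orthologs(dataset.gene_trees, calls)

    def test_scripted_teleost_translocations_recovered_post_3R(self,
                                                               opsin_scenario):
        orth = self._pipeline(opsin_scenario)
        calls = detect_translocations(
            opsin_scenario.locus_table, opsin_scenario.locus_table, orth,
            "zebrafish", "gar", opsin_scenario.species_tree)
        assert len(calls) == 2
        moved = {lid for c in calls for lid in c.locus_ids}
        assert moved == {
            "zebrafish_gnat.2R-2", "zebrafish_gnai.2R-2",
            "zebrafish_atp.2R-1.2R-2", "zebrafish_camk.2R-1.2R-2"}
        assert all(c.timing == "post-3R" for c in calls)

    def test_gar_against_its_ancestor_shows_no_translocations(self,
                                                              opsin_scenario):
        ancestor = opsin_scenario.snapshot_table("Actinopterygii")
        table = LocusTable()
        for l in opsin_scenario.locus_table:
            table.add(l)
        for l in ancestor:
            table.add(l)
        # orthologs by shared lineage identity (simulator truth)
        lineage = dict(opsin_scenario.locus_lineage)
        pairs = {}
        for l in ancestor:
            lin = l.locus_id.split("_", 1)[1]
            partner = f"gar_{lin}"
            if partner in opsin_scenario.locus_table:
                key = tuple(sorted(["gar", "Actinopterygii"]))
                a, b = sorted(
                    [("gar", partner), ("Actinopterygii", l.locus_id)])
                pairs.setdefault((a[0], b[0]), []).append((a[1], b[1]))
        calls = detect_translocations(
            table, table, pairs, "gar", "Actinopterygii",
            opsin_scenario.species_tree)
        assert calls == []

    def test_outgroup_not_pre_3R_gives_unresolved_timing(self, opsin_scenario):
        orth = self._pipeline(opsin_scenario)
        calls = detect_translocations(
            opsin_scenario.locus_table, opsin_scenario.locus_table, orth,
            "stickleback", "zebrafish", opsin_scenario.species_tree)
        assert all(c.timing == "unresolved" for c in calls)
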