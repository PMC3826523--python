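"""Model/Results facade tying the pipeline stages together.

``ParalogonModel`` is built from the three inputs of the analysis — a
locus table, one (or several, e.g. NJ and ML) rooted gene trees per
family, and a species tree with WGD placements — plus the tuning
parameters.  ``fit()`` runs block construction, neighboring-family
selection, duplication dating, paralogon assembly (with fission healing
and translocation timing against outgroups) and Dollo reconstruction,
returning a :class:`ParalogonResults` carrying every intermediate table
and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from . import ancestral, assembly, blocks as blocks_mod, dating
from .blocks import ChromosomeBlock, DEFAULT_WINDOW, FamilyProfile
from .loci import LocusTable
from .trees import GeneTree, SpeciesTree

log = logging.getLogger(__name__)

TreeInput = Union[GeneTree, Sequence[GeneTree]]


class ParalogonModel:
    """End-to-end paralogon analysis of one locus table.

    Parameters
    ----------
    locus_table : LocusTable
        Gene coordinates with family/subtype assignments for all species.
    gene_trees : mapping family -> GeneTree or sequence of GeneTree
        Rooted per-family trees; when several are given per family (e.g.
        alternative inferences) the first is used for orthology and
        synteny and all are polled for the family verdict.
    species_tree : SpeciesTree
        Rooted species tree with WGD placements.
    anchor_families : families whose loci seed the chromosome blocks
        (default: every family with a tree).
    focal_species : genome in which blocks and the paralogon are built
        (default: first species of the table).
    fission_outgroup : species used to heal lineage-specific fissions.
    rearrangement_outgroup : pre-WGD species against which derived
        genomes are screened for translocations.
    derived_species : genomes screened for translocations (default: all
        species descending from the most recent WGD).
    """

    def __init__(
        self,
        locus_table: LocusTable,
        gene_trees: Mapping[str, TreeInput],
        species_tree: SpeciesTree,
        *,
        anchor_families: Optional[Sequence[str]] = None,
        focal_species: Optional[str] = None,
        fission_outgroup: Optional[str] = None,
        rearrangement_outgroup: Optional[str] = None,
        derived_species: Optional[Sequence[str]] = None,
        window: int = DEFAULT_WINDOW,
        min_blocks: int = 2,
        min_support: int = 2,
        min_run: int = 2,
        max_family_members: Optional[int] = 200,
        collapse_below: Optional[float] = None,
        dating_window: str = "2R",
        unreliable_species: Sequence[str] = (),
        merge_blocks: bool = True,
        synteny_override: bool = False,
    ) -> None:
        self.table = locus_table
        self.gene_trees: Dict[str, List[GeneTree]] = {}
        for family, trees in gene_trees.items():
            if isinstance(trees, GeneTree):
                self.gene_trees[family] = [trees]
            else:
                self.gene_trees[family] = list(trees)
        self.stree = species_tree
        self.anchor_families = list(anchor_families
                                    if anchor_families is not None
                                    else sorted(self.gene_trees))
        species = locus_table.species
        if not species:
            raise ValueError("empty locus table")
        self.focal_species = focal_species or species[0]
        self.fission_outgroup = fission_outgroup
        self.rearrangement_outgroup = rearrangement_outgroup
        if derived_species is None and rearrangement_outgroup is not None:
            windows = species_tree.windows
            if windows:
                last = max(windows.values(), key=species_tree.depth)
                derived_species = sorted(
                    sp for sp in species
                    if species_tree.is_ancestor_or_equal(
                        last, species_tree.node(sp))
                )
            else:
                derived_species = []
        self.derived_species = list(derived_species or [])
        self.window = window
        self.min_blocks = min_blocks
        self.min_support = min_support
        self.min_run = min_run
        self.max_family_members = max_family_members
        self.collapse_below = collapse_below
        self.dating_window = dating_window
        self.unreliable_species = tuple(unreliable_species)
        self.merge_blocks = merge_blocks
        self.synteny_override = synteny_override

    @classmethod
    def from_simulation(cls, dataset, **kwargs) -> "ParalogonModel":
        """Build the model from a :class:`SimulatedDataset`."""
        trees: Dict[str, TreeInput] = dict(dataset.gene_trees)
        if dataset.perturbed_trees:
            trees = {
                fam: [tree] + ([dataset.perturbed_trees[fam]]
                               if fam in dataset.perturbed_trees else [])
                for fam, tree in dataset.gene_trees.items()
            }
        return cls(dataset.locus_table, trees, dataset.species_tree, **kwargs)

    # -----------------------------------------------------------------

    def fit(self) -> "ParalogonResults":
        table, stree = self.table, self.stree
        primary = {f: trees[0] for f, trees in self.gene_trees.items()}

        # 1. blocks around each anchor family, selections pooled
        per_family_blocks: Dict[str, List[ChromosomeBlock]] = {}
        selections: List[List[str]] = []
        profiles: Dict[str, FamilyProfile] = {}
        for family in self.anchor_families:
            anchors = list(table.filter(species=self.focal_species,
                                        family=family))
            if not anchors:
                log.info("no anchors for family %r in %s",
                         family, self.focal_species)
                continue
            fam_blocks = blocks_mod.define_blocks(
                anchors, self.window, table, merge=self.merge_blocks)
            per_family_blocks[family] = fam_blocks
            profile = blocks_mod.profile_families(fam_blocks, table)
            profiles[family] = profile
            selections.append(blocks_mod.select_families(
                profile, self.min_blocks, self.max_family_members))
        selected = blocks_mod.pool_selections(selections)

        # combined focal block set (one merged set over all anchors)
        all_anchors = [
            a for family in self.anchor_families
            for a in table.filter(species=self.focal_species, family=family)
        ]
        focal_blocks = blocks_mod.define_blocks(
            all_anchors, self.window, table, merge=self.merge_blocks)

        # 2. duplication dating and verdicts
        dated_families = sorted(
            (set(selected) | set(self.anchor_families)) & set(self.gene_trees)
        )
        calls: Dict[str, List[dating.DuplicationCall]] = {}
        verdicts: Dict[str, dating.FamilyVerdict] = {}
        for family in dated_families:
            per_tree = [
                dating.date_gene_tree(
                    tree, stree, self.collapse_below,
                    synteny_table=table if self.synteny_override else None)
                for tree in self.gene_trees[family]
            ]
            calls[family] = per_tree[0]
            verdicts[family] = dating.family_verdict(
                family, per_tree, self.dating_window)

        # 3. paralogy graph and groups in the focal genome
        graph = assembly.build_paralogy_graph(
            focal_blocks, dated_families, calls, primary, table,
            self.dating_window)
        groups = assembly.assemble_paralogons(graph, self.min_support)

        # 4. tree-based orthologs (dated families only)
        dated_trees = {f: primary[f] for f in dated_families}
        orthologs = assembly.map_orthologs(dated_trees, calls)

        # 5. fission healing -> ancestral units
        blocks_by_id = {b.block_id: b for b in focal_blocks}
        units: Dict[str, List[assembly.AncestralUnit]] = {}
        if self.fission_outgroup is not None:
            for group in groups:
                units[group.group_id] = assembly.detect_fission(
                    group, blocks_by_id, table, table, orthologs,
                    self.fission_outgroup, self.min_support)

        # 6. translocation screening of derived genomes
        translocations: List[assembly.TranslocationCall] = []
        if self.rearrangement_outgroup is not None:
            for sp in self.derived_species:
                translocations.extend(assembly.detect_translocations(
                    table, table, orthologs, sp,
                    self.rearrangement_outgroup, stree,
                    min_run=self.min_run))

        # 7. lineages, Dollo content, pre-window repertoire
        lineages = ancestral.build_lineages(calls, dated_trees, table, stree)
        content, losses = ancestral.dollo_reconstruct(
            lineages, stree, self.unreliable_species)
        pre = ancestral.pre_window_content(
            lineages, focal_blocks, table, stree, self.dating_window)
        for family, n in sorted(pre.items()):
            content.add(f"pre-{self.dating_window}", family, "unassigned", n)

        return ParalogonResults(
            model=self,
            blocks=focal_blocks,
            per_family_blocks=per_family_blocks,
            profiles=profiles,
            selected_families=selected,
            calls=calls,
            verdicts=verdicts,
            graph=graph,
            groups=groups,
            units=units,
            orthologs=orthologs,
            translocations=translocations,
            lineages=lineages,
            content=content,
            losses=losses,
        )


@dataclass
class ParalogonResults:
    """Everything :meth:`ParalogonModel.fit` inferred."""

    model: ParalogonModel
    blocks: List[ChromosomeBlock]
    per_family_blocks: Dict[str, List[ChromosomeBlock]]
    profiles: Dict[str, FamilyProfile]
    selected_families: List[str]
    calls: Dict[str, List[dating.DuplicationCall]]
    verdicts: Dict[str, dating.FamilyVerdict]
    graph: object
    groups: List[assembly.ParalogonGroup]
    units: Dict[str, List[assembly.AncestralUnit]]
    orthologs: assembly.OrthologPairs
    translocations: List[assembly.TranslocationCall]
    lineages: List[ancestral.SubtypeLineage]
    content: ancestral.AncestralContent
    losses: List[ancestral.LossPlacement]

    # -- convenience queries ----------------------------------------------

    def repertoire(self, node: str) -> Dict[str, int]:
        return self.content.family_counts(node)

    def subtype_count(self, node: str, family: str, subtype: str) -> int:
        return self.content.count(node, family, subtype)

    def main_group(self) -> assembly.ParalogonGroup:
        """The paralogon group containing the most blocks (ties: first)."""
        if not self.groups:
            raise ValueError("no paralogon groups")
        return max(self.groups, key=lambda g: (len(g.block_ids),
                                               g.block_ids))

    def ancestral_units(self,
                        group: Optional[assembly.ParalogonGroup] = None
                        ) -> List[assembly.AncestralUnit]:
        group = group or self.main_group()
        return self.units.get(group.group_id, [
            assembly.AncestralUnit(unit_id=f"{b}:unit", block_ids=(b,))
            for b in group.block_ids
        ])

    def summary_frame(self, nodes: Sequence[str],
                      families: Optional[Sequence[str]] = None):
        return ancestral.scenario_summary(self.content, nodes, families)

    def summary(self, nodes: Optional[Sequence[str]] = None) -> str:
        model = self.model
        lines = []
        push = lines.append
        push("Paralogon analysis results")
        push("=" * 60)
        push(f"focal genome:        {model.focal_species}")
        push(f"block window:        +-{model.window / 1e6:g} Mb, "
             f"min_blocks={model.min_blocks}, min_support={model.min_support}")
        push(f"chromosome blocks:   {len(self.blocks)}")
        push(f"selected families:   {len(self.selected_families)} "
             f"({', '.join(self.selected_families)})")
        tally: Dict[str, int] = {}
        for verdict in self.verdicts.values():
            tally[verdict.aggregate] = tally.get(verdict.aggregate, 0) + 1
        n_supported = (tally.get("supported-by-all", 0)
                       + tally.get("supported-by-one", 0))
        push(f"{model.dating_window}-window support: "
             f"{n_supported}/{len(self.verdicts)} families "
             f"(all trees: {tally.get('supported-by-all', 0)}, "
             f"one tree: {tally.get('supported-by-one', 0)})")
        for group in self.groups:
            units = self.units.get(group.group_id)
            extra = f" -> {len(units)} ancestral units" if units else ""
            push(f"paralogon {group.group_id}: "
                 f"{len(group.block_ids)} blocks "
                 f"({', '.join(group.block_ids)}){extra}")
        if self.translocations:
            push(f"translocations:      {len(self.translocations)}")
            for call in self.translocations:
                push(f"  {call.species} {call.chromosome}: "
                     f"{len(call.locus_ids)} loci from {call.source_unit} "
                     f"({call.timing})")
        else:
            push("translocations:      none detected")
        if nodes is None:
            nodes = [f"pre-{model.dating_window}"]
            win = model.dating_window
            if win in model.stree.windows:
                nodes.append(model.stree.name_of(model.stree.windows[win]))
        push("ancestral repertoires:")
        for node in nodes:
            if node not in self.content.counts:
                continue
            counts = self.content.family_counts(node)
            body = ", ".join(f"{fam}:{n}" for fam, n in sorted(counts.items()))
            push(f"  {node}: {body}")
        push(f"gene losses placed:  "
             f"{sum(not l.uncertain for l in self.losses)}")
        return "\n".join(lines)
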