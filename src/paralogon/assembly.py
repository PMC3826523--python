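"""Paralogon assembly: paralogous blocks, fissions and translocations.

Blocks of one genome are linked by the number of gene families that
contribute a WGD-dated paralog pair spanning them; connected components
of the resulting weighted graph (above a support threshold) are the
paralogon groups.  Lineage-specific chromosome fissions are healed by an
outgroup: two same-species blocks whose genes' orthologs co-locate on a
single outgroup chromosome represent one ancestral unit.  Rearrangements
are detected and timed against an outgroup that diverged before the most
recent WGD: a run of genes sitting on a chromosome dominated by a
different ancestral unit than their orthologs indicate was translocated,
and if the pre-WGD outgroup shows the intact arrangement the
translocation postdates the WGD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .blocks import ChromosomeBlock, assign_loci_to_blocks
from .dating import DuplicationCall
from .loci import GeneLocus, LocusTable
from .trees import GeneTree, SpeciesTree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParalogonGroup:
    group_id: str
    block_ids: Tuple[str, ...]
    support: Tuple[Tuple[str, str, int], ...]  # (block_a, block_b, n families)


@dataclass(frozen=True)
class AncestralUnit:
    unit_id: str
    block_ids: Tuple[str, ...]
    outgroup_chromosome: Optional[str] = None
    merged: bool = False
    flagged: bool = False          # no ortholog evidence available


@dataclass(frozen=True)
class TranslocationCall:
    species: str
    chromosome: str
    locus_ids: Tuple[str, ...]
    source_unit: str
    dominant_unit: str
    timing: str                    # post-<window> / unresolved


OrthologPairs = Dict[Tuple[str, str], List[Tuple[str, str]]]


def build_paralogy_graph(
    blocks: Sequence[ChromosomeBlock],
    selected_families: Sequence[str],
    calls: Mapping[str, Sequence[DuplicationCall]],
    gtrees: Mapping[str, GeneTree],
    table: LocusTable,
    window: str = "2R",
) -> nx.Graph:
    """Weighted block graph of one species.

    Edge weight (b1, b2) = number of selected families contributing at
    least one pair of loci, one in each block, whose gene-tree join node
    is a duplication dated to ``window``.
    """
    graph = nx.Graph()
    for block in blocks:
        graph.add_node(block.block_id)
    loci_by_block = assign_loci_to_blocks(blocks, table)
    for family in sorted(selected_families):
        gtree = gtrees.get(family)
        if gtree is None:
            log.warning("family %r has no gene tree; skipped", family)
            continue
        window_nodes = {
            c.node_id for c in calls.get(family, ()) if c.window == window
        }
        if not window_nodes:
            continue
        fam_by_block: Dict[str, List[GeneLocus]] = {}
        for block_id, loci in loci_by_block.items():
            members = [l for l in loci
                       if l.family == family and gtree.has_tip(l.locus_id)]
            if members:
                fam_by_block[block_id] = members
        block_ids = sorted(fam_by_block)
        for i in range(len(block_ids)):
            for j in range(i + 1, len(block_ids)):
                b1, b2 = block_ids[i], block_ids[j]
                if _has_window_pair(gtree, fam_by_block[b1],
                                    fam_by_block[b2], window_nodes):
                    w = graph.get_edge_data(b1, b2, {"weight": 0})["weight"]
                    graph.add_edge(b1, b2, weight=w + 1)
    return graph


def _has_window_pair(gtree, loci_a, loci_b, window_nodes) -> bool:
    for la in loci_a:
        for lb in loci_b:
            if la.locus_id == lb.locus_id:
                continue
            join = gtree.join(la.locus_id, lb.locus_id)
            if gtree.id_of(join) in window_nodes:
                return True
    return False


def assemble_paralogons(
    graph: nx.Graph, min_support: int = 2
) -> List[ParalogonGroup]:
    """Connected components after dropping edges below ``min_support``."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    pruned = nx.Graph()
    pruned.add_nodes_from(graph.nodes)
    kept_edges = [
        (a, b, d["weight"]) for a, b, d in graph.edges(data=True)
        if d["weight"] >= min_support
    ]
    pruned.add_edges_from((a, b) for a, b, _ in kept_edges)
    groups = []
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(pruned)),
        key=lambda c: c[0],
    )
    for k, comp in enumerate(components):
        support = tuple(
            sorted((a, b, w) for a, b, w in kept_edges
                   if a in comp and b in comp)
        )
        groups.append(ParalogonGroup(
            group_id=f"group{k}",
            block_ids=tuple(comp),
            support=support,
        ))
    return groups


def map_orthologs(
    gtrees: Mapping[str, GeneTree],
    calls: Mapping[str, Sequence[DuplicationCall]],
) -> OrthologPairs:
    """Cross-species ortholog pairs: tips whose join node is a speciation.

    Tree-based orthology: two loci from different species are orthologs
    exactly when no duplication separates them, i.e. their most recent
    common ancestor in the gene tree is not a flagged duplication node.
    Pairs are emitted per (species_a, species_b) with species_a < species_b.
    """
    pairs: OrthologPairs = {}
    for family in sorted(gtrees):
        gtree = gtrees[family]
        dup_nodes = {c.node_id for c in calls.get(family, ())}
        tips = gtree.tip_locus_ids
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                a, b = tips[i], tips[j]
                sp_a, sp_b = gtree.species_of_tip(a), gtree.species_of_tip(b)
                if sp_a == sp_b:
                    continue
                join = gtree.join(a, b)
                if gtree.id_of(join) in dup_nodes:
                    continue
                if sp_a > sp_b:
                    sp_a, sp_b, a, b = sp_b, sp_a, b, a
                pairs.setdefault((sp_a, sp_b), []).append((a, b))
    for key in pairs:
        pairs[key].sort()
    return pairs


def orthologs_between(
    pairs: OrthologPairs, species_a: str, species_b: str
) -> Dict[str, List[str]]:
    """locus id in species_a -> ortholog locus ids in species_b."""
    out: Dict[str, List[str]] = {}
    if species_a <= species_b:
        for a, b in pairs.get((species_a, species_b), ()):
            out.setdefault(a, []).append(b)
    else:
        for b, a in pairs.get((species_b, species_a), ()):
            out.setdefault(a, []).append(b)
    return out


def detect_fission(
    group: ParalogonGroup,
    blocks: Mapping[str, ChromosomeBlock],
    table: LocusTable,
    outgroup_table: LocusTable,
    ortholog_pairs: OrthologPairs,
    outgroup_species: str,
    min_support: int = 2,
) -> List[AncestralUnit]:
    """Merge same-species blocks that one outgroup chromosome spans.

    Each block is assigned the outgroup chromosome holding the strict
    majority of its genes' orthologs (requiring at least ``min_support``
    mapped genes); blocks sharing that chromosome are one ancestral unit
    split by a lineage-specific fission.  Blocks without ortholog
    evidence stay unmerged and are flagged.
    """
    group_blocks = [blocks[b] for b in group.block_ids]
    if not group_blocks:
        return []
    species = group_blocks[0].species
    ortho = orthologs_between(ortholog_pairs, species, outgroup_species)
    loci_by_block = assign_loci_to_blocks(group_blocks, table)
    dominant: Dict[str, Optional[str]] = {}
    for block in group_blocks:
        tally: Dict[str, int] = {}
        mapped = 0
        for locus in loci_by_block[block.block_id]:
            for partner in ortho.get(locus.locus_id, ()):
                if partner in outgroup_table:
                    chrom = outgroup_table.get(partner).chromosome
                    tally[chrom] = tally.get(chrom, 0) + 1
                    mapped += 1
        best: Optional[str] = None
        if tally:
            top = max(tally.values())
            leaders = [c for c, n in tally.items() if n == top]
            if len(leaders) == 1 and top >= min_support and 2 * top > mapped:
                best = leaders[0]
        dominant[block.block_id] = best
        if best is None:
            log.warning("block %s: no dominant outgroup chromosome; unmerged",
                        block.block_id)
    by_chrom: Dict[str, List[str]] = {}
    for block_id, chrom in dominant.items():
        if chrom is not None:
            by_chrom.setdefault(chrom, []).append(block_id)
    units: List[AncestralUnit] = []
    k = 0
    used: Set[str] = set()
    for chrom in sorted(by_chrom):
        members = tuple(sorted(by_chrom[chrom]))
        units.append(AncestralUnit(
            unit_id=f"{species}:unit{k}",
            block_ids=members,
            outgroup_chromosome=chrom,
            merged=len(members) > 1,
        ))
        used.update(members)
        k += 1
    for block_id in sorted(set(group.block_ids) - used):
        units.append(AncestralUnit(
            unit_id=f"{species}:unit{k}",
            block_ids=(block_id,),
            flagged=True,
        ))
        k += 1
    return units


def detect_translocations(
    derived: LocusTable,
    outgroup: LocusTable,
    ortholog_pairs: OrthologPairs,
    derived_species: str,
    outgroup_species: str,
    stree: SpeciesTree,
    units: Optional[Mapping[str, str]] = None,
    min_run: int = 2,
) -> List[TranslocationCall]:
    """Call runs of genes moved between paralogous regions.

    Every derived locus is projected onto the ancestral arrangement via
    its outgroup orthologs (``units`` optionally renames outgroup
    chromosomes to ancestral-unit ids; by default each outgroup
    chromosome is its own unit, the outgroup being taken as
    rearrangement-free for these regions).  On each derived chromosome
    the dominant unit is the strict majority among projected loci (tie:
    chromosome skipped); every maximal run of at least ``min_run``
    consecutive projected loci from a different unit is a translocation.
    Timing is ``post-<window>`` when the outgroup diverged before the
    most recent WGD window and the derived species went through it,
    otherwise ``unresolved`` (with a warning).
    """
    timing = "unresolved"
    if stree.windows:
        last = max(stree.windows.values(), key=stree.depth)
        window_name = next(
            w for w, n in stree.windows.items() if n is last
        )
        out_node = stree.node(outgroup_species)
        der_node = stree.node(derived_species)
        if (not stree.is_ancestor_or_equal(last, out_node)
                and stree.is_ancestor_or_equal(last, der_node)):
            timing = f"post-{window_name}"
    if timing == "unresolved":
        log.warning(
            "outgroup %r does not predate the most recent WGD relative to "
            "%r; translocation timing unresolved",
            outgroup_species, derived_species,
        )

    ortho = orthologs_between(ortholog_pairs, derived_species,
                              outgroup_species)

    def unit_of(locus: GeneLocus) -> Optional[str]:
        chroms = set()
        for partner in ortho.get(locus.locus_id, ()):
            if partner in outgroup:
                chroms.add(outgroup.get(partner).chromosome)
        if len(chroms) != 1:
            return None
        chrom = chroms.pop()
        return units.get(chrom, chrom) if units else chrom

    calls: List[TranslocationCall] = []
    derived_loci = [l for l in derived.sorted_loci()
                    if l.species == derived_species]
    by_chrom: Dict[str, List[GeneLocus]] = {}
    for locus in derived_loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom in sorted(by_chrom):
        projected = [
            (locus, unit_of(locus)) for locus in by_chrom[chrom]
        ]
        assigned = [(l, u) for l, u in projected if u is not None]
        if not assigned:
            continue
        tally: Dict[str, int] = {}
        for _l, u in assigned:
            tally[u] = tally.get(u, 0) + 1
        top = max(tally.values())
        leaders = [u for u, n in tally.items() if n == top]
        if len(leaders) != 1 or 2 * top <= len(assigned):
            log.warning("chromosome (%s, %s): no dominant ancestral unit",
                        derived_species, chrom)
            continue
        dominant = leaders[0]
        run: List[GeneLocus] = []
        run_unit: Optional[str] = None

        def flush() -> None:
            if run_unit is not None and len(run) >= min_run:
                calls.append(TranslocationCall(
                    species=derived_species,
                    chromosome=chrom,
                    locus_ids=tuple(l.locus_id for l in run),
                    source_unit=run_unit,
                    dominant_unit=dominant,
                    timing=timing,
                ))

        for locus, unit in assigned:
            if unit == run_unit:
                run.append(locus)
            else:
                flush()
                run = [locus]
                run_unit = unit if unit != dominant else None
                if run_unit is None:
                    run = []
        flush()
    calls.sort(key=lambda c: (c.species, c.chromosome, c.locus_ids))
    return calls
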