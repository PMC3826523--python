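"""Dollo reconstruction of ancestral gene repertoires.

Cutting each gene tree at its dated duplication nodes yields *subtype
lineages*: maximal groups of extant loci separated by no dated
duplication.  Under single-origin (Dollo) parsimony a lineage arises once
at its dated origin, is present on every species-tree path from there to
a surviving member, and is lost on the minimal set of branches covering
its absences.  Aggregating lineages per node gives the ancestral
repertoire; tips flagged as assembly-unreliable are treated as missing
data rather than evidence of loss.

Gene-tree topology cannot separate a local duplication that immediately
precedes a WGD window from the window itself (both reconcile to the same
species node), so the *pre*-window repertoire is inferred from synteny:
lineages of one family that co-occur in a single chromosome block of a
post-WGD genome must descend from distinct pre-window genes, because
co-duplicated copies land on different paralogous blocks.  The
pre-window multiplicity of a family is therefore the maximum number of
its window-dated lineages found together in one block (plus any lineage
that predates the window and survives through it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .blocks import ChromosomeBlock
from .dating import DuplicationCall, lca_map
from .loci import LocusTable
from .trees import GeneTree, SpeciesTree

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubtypeLineage:
    lineage_id: str
    family: str
    subtype: str
    origin_node: str
    origin_window: str            # window label of the generating duplication
    members: Tuple[str, ...]      # locus ids
    species: Tuple[str, ...]
    flagged_members: Tuple[str, ...] = ()  # absorbed through unresolved nodes
    parent_lineage: Optional[str] = None   # lineage this one was cut from


@dataclass(frozen=True)
class LossPlacement:
    lineage_id: str
    family: str
    branch: str                   # child-end node name of the loss branch
    n_equally_parsimonious: int = 1
    alternatives: Tuple[str, ...] = ()
    uncertain: bool = False       # subtree absence only in unreliable tips


class AncestralContent:
    """node name -> (family, subtype) -> inferred lineage count."""

    def __init__(self) -> None:
        self.counts: Dict[str, Dict[Tuple[str, str], int]] = {}

    def add(self, node: str, family: str, subtype: str, n: int = 1) -> None:
        per = self.counts.setdefault(node, {})
        per[(family, subtype)] = per.get((family, subtype), 0) + n

    def nodes(self) -> List[str]:
        return sorted(self.counts)

    def family_counts(self, node: str) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for (family, _subtype), n in self.counts.get(node, {}).items():
            out[family] = out.get(family, 0) + n
        return out

    def count(self, node: str, family: str,
              subtype: Optional[str] = None) -> int:
        if subtype is None:
            return self.family_counts(node).get(family, 0)
        return self.counts.get(node, {}).get((family, subtype.upper()), 0)


def build_lineages(
    calls: Mapping[str, Sequence[DuplicationCall]],
    gtrees: Mapping[str, GeneTree],
    table: LocusTable,
    stree: SpeciesTree,
) -> List[SubtypeLineage]:
    """Cut each gene tree at its resolved dated duplications.

    Loci whose path to the root crosses only unresolved duplications are
    absorbed into the nearest resolved lineage and flagged.
    """
    lineages: List[SubtypeLineage] = []
    for family in sorted(gtrees):
        gtree = gtrees[family]
        mapping = lca_map(gtree, stree)
        fam_calls = {c.node_id: c for c in calls.get(family, ())}
        root = gtree.root
        # component id -> (origin node name, origin window)
        comp_origin: Dict[int, Tuple[str, str]] = {}
        comp_members: Dict[int, List[str]] = {}
        comp_flagged: Dict[int, List[str]] = {}
        node_comp: Dict[int, int] = {}
        next_comp = [0]

        def new_comp(origin_node: str, window: str) -> int:
            cid = next_comp[0]
            next_comp[0] += 1
            comp_origin[cid] = (origin_node, window)
            comp_members[cid] = []
            comp_flagged[cid] = []
            return cid

        comp_parent: Dict[int, int] = {}
        root_origin = stree.name_of(mapping[gtree.id_of(root)])
        node_comp[id(root)] = new_comp(root_origin, "origin")
        unresolved_above: Dict[int, bool] = {id(root): False}
        for node in gtree.tree.preorder_node_iter():
            cid = node_comp[id(node)]
            nid = gtree.id_of(node)
            call = fam_calls.get(nid)
            for child in node.child_nodes():
                if call is not None and call.is_resolved:
                    child_cid = new_comp(call.species_node, call.window)
                    comp_parent[child_cid] = cid
                    unresolved_above[id(child)] = False
                else:
                    child_cid = cid
                    unresolved_above[id(child)] = (
                        unresolved_above[id(node)] or call is not None
                    )
                node_comp[id(child)] = child_cid
            if node.is_leaf():
                comp_members[cid].append(nid)
                if unresolved_above[id(node)]:
                    comp_flagged[cid].append(nid)
                    log.info(
                        "locus %s absorbed through an unresolved duplication",
                        nid,
                    )

        populated = {cid for cid, members in comp_members.items() if members}

        def nearest_populated_ancestor(cid: int) -> Optional[int]:
            parent = comp_parent.get(cid)
            while parent is not None:
                if parent in populated:
                    return parent
                parent = comp_parent.get(parent)
            return None

        for cid in sorted(comp_members):
            members = sorted(comp_members[cid])
            if not members:
                continue
            parent_cid = nearest_populated_ancestor(cid)
            origin_node, window = comp_origin[cid]
            subtypes = []
            species = set()
            for locus_id in members:
                species.add(gtree.species_of_tip(locus_id))
                if locus_id in table:
                    subtypes.append(table.get(locus_id).subtype)
            subtype = "unassigned"
            if subtypes:
                tally: Dict[str, int] = {}
                for s in subtypes:
                    tally[s] = tally.get(s, 0) + 1
                subtype = min(tally, key=lambda s: (-tally[s], s))
            lineages.append(SubtypeLineage(
                lineage_id=f"{family}.{cid}",
                family=family,
                subtype=subtype,
                origin_node=origin_node,
                origin_window=window,
                members=tuple(members),
                species=tuple(sorted(species)),
                flagged_members=tuple(sorted(comp_flagged[cid])),
                parent_lineage=(f"{family}.{parent_cid}"
                                if parent_cid is not None else None),
            ))
    return lineages


def dollo_reconstruct(
    lineages: Sequence[SubtypeLineage],
    stree: SpeciesTree,
    unreliable_species: Iterable[str] = (),
) -> Tuple[AncestralContent, List[LossPlacement]]:
    """Place each lineage on the species tree and infer losses.

    A lineage is present at its origin node and on every node of the
    paths to its surviving species; the minimal covering loss set places
    one loss at the top of each absent subtree hanging off a present
    node.  Loss placement is continuation-aware: a subtree where the
    gene survives as a younger cut lineage (a descendant duplication's
    products) is no loss of the parent lineage.  Subtrees whose only
    absences are in assembly-unreliable species are reported as
    ``uncertain`` instead of as losses.  Ties among equally parsimonious
    placements (possible only around unreliable tips) are enumerated.
    """
    unreliable = set(unreliable_species)
    content = AncestralContent()
    losses: List[LossPlacement] = []
    by_id = {l.lineage_id: l for l in lineages}
    continued: Dict[str, Set[str]] = {l.lineage_id: set() for l in lineages}
    for lineage in lineages:
        parent = lineage.parent_lineage
        while parent is not None:
            continued[parent].update(lineage.species)
            parent = by_id[parent].parent_lineage if parent in by_id else None
    for lineage in lineages:
        origin = stree.node(lineage.origin_node)
        origin_leaves = stree.leaves_under(origin)
        outside = set(lineage.species) - origin_leaves
        if outside:
            raise ValueError(
                f"lineage {lineage.lineage_id!r}: member species {sorted(outside)} "
                f"fall outside the clade of origin node {lineage.origin_node!r} "
                "(single-origin violation)"
            )
        present: Set[int] = set()
        for sp in lineage.species:
            node = stree.node(sp)
            while True:
                present.add(id(node))
                if node is origin:
                    break
                node = node.parent_node
        for nid_node in _subtree_nodes(origin):
            if id(nid_node) in present:
                content.add(stree.name_of(nid_node), lineage.family,
                            lineage.subtype)
        # paths along which the gene survives as a younger cut lineage
        alive = set(present)
        for sp in continued[lineage.lineage_id] & origin_leaves:
            node = stree.node(sp)
            while True:
                alive.add(id(node))
                if node is origin:
                    break
                node = node.parent_node
        # losses: maximal absent subtrees under nodes where this lineage
        # itself survives; subtrees where the gene survives only as a
        # younger cut lineage belong to that lineage's accounting
        stack = [origin] if id(origin) in present else []
        while stack:
            node = stack.pop()
            for child in node.child_nodes():
                if id(child) in present:
                    stack.append(child)
                    continue
                if id(child) in alive:
                    continue
                tips = stree.leaves_under(child)
                reliable_absent = sorted(tips - unreliable)
                if not reliable_absent:
                    losses.append(LossPlacement(
                        lineage_id=lineage.lineage_id,
                        family=lineage.family,
                        branch=stree.name_of(child),
                        uncertain=True,
                    ))
                    continue
                anchor = stree.mrca_of_species(reliable_absent)
                alternatives = [
                    stree.name_of(n) for n in stree.path_up(anchor, child)
                ]
                losses.append(LossPlacement(
                    lineage_id=lineage.lineage_id,
                    family=lineage.family,
                    branch=stree.name_of(child),
                    n_equally_parsimonious=len(alternatives),
                    alternatives=tuple(sorted(alternatives)),
                ))
    losses.sort(key=lambda l: (l.family, l.lineage_id, l.branch))
    return content, losses


def _subtree_nodes(node):
    stack = [node]
    while stack:
        current = stack.pop()
        yield current
        stack.extend(current.child_nodes())


def pre_window_content(
    lineages: Sequence[SubtypeLineage],
    focal_blocks: Sequence[ChromosomeBlock],
    table: LocusTable,
    stree: SpeciesTree,
    window: str = "2R",
) -> Dict[str, int]:
    """Infer per-family gene counts just before a WGD window from synteny.

    See the module docstring: block co-occurrence of window-dated
    lineages reveals pre-window multiplicity.  Families with window-dated
    lineages but no representation in the focal blocks are reported with
    the minimum of one ancestral gene.
    """
    window_node = stree.window_node(window)
    out: Dict[str, int] = {}
    families = sorted({l.family for l in lineages})
    for family in families:
        fam_lineages = [l for l in lineages if l.family == family]
        window_lineages = [l for l in fam_lineages if l.origin_window == window]
        best = 0
        seen_in_blocks = False
        for block in focal_blocks:
            distinct = 0
            for lin in window_lineages:
                if any(
                    locus_id in table and block.contains(table.get(locus_id))
                    for locus_id in lin.members
                ):
                    distinct += 1
            if distinct:
                seen_in_blocks = True
            best = max(best, distinct)
        if window_lineages and not seen_in_blocks:
            best = 1
        # lineages older than the window that survive through it
        passed = 0
        for lin in fam_lineages:
            if lin.origin_window == window:
                continue
            origin = stree.node(lin.origin_node)
            if not (stree.is_ancestor_or_equal(origin, window_node)
                    and origin is not window_node):
                continue
            if any(
                stree.is_ancestor_or_equal(window_node, stree.node(sp))
                for sp in lin.species
            ):
                passed += 1
        count = best + passed
        if count:
            out[family] = count
    return out


def scenario_summary(
    content: AncestralContent,
    nodes: Sequence[str],
    families: Optional[Sequence[str]] = None,
):
    """Repertoire table (node x family x subtype counts) as a DataFrame."""
    import pandas as pd

    rows = []
    for node in nodes:
        if node not in content.counts:
            raise KeyError(f"no reconstructed content for node {node!r}")
        for (family, subtype), n in sorted(content.counts[node].items()):
            if families is not None and family not in families:
                continue
            rows.append({"node": node, "family": family,
                         "subtype": subtype, "count": n})
    return pd.DataFrame(rows, columns=["node", "family", "subtype", "count"])
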