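"""Relative dating of gene-tree duplication nodes against WGD placements.

Each gene-tree node is mapped to the most recent species-tree node
containing all its descendant species (LCA reconciliation).  A node is a
duplication when two of its children map to comparable species nodes.
The duplication is then dated by the species-tree branches on which it
could have occurred: the branch of its mapped node, extended rootward to
just below its parent node's mapping (including the parent's own branch
when the parent is itself a duplication, since two duplications can share
a branch).  If every feasible branch carries the same window label the
duplication is assigned that label; otherwise it is ``unresolved``.  With
no gene loss the feasible range is a single branch and this reduces to
plain mapped-branch dating; under loss it refuses to guess rather than
assigning a wrong window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy

from .trees import GeneTree, SpeciesTree

log = logging.getLogger(__name__)

UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class DuplicationCall:
    """A dated duplication node of one gene tree."""

    node_id: str
    species_node: str          # where the duplication evidence places it
    window: str                # e.g. "2R", "3R", "post-3R-local", "unresolved"
    candidate_windows: Tuple[str, ...] = ()

    @property
    def is_resolved(self) -> bool:
        return self.window != UNRESOLVED


@dataclass(frozen=True)
class FamilyVerdict:
    family: str
    per_tree: Tuple[str, ...]   # "2R-consistent" / "inconclusive" per input tree
    aggregate: str              # supported-by-all / supported-by-one / inconclusive
    undated_consistent: bool = False


def lca_map(
    gtree: GeneTree, stree: SpeciesTree
) -> Dict[str, dendropy.Node]:
    """Map every gene-tree node id to its LCA species-tree node."""
    mapping: Dict[str, dendropy.Node] = {}
    for node in gtree.tree.postorder_node_iter():
        nid = gtree.id_of(node)
        if node.is_leaf():
            species = gtree.species_of_tip(nid)
            try:
                mapping[nid] = stree.node(species)
            except KeyError:
                raise ValueError(
                    f"gene-tree tip {nid!r}: species {species!r} "
                    f"not in the species tree"
                ) from None
        else:
            children = [mapping[gtree.id_of(c)] for c in node.child_nodes()]
            mapping[nid] = stree.mrca(children)
    return mapping


def annotate_duplications(
    gtree: GeneTree,
    mapping: Mapping[str, dendropy.Node],
    stree: SpeciesTree,
) -> Dict[str, dendropy.Node]:
    """Flag duplication nodes; returns node_id -> duplication location.

    Binary nodes: duplication iff the node maps to the same species node
    as one of its children.  Polytomies: duplication iff any two children
    have comparable mappings; the duplication is located at the top of
    the comparable pair(s), which for binary nodes coincides with the
    node's own mapping and for polytomies stays as low as the evidence
    allows (collapsing weak splits can therefore never push a lineage
    duplication up into a WGD window).
    """
    out: Dict[str, dendropy.Node] = {}
    for node in gtree.internal_nodes():
        child_maps = [mapping[gtree.id_of(c)] for c in node.child_nodes()]
        tops: List[dendropy.Node] = []
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                a, b = child_maps[i], child_maps[j]
                if stree.comparable(a, b):
                    tops.append(a if stree.is_ancestor_or_equal(a, b) else b)
        if not tops:
            continue
        # usually all pair tops coincide (always, for binary nodes); a
        # degenerate polytomy with several incomparable tops gets one
        # deterministic call rather than a promotion to their MRCA
        location = min(tops, key=lambda n: (stree.depth(n), stree.name_of(n)))
        out[gtree.id_of(node)] = location
    return out


def classify_window(
    gtree: GeneTree,
    node_id: str,
    mapping: Mapping[str, dendropy.Node],
    duplications: Mapping[str, dendropy.Node],
    stree: SpeciesTree,
) -> DuplicationCall:
    """Date one flagged duplication node (see module docstring)."""
    if node_id not in duplications:
        raise ValueError(f"node {node_id!r} is not flagged as a duplication")
    location = duplications[node_id]
    node = gtree.node_by_id(node_id)
    parent = node.parent_node

    bounded_by_speciation = False
    if parent is None:
        # no outgroup context above the root: feasible range extends to the
        # species-tree root
        top = stree.tree.seed_node
        candidates = stree.path_up(location, top)
        include_top = True
    else:
        pid = gtree.id_of(parent)
        pmap = duplications.get(pid, mapping[pid])
        if not stree.is_ancestor_or_equal(pmap, location):
            candidates = [location]
            include_top = True
        else:
            candidates = stree.path_up(location, pmap)
            # a duplication parent may share its branch with this node;
            # a speciation parent bounds the range strictly below itself
            include_top = pid in duplications
            bounded_by_speciation = not include_top
    if not include_top and len(candidates) > 1:
        candidates = candidates[:-1]

    labels = []
    for cand in candidates:
        label = stree.branch_window_label(cand)
        if label not in labels:
            labels.append(label)
    if len(labels) == 1:
        window = labels[0]
    else:
        # A feasible range bounded above by a speciation node that contains
        # exactly one WGD branch is attributed to that WGD: any other
        # placement would require extra independent losses in the lineages
        # whose absence widened the range (e.g. teleost duplications are
        # dated to 3R even when the pre-3R outgroup copy is missing).
        in_range_windows = [l for l in labels if l in stree.windows]
        if bounded_by_speciation and len(in_range_windows) == 1:
            window = in_range_windows[0]
        else:
            window = UNRESOLVED
    return DuplicationCall(
        node_id=node_id,
        species_node=stree.name_of(location),
        window=window,
        candidate_windows=tuple(labels),
    )


def date_gene_tree(
    gtree: GeneTree,
    stree: SpeciesTree,
    collapse_below: Optional[float] = None,
    synteny_table=None,
) -> List[DuplicationCall]:
    """LCA-map, flag and date every duplication node of one gene tree.

    ``synteny_table`` (a LocusTable) switches on the synteny override of
    :func:`apply_synteny_override`.
    """
    if collapse_below is not None:
        gtree = gtree.collapse_low_support(collapse_below)
    mapping = lca_map(gtree, stree)
    duplications = annotate_duplications(gtree, mapping, stree)
    calls = [
        classify_window(gtree, nid, mapping, duplications, stree)
        for nid in sorted(duplications)
    ]
    if synteny_table is not None:
        calls = apply_synteny_override(calls, gtree, synteny_table, stree)
    return calls


def apply_synteny_override(
    calls: Sequence[DuplicationCall],
    gtree: GeneTree,
    table,
    stree: SpeciesTree,
) -> List[DuplicationCall]:
    """Demote lineage-duplication calls that synteny contradicts.

    Copies produced by a duplication confined to one lineage (a tandem or
    otherwise small-scale event) are expected to co-reside on one
    chromosome.  When the two sides of a duplication dated outside every
    WGD window carry same-species loci on *different* chromosomes, the
    chromosomal locations contradict the tree position — the typical
    signature of WGD paralogs whose reconciliation was depressed by
    reciprocal losses or by anomalous clustering — and the call is
    demoted to ``unresolved``.  The override is conservative: it never
    promotes a call into a WGD window.
    """
    out: List[DuplicationCall] = []
    for call in calls:
        if not call.is_resolved or call.window in stree.windows:
            out.append(call)
            continue
        node = gtree.node_by_id(call.node_id)
        per_child: List[Dict[str, Set[str]]] = []
        for child in node.child_nodes():
            chroms: Dict[str, Set[str]] = {}
            for leaf in child.leaf_iter():
                locus_id = gtree.id_of(leaf)
                if locus_id in table:
                    locus = table.get(locus_id)
                    chroms.setdefault(locus.species, set()).add(
                        locus.chromosome)
            per_child.append(chroms)
        contradiction = False
        for i in range(len(per_child)):
            for j in range(i + 1, len(per_child)):
                shared = set(per_child[i]) & set(per_child[j])
                for sp in shared:
                    if per_child[i][sp].isdisjoint(per_child[j][sp]):
                        contradiction = True
        if contradiction:
            out.append(DuplicationCall(
                node_id=call.node_id,
                species_node=call.species_node,
                window=UNRESOLVED,
                candidate_windows=call.candidate_windows or (call.window,),
            ))
        else:
            out.append(call)
    return out


def family_verdict(
    family: str,
    calls_per_tree: Sequence[Sequence[DuplicationCall]],
    window: str = "2R",
) -> FamilyVerdict:
    """Aggregate per-tree dating into the family verdict.

    A tree is consistent with the window when it contains at least one
    duplication dated to it.  ``supported-by-all`` requires every input
    tree (e.g. NJ and ML topologies) to be consistent; ``supported-by-one``
    some but not all; otherwise ``inconclusive``.  Trees whose only
    window-compatible duplications are unresolved for lack of an earlier-
    diverging lineage are flagged ``undated_consistent``.
    """
    if not calls_per_tree:
        raise ValueError("family_verdict needs at least one tree's calls")
    per_tree = []
    undated = False
    for calls in calls_per_tree:
        if any(c.window == window for c in calls):
            per_tree.append(f"{window}-consistent")
        else:
            per_tree.append("inconclusive")
            for c in calls:
                cands = set(c.candidate_windows)
                if c.window == UNRESOLVED and window in cands and cands <= {
                    window, "pre-window"
                }:
                    undated = True
    n_yes = sum(v != "inconclusive" for v in per_tree)
    if n_yes == len(per_tree):
        aggregate = "supported-by-all"
    elif n_yes > 0:
        aggregate = "supported-by-one"
    else:
        aggregate = "inconclusive"
    return FamilyVerdict(
        family=family,
        per_tree=tuple(per_tree),
        aggregate=aggregate,
        undated_consistent=undated,
    )
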