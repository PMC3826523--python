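"""Independent brute-force oracles for reconciliation and Dollo placement.

These deliberately avoid the package's algorithms: LCA mapping is found
by scanning every species clade, duplications by the textbook child-map
criterion, orthologs by explicit tip-pair join checks, and loss sets by
exhaustive search over branch subsets.
"""

from itertools import combinations


def species_clades(stree):
    """(node name, frozenset of tip names) for every species-tree node."""
    out = []
    for node in stree.tree.preorder_node_iter():
        out.append((stree.name_of(node),
                    frozenset(stree.leaves_under(node))))
    return out


def brute_lca_map(gtree, stree):
    """Gene node id -> name of the smallest clade containing its species."""
    clades = species_clades(stree)
    mapping = {}
    for node in gtree.tree.postorder_node_iter():
        nid = gtree.id_of(node)
        species = {gtree.species_of_tip(gtree.id_of(leaf))
                   for leaf in node.leaf_iter()}
        best = None
        for name, tips in clades:
            if species <= tips and (best is None or len(tips) < len(best[1])):
                best = (name, tips)
        mapping[nid] = best[0]
    return mapping


def brute_duplications(gtree, mapping):
    """Binary-tree duplication flags: map(node) == map(child) for a child."""
    dups = {}
    for node in gtree.tree.postorder_node_iter():
        if node.is_leaf():
            continue
        nid = gtree.id_of(node)
        child_maps = [mapping[gtree.id_of(c)] for c in node.child_nodes()]
        if mapping[nid] in child_maps:
            dups[nid] = mapping[nid]
    return dups


def brute_ortholog_pairs(gtree, dup_node_ids):
    """All cross-species tip pairs whose join is not a duplication."""
    tips = gtree.tip_locus_ids
    pairs = set()
    for a, b in combinations(tips, 2):
        sa, sb = gtree.species_of_tip(a), gtree.species_of_tip(b)
        if sa == sb:
            continue
        join = gtree.id_of(gtree.join(a, b))
        if join in dup_node_ids:
            continue
        pairs.add(tuple(sorted([(sa, a), (sb, b)])))
    return pairs


def brute_min_loss_cover(stree, origin_name, present_species):
    """Smallest branch set covering every absent tip under the origin.

    A valid cover chooses branches below the origin such that every
    absent tip lies under at least one chosen branch and no present tip
    lies under any.  Returns (size, list of covers of that size), each
    cover a frozenset of branch (child node) names.
    """
    origin = stree.node(origin_name)
    tips = stree.leaves_under(origin)
    absent = tips - set(present_species)
    if not absent:
        return 0, [frozenset()]
    branches = []
    for node in origin.preorder_iter():
        if node is origin:
            continue
        under = stree.leaves_under(node)
        if under & set(present_species):
            continue
        branches.append((stree.name_of(node), frozenset(under)))
    for size in range(1, len(branches) + 1):
        covers = []
        for combo in combinations(branches, size):
            covered = set()
            for _name, under in combo:
                covered |= under
            if absent <= covered:
                covers.append(frozenset(name for name, _ in combo))
        if covers:
            return size, covers
    raise AssertionError("no cover found")
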