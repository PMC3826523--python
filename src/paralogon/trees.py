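"""Rooted species and gene trees, with WGD placements on species-tree branches.

Newick is read and written through dendropy.  A species tree carries
whole-genome-duplication placements as bracketed branch comments of the
form ``[wgd=2R-1]`` attached to the child node of the branch; labels that
differ only in a trailing ``-<number>`` (the two 2R doublings) are merged
into a single dating *window* (``2R-1``/``2R-2`` -> window ``2R``), since
tree topology cannot order two doublings on one branch.

Gene-tree tips are named ``species|locus_id``.  Every node receives a
deterministic identifier (tips: the tip label; internal nodes: ``n<k>`` in
postorder), stable under Newick round trips because child order is kept.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy

_WGD_COMMENT = re.compile(r"^\s*wgd\s*=\s*(.+?)\s*$")
_WINDOW_SUFFIX = re.compile(r"^(.+)-(\d+)$")


def window_of_label(label: str) -> str:
    """Merge ordered same-branch WGD labels into their window name."""
    m = _WINDOW_SUFFIX.match(label)
    return m.group(1) if m else label


def _read_tree(source: str, from_path: bool) -> dendropy.Tree:
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if from_path:
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    tree.is_rooted = True
    return tree


def _node_name(node: dendropy.Node) -> Optional[str]:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


class SpeciesTree:
    """Rooted species tree with per-branch ordered WGD labels."""

    def __init__(self, tree: dendropy.Tree) -> None:
        self.tree = tree
        self._by_name: Dict[str, dendropy.Node] = {}
        self._depth: Dict[int, int] = {}
        self.wgd_labels: Dict[int, List[str]] = {}  # node id -> ordered labels
        self.placements: Dict[str, dendropy.Node] = {}  # label -> branch child
        for node in tree.preorder_node_iter():
            name = _node_name(node)
            if name is None:
                raise ValueError("species tree has an unnamed node")
            if name in self._by_name:
                raise ValueError(f"duplicate node name {name!r} in species tree")
            self._by_name[name] = node
            parent = node.parent_node
            self._depth[id(node)] = 0 if parent is None else self._depth[id(parent)] + 1
            labels = []
            for comment in node.comments or ():
                m = _WGD_COMMENT.match(comment)
                if m:
                    labels.append(m.group(1))
            if labels:
                self.wgd_labels[id(node)] = labels
                for lab in labels:
                    if lab in self.placements:
                        raise ValueError(f"WGD label {lab!r} placed on two branches")
                    self.placements[lab] = node
                ordinals = [
                    int(_WINDOW_SUFFIX.match(l).group(2))
                    for l in labels
                    if _WINDOW_SUFFIX.match(l)
                ]
                if ordinals != sorted(ordinals):
                    raise ValueError(
                        f"WGD labels on branch into {name!r} are out of order"
                    )
        # merged windows; all labels of one window must share a branch
        self.windows: Dict[str, dendropy.Node] = {}
        for label, node in self.placements.items():
            window = window_of_label(label)
            if window in self.windows and self.windows[window] is not node:
                raise ValueError(f"window {window!r} spans two branches")
            self.windows[window] = node

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(_read_tree(text, from_path=False))

    @classmethod
    def read(cls, path) -> "SpeciesTree":
        return cls(_read_tree(str(path), from_path=True))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick())

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_item_comments=False,
            unquoted_underscores=True,
        )

    # -- queries -----------------------------------------------------------

    def node(self, name: str) -> dendropy.Node:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown species-tree node {name!r}") from None

    def name_of(self, node: dendropy.Node) -> str:
        return _node_name(node)  # type: ignore[return-value]

    @property
    def species(self) -> List[str]:
        return [t.label for t in self.tree.taxon_namespace]

    def depth(self, node: dendropy.Node) -> int:
        return self._depth[id(node)]

    def leaves_under(self, node: dendropy.Node) -> Set[str]:
        return {_node_name(l) for l in node.leaf_iter()}  # type: ignore[misc]

    def is_ancestor_or_equal(self, anc: dendropy.Node, node: dendropy.Node) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent_node
        return False

    def comparable(self, a: dendropy.Node, b: dendropy.Node) -> bool:
        return self.is_ancestor_or_equal(a, b) or self.is_ancestor_or_equal(b, a)

    def mrca(self, nodes: Sequence[dendropy.Node]) -> dendropy.Node:
        it = iter(nodes)
        current = next(it)
        for node in it:
            a, b = current, node
            while self._depth[id(a)] > self._depth[id(b)]:
                a = a.parent_node
            while self._depth[id(b)] > self._depth[id(a)]:
                b = b.parent_node
            while a is not b:
                a, b = a.parent_node, b.parent_node
            current = a
        return current

    def mrca_of_species(self, names: Iterable[str]) -> dendropy.Node:
        return self.mrca([self.node(n) for n in names])

    def path_up(self, lower: dendropy.Node, upper: dendropy.Node) -> List[dendropy.Node]:
        """Nodes from ``lower`` up to ``upper`` inclusive (child ends of branches)."""
        out = []
        node = lower
        while node is not None:
            out.append(node)
            if node is upper:
                return out
            node = node.parent_node
        raise ValueError("upper is not an ancestor of lower")

    # -- WGD windows -------------------------------------------------------

    def branch_wgd_window(self, node: dendropy.Node) -> Optional[str]:
        labels = self.wgd_labels.get(id(node))
        if not labels:
            return None
        return window_of_label(labels[0])

    def window_node(self, window: str) -> dendropy.Node:
        try:
            return self.windows[window]
        except KeyError:
            raise KeyError(f"no WGD window {window!r} on the species tree") from None

    def _terminal_windows(self) -> Set[str]:
        """Windows with no other window strictly below them."""
        out = set()
        for w, node in self.windows.items():
            if not any(
                other is not node and self.is_ancestor_or_equal(node, other)
                for other in self.windows.values()
            ):
                out.add(w)
        return out

    def branch_window_label(self, node: dendropy.Node) -> str:
        """Dating label for the branch entering ``node``.

        WGD branches get their window name; other branches are labeled by
        their position relative to the placed windows: ``pre-window`` above
        the first window, ``between-<A>-<B>`` on the path linking two
        windows, ``post-<W>-local`` on terminal branches of taxa that went
        through the most recent window, ``lineage-local`` otherwise.
        """
        window = self.branch_wgd_window(node)
        if window is not None:
            return window
        above = [
            w for w, wn in self.windows.items()
            if wn is not node and self.is_ancestor_or_equal(wn, node)
        ]
        below = [
            w for w, wn in self.windows.items()
            if wn is not node and self.is_ancestor_or_equal(node, wn)
        ]
        if below and not above:
            return "pre-window"
        if above and below:
            nearest_above = max(above, key=lambda w: self.depth(self.windows[w]))
            nearest_below = min(below, key=lambda w: self.depth(self.windows[w]))
            return f"between-{nearest_above}-{nearest_below}"
        if above and node.is_leaf():
            nearest = max(above, key=lambda w: self.depth(self.windows[w]))
            if nearest in self._terminal_windows():
                return f"post-{nearest}-local"
        return "lineage-local"


def split_tip_label(label: str) -> Tuple[str, str]:
    """Split ``species|locus_id`` (a bare label doubles as both)."""
    if "|" in label:
        species, locus_id = label.split("|", 1)
        return species, locus_id
    return label, label


class GeneTree:
    """Rooted gene-family tree with (species, locus_id) tips."""

    def __init__(self, tree: dendropy.Tree) -> None:
        self.tree = tree
        tree.is_rooted = True
        self.assign_ids()

    def assign_ids(self) -> None:
        self._tip_species: Dict[str, str] = {}
        self._leaf_by_locus: Dict[str, dendropy.Node] = {}
        self.node_id: Dict[int, str] = {}
        counter = 0
        seen_tips: Set[str] = set()
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                label = _node_name(node)
                if label is None:
                    raise ValueError("gene tree has an unnamed tip")
                if label in seen_tips:
                    raise ValueError(f"duplicate gene-tree tip {label!r}")
                seen_tips.add(label)
                species, locus_id = split_tip_label(label)
                self._tip_species[locus_id] = species
                self._leaf_by_locus[locus_id] = node
                self.node_id[id(node)] = locus_id
            else:
                self.node_id[id(node)] = f"n{counter}"
                counter += 1

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        return cls(_read_tree(text, from_path=False))

    @classmethod
    def read(cls, path) -> "GeneTree":
        return cls(_read_tree(str(path), from_path=True))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick())

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_item_comments=False,
            unquoted_underscores=True,
        )

    def copy(self) -> "GeneTree":
        return GeneTree(self.tree.clone(depth=1))

    # -- queries -----------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def nodes(self) -> List[dendropy.Node]:
        return list(self.tree.postorder_node_iter())

    def internal_nodes(self) -> List[dendropy.Node]:
        return [n for n in self.tree.postorder_node_iter() if not n.is_leaf()]

    def id_of(self, node: dendropy.Node) -> str:
        return self.node_id[id(node)]

    def node_by_id(self, node_id: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if self.node_id[id(node)] == node_id:
                return node
        raise KeyError(f"no gene-tree node {node_id!r}")

    @property
    def tip_locus_ids(self) -> List[str]:
        return sorted(self._leaf_by_locus)

    def species_of_tip(self, locus_id: str) -> str:
        return self._tip_species[locus_id]

    @property
    def tip_species(self) -> Set[str]:
        return set(self._tip_species.values())

    def leaf(self, locus_id: str) -> dendropy.Node:
        return self._leaf_by_locus[locus_id]

    def has_tip(self, locus_id: str) -> bool:
        return locus_id in self._leaf_by_locus

    def join(self, locus_a: str, locus_b: str) -> dendropy.Node:
        """Most recent common ancestor node of two tips."""
        ancestors = set()
        node = self._leaf_by_locus[locus_a]
        while node is not None:
            ancestors.add(id(node))
            node = node.parent_node
        node = self._leaf_by_locus[locus_b]
        while node is not None:
            if id(node) in ancestors:
                return node
            node = node.parent_node
        raise ValueError("tips do not share an ancestor")

    # -- manipulation ------------------------------------------------------

    def reroot_with_outgroup(self, tip_label: str) -> "GeneTree":
        """Return a copy rerooted on the branch above the named tip."""
        clone = self.tree.clone(depth=1)
        target = None
        for leaf in clone.leaf_node_iter():
            if _node_name(leaf) == tip_label:
                target = leaf
                break
        if target is None:
            raise KeyError(f"no tip named {tip_label!r}")
        clone.reroot_at_edge(target.edge, update_bipartitions=False)
        clone.is_rooted = True
        return GeneTree(clone)

    def collapse_low_support(self, threshold: float) -> "GeneTree":
        """Copy with internal edges of support < threshold collapsed.

        Support is read from internal-node labels; nodes without a numeric
        label are kept.  Mirrors discarding weakly supported bootstrap
        splits before dating.
        """
        clone = self.tree.clone(depth=1)
        to_collapse = []
        for node in clone.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            label = node.label
            if label is None:
                continue
            try:
                support = float(label)
            except ValueError:
                continue
            if support < threshold:
                to_collapse.append(node)
        for node in to_collapse:
            node.edge.collapse()
        return GeneTree(clone)


def build_gene_tree(structure) -> GeneTree:
    """Build a GeneTree from nested tuples.

    A leaf is a string ``"species|locus_id"``; an internal node is a tuple
    of child structures.  Child order is preserved.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def make(spec) -> dendropy.Node:
        node = dendropy.Node()
        if isinstance(spec, str):
            node.taxon = taxa.require_taxon(label=spec)
        else:
            for child in spec:
                node.add_child(make(child))
        return node

    tree.seed_node = make(structure)
    tree.is_rooted = True
    return GeneTree(tree)
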