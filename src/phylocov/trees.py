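"""Rooted tree containers and newick I/O for dated species trees and gene trees.

The species tree is a rooted, dated (ultrametric) phylogeny whose internal
nodes carry ages in million years (My); branch durations are differences of
ages between parent and child.  Gene trees are rooted binary trees whose
leaves carry a gene identifier and the species it belongs to.  Newick parsing
is delegated to dendropy; this module only adds the validation and the
lightweight node structures the reconciliation machinery needs.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "SpeciesTree",
    "GeneTree",
    "LeafSpeciesMap",
    "parse_species_tree",
    "parse_gene_trees",
    "write_tree",
    "write_forest",
]


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str
        Node label.  For gene-tree leaves this is the full leaf label
        (gene identifier); internal nodes may carry auto-generated labels.
    children : list[Node]
    parent : Node | None
    length : float | None
        Branch length above this node, if the source newick had one.
    age : float | None
        Node age in My (species trees only; leaves are 0).
    species : str | None
        Species identifier (gene-tree leaves only).
    event : str | None
        Post-reconciliation annotation on gene-tree internal nodes:
        ``"speciation"`` or ``"duplication"``.
    """

    __slots__ = ("label", "children", "parent", "length", "age", "species", "event")

    def __init__(self, label: str = "", length: float | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.age: float | None = None
        self.species: str | None = None
        self.event: str | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)}-ary"
        return f"<Node {self.label!r} ({kind})>"


def _dendropy_to_nodes(dtree: dendropy.Tree) -> Node:
    """Convert a dendropy tree to the local Node structure."""

    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label or ""
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return convert(dtree.seed_node)


def _parse_newick_trees(text: str) -> list[Node]:
    trees = dendropy.TreeList.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,
    )
    if not trees:
        raise TreeError("no trees found in newick input")
    return [_dendropy_to_nodes(t) for t in trees]


class SpeciesTree:
    """Rooted, dated species phylogeny.

    Every node carries an age in My (0 at the leaves, strictly increasing
    towards the root), so each branch has a strictly positive duration
    ``age(parent) - age(child)``.  Used as the frame onto which gene-tree
    events (duplications, losses, gains) are mapped.
    """

    def __init__(self, root: Node):
        self.root = root
        self._label_internal_nodes()
        self._validate()
        self._index()

    # -- construction helpers -------------------------------------------------

    def _label_internal_nodes(self) -> None:
        used = {n.label for n in self.root.postorder() if n.label}
        counter = itertools.count(1)
        for n in self.root.postorder():
            if not n.label:
                while True:
                    candidate = f"N{next(counter)}"
                    if candidate not in used:
                        break
                n.label = candidate
                used.add(candidate)

    def _validate(self) -> None:
        leaves = self.root.leaves()
        labels = [l.label for l in leaves]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels in species tree: {dupes}")
        for n in self.root.postorder():
            if not n.is_leaf and len(n.children) < 2:
                raise TreeError(f"internal node {n.label!r} has fewer than 2 children")
            if n.age is None:
                raise TreeError(f"node {n.label!r} has no age")
            if n.is_leaf and n.age != 0:
                raise TreeError(f"leaf {n.label!r} must have age 0, got {n.age}")
            for c in n.children:
                if not (n.age > c.age >= 0):
                    raise TreeError(
                        f"non-monotone ages: age({n.label})={n.age} must exceed "
                        f"age({c.label})={c.age}"
                    )

    def _index(self) -> None:
        self._by_label: dict[str, Node] = {}
        self._depth: dict[int, int] = {}
        self._order: dict[int, int] = {}
        for i, n in enumerate(self.root.preorder()):
            if n.label in self._by_label:
                raise TreeError(f"duplicate node label in species tree: {n.label!r}")
            self._by_label[n.label] = n
            self._depth[id(n)] = 0 if n.parent is None else self._depth[id(n.parent)] + 1
            self._order[id(n)] = i

    # -- queries --------------------------------------------------------------

    def node(self, label: str) -> Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise TreeError(f"unknown species-tree node: {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.root.leaves()]

    def depth(self, node: Node) -> int:
        return self._depth[id(node)]

    def preorder_index(self, node: Node) -> int:
        return self._order[id(node)]

    def branch_duration(self, node: Node) -> float:
        """Duration in My of the branch above `node` (0 for the root)."""
        if node.parent is None:
            return 0.0
        return node.parent.age - node.age

    def lca(self, a: Node, b: Node) -> Node:
        da, db = self._depth[id(a)], self._depth[id(b)]
        while da > db:
            a = a.parent
            da -= 1
        while db > da:
            b = b.parent
            db -= 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def is_ancestor_or_equal(self, anc: Node, node: Node) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def path_up(self, descendant: Node, ancestor: Node) -> list[Node]:
        """Nodes from `descendant` up to `ancestor`, both included."""
        path = [descendant]
        node = descendant
        while node is not ancestor:
            node = node.parent
            if node is None:
                raise TreeError(
                    f"{ancestor.label!r} is not an ancestor of {descendant.label!r}"
                )
            path.append(node)
        return path

    def leaf_set(self, node: Node) -> frozenset[str]:
        return frozenset(l.label for l in node.leaves())


@dataclass
class LeafSpeciesMap:
    """Rule that resolves a gene-tree leaf label to a species identifier.

    Either a delimiter + field index (default: the part after the last
    underscore, i.e. labels of the form ``<geneID>_<speciesCode>``) or an
    explicit lookup table.  Resolution is total: a leaf that cannot be
    resolved raises :class:`TreeError`.
    """

    delimiter: str = "_"
    field_index: int = -1
    table: Mapping[str, str] | None = None

    def species_of(self, leaf_label: str) -> str:
        if self.table is not None:
            try:
                return self.table[leaf_label]
            except KeyError:
                raise TreeError(
                    f"leaf {leaf_label!r} not found in leaf-to-species table"
                ) from None
        parts = leaf_label.split(self.delimiter)
        if len(parts) < 2:
            raise TreeError(
                f"cannot extract species from leaf {leaf_label!r} "
                f"with delimiter {self.delimiter!r}"
            )
        return parts[self.field_index]


class GeneTree:
    """Rooted binary gene-family tree with species-labeled leaves.

    Multifurcations in the input are resolved deterministically (left to
    right) into binary nodes joined by zero-length edges, so downstream
    strict reconciliation always sees a binary tree.  Single-leaf trees are
    valid and represent singleton (species-specific) families.
    """

    def __init__(self, root: Node, species_tree: SpeciesTree | None = None):
        self.root = root
        self._resolve_multifurcations()
        if species_tree is not None:
            self.validate_species(species_tree)

    def _resolve_multifurcations(self) -> None:
        for n in list(self.root.postorder()):
            while len(n.children) > 2:
                # Fold the two leftmost children under a new zero-length node.
                a, b = n.children[0], n.children[1]
                joint = Node(label="", length=0.0)
                joint.add_child(a)
                joint.add_child(b)
                joint.parent = n
                n.children = [joint] + n.children[2:]
            if len(n.children) == 1:
                # Suppress unifurcations, merging branch lengths.
                (child,) = n.children
                if n.parent is None:
                    child.parent = None
                    self.root = child
                else:
                    idx = n.parent.children.index(n)
                    if child.length is not None and n.length is not None:
                        child.length += n.length
                    child.parent = n.parent
                    n.parent.children[idx] = child

    def validate_species(self, species_tree: SpeciesTree) -> None:
        unknown = [
            l.label
            for l in self.root.leaves()
            if l.species is None or l.species not in species_tree
        ]
        if unknown:
            raise TreeError(
                f"gene-tree leaves with species absent from species tree: {unknown}"
            )

    @property
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    @property
    def species(self) -> frozenset[str]:
        return frozenset(l.species for l in self.leaves)

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()


# -- parsing ------------------------------------------------------------------


def parse_species_tree(
    newick: str,
    ages: Mapping[str, float] | None = None,
    *,
    rtol: float = 1e-6,
) -> SpeciesTree:
    """Parse a rooted dated species tree.

    Node ages may come from ultrametric branch lengths (the default: leaf
    ages are 0 and every internal node's age must be consistent across its
    children) or from an explicit ``ages`` table keyed by internal-node
    label.  If both are available the table wins.

    Parameters
    ----------
    newick : str
        Newick text of a single rooted tree.
    ages : mapping, optional
        Internal-node label -> age in My.

    Raises
    ------
    TreeError
        On malformed newick, non-ultrametric lengths without an age table,
        non-monotone ages, or duplicate leaf labels.
    """
    try:
        roots = _parse_newick_trees(newick)
    except Exception as exc:  # dendropy raises various error types
        raise TreeError(f"malformed newick: {exc}") from exc
    if len(roots) != 1:
        raise TreeError(f"expected a single species tree, got {len(roots)}")
    root = roots[0]

    if ages:
        for n in root.postorder():
            if n.is_leaf:
                n.age = 0.0
            elif n.label in ages:
                n.age = float(ages[n.label])
            else:
                raise TreeError(f"no age given for internal node {n.label!r}")
        # Age table wins over any branch lengths; warn if they disagree.
        for n in root.postorder():
            if n.parent is not None and n.length is not None:
                implied = n.parent.age - n.age
                if abs(implied - n.length) > rtol * max(1.0, abs(n.length)):
                    import warnings

                    warnings.warn(
                        f"branch length {n.length} above {n.label!r} conflicts with "
                        f"age-table duration {implied}; using the age table",
                        stacklevel=2,
                    )
                    break
    else:
        for n in root.postorder():
            if n.is_leaf:
                n.age = 0.0
            else:
                child_ages = []
                for c in n.children:
                    if c.length is None:
                        raise TreeError(
                            "species tree has no branch lengths and no age table"
                        )
                    child_ages.append(c.age + c.length)
                span = max(child_ages) - min(child_ages)
                scale = max(abs(a) for a in child_ages) or 1.0
                if span > rtol * scale:
                    raise TreeError(
                        f"non-ultrametric branch lengths at node {n.label or '<unnamed>'!r}: "
                        f"children imply ages {child_ages}"
                    )
                n.age = child_ages[0]

    return SpeciesTree(root)


def parse_gene_trees(
    newick: str,
    species_tree: SpeciesTree,
    species_map: LeafSpeciesMap | None = None,
) -> list[GeneTree]:
    """Parse a newick forest (one tree per line or ';'-separated) of gene trees.

    Every leaf is resolved to a species via `species_map` (default: suffix
    after the last underscore) and checked against the species tree.
    """
    species_map = species_map or LeafSpeciesMap()
    try:
        roots = _parse_newick_trees(newick)
    except TreeError:
        raise
    except Exception as exc:
        raise TreeError(f"malformed newick: {exc}") from exc
    forest = []
    for root in roots:
        for leaf in root.leaves():
            leaf.species = species_map.species_of(leaf.label)
        forest.append(GeneTree(root, species_tree))
    return forest


# -- writing ------------------------------------------------------------------


def _node_to_newick(node: Node, include_annotations: bool, dated: bool) -> str:
    if node.is_leaf:
        body = node.label
    else:
        inner = ",".join(
            _node_to_newick(c, include_annotations, dated) for c in node.children
        )
        body = f"({inner}){node.label}"
    if dated and node.parent is not None and node.age is not None:
        body += f":{node.parent.age - node.age:g}"
    elif node.length is not None:
        body += f":{node.length:g}"
    if include_annotations and node.event is not None:
        tag = "D" if node.event == "duplication" else "S"
        body += f"[&&NHX:Ev={tag}]"
    return body


def write_tree(tree: SpeciesTree | GeneTree, include_annotations: bool = False) -> str:
    """Serialize a tree to newick.  Round-trip safe: re-parsing reproduces
    topology, labels and (for species trees) ages."""
    if isinstance(tree, SpeciesTree):
        return _node_to_newick(tree.root, include_annotations, dated=True) + ";"
    return _node_to_newick(tree.root, include_annotations, dated=False) + ";"


def write_forest(forest: Sequence[GeneTree], include_annotations: bool = False) -> str:
    """One newick line per gene tree."""
    return "\n".join(write_tree(t, include_annotations) for t in forest) + "\n"
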