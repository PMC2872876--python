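"""Independent brute-force oracles used only by the tests.

These re-derive minimal reconciliation event counts and minimal Dollo loss
sets from first principles (exhaustive enumeration), without calling the
implementation's algorithms.
"""

from __future__ import annotations

import itertools
from phylocov.trees import GeneTree, Node, SpeciesTree


def _ancestors_or_self(node):
    while node is not None:
        yield node
        node = node.parent


def _naive_lca(a, b):
    anc_a = list(_ancestors_or_self(a))
    for n in _ancestors_or_self(b):
        if n in anc_a:
            return n
    raise AssertionError("nodes share no ancestor")


def brute_force_min_events(gene_tree: GeneTree, species_tree: SpeciesTree):
    """Minimal (duplications, losses) over all valid reconciliation maps.

    Enumerates every map M that sends each internal gene node to an
    ancestor-or-equal of its children's images; classifies each node as a
    speciation (children's images fall into distinct child subtrees of M(v),
    both strictly below M(v)) or a duplication; and counts, for every gene
    edge, one loss per off-path child of every species node the lineage
    traversed without diversifying.  Returns (min_dups, min_losses,
    min_total) where the first two are coordinate-wise minima and the third
    is the minimum of dups + losses.
    """
    internals = [v for v in gene_tree.postorder() if not v.is_leaf]
    leaf_map = {
        l: species_tree.node(l.species) for l in gene_tree.leaves
    }
    if not internals:
        return 0, 0, 0

    best_d, best_l, best_total = None, None, None

    def candidates(m1, m2):
        return list(_ancestors_or_self(_naive_lca(m1, m2)))

    def count_events(assignment):
        dups = losses = 0
        for v in internals:
            s = assignment[v]
            m1 = assignment.get(v.children[0], leaf_map.get(v.children[0]))
            m2 = assignment.get(v.children[1], leaf_map.get(v.children[1]))
            # child subtree of s containing each image (None if image == s)
            def child_of_s(m):
                if m is s:
                    return None
                node = m
                while node.parent is not s:
                    node = node.parent
                return node
            c1, c2 = child_of_s(m1), child_of_s(m2)
            is_spec = c1 is not None and c2 is not None and c1 is not c2
            if not is_spec:
                dups += 1
            for m in (m1, m2):
                # species nodes traversed without diversifying on this edge
                path = []
                node = m
                while node is not s:
                    node = node.parent
                    path.append(node)
                # path = nodes strictly above m up to and including s
                traversed = path[:-1] if is_spec else path
                for u in traversed:
                    prev = path[path.index(u) - 1] if path.index(u) > 0 else m
                    losses += sum(1 for ch in u.children if ch is not prev)
        return dups, losses

    def enumerate_maps(i, assignment):
        nonlocal best_d, best_l, best_total
        if i == len(internals):
            d, l = count_events(assignment)
            best_d = d if best_d is None else min(best_d, d)
            best_l = l if best_l is None else min(best_l, l)
            best_total = d + l if best_total is None else min(best_total, d + l)
            return
        v = internals[i]
        m1 = assignment.get(v.children[0], leaf_map.get(v.children[0]))
        m2 = assignment.get(v.children[1], leaf_map.get(v.children[1]))
        for cand in candidates(m1, m2):
            assignment[v] = cand
            enumerate_maps(i + 1, assignment)
        del assignment[v]

    enumerate_maps(0, {})
    return best_d, best_l, best_total


def brute_force_dollo(origin: Node, present: frozenset[str]):
    """Minimal loss-branch sets by exhaustive subset enumeration.

    Losses may be placed on any branch strictly inside the origin clade; a
    set is valid iff exactly the `present` species survive (a species
    survives iff no branch on its path from the origin is a loss).  Returns
    the list of all minimum-size valid sets (as frozensets of node labels).
    """
    clade_nodes = [n for n in origin.postorder() if n is not origin]
    leaves = [n for n in origin.postorder() if n.is_leaf]

    def survivors(loss_set):
        alive = set()
        for leaf in leaves:
            node = leaf
            lost = False
            while node is not origin:
                if node in loss_set:
                    lost = True
                    break
                node = node.parent
            if not lost:
                alive.add(leaf.label)
        return alive

    for size in range(len(clade_nodes) + 1):
        hits = [
            frozenset(n.label for n in combo)
            for combo in itertools.combinations(clade_nodes, size)
            if survivors(set(combo)) == set(present)
        ]
        if hits:
            return hits
    return []


# -- exhaustive/random tree generation ----------------------------------------


def all_rooted_topologies(leaves: list):
    """All rooted binary tree shapes over the given (ordered) leaf objects."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in all_rooted_topologies(rest):
        for target in _subtrees(sub):
            yield _graft(sub, target, first)


def _subtrees(root):
    yield root
    if isinstance(root, tuple):
        yield from _subtrees(root[0])
        yield from _subtrees(root[1])


def _graft(root, target, new_leaf):
    if root is target:
        return (new_leaf, target)
    if isinstance(root, tuple):
        return (
            _graft(root[0], target, new_leaf),
            _graft(root[1], target, new_leaf),
        )
    return root


def shape_to_newick(shape) -> str:
    if isinstance(shape, tuple):
        return f"({shape_to_newick(shape[0])},{shape_to_newick(shape[1])})"
    return str(shape)


_SHAPE_CACHE: dict[int, list] = {}


def _shapes(n_leaves: int) -> list:
    if n_leaves not in _SHAPE_CACHE:
        _SHAPE_CACHE[n_leaves] = list(all_rooted_topologies(list(range(n_leaves))))
    return _SHAPE_CACHE[n_leaves]


def random_gene_tree_newick(n_leaves: int, species: list[str], rng) -> str:
    """Random rooted binary shape with uniformly random species labels."""
    leaves = [
        f"g{i}_{species[rng.integers(0, len(species))]}" for i in range(n_leaves)
    ]
    shapes = _shapes(n_leaves)
    shape = shapes[rng.integers(0, len(shapes))]

    def to_newick(s):
        if isinstance(s, tuple):
            return f"({to_newick(s[0])},{to_newick(s[1])})"
        return leaves[s]

    return to_newick(shape) + ";"
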