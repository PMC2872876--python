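"""Strict gene-tree / species-tree reconciliation.

Each gene-tree node is mapped to the last common ancestor (LCA), in the
species tree, of the species found below it.  A node is a duplication
precisely when it maps to the same species-tree node as one of its children;
otherwise it is a speciation.  Losses are the species-tree branches the gene
lineage must have traversed without leaving a surviving descendant, which
yields the minimal duplication/loss scenario explaining the gene tree.

Each duplication also receives a species-overlap confidence score
|A ∩ B| / |A ∪ B|, where A and B are the species sets of the two
post-duplication subtrees; values near 0 flag dubious duplications whose
acceptance would imply many complementary losses.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import GeneTree, Node, SpeciesTree, TreeError

__all__ = [
    "DuplicationEvent",
    "LossEvent",
    "ReconciliationResult",
    "lca_map",
    "reconcile",
    "species_overlap_score",
    "per_branch_confidence_summary",
]


@dataclass
class DuplicationEvent:
    """A duplication at `gene_node`, placed on the species-tree branch above
    `species_node`, with post-duplication species sets `side_a`, `side_b`."""

    gene_node: Node
    species_node: Node
    side_a: frozenset[str]
    side_b: frozenset[str]

    @property
    def branch(self) -> str:
        return self.species_node.label

    @property
    def score(self) -> float:
        return species_overlap_score(self)


@dataclass
class LossEvent:
    """A loss on the species-tree branch above `species_node`, implied by the
    gene-tree edge from `gene_parent` down to `gene_child`."""

    species_node: Node
    gene_parent: Node
    gene_child: Node

    @property
    def branch(self) -> str:
        return self.species_node.label


@dataclass
class ReconciliationResult:
    gene_tree: GeneTree
    mapping: dict[Node, Node]
    duplications: list[DuplicationEvent] = field(default_factory=list)
    losses: list[LossEvent] = field(default_factory=list)
    tree_id: str = ""

    @property
    def n_duplications(self) -> int:
        return len(self.duplications)

    @property
    def n_losses(self) -> int:
        return len(self.losses)

    def duplications_per_branch(self) -> dict[str, int]:
        tally: dict[str, int] = defaultdict(int)
        for d in self.duplications:
            tally[d.branch] += 1
        return dict(tally)

    def losses_per_branch(self) -> dict[str, int]:
        tally: dict[str, int] = defaultdict(int)
        for l in self.losses:
            tally[l.branch] += 1
        return dict(tally)


def lca_map(gene_tree: GeneTree, species_tree: SpeciesTree) -> dict[Node, Node]:
    """Bottom-up LCA mapping M: gene-tree node -> species-tree node.

    Leaves map to their species; an internal node maps to the LCA of its
    children's images, so M(v) is always ancestor-or-equal of M(c).
    """
    mapping: dict[Node, Node] = {}
    for v in gene_tree.postorder():
        if v.is_leaf:
            if v.species is None:
                raise TreeError(f"gene-tree leaf {v.label!r} has no species")
            mapping[v] = species_tree.node(v.species)
        else:
            m = mapping[v.children[0]]
            for c in v.children[1:]:
                m = species_tree.lca(m, mapping[c])
            mapping[v] = m
    return mapping


def _species_below(node: Node) -> frozenset[str]:
    return frozenset(l.species for l in node.leaves())


def reconcile(
    gene_tree: GeneTree, species_tree: SpeciesTree, tree_id: str = ""
) -> ReconciliationResult:
    """Strict (minimal) reconciliation of a gene tree against the species tree.

    Returns the LCA mapping together with the minimal set of duplication and
    loss events, each attributed to a species-tree branch (identified by the
    node below the branch).  For each gene-tree edge (v, c), one loss is
    placed on every off-path child branch of the species nodes strictly
    between M(c) and M(v); when v is a duplication and M(c) ≠ M(v), the
    off-path children of M(v) itself also incur a loss (the second copy
    never reached them).

    Single-leaf gene trees (singleton families) yield no events.
    """
    mapping = lca_map(gene_tree, species_tree)
    result = ReconciliationResult(gene_tree, mapping, tree_id=tree_id)

    for v in gene_tree.postorder():
        if v.is_leaf:
            continue
        m = mapping[v]
        is_dup = any(mapping[c] is m for c in v.children)
        v.event = "duplication" if is_dup else "speciation"
        if is_dup:
            result.duplications.append(
                DuplicationEvent(
                    gene_node=v,
                    species_node=m,
                    side_a=_species_below(v.children[0]),
                    side_b=_species_below(v.children[1]),
                )
            )
        for c in v.children:
            path = species_tree.path_up(mapping[c], m)  # M(c) .. M(v)
            # Species nodes traversed without branching off: strictly between
            # M(c) and M(v); at a duplication the copy also silently passes
            # through M(v) itself whenever it maps below it.
            last = len(path) - 1 if is_dup and mapping[c] is not m else len(path) - 2
            for i in range(1, last + 1):
                s, came_from = path[i], path[i - 1]
                for child in s.children:
                    if child is not came_from:
                        result.losses.append(LossEvent(child, v, c))
    return result


def species_overlap_score(event: DuplicationEvent) -> float:
    """Species-overlap (duplication-consistency) score |A∩B| / |A∪B| ∈ [0,1]."""
    a, b = event.side_a, event.side_b
    if not a or not b:
        raise ValueError("duplication event with an empty post-duplication side")
    return len(a & b) / len(a | b)


def per_branch_confidence_summary(
    results: list[ReconciliationResult],
) -> pd.DataFrame:
    """Mean and standard deviation of overlap scores per species-tree node.

    Nodes with no mapped duplication are omitted.  The standard deviation is
    the population form (divide by n).
    """
    scores: dict[str, list[float]] = defaultdict(list)
    for r in results:
        for d in r.duplications:
            scores[d.branch].append(d.score)
    rows = [
        {
            "node": branch,
            "n_duplications": len(vals),
            "mean_score": float(np.mean(vals)),
            "sd_score": float(np.std(vals)),  # population sd
        }
        for branch, vals in sorted(scores.items())
    ]
    return pd.DataFrame(rows, columns=["node", "n_duplications", "mean_score", "sd_score"])
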