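"""Presence/absence characters, gain/loss mapping and genome-content trajectories.

Two character datasets can be built from a reconciled forest:

* ``"families"`` — one character per gene family (plus one per
  species-specific singleton gene);
* ``"with_duplications"`` — additionally one character per inferred
  duplication event, whose presence records which species retain the
  post-duplication copy.

Gains are read directly off gene-tree topology: every character is gained
exactly once, on its origin branch.  Losses are placed under Dollo parsimony
(single gain, minimal losses): one loss on the root branch of every maximal
subtree of the origin clade in which the character is absent.  Accumulating
gains − losses from the root down a lineage yields the inferred
genome-content trajectory through time.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reconcile import ReconciliationResult
from .trees import Node, SpeciesTree, TreeError

__all__ = [
    "Character",
    "CharacterMatrix",
    "BranchEventTally",
    "ContentTrajectory",
    "build_matrix",
    "assign_gains",
    "place_losses_dollo",
    "build_tally",
    "content_trajectory",
    "losses_through_time",
    "compare_mappings",
]

FLAVORS = ("families", "with_duplications")


@dataclass(frozen=True)
class Character:
    """A presence/absence character with a single origin on the species tree.

    `origin` is the species-tree node below the branch on which the character
    was gained; characters gained above the species root use the root node
    (a virtual root branch of duration 0).  Presence is restricted to species
    descending from the origin.
    """

    id: str
    kind: str  # family | duplication | singleton
    origin: str
    present: frozenset[str]


@dataclass
class CharacterMatrix:
    characters: list[Character]
    species: list[str]
    flavor: str

    def __post_init__(self) -> None:
        ids = [c.id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate character identifiers")

    def __len__(self) -> int:
        return len(self.characters)

    def presence_count(self, species: str) -> int:
        return sum(1 for c in self.characters if species in c.present)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "kind": [c.kind for c in self.characters],
            "origin": [c.origin for c in self.characters],
        }
        for sp in self.species:
            data[sp] = [int(sp in c.present) for c in self.characters]
        return pd.DataFrame(data, index=[c.id for c in self.characters])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="character")


@dataclass
class BranchEventTally:
    """Per species-tree branch (keyed by the node below it): gains and losses."""

    gains: dict[str, int] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)

    def gains_at(self, branch: str) -> int:
        return self.gains.get(branch, 0)

    def losses_at(self, branch: str) -> int:
        return self.losses.get(branch, 0)

    @property
    def total_gains(self) -> int:
        return sum(self.gains.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())


@dataclass
class ContentTrajectory:
    """Gene-content counts along a root-to-leaf lineage, by node age (My)."""

    lineage: list[str]
    ages: list[float]
    contents: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": self.lineage, "age_my": self.ages, "content": self.contents}
        )

    @property
    def endpoint(self) -> int:
        return self.contents[-1]


def build_matrix(
    results: Sequence[ReconciliationResult],
    species_tree: SpeciesTree,
    flavor: str = "families",
) -> CharacterMatrix:
    """Build the presence/absence character matrix from a reconciled forest.

    Families with a single gene become ``singleton`` characters gained on the
    terminal branch of their species.  Multi-gene families become ``family``
    characters gained on the branch above the family root's mapped species
    node.  Under ``flavor="with_duplications"``, each duplication event adds
    one ``duplication`` character, present in the species that retain at
    least one descendant of the second post-duplication copy (deterministic
    child ordering).
    """
    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {FLAVORS}")
    characters: list[Character] = []
    for i, res in enumerate(results):
        fam_id = res.tree_id or f"fam{i}"
        leaves = res.gene_tree.leaves
        present = frozenset(l.species for l in leaves)
        if len(leaves) == 1:
            characters.append(
                Character(f"{fam_id}", "singleton", next(iter(present)), present)
            )
            continue
        origin = res.mapping[res.gene_tree.root]
        characters.append(Character(f"{fam_id}", "family", origin.label, present))
        if flavor == "with_duplications":
            for j, dup in enumerate(res.duplications):
                copy = dup.gene_node.children[1]
                retained = frozenset(l.species for l in copy.leaves())
                characters.append(
                    Character(
                        f"{fam_id}.dup{j}", "duplication", dup.branch, retained
                    )
                )
    return CharacterMatrix(characters, species_tree.leaf_labels, flavor)


def assign_gains(matrix: CharacterMatrix) -> dict[str, int]:
    """One gain per character, on its origin branch; total gains = #characters."""
    gains: dict[str, int] = defaultdict(int)
    for c in matrix.characters:
        gains[c.origin] += 1
    return dict(gains)


def place_losses_dollo(character: Character, species_tree: SpeciesTree) -> list[str]:
    """Minimal Dollo loss placement for one character.

    With a single gain on the origin branch, the unique minimal loss set
    contains one loss on the root branch of every maximal subtree of the
    origin clade devoid of the character.  Returns the labels of the species
    nodes below the loss branches.
    """
    origin = species_tree.node(character.origin)
    clade = species_tree.leaf_set(origin)
    if not character.present:
        raise TreeError(f"character {character.id!r} present in no species")
    outside = character.present - clade
    if outside:
        raise TreeError(
            f"character {character.id!r} present outside its origin clade: "
            f"{sorted(outside)}"
        )

    losses: list[str] = []

    def walk(node: Node) -> None:
        if not (species_tree.leaf_set(node) & character.present):
            losses.append(node.label)
            return
        for child in node.children:
            walk(child)

    for child in origin.children:
        walk(child)
    return losses


def build_tally(
    matrix: CharacterMatrix, species_tree: SpeciesTree
) -> BranchEventTally:
    """Map every character's gain and Dollo losses onto species-tree branches."""
    gains = assign_gains(matrix)
    losses: dict[str, int] = defaultdict(int)
    for c in matrix.characters:
        for branch in place_losses_dollo(c, species_tree):
            losses[branch] += 1
    return BranchEventTally(gains=gains, losses=dict(losses))


def content_trajectory(
    tally: BranchEventTally, species_tree: SpeciesTree, target_species: str
) -> ContentTrajectory:
    """Inferred gene-content counts from the root down to `target_species`.

    Root content counts the characters gained on the virtual root branch;
    each subsequent branch adds its gains and subtracts its losses.
    """
    if target_species not in species_tree:
        raise TreeError(f"unknown target species {target_species!r}")
    target = species_tree.node(target_species)
    if not target.is_leaf:
        raise TreeError(f"{target_species!r} is not an extant species")
    path = list(reversed(species_tree.path_up(target, species_tree.root)))

    root = path[0]
    content = tally.gains_at(root.label) - tally.losses_at(root.label)
    lineage, ages, contents = [root.label], [root.age], [content]
    for node in path[1:]:
        content += tally.gains_at(node.label) - tally.losses_at(node.label)
        if content < 0:
            raise TreeError(
                f"negative inferred content ({content}) at node {node.label!r}"
            )
        lineage.append(node.label)
        ages.append(node.age)
        contents.append(content)
    return ContentTrajectory(lineage, ages, contents)


def losses_through_time(
    tally: BranchEventTally, species_tree: SpeciesTree
) -> pd.DataFrame:
    """Per-branch loss counts against branch age; terminal branches are tagged
    with their species name."""
    rows = []
    for node in species_tree.root.preorder():
        if node.parent is None:
            continue
        rows.append(
            {
                "branch": node.label,
                "parent_age_my": node.parent.age,
                "age_my": node.age,
                "losses": tally.losses_at(node.label),
                "gains": tally.gains_at(node.label),
                "species": node.label if node.is_leaf else "",
            }
        )
    return pd.DataFrame(rows)


def compare_mappings(
    tally_a: BranchEventTally,
    tally_b: BranchEventTally,
    species_tree: SpeciesTree,
    target_species: str | None = None,
) -> tuple[pd.DataFrame, ContentTrajectory | None]:
    """Signed per-branch event differences (a − b) and, if a target lineage is
    given, the content-ratio trajectory a/b (NaN where b's content is 0)."""
    rows = []
    for node in species_tree.root.preorder():
        rows.append(
            {
                "branch": node.label,
                "gain_delta": tally_a.gains_at(node.label) - tally_b.gains_at(node.label),
                "loss_delta": tally_a.losses_at(node.label)
                - tally_b.losses_at(node.label),
            }
        )
    deltas = pd.DataFrame(rows)

    ratio = None
    if target_species is not None:
        traj_a = content_trajectory(tally_a, species_tree, target_species)
        traj_b = content_trajectory(tally_b, species_tree, target_species)
        contents = [
            a / b if b > 0 else float("nan")
            for a, b in zip(traj_a.contents, traj_b.contents)
        ]
        ratio = ContentTrajectory(traj_a.lineage, traj_a.ages, contents)
    return deltas, ratio


def plot_trajectory(trajectory: ContentTrajectory, ax=None, **kwargs):
    """Plot a content trajectory against time (My before present, reversed axis).

    Requires matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trajectory.ages, trajectory.contents, marker="o", **kwargs)
    ax.set_xlabel("age (My)")
    ax.set_ylabel("inferred gene content")
    ax.invert_xaxis()
    return ax
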