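"""Fully synthetic ground truth: gene families, sequences, and re-inference.

Gene families evolve on the dated species tree by a linear birth-death
process (per-gene duplication and loss rates per My) plus optional per-branch
family origination; every event is logged, so the true event map is known.
Protein sequences then evolve along the true gene trees under a uniform
20-state substitution model (each site independently replaced on a branch of
duration t with probability 1 − e^(−r·t)).

Tree re-inference uses Poisson-corrected p-distances on the unambiguous
(non-'X') sites followed by neighbor joining with midpoint rooting.  The
end-to-end scenario runner pairs a clean arm with a degraded arm (ambiguity
stretches injected into selected species) on the *same* simulated families,
so per-branch gain ratios isolate the effect of low-coverage degradation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

from .gainloss import BranchEventTally, build_matrix, build_tally
from .lowcov import AMINO_ACIDS, DegradationProfile, ProteinSet, degrade
from .reconcile import ReconciliationResult, reconcile
from .trees import GeneTree, Node, SpeciesTree

__all__ = [
    "SimulationConfig",
    "SimEvent",
    "FamilySimulation",
    "DistanceMatrix",
    "ScenarioResult",
    "simulate_families",
    "simulate_sequences",
    "p_distance",
    "distance_matrix",
    "nj_tree",
    "run_scenario",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the gene-family / sequence simulator.

    Rates are per My: `dup_rate` and `loss_rate` per gene lineage,
    `orig_rate` per species-tree branch.  `subst_rate` is expected
    substitutions per site per My.  A fixed seed gives bit-identical output.
    """

    species_tree: SpeciesTree
    n_root_families: int = 500
    dup_rate: float = 0.001
    loss_rate: float = 0.001
    orig_rate: float = 0.0
    seq_length: int = 300
    subst_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dup_rate", "loss_rate", "orig_rate", "subst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimEvent:
    """A logged true event: origination, duplication or loss."""

    family: str
    etype: str  # origination | duplication | loss
    branch: str  # species-tree node below the branch the event occurred on
    time_my: float
    gene_node: Node | None = None  # duplication node in the true gene tree
    bilateral: bool | None = None  # both copies left extant descendants


@dataclass
class FamilySimulation:
    gene_trees: list[GeneTree]
    family_ids: list[str]
    events: list[SimEvent]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": e.family,
                    "event": e.etype,
                    "branch": e.branch,
                    "time_my": e.time_my,
                    "bilateral": e.bilateral,
                }
                for e in self.events
            ]
        )

    def true_duplication_tally(self, bilateral_only: bool = True) -> dict[str, int]:
        tally: dict[str, int] = {}
        for e in self.events:
            if e.etype != "duplication":
                continue
            if bilateral_only and not e.bilateral:
                continue
            tally[e.branch] = tally.get(e.branch, 0) + 1
        return tally

    def total_gene_time_my(self) -> float:
        """Summed lifetime (My) of all surviving gene-tree branches; the
        exposure denominator for rate estimation on true trees."""
        total = 0.0
        for gt in self.gene_trees:
            for node in gt.postorder():
                if node.parent is not None:
                    total += node.parent.age - node.age
        return total


class _FamilySimulator:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.events: list[SimEvent] = []
        self.family: str = ""
        self._gene_counter = itertools.count(1)

    def _lineage(self, sp_node: Node, t_start: float) -> Node | None:
        """Evolve one gene lineage entering the branch above `sp_node` at age
        `t_start`; returns the surviving gene subtree (pruned) or None."""
        cfg, rng = self.cfg, self.rng
        rate = cfg.dup_rate + cfg.loss_rate
        t = t_start
        while True:
            wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
            if t - wait <= sp_node.age:
                return self._at_node(sp_node)
            t -= wait
            if rng.random() < cfg.loss_rate / rate:
                self.events.append(SimEvent(self.family, "loss", sp_node.label, t))
                return None
            event = SimEvent(self.family, "duplication", sp_node.label, t)
            self.events.append(event)
            left = self._lineage(sp_node, t)
            right = self._lineage(sp_node, t)
            event.bilateral = left is not None and right is not None
            if left is None and right is None:
                return None
            if left is None or right is None:
                return left if right is None else right
            node = Node()
            node.age = t
            node.event = "duplication"
            node.add_child(left)
            node.add_child(right)
            event.gene_node = node
            return node

    def _at_node(self, sp_node: Node) -> Node | None:
        """Gene lineage arriving at species node `sp_node` (leaf or speciation)."""
        if sp_node.is_leaf:
            leaf = Node(label=f"g{next(self._gene_counter)}_{sp_node.label}")
            leaf.age = 0.0
            leaf.species = sp_node.label
            return leaf
        children = [self._lineage(c, sp_node.age) for c in sp_node.children]
        survivors = [c for c in children if c is not None]
        if not survivors:
            return None
        if len(survivors) == 1:
            return survivors[0]
        node = Node()
        node.age = sp_node.age
        node.event = "speciation"
        for c in survivors:
            node.add_child(c)
        return node


def _set_lengths_from_ages(root: Node) -> None:
    for n in root.postorder():
        if n.parent is not None:
            n.length = n.parent.age - n.age


def simulate_families(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> FamilySimulation:
    """Simulate gene families along the species tree; extinct families dropped.

    `n_root_families` families are present in the ancestral genome at the
    species-tree root; further families originate on each branch at
    `orig_rate` per My (uniform position on the branch).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sim = _FamilySimulator(cfg, rng)
    species = cfg.species_tree
    gene_trees: list[GeneTree] = []
    family_ids: list[str] = []

    def finish(root: Node | None, fam_id: str) -> None:
        if root is None:
            return
        _set_lengths_from_ages(root)
        gene_trees.append(GeneTree(root, species))
        family_ids.append(fam_id)

    for i in range(cfg.n_root_families):
        fam = f"fam{i}"
        sim.family = fam
        sim.events.append(
            SimEvent(fam, "origination", species.root.label, species.root.age)
        )
        finish(sim._at_node(species.root), fam)

    if cfg.orig_rate > 0:
        counter = itertools.count(cfg.n_root_families)
        for node in species.root.preorder():
            if node.parent is None:
                continue
            duration = node.parent.age - node.age
            for _ in range(rng.poisson(cfg.orig_rate * duration)):
                fam = f"fam{next(counter)}"
                sim.family = fam
                t0 = float(rng.uniform(node.age, node.parent.age))
                sim.events.append(SimEvent(fam, "origination", node.label, t0))
                finish(sim._lineage(node, t0), fam)

    return FamilySimulation(gene_trees, family_ids, sim.events)


_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def simulate_sequences(
    gene_tree: GeneTree,
    length: int,
    subst_rate: float,
    rng: np.random.Generator | int = 0,
) -> ProteinSet:
    """Evolve protein sequences along a dated gene tree.

    The root sequence is uniform over the 20 amino acids; on each branch of
    duration t every site is independently replaced, with probability
    1 − e^(−r·t), by a uniformly chosen *different* residue.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    root = gene_tree.root
    seqs: dict[Node, np.ndarray] = {root: rng.integers(0, 20, size=length)}
    sequences: dict[str, str] = {}
    species: dict[str, str] = {}
    for node in root.preorder():
        if node is not root:
            t = node.parent.age - node.age
            p = 1.0 - math.exp(-subst_rate * t)
            seq = seqs[node.parent].copy()
            hit = rng.random(length) < p
            n_hit = int(hit.sum())
            if n_hit:
                seq[hit] = (seq[hit] + rng.integers(1, 20, size=n_hit)) % 20
            seqs[node] = seq
        if node.is_leaf:
            sequences[node.label] = _AA_ARRAY[seqs[node]].tobytes().decode()
            species[node.label] = node.species
    return ProteinSet(sequences, species)


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Poisson-corrected distance over comparable (neither 'X') sites.

    Returns ``(distance, n_comparable)``; distance is NaN when no site is
    comparable or the proportion of differences reaches 1.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    x = ord("X")
    comparable = (a != x) & (b != x)
    n = int(comparable.sum())
    if n == 0:
        return math.nan, 0
    p = float((a[comparable] != b[comparable]).mean())
    if p >= 1.0:
        return math.nan, n
    return -math.log(1.0 - p), n


@dataclass
class DistanceMatrix:
    """Pairwise gene distances with a validity mask.

    A pair is invalid when fewer than `min_sites` comparable sites remain or
    the distance is undefined (saturation)."""

    ids: list[str]
    matrix: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix(
    proteins: ProteinSet, ids: Sequence[str] | None = None, min_sites: int = 20
) -> DistanceMatrix:
    """All pairwise Poisson-corrected distances among the given sequences."""
    ids = sorted(proteins.sequences) if ids is None else list(ids)
    n = len(ids)
    mat = np.zeros((n, n))
    valid = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d, sites = p_distance(proteins.sequences[ids[i]], proteins.sequences[ids[j]])
            ok = sites >= min_sites and not math.isnan(d)
            mat[i, j] = mat[j, i] = d if ok else math.nan
            valid[i, j] = valid[j, i] = ok
    return DistanceMatrix(ids, mat, valid)


def _skbio_to_node(sk_node) -> Node:
    node = Node(label=sk_node.name or "", length=sk_node.length)
    for child in sk_node.children:
        node.add_child(_skbio_to_node(child))
    return node


def nj_tree(dmat: DistanceMatrix, species_tree: SpeciesTree) -> GeneTree:
    """Neighbor-joining tree from a distance matrix, midpoint-rooted.

    Invalid pairs are imputed as 1.05 × the largest valid distance, which
    keeps them maximally peripheral without distorting valid joins.  Requires
    at least 3 taxa and at least one valid off-diagonal pair.
    """
    n = len(dmat)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    off = ~np.eye(n, dtype=bool)
    mat = dmat.matrix.copy()
    invalid = ~dmat.valid & off
    if invalid.any():
        valid_vals = mat[dmat.valid & off]
        if valid_vals.size == 0:
            raise ValueError("no valid pairwise distances")
        mat[invalid] = float(valid_vals.max()) * 1.05
    np.fill_diagonal(mat, 0.0)

    sk_dm = skbio.DistanceMatrix(mat, ids=dmat.ids)
    unrooted = skbio.tree.nj(sk_dm)
    try:
        rooted = unrooted.root_at_midpoint()
    except Exception:
        rooted = unrooted  # zero-length degenerate case: keep the NJ root
    root = _skbio_to_node(rooted)
    for leaf in root.leaves():
        leaf.species = leaf.label.rsplit("_", 1)[-1]
    return GeneTree(root, species_tree)


def _trivial_gene_tree(
    proteins: ProteinSet, ids: Sequence[str], species_tree: SpeciesTree
) -> GeneTree:
    """Forced topology for 1- or 2-gene families."""
    leaves = []
    for sid in ids:
        leaf = Node(label=sid)
        leaf.species = proteins.species[sid]
        leaves.append(leaf)
    if len(leaves) == 1:
        return GeneTree(leaves[0], species_tree)
    root = Node()
    for leaf in leaves:
        root.add_child(leaf)
    return GeneTree(root, species_tree)


@dataclass
class ScenarioResult:
    """Paired clean/degraded outcome of the end-to-end scenario."""

    simulation: FamilySimulation
    tally_clean: BranchEventTally
    tally_degraded: BranchEventTally
    results_clean: list[ReconciliationResult]
    results_degraded: list[ReconciliationResult]
    species_tree: SpeciesTree

    def branch_summary(self) -> pd.DataFrame:
        """Per-branch gains in each arm and the degraded/clean gain ratio
        (NaN where the clean arm has no gains)."""
        rows = []
        for node in self.species_tree.root.preorder():
            g_clean = self.tally_clean.gains_at(node.label)
            g_deg = self.tally_degraded.gains_at(node.label)
            rows.append(
                {
                    "branch": node.label,
                    "age_my": node.age,
                    "gains_clean": g_clean,
                    "gains_degraded": g_deg,
                    "gain_ratio": g_deg / g_clean if g_clean > 0 else math.nan,
                }
            )
        return pd.DataFrame(rows)

    def gain_ratio_excess(self, focal_branches: Sequence[str]) -> tuple[float, float]:
        """(mean gain ratio on focal branches, mean ratio elsewhere), over
        branches where the ratio is defined."""
        df = self.branch_summary().dropna(subset=["gain_ratio"])
        focal = df[df["branch"].isin(focal_branches)]["gain_ratio"]
        other = df[~df["branch"].isin(focal_branches)]["gain_ratio"]
        return float(focal.mean()), float(other.mean())


def _infer_forest(
    proteins: ProteinSet,
    family_members: list[list[str]],
    species_tree: SpeciesTree,
    min_sites: int,
) -> list[ReconciliationResult]:
    results = []
    for i, ids in enumerate(family_members):
        if len(ids) >= 3:
            dmat = distance_matrix(proteins, ids, min_sites=min_sites)
            try:
                tree = nj_tree(dmat, species_tree)
            except ValueError:
                tree = _trivial_gene_tree(proteins, ids, species_tree)
        else:
            tree = _trivial_gene_tree(proteins, ids, species_tree)
        results.append(reconcile(tree, species_tree, tree_id=f"fam{i}"))
    return results


def run_scenario(
    cfg: SimulationConfig,
    profile: DegradationProfile,
    min_sites: int = 20,
) -> ScenarioResult:
    """End-to-end paired experiment: simulate, degrade, re-infer, reconcile.

    Pipeline: simulate families and sequences once; the degraded arm masks
    the targeted species' sequences with ambiguity stretches; both arms then
    go through distance-based NJ re-inference, strict reconciliation, the
    "with duplications" character matrix and Dollo gain/loss mapping.
    An all-zero degradation profile makes the two arms identical.
    """
    species_tree = cfg.species_tree
    rng_fam = np.random.default_rng([cfg.seed, 0])
    rng_seq = np.random.default_rng([cfg.seed, 1])
    rng_deg = np.random.default_rng([cfg.seed, 2])

    sim = simulate_families(cfg, rng_fam)

    sequences: dict[str, str] = {}
    species: dict[str, str] = {}
    family_members: list[list[str]] = []
    for gt in sim.gene_trees:
        pset = simulate_sequences(gt, cfg.seq_length, cfg.subst_rate, rng_seq)
        sequences.update(pset.sequences)
        species.update(pset.species)
        family_members.append(sorted(pset.sequences))
    clean = ProteinSet(sequences, species)
    degraded = degrade(clean, profile, rng_deg)

    results_clean = _infer_forest(clean, family_members, species_tree, min_sites)
    results_degraded = _infer_forest(degraded, family_members, species_tree, min_sites)

    tally_clean = build_tally(
        build_matrix(results_clean, species_tree, "with_duplications"), species_tree
    )
    tally_degraded = build_tally(
        build_matrix(results_degraded, species_tree, "with_duplications"), species_tree
    )
    return ScenarioResult(
        simulation=sim,
        tally_clean=tally_clean,
        tally_degraded=tally_degraded,
        results_clean=results_clean,
        results_degraded=results_degraded,
        species_tree=species_tree,
    )
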