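"""Screen for suspicious orphan-driven duplications and cohort statistics.

A duplication node mapped to a focal species-tree node (typically the basal
eutherian node) with a single "orphan" species on one side is suspicious: it
implies one deep duplication followed by losses in many shallower branches.
It is even more dubious when the orphan species is absent from the other
side, which would require reciprocal complementary losses.  Per-species hit
counts under five nested criteria are compared between genome-quality
cohorts (low- vs high-coverage) with a one-tail Mann-Whitney test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reconcile import ReconciliationResult
from .trees import SpeciesTree, TreeError

__all__ = [
    "OrphanHit",
    "TestResult",
    "CRITERIA",
    "find_orphan_duplications",
    "tabulate_cohorts",
    "mann_whitney_one_tail",
    "screen_report",
]

# Nested hit criteria, from loosest to tightest.  "vs>5" requires more than
# five species on the non-orphan side; "no_sp" additionally requires the
# orphan species to be absent from that side.
CRITERIA = ("isolated", "vs5", "vs5_no_sp", "vs10", "vs10_no_sp")


@dataclass(frozen=True)
class OrphanHit:
    """One orphan side of a duplication node at the focal species-tree node."""

    tree_id: str
    orphan_species: str
    other_side_size: int
    orphan_absent: bool  # orphan species missing from the other side

    def satisfies(self, criterion: str) -> bool:
        if criterion == "isolated":
            return True
        if criterion == "vs5":
            return self.other_side_size > 5
        if criterion == "vs5_no_sp":
            return self.other_side_size > 5 and self.orphan_absent
        if criterion == "vs10":
            return self.other_side_size > 10
        if criterion == "vs10_no_sp":
            return self.other_side_size > 10 and self.orphan_absent
        raise ValueError(f"unknown criterion {criterion!r}")


@dataclass(frozen=True)
class TestResult:
    """One-tail Mann-Whitney comparison of two groups of per-species counts."""

    U: float
    z: float | None
    p_value: float
    method: str
    n1: int
    n2: int


def find_orphan_duplications(
    results: Sequence[ReconciliationResult],
    species_tree: SpeciesTree,
    focal_node: str,
) -> list[OrphanHit]:
    """All orphan hits among duplications mapped to `focal_node`.

    A hit is one singleton side of a duplication; a duplication with two
    singleton sides therefore yields two hits (each species orphan once).
    """
    focal = species_tree.node(focal_node)
    if focal.is_leaf:
        raise TreeError(f"focal node {focal_node!r} is a leaf, not an internal node")
    hits: list[OrphanHit] = []
    for res in results:
        for dup in res.duplications:
            if dup.species_node is not focal:
                continue
            for orphan_side, other_side in (
                (dup.side_a, dup.side_b),
                (dup.side_b, dup.side_a),
            ):
                if len(orphan_side) == 1:
                    (sp,) = orphan_side
                    hits.append(
                        OrphanHit(
                            tree_id=res.tree_id,
                            orphan_species=sp,
                            other_side_size=len(other_side),
                            orphan_absent=sp not in other_side,
                        )
                    )
    return hits


def tabulate_cohorts(
    hits: Iterable[OrphanHit], cohorts: Mapping[str, str]
) -> pd.DataFrame:
    """Per-species hit counts under the five nested criteria.

    `cohorts` maps each orphan species to its cohort label (e.g.
    ``"low-coverage"`` / ``"high-coverage"``).  Returns a DataFrame indexed by
    species with the five criterion columns plus ``cohort``, sorted by
    descending ``isolated`` count within cohort.  Every species in `cohorts`
    gets a row; species without hits count as zeros (a zero is evidence in
    the rank test, not missing data).
    """
    counts: dict[str, dict[str, int]] = {
        sp: {c: 0 for c in CRITERIA} for sp in cohorts
    }
    for hit in hits:
        sp = hit.orphan_species
        if sp not in cohorts:
            raise ValueError(f"species {sp!r} has no cohort label")
        row = counts.setdefault(sp, {c: 0 for c in CRITERIA})
        for c in CRITERIA:
            if hit.satisfies(c):
                row[c] += 1
    table = pd.DataFrame.from_dict(counts, orient="index", columns=list(CRITERIA))
    table["cohort"] = [cohorts[sp] for sp in table.index]
    table = table.sort_values(["cohort", "isolated"], ascending=[True, False])
    table.index.name = "species"
    return table


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{pairs x_i > y_j} + ½·#{ties}."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float, max_combinations: int,
             rng: np.random.Generator) -> float:
    """Permutation distribution of U (handles ties exactly by enumerating
    group assignments); Monte-Carlo fallback above `max_combinations`."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    # U depends only on the midranks of the indices assigned to group 1.
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    n_comb = math.comb(n, n1)
    if n_comb <= max_combinations:
        count = 0
        for idx in itertools.combinations(range(n), n1):
            u = sum(ranks[i] for i in idx) - offset
            if u >= u_obs - 1e-9:
                count += 1
        return count / n_comb
    draws = max_combinations
    count = 0
    for _ in range(draws):
        idx = rng.choice(n, size=n1, replace=False)
        if ranks[idx].sum() - offset >= u_obs - 1e-9:
            count += 1
    return (count + 1) / (draws + 1)


def mann_whitney_one_tail(
    group1: Sequence[float],
    group2: Sequence[float],
    method: str = "normal",
    *,
    max_combinations: int = 2_000_000,
    seed: int = 0,
) -> TestResult:
    """One-tail Mann-Whitney test of group1 stochastically larger than group2.

    ``method="normal"`` uses the tie-corrected normal approximation without
    continuity correction: P = 1 − Φ((U − n₁n₂/2)/σ).  ``method="exact"``
    enumerates the permutation distribution of U (Monte-Carlo above
    `max_combinations` group assignments).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)

    if method == "normal":
        n = n1 + n2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            # All pooled values identical: U is exactly n1*n2/2, P = 1/2.
            z = 0.0
            p = 0.5
        else:
            z = (u - n1 * n2 / 2.0) / math.sqrt(sigma2)
            p = float(stats.norm.sf(z))
        return TestResult(U=u, z=z, p_value=p, method="normal-approximation",
                          n1=n1, n2=n2)
    if method == "exact":
        rng = np.random.default_rng(seed)
        p = _exact_p(x, y, u, max_combinations, rng)
        return TestResult(U=u, z=None, p_value=p, method="exact", n1=n1, n2=n2)
    raise ValueError(f"unknown method {method!r}")


def screen_report(
    table: pd.DataFrame,
    low_label: str = "low-coverage",
    high_label: str = "high-coverage",
    exclude: Sequence[str] = (),
    method: str = "normal",
) -> pd.DataFrame:
    """One Mann-Whitney test per criterion column: low-coverage counts greater
    than high-coverage counts.

    `exclude` drops the named species before testing (sensitivity variant,
    e.g. removing the basal Afrotherian and armadillo taxa).  Raises if an
    exclusion empties a cohort.
    """
    sub = table.drop(index=[sp for sp in exclude if sp in table.index])
    low = sub[sub["cohort"] == low_label]
    high = sub[sub["cohort"] == high_label]
    if low.empty or high.empty:
        raise ValueError("exclusion list removed an entire cohort")
    rows = []
    for criterion in CRITERIA:
        res = mann_whitney_one_tail(
            low[criterion].to_numpy(), high[criterion].to_numpy(), method=method
        )
        rows.append(
            {
                "criterion": criterion,
                "U": res.U,
                "z": res.z,
                "p_value": res.p_value,
                "n_low": res.n1,
                "n_high": res.n2,
            }
        )
    return pd.DataFrame(rows).set_index("criterion")
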