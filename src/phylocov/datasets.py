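"""Bundled reference data.

* The published per-species counts of dubious orphan duplications at the
  basal eutherian node for 14 low-coverage (~2×) and 9 high-coverage mammal
  genomes, under the five nested screen criteria.
* Low-coverage degradation profiles (mean and sd of the ambiguous fraction
  of sequence length) observed in real 2× genomes and used to perturb three
  high-coverage proteomes.
* A compact dated eutherian species tree (7 placental mammals + marsupial
  outgroup, round-number ages in My) used as the simulation fixture.
"""

from __future__ import annotations

import pandas as pd

from .lowcov import DegradationProfile
from .trees import SpeciesTree, parse_species_tree

__all__ = [
    "eutherian_orphan_counts",
    "AFROTHERIAN_AND_ARMADILLO",
    "degradation_profile",
    "eutherian_species_tree",
    "BASAL_EUTHERIAN_BRANCHES",
    "DEGRADED_FIXTURE_SPECIES",
]

# Counts of orphan-duplication hits at the eutherian node per species, under
# the criteria: isolated | other side >5 | >5 & orphan absent | >10 |
# >10 & orphan absent.  Cohorts: 2x = low-coverage draft genomes.
_LOW_COVERAGE = {
    "Sorex araneus": (621, 591, 581, 563, 557),
    "Erinaceus europaeus": (565, 531, 523, 498, 493),
    "Ochotona princeps": (376, 343, 337, 308, 302),
    "Cavia porcellus": (344, 308, 302, 280, 274),
    "Echinops telfairi": (272, 246, 235, 237, 227),
    "Myotis lucifugus": (192, 168, 156, 146, 137),
    "Tupaia belangeri": (192, 159, 150, 132, 126),
    "Spermophilus tridecemlineatus": (182, 142, 140, 110, 108),
    "Oryctolagus cuniculus": (149, 114, 108, 93, 88),
    "Otolemur garnettii": (125, 100, 97, 79, 76),
    "Loxodonta africana": (109, 77, 64, 70, 59),
    "Microcebus murinus": (112, 90, 86, 62, 59),
    "Felis catus": (98, 73, 70, 57, 54),
    "Dasypus novemcinctus": (15, 6, 0, 4, 0),
}
_HIGH_COVERAGE = {
    "Bos taurus": (200, 168, 131, 148, 112),
    "Canis familiaris": (156, 120, 94, 93, 71),
    "Mus musculus": (129, 100, 94, 75, 70),
    "Equus caballus": (134, 110, 78, 86, 58),
    "Rattus norvegicus": (73, 52, 37, 37, 28),
    "Pongo pygmaeus": (34, 25, 21, 17, 14),
    "Macaca mulatta": (62, 44, 24, 28, 14),
    "Pan troglodytes": (24, 13, 7, 10, 5),
    "Homo sapiens": (14, 7, 5, 4, 3),
}

#: Basal Afrotherian and armadillo (Xenarthra) taxa whose orphan hits could be
#: genuine deep duplications; excluded in the sensitivity variant.
AFROTHERIAN_AND_ARMADILLO = (
    "Echinops telfairi",
    "Loxodonta africana",
    "Dasypus novemcinctus",
)

_CRITERIA = ("isolated", "vs5", "vs5_no_sp", "vs10", "vs10_no_sp")


def eutherian_orphan_counts() -> pd.DataFrame:
    """Published orphan-duplication screen counts at the eutherian node.

    Returns a DataFrame indexed by species with the five criterion columns
    and a ``cohort`` column (``"low-coverage"`` / ``"high-coverage"``),
    suitable for :func:`phylocov.screen.screen_report`.
    """
    rows = []
    for cohort, counts in (
        ("low-coverage", _LOW_COVERAGE),
        ("high-coverage", _HIGH_COVERAGE),
    ):
        for sp, vals in counts.items():
            rows.append({"species": sp, "cohort": cohort, **dict(zip(_CRITERIA, vals))})
    table = pd.DataFrame(rows).set_index("species")
    return table[list(_CRITERIA) + ["cohort"]]


# Ambiguity-stretch parameters (mean, sd) as fractions of sequence length,
# matching the ranges observed in real 2x genomes.
_PROFILES = {
    "Pan troglodytes": (0.09, 0.03),
    "Mus musculus": (0.12, 0.03),
    "Bos taurus": (0.15, 0.03),
}

#: Fixture species degraded in the simulation scenario, mirrored onto the
#: compact tree: (species, mu, delta).
DEGRADED_FIXTURE_SPECIES = (
    ("Chimp", 0.09, 0.03),
    ("Mouse", 0.12, 0.03),
    ("Cow", 0.15, 0.03),
)


def degradation_profile(species: str) -> DegradationProfile:
    """Degradation profile for one of the three perturbed proteomes."""
    try:
        mu, delta = _PROFILES[species]
    except KeyError:
        raise KeyError(
            f"no published profile for {species!r}; available: {sorted(_PROFILES)}"
        ) from None
    return DegradationProfile({species: (mu, delta)})


_FIXTURE_NEWICK = (
    "(((((Human:6,Chimp:6)Primates:84,(Mouse:20,Rat:20)Rodents:70)"
    "Euarchontoglires:5,(Dog:85,Cow:85)Laurasiatheria:10)Boreoeutheria:10,"
    "Tenrec:105)Eutheria:65,Opossum:170)Theria;"
)

#: Deep eutherian stem branches where low-coverage artifacts concentrate:
#: the branch above the eutherian root and the branch above Boreoeutheria.
BASAL_EUTHERIAN_BRANCHES = ("Eutheria", "Boreoeutheria")


def eutherian_species_tree() -> SpeciesTree:
    """Dated 8-taxon mammal tree: 7 placentals + marsupial outgroup.

    Topology: ((((Human,Chimp),(Mouse,Rat)),(Dog,Cow)),Tenrec),Opossum with
    round-number node ages (My): Primates 6, Rodents 20, Euarchontoglires 90,
    Laurasiatheria 85, Boreoeutheria 95, Eutheria 105, root (Theria) 170.
    """
    return parse_species_tree(_FIXTURE_NEWICK)
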