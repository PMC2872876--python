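"""Low-coverage degradation of protein sequences and ambiguity accounting.

Low sequencing coverage leaves genes fragmented: in protein annotations this
surfaces as runs of the ambiguity character 'X'.  The simulator emulates it
by replacing, in every sequence of a targeted species, one contiguous stretch
whose total length is a truncated-normal fraction of the sequence length.
Also provides per-sequence/per-species ambiguity statistics and the
gap-threshold alignment column-trimming rule used before tree inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "ProteinSet",
    "DegradationProfile",
    "AmbiguityStats",
    "degrade",
    "ambiguity_stats",
    "cohort_ambiguity_compare",
    "trim_columns",
    "TrimResult",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = frozenset(AMINO_ACIDS + "X")


@dataclass
class ProteinSet:
    """Protein sequences keyed by identifier, each assigned to a species.

    Sequences are strings over the 20 amino acids plus the ambiguity
    character 'X'.
    """

    sequences: dict[str, str] = field(default_factory=dict)
    species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence {sid!r}")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"invalid residues {sorted(bad)} in {sid!r}")
            if sid not in self.species:
                raise ValueError(f"sequence {sid!r} has no species assignment")

    def __len__(self) -> int:
        return len(self.sequences)

    def ids_of_species(self, species: str) -> list[str]:
        return [sid for sid, sp in self.species.items() if sp == species]

    @property
    def all_species(self) -> set[str]:
        return set(self.species.values())

    def to_fasta(self, handle: TextIO) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description=self.species[sid])
            for sid, seq in self.sequences.items()
        ]
        SeqIO.write(records, handle, "fasta")

    @classmethod
    def from_fasta(cls, handle: TextIO, species_of=None) -> "ProteinSet":
        """Read FASTA; species taken from the record description, or from
        `species_of(record_id)` when given."""
        sequences, species = {}, {}
        for rec in SeqIO.parse(handle, "fasta"):
            sequences[rec.id] = str(rec.seq).upper()
            if species_of is not None:
                species[rec.id] = species_of(rec.id)
            else:
                desc = rec.description.split(None, 1)
                species[rec.id] = desc[1] if len(desc) > 1 else rec.id.rsplit("_", 1)[-1]
        return cls(sequences, species)


@dataclass
class DegradationProfile:
    """Per-species ambiguity-stretch parameters.

    For each targeted species: μ = mean and δ = standard deviation of the
    ambiguous fraction of sequence length (normal, truncated to [0, 1]).
    """

    params: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for sp, (mu, delta) in self.params.items():
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"mu for {sp!r} must be in [0,1], got {mu}")
            if delta < 0:
                raise ValueError(f"delta for {sp!r} must be >= 0, got {delta}")

    def __contains__(self, species: str) -> bool:
        return species in self.params

    def merged(self, other: "DegradationProfile") -> "DegradationProfile":
        return DegradationProfile({**self.params, **other.params})


@dataclass
class AmbiguityStats:
    """Fraction of 'X' residues per sequence, and the per-species means."""

    per_sequence: dict[str, float]
    per_species: dict[str, float]


def _truncated_normal(mu: float, delta: float, rng: np.random.Generator) -> float:
    """Draw Normal(mu, delta) restricted to [0, 1] by resampling (no point
    mass at the bounds, unlike clipping)."""
    if delta == 0:
        if not 0 <= mu <= 1:
            raise ValueError("mu outside [0,1] with zero delta")
        return mu
    while True:
        f = rng.normal(mu, delta)
        if 0.0 <= f <= 1.0:
            return f


def degrade(
    proteins: ProteinSet,
    profile: DegradationProfile,
    seed: int | np.random.Generator = 0,
    stretches: int = 1,
) -> ProteinSet:
    """Inject contiguous ambiguity stretches into targeted species' sequences.

    For every sequence of length L belonging to a species in `profile`, a
    fraction f ~ Normal(μ, δ) truncated to [0, 1] is drawn and round(f·L)
    residues are replaced by 'X' as one contiguous run at a uniformly random
    start (with ``stretches=k``, the run is split into k runs at random
    positions).  Untargeted species pass through unchanged.  Lengths and
    identifiers are never altered.
    """
    if stretches < 1:
        raise ValueError("stretches must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, str] = {}
    for sid, seq in proteins.sequences.items():
        sp = proteins.species[sid]
        if sp not in profile:
            out[sid] = seq
            continue
        mu, delta = profile.params[sp]
        L = len(seq)
        total = int(round(_truncated_normal(mu, delta, rng) * L))
        if total == 0:
            out[sid] = seq
            continue
        # Split the total masked length into `stretches` positive parts.
        if stretches == 1:
            parts = [total]
        else:
            k = min(stretches, total)
            cuts = sorted(rng.choice(np.arange(1, total), size=k - 1, replace=False)) if total > 1 else []
            parts = list(np.diff([0, *cuts, total]))
        chars = list(seq)
        for part in parts:
            start = int(rng.integers(0, L - part + 1))
            chars[start : start + part] = "X" * part
        out[sid] = "".join(chars)
    return ProteinSet(out, dict(proteins.species))


def ambiguity_stats(proteins: ProteinSet) -> AmbiguityStats:
    """Per-sequence 'X' fraction and per-species mean over sequences."""
    per_sequence = {
        sid: seq.count("X") / len(seq) for sid, seq in proteins.sequences.items()
    }
    per_species: dict[str, float] = {}
    for sp in proteins.all_species:
        vals = [per_sequence[sid] for sid in proteins.ids_of_species(sp)]
        per_species[sp] = float(np.mean(vals))
    return AmbiguityStats(per_sequence, per_species)


def cohort_ambiguity_compare(
    stats: AmbiguityStats, gene_subsets: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Mean ambiguity per named subset of sequence identifiers.

    Used for the negative control: genes inferred as duplicated on the deep
    eutherian branches are not expected to be more ambiguous than genes
    duplicated elsewhere."""
    means: dict[str, float] = {}
    for name, ids in gene_subsets.items():
        missing = [i for i in ids if i not in stats.per_sequence]
        if missing:
            raise KeyError(f"unknown sequence identifiers in subset {name!r}: {missing}")
        means[name] = float(np.mean([stats.per_sequence[i] for i in ids]))
    return means


@dataclass
class TrimResult:
    alignment: list[str]
    kept_columns: list[int]
    threshold: float


def trim_columns(
    alignment: Sequence[str], gap_char: str = "-", threshold: float = 0.10
) -> TrimResult:
    """Drop alignment columns whose gap fraction strictly exceeds `threshold`.

    If that would remove more than one-third of the columns, the threshold is
    raised in steps of 0.01 until at least two-thirds of the original columns
    survive.  Raises on ragged (non-rectangular) alignments.
    """
    if not alignment:
        raise ValueError("empty alignment")
    ncol = len(alignment[0])
    if any(len(row) != ncol for row in alignment):
        raise ValueError("ragged alignment: sequences differ in length")
    mat = np.array([list(row) for row in alignment])
    gap_frac = (mat == gap_char).mean(axis=0)

    min_keep = math.ceil(2 * ncol / 3)
    thr = threshold
    keep = gap_frac <= thr + 1e-12
    while keep.sum() < min_keep and thr < 1.0:
        thr = round(thr + 0.01, 10)
        keep = gap_frac <= thr + 1e-12
    kept = [i for i in range(ncol) if keep[i]]
    trimmed = ["".join(row[i] for i in kept) for row in alignment]
    return TrimResult(alignment=trimmed, kept_columns=kept, threshold=thr)
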