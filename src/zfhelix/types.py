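"""Core domain types shared across the package.

A Cys2His2 zinc finger reads ~3 bp of DNA through six designable residues at
recognition-helix positions -1, 1, 2, 3, 5 and 6 (position +4 is an invariant
leucine and is never stored).  Adjacent fingers share an *overlap base*: the
base adjacent to a finger's triplet that couples the neighbouring finger's
position-6 side chain to this finger's positions -1/2.  Throughout the package
a finger's nucleotide sub-target is written as a 4-mer ``[overlap, t1, t2, t3]``
and a two-finger target as a 7-mer whose base 4 is shared between the two
overlapping 4-mers (bases 1-4 and bases 4-7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: DNA alphabet, the column order of every nucleotide PWM.
BASES: str = "ACGT"
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

#: Designable helix positions, N->C.  Index i of a helix string is position
#: HELIX_POSITIONS[i]; the invariant +4 leucine is excluded.
HELIX_POSITIONS: tuple[int, ...] = (-1, 1, 2, 3, 5, 6)

#: Allowed DNA target lengths (3-mer half-site .. 8-mer specificity library).
TARGET_LENGTHS: frozenset[int] = frozenset({3, 4, 6, 7, 8})


class InputError(ValueError):
    """Malformed user input (bad alphabet, bad table row, bad config)."""


def _check_protein(seq: str, length: int) -> None:
    if len(seq) != length:
        raise InputError(f"helix must have {length} residues, got {len(seq)}: {seq!r}")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise InputError(f"non-standard residue symbols {sorted(bad)} in {seq!r}")


@dataclass(frozen=True, slots=True)
class CoreHelix:
    """The six designable recognition-helix residues of one finger.

    ``residues[i]`` is the residue at helix position ``HELIX_POSITIONS[i]``.
    """

    residues: str

    def __post_init__(self) -> None:
        _check_protein(self.residues, 6)

    def __str__(self) -> str:
        return self.residues

    def __len__(self) -> int:
        return 6


@dataclass(frozen=True, slots=True)
class HelixPair:
    """Two core helices designed to bind a 7-mer target.

    ``finger1`` binds the 3' sub-target (bases 4-7 of the 7-mer) and receives
    the overlap environment through its positions -1/2; ``finger2`` binds
    bases 1-4 and contributes its position-6 residue at the shared base 4.
    """

    finger1: CoreHelix
    finger2: CoreHelix

    @classmethod
    def from_string(cls, s: str) -> "HelixPair":
        """Parse a 12-residue string (finger1 then finger2)."""
        _check_protein(s, 12)
        return cls(CoreHelix(s[:6]), CoreHelix(s[6:]))

    def __str__(self) -> str:
        return self.finger1.residues + self.finger2.residues

    def __len__(self) -> int:
        return 12


@dataclass(frozen=True, slots=True)
class DnaTarget:
    """A DNA target sequence, 5'->3', over {A, C, G, T}.

    For 7-mers, base 4 is the overlap base shared by the two 4-mer
    sub-targets (bases 1-4 and bases 4-7).
    """

    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise InputError(
                f"non-ACGT symbols {sorted(bad)} in target {self.sequence!r}"
            )
        if len(self.sequence) not in TARGET_LENGTHS:
            raise InputError(
                f"target length {len(self.sequence)} not in {sorted(TARGET_LENGTHS)}"
            )

    def __str__(self) -> str:
        return self.sequence

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def overlap_base(self) -> str:
        """The shared overlap base: base 1 of a 4-mer, base 4 of a 7-mer."""
        if len(self.sequence) == 7:
            return self.sequence[3]
        if len(self.sequence) == 4:
            return self.sequence[0]
        raise InputError(f"no overlap-base convention for a {len(self)}-mer")

    def subtargets(self) -> tuple["DnaTarget", "DnaTarget"]:
        """Split a 7-mer into the finger1 (bases 4-7) and finger2 (bases 1-4)
        sub-4-mers, in (finger1, finger2) order."""
        if len(self.sequence) != 7:
            raise InputError("subtargets are defined for 7-mers only")
        return DnaTarget(self.sequence[3:]), DnaTarget(self.sequence[:4])


@dataclass(frozen=True, slots=True)
class LibraryContext:
    """The fixed neighbour-finger environment of a selection library.

    ``fixed_helices`` holds the helices of the anchoring domains (N-terminal
    neighbours of the randomised finger); the last one's position-6 residue is
    the side chain presented at the overlap.  ``overlap_base`` is the base that
    neighbour specifies at the overlap position.
    """

    library_id: str
    fixed_helices: tuple[CoreHelix, ...]
    overlap_base: str

    def __post_init__(self) -> None:
        if self.overlap_base not in BASES:
            raise InputError(f"overlap base must be one of {BASES}")
        if not self.fixed_helices:
            raise InputError("a library context needs at least one fixed helix")

    @property
    def neighbor_p6(self) -> str:
        """Position-6 residue of the adjacent fixed finger (the overlap side chain)."""
        return self.fixed_helices[-1].residues[5]


@dataclass(slots=True)
class SelectionRecord:
    """One surviving helix (or pair) with its per-encoding read counts."""

    helix_or_pair: CoreHelix | HelixPair
    encoding_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.encoding_counts.values())

    @property
    def n_encodings(self) -> int:
        return len(self.encoding_counts)

    @property
    def sequence(self) -> str:
        return str(self.helix_or_pair)


@dataclass(slots=True)
class SelectionDataset:
    """One B1H selection: a library context (or pair-library id), a DNA
    target, and the surviving helix records."""

    target: DnaTarget
    records: list[SelectionRecord]
    context: LibraryContext | None = None
    library_id: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            seq = rec.sequence
            if seq in seen:
                raise InputError(f"duplicate helix {seq!r} in dataset")
            seen.add(seq)
            if any(c < 0 for c in rec.encoding_counts.values()):
                raise InputError(f"negative read count for helix {seq!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def is_pair(self) -> bool:
        return len(self.target) == 7

    def sequences(self) -> list[str]:
        return [rec.sequence for rec in self.records]

    def read_weights(self) -> list[int]:
        return [rec.total_reads for rec in self.records]
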