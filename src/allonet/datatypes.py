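"""In-memory domain containers shared by all pipeline stages.

Everything downstream of the readers operates on these types only:
:class:`Alignment` for aligned sequences, :class:`StructureModel` for a
coarse per-residue view of a protein structure (one CA coordinate plus an
optional side-chain centroid per residue, and hetero groups such as heme).
Phylogenetic trees are represented directly as :class:`dendropy.Tree`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentFormatError, EmptyInputError, IdentifierError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X", "-"}

#: Heavy-atom counts of the 20 standard side chains (glycine has none).
SIDECHAIN_HEAVY_ATOMS = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class SeqRecord:
    """One aligned sequence: an identifier and its residue string."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise IdentifierError("sequence identifier must be non-empty")
        if not self.residues:
            raise EmptyInputError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - ALPHABET
        if bad:
            raise AlignmentFormatError(
                f"sequence {self.id!r} contains characters outside the "
                f"amino-acid alphabet: {sorted(bad)}"
            )


class Alignment:
    """An ordered multiple sequence alignment over {20 aa, 'X', '-'}.

    Columns are indexed 0-based internally; user-facing position labels are
    1-based with respect to the ungapped reference sequence (``ref_index``,
    default the first record).
    """

    def __init__(self, records: list[SeqRecord], ref_index: int = 0):
        if len(records) < 2:
            raise EmptyInputError("an alignment needs at least 2 sequences")
        lengths = {len(r.residues) for r in records}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise IdentifierError(f"duplicate sequence ids: {dup}")
        if not 0 <= ref_index < len(records):
            raise IndexError("ref_index out of range")
        self.records = list(records)
        self.ref_index = ref_index

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def to_matrix(self) -> np.ndarray:
        """Character matrix of shape (n, length), dtype '<U1'."""
        return np.array([list(r.residues.upper()) for r in self.records])

    # -- reference coordinates ------------------------------------------
    def ref_positions(self) -> list[int | None]:
        """1-based ungapped reference position per column (None at ref gaps)."""
        out: list[int | None] = []
        pos = 0
        for ch in self.records[self.ref_index].residues:
            if ch == "-":
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def ref_sequence(self) -> str:
        """The reference sequence with gaps removed."""
        return self.records[self.ref_index].residues.replace("-", "")

    def subset_columns(self, columns: list[int]) -> "Alignment":
        recs = [
            SeqRecord(r.id, "".join(r.residues[j] for j in columns))
            for r in self.records
        ]
        return Alignment(recs, ref_index=self.ref_index)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.records == other.records
            and self.ref_index == other.ref_index
        )

    def __repr__(self) -> str:
        return f"Alignment(n={self.n}, length={self.length})"


@dataclass(frozen=True)
class Residue:
    """One residue of a structure: CA plus an optional side-chain centroid."""

    number: int
    name: str
    ca: tuple[float, float, float]
    sidechain_centroid: tuple[float, float, float] | None = None
    sidechain_count: int = 0
    icode: str = ""

    @property
    def key(self) -> str:
        """Residue number with insertion-code suffix, e.g. '52' or '52A'."""
        return f"{self.number}{self.icode}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class HeteroGroup:
    """A non-polymer group (e.g. HEM) as a bag of heavy-atom coordinates."""

    name: str
    coords: np.ndarray  # (n_atoms, 3)


@dataclass
class StructureModel:
    """Coarse structure: ordered chains of residues plus hetero groups."""

    chains: list[Chain] = field(default_factory=list)
    hetero_groups: list[HeteroGroup] = field(default_factory=list)

    def residues(self) -> list[tuple[str, Residue]]:
        return [(c.id, r) for c in self.chains for r in c.residues]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def hetero(self, name: str) -> HeteroGroup:
        for g in self.hetero_groups:
            if g.name == name:
                return g
        raise KeyError(f"no hetero group {name!r}")

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain ('X' for non-standard residues)."""
        return "".join(
            THREE_TO_ONE.get(r.name, "X") for r in self.chain(chain_id).residues
        )
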