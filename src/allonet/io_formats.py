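"""Readers and writers for every on-disk format the pipeline touches.

Aligned FASTA for sequences (Bio.SeqIO underneath), Newick for trees
(dendropy), a pragmatic PDB subset for structures (Bio.PDB: first model
only, highest-occupancy altloc), and CSV/TSV for matrices and profiles.
All other modules consume only the in-memory types from
:mod:`allonet.datatypes`.
"""

from __future__ import annotations

import io
import math
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .datatypes import (
    Alignment,
    Chain,
    HeteroGroup,
    Residue,
    SeqRecord,
    StructureModel,
)
from .errors import (
    EmptyInputError,
    IdentifierError,
    SerializationError,
    StructureError,
    TreeError,
)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


# ----------------------------------------------------------------------
# alignments
# ----------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Raises an alignment-format error on ragged lengths, an identifier
    error on duplicate ids, and an empty-input error on an empty file.
    """
    if format != "fasta":
        raise ValueError(f"unsupported alignment format {format!r}")
    records = [
        SeqRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise EmptyInputError(f"no sequences in {path}")
    return Alignment(records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description="")
        for r in aln.records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; missing branch lengths default to 1.0."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    return _normalize_tree(tree)


def read_tree_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"cannot parse Newick string: {exc}") from exc
    return _normalize_tree(tree)


def _normalize_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise IdentifierError(f"duplicate leaf labels in tree: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
        elif edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip()
        + "\n"
    )


# ----------------------------------------------------------------------
# structures (PDB subset)
# ----------------------------------------------------------------------

def read_structure(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM records of the first model of a PDB file.

    Altloc rule: keep the highest-occupancy location, ties resolved in
    favour of altloc 'A'. The side-chain centroid is the mean of the
    side-chain heavy atoms when any are present; waters are skipped.
    Insertion codes become suffixes of the residue key.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError(f"no models in {path}") from None

    chains: list[Chain] = []
    hetero: dict[str, list[np.ndarray]] = {}
    n_ca = 0
    for bio_chain in model:
        residues: list[Residue] = []
        for res in bio_chain:
            hetflag, resseq, icode = res.id
            if hetflag == "W":
                continue
            atoms = {}
            for atom in res.get_unpacked_list():
                if atom.element == "H":
                    continue
                name = atom.get_name()
                prev = atoms.get(name)
                if prev is not None:
                    if (atom.get_occupancy() or 0.0, _altloc_pref(atom)) <= (
                        prev.get_occupancy() or 0.0,
                        _altloc_pref(prev),
                    ):
                        continue
                atoms[name] = atom
            coords = {n: np.asarray(a.get_coord(), float) for n, a in atoms.items()}
            if hetflag != " ":
                group = hetflag[2:].strip() or res.get_resname().strip()
                hetero.setdefault(group, []).extend(coords.values())
                continue
            if "CA" not in coords:
                continue
            side = [c for n, c in coords.items() if n not in BACKBONE_ATOMS]
            centroid = (
                tuple(np.mean(side, axis=0)) if side else None
            )
            residues.append(
                Residue(
                    number=int(resseq),
                    name=res.get_resname().strip(),
                    ca=tuple(coords["CA"]),
                    sidechain_centroid=centroid,
                    sidechain_count=len(side),
                    icode=icode.strip(),
                )
            )
            n_ca += 1
        if residues:
            chains.append(Chain(id=bio_chain.id, residues=residues))
    if n_ca == 0:
        raise StructureError(f"no CA atoms in {path}")
    groups = [
        HeteroGroup(name=name, coords=np.array(coords_list))
        for name, coords_list in hetero.items()
    ]
    return StructureModel(chains=chains, hetero_groups=groups)


def _altloc_pref(atom) -> int:
    # Higher is better; altloc 'A' (or blank) wins occupancy ties.
    alt = atom.get_altloc()
    return 1 if alt in (" ", "", "A") else 0


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as PDB text.

    Each residue is emitted as a CA atom plus, when a side chain exists,
    a single CB pseudo-atom at the side-chain centroid; hetero groups are
    emitted as HETATM records. This is a coarse serialization intended
    for synthetic structures and round-tripping through
    :func:`read_structure` (which recovers per-residue masses from the
    residue name, not from the atom count).
    """
    lines = []
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            lines.append(_pdb_atom(serial, "CA", res, chain.id, res.ca))
            serial += 1
            if res.sidechain_centroid is not None:
                lines.append(
                    _pdb_atom(serial, "CB", res, chain.id, res.sidechain_centroid)
                )
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    for group in model.hetero_groups:
        for i, xyz in enumerate(np.asarray(group.coords), start=1):
            name = f"X{i}" if i < 100 else "X"
            lines.append(
                f"HETATM{serial:>5} {name:<4s}{group.name:>4s} X{900:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}           C"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _pdb_atom(serial: int, atom: str, res: Residue, chain_id: str, xyz) -> str:
    elem = atom[0]
    return (
        f"ATOM  {serial:>5} {atom:<4s}{res.name:>4s} {chain_id}{res.number:>4}"
        f"{res.icode or ' ':1}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"           {elem}"
    )


# ----------------------------------------------------------------------
# matrices and profiles
# ----------------------------------------------------------------------

def write_matrix(
    values: np.ndarray,
    path: str | Path,
    labels: list | None = None,
    index_labels: list | None = None,
) -> None:
    """Write a finite numeric matrix (or vector) as CSV, 17-digit floats.

    NaN or infinite entries raise a serialization error; round-trip
    through :func:`read_matrix` reproduces values to better than 1e-12.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise SerializationError("matrix contains NaN or infinite entries")
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
        labels = labels or ["value"]
    df = pd.DataFrame(arr, columns=labels, index=index_labels)
    df.to_csv(path, float_format="%.17g", index=index_labels is not None)


def read_matrix(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    for col in df.columns:
        if df[col].dtype.kind == "f" and df[col].map(
            lambda v: isinstance(v, float) and math.isnan(v)
        ).any():
            raise SerializationError(f"column {col!r} contains NaN")
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def alignment_to_string(aln: Alignment) -> str:
    buf = io.StringIO()
    for r in aln.records:
        buf.write(f">{r.id}\n{r.residues}\n")
    return buf.getvalue()
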