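"""I/O for every external format the pipeline touches.

Readers: FASTA, aligned FASTA, PSI-BLAST ASCII PSSM, PDB ``ATOM`` records.
Writers: FASTA, PSSM (same dialect), the tab-separated prediction pair list
and the plain-text upper-triangular contact matrix.

All user-facing residue indices (pair list, matrix file, PDB) are 1-based;
everything internal to the package is 0-based and converted here, at the
I/O boundary.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqUtils import seq1

from .errors import (
    AlignmentShapeError,
    ChainNotFoundError,
    ContractError,
    ParseError,
)

#: The 20 standard one-letter codes, alphabetical.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the PSI-BLAST ASCII PSSM dialect.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_VALID_RESIDUES = frozenset(AA20 + "X")


@dataclasses.dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence (one-letter codes, 'X' allowed)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ContractError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ContractError(
                f"sequence {self.id!r} contains invalid residue codes: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped sequences; the first row is the query."""

    rows: tuple[tuple[str, str], ...]
    ncols: int

    def __post_init__(self) -> None:
        for rid, seq in self.rows:
            if len(seq) != self.ncols:
                raise AlignmentShapeError(
                    f"alignment row {rid!r} has length {len(seq)}, expected {self.ncols}"
                )

    @property
    def nrows(self) -> int:
        return len(self.rows)

    @property
    def query(self) -> str:
        """The first row with gaps removed."""
        return self.rows[0][1].replace("-", "")


@dataclasses.dataclass(frozen=True)
class PSSMProfile:
    """Per-position log-odds scores plus per-position information content.

    ``scores`` is an ``L x 20`` integer matrix in :data:`PSSM_ALPHABET`
    column order; ``info`` holds information content in bits.
    """

    length: int
    scores: np.ndarray
    info: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != (self.length, 20):
            raise ContractError(
                f"PSSM scores shape {self.scores.shape} != ({self.length}, 20)"
            )
        if self.info.shape != (self.length,):
            raise ContractError("PSSM info vector length mismatch")


@dataclasses.dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclasses.dataclass(frozen=True)
class ResidueRecord:
    seq_index: int  # 1-based residue number from the coordinate file
    code: str  # one-letter residue code ('X' for unknowns)
    atoms: tuple[Atom, ...]


@dataclasses.dataclass(frozen=True)
class StructureCoordinates:
    """Heavy-atom coordinates of one chain, ordered by residue number."""

    chain_id: str
    residues: tuple[ResidueRecord, ...]

    def __post_init__(self) -> None:
        indices = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ContractError("residue sequence indices must be strictly increasing")

    def by_index(self) -> dict[int, ResidueRecord]:
        return {r.seq_index: r for r in self.residues}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _parse_fasta_records(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    text = path.read_text()
    stripped = text.strip()
    if not stripped:
        raise ParseError(f"{path}: empty FASTA file (line 1)")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header starting with '>'"
                )
            break
    with path.open() as fh:
        return [(title.split()[0], seq) for title, seq in SimpleFastaParser(fh)]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file; sequences are uppercased and '*' is stripped."""
    records = []
    for rid, seq in _parse_fasta_records(path):
        if not rid:
            raise ParseError(f"{path}: record with empty header id")
        records.append(ProteinSequence(rid, seq.upper().replace("*", "")))
    return records


def write_fasta(path: str | Path, sequences: Iterable[ProteinSequence]) -> None:
    with Path(path).open("w") as fh:
        for rec in sequences:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned-FASTA file; ragged input is rejected."""
    records = _parse_fasta_records(path)
    ncols = len(records[0][1])
    rows = tuple((rid, seq.upper()) for rid, seq in records)
    for rid, seq in rows:
        if len(seq) != ncols:
            raise AlignmentShapeError(
                f"{path}: row {rid!r} has length {len(seq)}, expected {ncols}"
            )
    return MultipleAlignment(rows=rows, ncols=ncols)


def write_alignment(path: str | Path, msa: MultipleAlignment) -> None:
    with Path(path).open("w") as fh:
        for rid, seq in msa.rows:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------


def _pssm_information(score_row: Sequence[int]) -> float:
    # Implied distribution from half-bit log-odds over a uniform background,
    # then relative entropy against that background (bits).
    log2p = np.asarray(score_row, dtype=float) / 2.0
    log2p -= log2p.max()
    p = 2.0 ** log2p
    p /= p.sum()
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(20.0 * p[nz])))


def read_psiblast_pssm(
    path: str | Path, expected_length: int | None = None
) -> PSSMProfile:
    """Parse the standard PSI-BLAST ASCII PSSM.

    Only the first 20 score columns are consumed.  The per-position
    information column is captured when present; otherwise information
    content is computed as relative entropy against a uniform background.
    """
    path = Path(path)
    scores: list[list[int]] = []
    info: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if len(tokens) < 2 or not tokens[0].isdigit():
            continue
        if len(tokens[1]) != 1 or not tokens[1].isalpha():
            continue
        fields = tokens[2:]
        if len(fields) < 20:
            raise ParseError(
                f"{path}: line {lineno}: expected 20 score fields, found {len(fields)}"
            )
        try:
            row = [int(f) for f in fields[:20]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer score field") from exc
        scores.append(row)
        # Full dialect: 20 log-odds + 20 percentages + information + weight.
        if len(fields) >= 42:
            try:
                info.append(float(fields[40]))
            except ValueError:
                info.append(_pssm_information(row))
        else:
            info.append(_pssm_information(row))
    if not scores:
        raise ParseError(f"{path}: no PSSM rows found")
    if expected_length is not None and len(scores) != expected_length:
        raise ParseError(
            f"{path}: {len(scores)} PSSM rows, expected {expected_length}"
        )
    return PSSMProfile(
        length=len(scores),
        scores=np.asarray(scores, dtype=int),
        info=np.asarray(info, dtype=float),
    )


def write_psiblast_pssm(path: str | Path, pssm: PSSMProfile, sequence: str) -> None:
    """Write a PSSM in the ASCII dialect :func:`read_psiblast_pssm` accepts."""
    if len(sequence) != pssm.length:
        raise ContractError("sequence length does not match PSSM length")
    with Path(path).open("w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("      " + "   ".join(PSSM_ALPHABET) + "\n")
        for k in range(pssm.length):
            row = " ".join(f"{v:4d}" for v in pssm.scores[k])
            fh.write(f"{k + 1:5d} {sequence[k]} {row}  {pssm.info[k]:6.2f}\n")


# ---------------------------------------------------------------------------
# PDB coordinates
# ---------------------------------------------------------------------------


def read_coordinates(path: str | Path, chain: str) -> StructureCoordinates:
    """Read heavy-atom ATOM records for one chain of a PDB file.

    HETATM records and hydrogens are dropped; only altloc ' ' or 'A' atoms
    are kept; insertion codes are rejected.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ChainNotFoundError(
            f"chain {chain!r} not found in {path} "
            f"(available: {[c.id for c in model]})"
        )
    residues: list[ResidueRecord] = []
    for residue in model[chain]:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue  # HETATM
        if icode.strip():
            raise ParseError(
                f"{path}: residue {resseq}{icode} carries an insertion code; "
                "renumber the chain before use"
            )
        atoms = []
        for atom in residue.get_unpacked_list():
            element = (atom.element or "").strip().upper()
            if element in ("H", "D"):
                continue
            if atom.get_altloc() not in (" ", "A"):
                continue
            x, y, z = (float(v) for v in atom.get_coord())
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ParseError(f"{path}: non-finite coordinate in residue {resseq}")
            atoms.append(Atom(name=atom.get_name(), element=element, coord=(x, y, z)))
        if atoms:
            code = seq1(residue.get_resname(), undef_code="X")
            residues.append(
                ResidueRecord(seq_index=resseq, code=code, atoms=tuple(atoms))
            )
    return StructureCoordinates(chain_id=chain, residues=tuple(residues))


def write_pdb(path: str | Path, structure: StructureCoordinates) -> None:
    """Write ATOM records (fixed-column PDB format) for one chain."""
    from Bio.SeqUtils import seq3

    with Path(path).open("w") as fh:
        serial = 1
        for res in structure.residues:
            resname = seq3(res.code).upper()
            for atom in res.atoms:
                x, y, z = atom.coord
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} {resname:>3s} "
                    f"{structure.chain_id}{res.seq_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Prediction output files
# ---------------------------------------------------------------------------

PAIR_LIST_HEADER = "i\tj\tprobability\tlabel"


def _check_prediction(i: int, j: int, prob: float, label: int, length: int | None):
    if i >= j:
        raise ContractError(f"pair ({i}, {j}): expected i < j (1-based)")
    if i < 1:
        raise ContractError(f"pair ({i}, {j}): indices must be >= 1")
    if length is not None and j > length:
        raise ContractError(f"pair ({i}, {j}): index exceeds sequence length {length}")
    if not 0.0 <= prob <= 1.0:
        raise ContractError(f"pair ({i}, {j}): probability {prob} outside [0, 1]")
    if label not in (0, 1):
        raise ContractError(f"pair ({i}, {j}): label {label} not in {{0, 1}}")


def write_pair_list(
    path: str | Path, predictions: Iterable[tuple[int, int, float, int]]
) -> None:
    """Write the TSV pair list: ``i  j  probability  label`` (1-based, i < j)."""
    rows = sorted(predictions)
    for i, j, prob, label in rows:
        _check_prediction(i, j, prob, label, None)
    with Path(path).open("w") as fh:
        fh.write(PAIR_LIST_HEADER + "\n")
        for i, j, prob, label in rows:
            fh.write(f"{i}\t{j}\t{prob:.6f}\t{label}\n")


def read_pair_list(path: str | Path) -> list[tuple[int, int, float, int]]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != PAIR_LIST_HEADER:
        raise ParseError(f"{path}: missing pair-list header")
    out = []
    for line in lines[1:]:
        i, j, prob, label = line.split("\t")
        out.append((int(i), int(j), float(prob), int(label)))
    return out


def write_contact_matrix(
    path: str | Path, length: int, predictions: Iterable[tuple[int, int, float, int]]
) -> None:
    """Write the upper-triangular matrix file.

    Cell (i, j), i < j holds the 0/1 prediction label; unscored upper cells
    are "0"; the diagonal and lower triangle are "-".
    """
    grid = [["-"] * length for _ in range(length)]
    for i in range(length):
        for j in range(i + 1, length):
            grid[i][j] = "0"
    for i, j, prob, label in predictions:
        _check_prediction(i, j, prob, label, length)
        grid[i - 1][j - 1] = str(label)
    with Path(path).open("w") as fh:
        for row in grid:
            fh.write(" ".join(row) + "\n")


def read_contact_matrix(path: str | Path) -> list[list[str]]:
    return [line.split() for line in Path(path).read_text().splitlines()]
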