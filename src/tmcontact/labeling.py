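"""Ground-truth interhelical contact labels from 3D coordinates.

Three residue-pair contact definitions:

* **I**   — minimum heavy-atom distance strictly below 5.5 Å (default),
* **II**  — some heavy-atom pair within the sum of the two van der Waals
            radii plus 0.6 Å,
* **III** — Cβ–Cβ distance (Cα for glycine) within 8 Å.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, ContractError, MissingAtomError, TableLookupError
from .features import TopologyString, enumerate_candidate_pairs
from .seqio import ResidueRecord, StructureCoordinates

logger = logging.getLogger(__name__)

DEFINITIONS = ("I", "II", "III")

HEAVY_ATOM_CUTOFF = 5.5  # definition I, strict
VDW_EXTRA = 0.6  # definition II
CBETA_CUTOFF = 8.0  # definition III


@dataclasses.dataclass(frozen=True)
class VdwRadiusTable:
    """Van der Waals radii (Å), Li–Nussinov style.

    ``by_atom_name`` refines protein atom-name classes; anything not listed
    falls back to ``by_element`` with a warning.
    """

    by_atom_name: dict[str, float]
    by_element: dict[str, float]

    def __post_init__(self) -> None:
        for radius in list(self.by_atom_name.values()) + list(self.by_element.values()):
            if not 0.5 < radius < 3.0:
                raise ContractError(f"implausible VDW radius {radius} Å")

    def lookup(self, atom_name: str, element: str) -> float:
        if atom_name in self.by_atom_name:
            return self.by_atom_name[atom_name]
        element = element.upper()
        if element not in self.by_element:
            raise TableLookupError(
                f"no VDW radius for element {element!r} (atom {atom_name!r})"
            )
        logger.debug("atom %r not in name table; element fallback %s", atom_name, element)
        return self.by_element[element]


#: Bundled compact radius table: carbonyl/carboxyl C 1.61, sp3 C 1.88,
#: amide/amine N 1.64, carbonyl O 1.42, hydroxyl/carboxyl O 1.46, S 1.77;
#: plain element fallbacks otherwise.
DEFAULT_VDW_TABLE = VdwRadiusTable(
    by_atom_name={
        "C": 1.61,
        "O": 1.42,
        "OXT": 1.46,
        "N": 1.64,
        "CA": 1.88,
        "CB": 1.88,
        "SG": 1.77,
        "SD": 1.77,
        "OG": 1.46,
        "OG1": 1.46,
        "OH": 1.46,
    },
    by_element={"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90},
)


@dataclasses.dataclass(frozen=True)
class ContactMap:
    """Labelled interhelical residue pairs, 1-based, i < j."""

    length: int
    contacts: frozenset[tuple[int, int]]
    definition: str

    def __post_init__(self) -> None:
        if self.definition not in DEFINITIONS:
            raise ConfigurationError(f"unknown contact definition {self.definition!r}")
        for i, j in self.contacts:
            if not (1 <= i < j <= self.length):
                raise ContractError(f"contact ({i}, {j}) outside 1..{self.length}")

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return pair in self.contacts

    def __len__(self) -> int:
        return len(self.contacts)


def _coords(res: ResidueRecord) -> np.ndarray:
    if not res.atoms:
        raise MissingAtomError(f"residue {res.seq_index} has no atoms")
    return np.array([a.coord for a in res.atoms], dtype=float)


def min_heavy_atom_distance(res_a: ResidueRecord, res_b: ResidueRecord) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs (Å)."""
    return float(cdist(_coords(res_a), _coords(res_b)).min())


def contact_def1(res_a: ResidueRecord, res_b: ResidueRecord) -> bool:
    """Definition I: minimum heavy-atom distance < 5.5 Å (strict)."""
    return min_heavy_atom_distance(res_a, res_b) < HEAVY_ATOM_CUTOFF


def contact_def2(
    res_a: ResidueRecord,
    res_b: ResidueRecord,
    table: VdwRadiusTable = DEFAULT_VDW_TABLE,
) -> bool:
    """Definition II: some atom pair within r_vdw(a) + r_vdw(b) + 0.6 Å."""
    dist = cdist(_coords(res_a), _coords(res_b))
    ra = np.array([table.lookup(a.name, a.element) for a in res_a.atoms])
    rb = np.array([table.lookup(b.name, b.element) for b in res_b.atoms])
    cutoff = ra[:, None] + rb[None, :] + VDW_EXTRA
    return bool((dist <= cutoff).any())


def _cbeta(res: ResidueRecord) -> np.ndarray:
    wanted = "CA" if res.code == "G" else "CB"
    for atom in res.atoms:
        if atom.name == wanted:
            return np.asarray(atom.coord, dtype=float)
    raise MissingAtomError(
        f"residue {res.seq_index} ({res.code}) lacks the required {wanted} atom"
    )


def contact_def3(res_a: ResidueRecord, res_b: ResidueRecord) -> bool:
    """Definition III: Cβ–Cβ (Cα for glycine) distance ≤ 8 Å."""
    return float(np.linalg.norm(_cbeta(res_a) - _cbeta(res_b))) <= CBETA_CUTOFF


def label_contacts(
    structure: StructureCoordinates,
    topo: TopologyString,
    definition: str = "I",
    table: VdwRadiusTable = DEFAULT_VDW_TABLE,
) -> ContactMap:
    """Evaluate every interhelical candidate pair under one definition.

    Structure residue numbers must map into 1..L of the topology.  Candidate
    pairs whose residues are absent from the model — or, under definition
    III, lack the required Cβ/Cα atom — are skipped with a warning.
    """
    if definition not in DEFINITIONS:
        raise ConfigurationError(f"unknown contact definition {definition!r}")
    L = len(topo)
    by_index = structure.by_index()
    for idx in by_index:
        if not 1 <= idx <= L:
            raise ContractError(
                f"structure residue {idx} does not map into sequence 1..{L}"
            )
    contacts: set[tuple[int, int]] = set()
    for i0, j0 in enumerate_candidate_pairs(topo):
        i, j = i0 + 1, j0 + 1
        res_a, res_b = by_index.get(i), by_index.get(j)
        if res_a is None or res_b is None:
            logger.warning("pair (%d, %d): residue missing from model; skipped", i, j)
            continue
        try:
            if definition == "I":
                hit = contact_def1(res_a, res_b)
            elif definition == "II":
                hit = contact_def2(res_a, res_b, table)
            else:
                hit = contact_def3(res_a, res_b)
        except MissingAtomError as exc:
            logger.warning("pair (%d, %d): %s; skipped", i, j, exc)
            continue
        if hit:
            contacts.add((i, j))
    return ContactMap(length=L, contacts=frozenset(contacts), definition=definition)
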