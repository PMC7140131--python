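"""Synthetic fixtures with known planted structure.

Generates (a) multiple alignments whose chosen column pairs coevolve
through a fixed residue bijection, (b) idealised antiparallel helix-bundle
coordinates whose geometric contacts are known by construction, and (c)
complete training sets where the planted couplings are placed exactly at
the geometric contact pairs, exercising the real covariation → tracks →
featurizer → labeling pipeline end to end.

Every generator is a pure function of the spec seed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

from .covariation import covariation_matrix, zscore_standardize
from .errors import ConfigurationError
from .features import (
    PairFeatureVector,
    TopologyString,
    build_pair_vector,
    build_tracks,
    enumerate_candidate_pairs,
    parse_topology,
)
from .labeling import ContactMap, label_contacts
from .seqio import (
    AA20,
    Atom,
    MultipleAlignment,
    PSSMProfile,
    ProteinSequence,
    ResidueRecord,
    StructureCoordinates,
    PSSM_ALPHABET,
    write_alignment,
    write_fasta,
    write_pdb,
    write_psiblast_pssm,
)

#: Fixed background residue distribution (roughly database-like), ordered
#: as :data:`tmcontact.seqio.AA20`.  Glycine is excluded so every synthetic
#: residue legitimately carries a pseudo-Cβ atom.
_BG_RAW = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.8, "F": 3.9, "G": 0.0, "H": 2.3,
    "I": 6.0, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.6, "T": 5.3, "V": 6.9, "W": 1.1, "Y": 2.9,
}
BACKGROUND_FREQS = np.array([_BG_RAW[a] for a in AA20], dtype=float)
BACKGROUND_FREQS /= BACKGROUND_FREQS.sum()

#: Fixed bijection used to couple planted column pairs (alphabet rotation).
_COUPLING_SHIFT = 7

_CA_RADIUS = 2.3  # Å from the helix axis, ideal alpha helix
_LOOP_LENGTH = 2  # residues between helixes and at each terminus


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_proteins: int = 10
    n_sequences: int = 64
    seq_length: int = 0  # 0 → derived from the helix layout
    planted_pairs: tuple[tuple[int, int], ...] = ()
    p_couple: float = 1.0
    n_helices: int = 2
    residues_per_helix: int = 7
    axis_separation: float = 9.0
    rise: float = 1.5
    twist: float = 100.0
    side_chain_radius: float = 2.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_couple <= 1.0:
            raise ConfigurationError("p_couple must lie in [0, 1]")
        if self.axis_separation < 1.0:
            raise ConfigurationError(
                "axis separation below 1 Å would overlap the helixes"
            )
        if self.n_sequences < 2:
            raise ConfigurationError("an alignment needs at least 2 sequences")

    @property
    def length(self) -> int:
        if self.seq_length:
            return self.seq_length
        return (
            self.n_helices * self.residues_per_helix
            + (self.n_helices + 1) * _LOOP_LENGTH
        )


def _draw_background(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.choice(20, size=shape, p=BACKGROUND_FREQS)


def generate_msa(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> MultipleAlignment:
    """Background columns i.i.d. from the fixed distribution; each planted
    pair (a, b) copies column a through a fixed residue bijection with
    probability ``p_couple`` per row (0-based column indices)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    L = spec.length
    for a, b in spec.planted_pairs:
        if not (0 <= a < L and 0 <= b < L) or a == b:
            raise ConfigurationError(f"planted pair ({a}, {b}) out of range for L={L}")
    codes = _draw_background(rng, (spec.n_sequences, L))
    for a, b in spec.planted_pairs:
        coupled = rng.random(spec.n_sequences) < spec.p_couple
        codes[coupled, b] = (codes[coupled, a] + _COUPLING_SHIFT) % 20
    rows = tuple(
        (f"seq{r}", "".join(AA20[c] for c in codes[r]))
        for r in range(spec.n_sequences)
    )
    return MultipleAlignment(rows=rows, ncols=L)


def bundle_topology(spec: SyntheticSpec) -> TopologyString:
    """Loops of 'i'/'o' (alternating sides) around ``n_helices`` H-runs."""
    parts: list[str] = []
    side = "i"
    for _ in range(spec.n_helices):
        parts.append(side * _LOOP_LENGTH)
        parts.append("H" * spec.residues_per_helix)
        side = "o" if side == "i" else "i"
    parts.append(side * _LOOP_LENGTH)
    return parse_topology("".join(parts))


def generate_helix_bundle(
    spec: SyntheticSpec, sequence: str | None = None
) -> tuple[StructureCoordinates, TopologyString, ProteinSequence]:
    """Idealised antiparallel helix bundle.

    Each helix sits on its own axis (parallel to z, spaced along x by the
    configured separation) with a Cα at 2.3 Å from the axis and a single
    pseudo-side-chain Cβ extending ``side_chain_radius`` further out.
    Helix phases alternate so neighbouring helixes face each other; loop
    residues are placed on straight segments between helix ends.
    """
    if spec.n_helices < 2:
        raise ConfigurationError("a bundle needs at least 2 helixes")
    topo = bundle_topology(spec)
    L = len(topo)
    if sequence is None:
        rng = np.random.default_rng(spec.seed + 1)
        sequence = "".join(AA20[c] for c in _draw_background(rng, L))
    if len(sequence) != L:
        raise ConfigurationError("sequence length does not match the helix layout")

    coords: dict[int, tuple[np.ndarray, np.ndarray]] = {}  # pos0 → (CA, CB)
    r_cb = _CA_RADIUS + spec.side_chain_radius
    for seg in topo.segments:
        h = seg.ordinal - 1
        x0 = h * spec.axis_separation
        direction = 1.0 if h % 2 == 0 else -1.0
        phase = 0.0 if h % 2 == 0 else math.pi
        m = len(seg)
        for t in range(m):
            theta = phase + direction * math.radians(spec.twist) * t
            z = direction * (t - (m - 1) / 2.0) * spec.rise
            radial = np.array([math.cos(theta), math.sin(theta), 0.0])
            axis_point = np.array([x0, 0.0, z])
            coords[seg.start + t] = (
                axis_point + _CA_RADIUS * radial,
                axis_point + r_cb * radial,
            )
    # loop residues: straight interpolation between flanking helix ends
    helix_pts = sorted(coords)
    for pos in range(L):
        if pos in coords:
            continue
        before = [p for p in helix_pts if p < pos]
        after = [p for p in helix_pts if p > pos]
        if before and after:
            a, b = before[-1], after[0]
            frac = (pos - a) / (b - a)
            ca = coords[a][0] * (1 - frac) + coords[b][0] * frac
        elif after:
            ca = coords[after[0]][0] + np.array([0.0, 0.0, -4.0 * (after[0] - pos)])
        else:
            ca = coords[before[-1]][0] + np.array([0.0, 0.0, 4.0 * (pos - before[-1])])
        coords[pos] = (ca, ca.copy())

    residues = tuple(
        ResidueRecord(
            seq_index=pos + 1,
            code=sequence[pos],
            atoms=(
                Atom("CA", "C", tuple(float(v) for v in coords[pos][0])),
                Atom("CB", "C", tuple(float(v) for v in coords[pos][1])),
            ),
        )
        for pos in range(L)
    )
    structure = StructureCoordinates(chain_id="A", residues=residues)
    return structure, topo, ProteinSequence("synthetic", sequence)


def pssm_from_msa(msa: MultipleAlignment) -> PSSMProfile:
    """Frequency-based stand-in for a PSI-BLAST profile.

    Scores are half-bit log-odds of column frequencies against the
    background; information content is the relative entropy against a
    uniform background, so a fully conserved column scores log2(20) bits.
    """
    from .covariation import encode_alignment

    enc = encode_alignment(msa)
    L = msa.ncols
    scores = np.zeros((L, 20), dtype=int)
    info = np.zeros(L, dtype=float)
    order = [AA20.index(a) for a in PSSM_ALPHABET]
    for c in range(L):
        col = enc[:, c]
        col = col[col >= 0]
        counts = np.bincount(col, minlength=20).astype(float)
        n = counts.sum()
        if n == 0:
            continue
        freqs = counts / n
        nz = freqs > 0
        info[c] = float(np.sum(freqs[nz] * np.log2(20.0 * freqs[nz])))
        logodds = 2.0 * np.log2(
            np.maximum(freqs, 1e-4) / np.maximum(BACKGROUND_FREQS, 1e-4)
        )
        scores[c] = np.round(logodds[order]).astype(int)
    return PSSMProfile(length=L, scores=scores, info=info)


def _greedy_matching(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Largest prefix of pairs in sorted order sharing no column."""
    used: set[int] = set()
    out = []
    for i, j in sorted(pairs):
        if i in used or j in used:
            continue
        out.append((i, j))
        used.update((i, j))
    return out


@dataclasses.dataclass(frozen=True)
class SyntheticProtein:
    protein_id: str
    sequence: ProteinSequence
    msa: MultipleAlignment
    pssm: PSSMProfile
    topology: TopologyString
    structure: StructureCoordinates
    contacts: ContactMap
    planted_pairs: tuple[tuple[int, int], ...]


def generate_protein(
    spec: SyntheticSpec, index: int = 0, definition: str = "I"
) -> SyntheticProtein:
    """One synthetic protein: bundle geometry, contacts, and an MSA whose
    planted couplings sit exactly at (a matching subset of) the contacts."""
    seed = np.random.SeedSequence(spec.seed, spawn_key=(index,))
    rng = np.random.default_rng(seed)
    structure, topo, _ = generate_helix_bundle(spec)
    contacts = label_contacts(structure, topo, definition)
    planted = tuple(_greedy_matching([(i - 1, j - 1) for i, j in contacts.contacts]))
    pspec = dataclasses.replace(spec, planted_pairs=planted, seq_length=len(topo))
    msa = generate_msa(pspec, rng=rng)
    sequence = ProteinSequence(f"prot{index}", msa.rows[0][1])
    structure, topo, _ = generate_helix_bundle(spec, sequence=sequence.residues)
    return SyntheticProtein(
        protein_id=f"prot{index}",
        sequence=sequence,
        msa=msa,
        pssm=pssm_from_msa(msa),
        topology=topo,
        structure=structure,
        contacts=contacts,
        planted_pairs=planted,
    )


def generate_training_set(
    spec: SyntheticSpec, method: str = "ELSC", definition: str = "I"
) -> tuple[list[PairFeatureVector], np.ndarray, list[str]]:
    """Vectors + labels for ``n_proteins`` synthetic proteins via the real
    pipeline; returns (vectors, labels, protein id per vector)."""
    vectors: list[PairFeatureVector] = []
    labels: list[int] = []
    owners: list[str] = []
    for p in range(spec.n_proteins):
        prot = generate_protein(spec, index=p, definition=definition)
        cov = zscore_standardize(covariation_matrix(prot.msa, method))
        tracks = build_tracks(prot.pssm, prot.topology)
        for i, j in enumerate_candidate_pairs(prot.topology):
            vectors.append(build_pair_vector(i, j, tracks, cov))
            labels.append(1 if (i + 1, j + 1) in prot.contacts else 0)
            owners.append(prot.protein_id)
    return vectors, np.asarray(labels, dtype=int), owners


def write_protein_files(prot: SyntheticProtein, outdir: str | Path) -> dict[str, Path]:
    """Emit the on-disk formats the CLI consumes for one synthetic protein."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prot.protein_id}.fasta",
        "msa": outdir / f"{prot.protein_id}.aln.fasta",
        "pssm": outdir / f"{prot.protein_id}.pssm",
        "topology": outdir / f"{prot.protein_id}.topo",
        "pdb": outdir / f"{prot.protein_id}.pdb",
    }
    write_fasta(paths["fasta"], [prot.sequence])
    write_alignment(paths["msa"], prot.msa)
    write_psiblast_pssm(paths["pssm"], prot.pssm, prot.sequence.residues)
    paths["topology"].write_text(prot.topology.codes + "\n")
    write_pdb(paths["pdb"], prot.structure)
    return paths
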