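"""Per-residue feature tracks and the 31-element pair feature vector.

Tracks over the sequence length L:

* ``E`` — evolutionary conservation (per-position information content, bits)
* ``T`` — digitised topology (H→2, o→1, i→0)
* ``R`` — relative position within each transmembrane helix (−1 off-helix)

A candidate residue pair (i, j) is featurised with two sliding windows of
size 5 centred on i and j: the single z-scored covariation value C_ij
followed by the (E, T, R) triplet of each window position, 31 values in
total.  Window positions falling outside the sequence are filled with the
sentinel triplet (0, −1, −1).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .covariation import CovariationMatrix
from .errors import ContractError, ParseError
from .seqio import PSSMProfile

#: Digitised topology codes.
TOPOLOGY_DIGITS = {"i": 0, "o": 1, "H": 2}

#: Sentinel (E, T, R) triplet used to pad windows at the sequence termini.
PAD_TRIPLET = (0.0, -1.0, -1.0)

WINDOW_OFFSETS = (-2, -1, 0, 1, 2)

#: Elements in the default pair feature vector: 1 + 2 windows x 5 x 3.
PAIR_VECTOR_SIZE = 1 + 2 * len(WINDOW_OFFSETS) * 3


@dataclasses.dataclass(frozen=True)
class HelixSegment:
    """Maximal run of 'H' codes; 0-based inclusive bounds, 1-based ordinal."""

    start: int
    end: int
    ordinal: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass(frozen=True)
class TopologyString:
    """Case-normalised topology codes plus the derived helix segments."""

    codes: str
    segments: tuple[HelixSegment, ...]

    def __len__(self) -> int:
        return len(self.codes)

    def segment_of(self, pos: int) -> int:
        """Ordinal of the helix containing 0-based ``pos``, or 0 if none."""
        for seg in self.segments:
            if seg.start <= pos <= seg.end:
                return seg.ordinal
        return 0


@dataclasses.dataclass(frozen=True)
class ResidueFeatureTracks:
    E: np.ndarray
    T: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.E) == len(self.T) == len(self.R)):
            raise ContractError("feature tracks must share one length")
        if not np.array_equal(self.R == -1, self.T != 2):
            raise ContractError("R must be -1 exactly at non-helix positions")

    def __len__(self) -> int:
        return len(self.E)


@dataclasses.dataclass(frozen=True)
class PairFeatureVector:
    i: int  # 0-based
    j: int  # 0-based
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ContractError("pair positions must differ")


def parse_topology(codes: str) -> TopologyString:
    """Parse a topology string over {H, h, i, I, o, O}; enumerate helix runs."""
    normalised = []
    for pos, ch in enumerate(codes):
        low = ch.lower()
        if low == "h":
            normalised.append("H")
        elif low in ("i", "o"):
            normalised.append(low)
        else:
            raise ParseError(
                f"illegal topology character {ch!r} at position {pos + 1}"
            )
    norm = "".join(normalised)
    segments: list[HelixSegment] = []
    start = None
    for pos, ch in enumerate(norm + "$"):  # sentinel terminates a final run
        if ch == "H" and start is None:
            start = pos
        elif ch != "H" and start is not None:
            segments.append(
                HelixSegment(start=start, end=pos - 1, ordinal=len(segments) + 1)
            )
            start = None
    return TopologyString(codes=norm, segments=tuple(segments))


def digitize_topology(topo: TopologyString) -> np.ndarray:
    """H→2, o→1, i→0 (fixed, documented mapping)."""
    return np.array([TOPOLOGY_DIGITS[c] for c in topo.codes], dtype=float)


def relative_positions(topo: TopologyString) -> np.ndarray:
    """Integer rank of each residue within its helix; −1 off-helix.

    Odd-ordinal helixes are numbered 1..len from the N-terminal end,
    even-ordinal helixes 1..len from the C-terminal end, reflecting the
    alternating membrane crossings.
    """
    r = np.full(len(topo), -1.0)
    for seg in topo.segments:
        ranks = np.arange(1, len(seg) + 1, dtype=float)
        if seg.ordinal % 2 == 0:
            ranks = ranks[::-1]
        r[seg.start : seg.end + 1] = ranks
    return r


def conservation_scalar(
    pssm: PSSMProfile, expected_length: int | None = None
) -> np.ndarray:
    """Per-position conservation: information content in bits (≥ 0)."""
    if expected_length is not None and pssm.length != expected_length:
        raise ContractError(
            f"PSSM length {pssm.length} != sequence length {expected_length}"
        )
    e = np.asarray(pssm.info, dtype=float).copy()
    if not np.all(np.isfinite(e)):
        raise ContractError("non-finite conservation values in PSSM")
    return np.maximum(e, 0.0)


def build_tracks(
    pssm: PSSMProfile, topo: TopologyString
) -> ResidueFeatureTracks:
    """Assemble the (E, T, R) tracks; lengths must agree."""
    if pssm.length != len(topo):
        raise ContractError(
            f"PSSM length {pssm.length} != topology length {len(topo)}"
        )
    return ResidueFeatureTracks(
        E=conservation_scalar(pssm),
        T=digitize_topology(topo),
        R=relative_positions(topo),
    )


def enumerate_candidate_pairs(
    topo: TopologyString, all_pairs: bool = False
) -> list[tuple[int, int]]:
    """All 0-based (i, j), i < j, on different helix segments.

    Fewer than two helixes yields an empty list.  ``all_pairs`` lifts the
    interhelical restriction entirely.
    """
    L = len(topo)
    if all_pairs:
        return [(i, j) for i in range(L) for j in range(i + 1, L)]
    pairs: list[tuple[int, int]] = []
    for a in range(len(topo.segments)):
        for b in range(a + 1, len(topo.segments)):
            sa, sb = topo.segments[a], topo.segments[b]
            for i in range(sa.start, sa.end + 1):
                for j in range(sb.start, sb.end + 1):
                    pairs.append((i, j))
    pairs.sort()
    return pairs


def _window_triplets(pos: int, tracks: ResidueFeatureTracks) -> list[float]:
    L = len(tracks)
    out: list[float] = []
    for off in WINDOW_OFFSETS:
        k = pos + off
        if 0 <= k < L:
            out.extend((tracks.E[k], tracks.T[k], tracks.R[k]))
        else:
            out.extend(PAD_TRIPLET)
    return out


def build_pair_vector(
    i: int,
    j: int,
    tracks: ResidueFeatureTracks,
    cov: CovariationMatrix,
    require_standardized: bool = True,
) -> PairFeatureVector:
    """The 31-element vector [C_ij, (E,T,R)_{i−2..i+2}, (E,T,R)_{j−2..j+2}].

    ``i`` and ``j`` are 0-based; the covariation matrix must already be
    z-scored unless ``require_standardized`` is lifted.
    """
    L = len(tracks)
    if i == j:
        raise ContractError("pair positions must differ")
    for pos in (i, j):
        if not 0 <= pos < L:
            raise IndexError(f"position {pos} outside [0, {L - 1}]")
    if cov.length != L:
        raise ContractError(f"covariation matrix length {cov.length} != tracks {L}")
    if require_standardized and not cov.standardized:
        raise ContractError("covariation matrix must be z-scored first")
    c = float(cov.scores[i, j])
    if np.isnan(c):
        raise ContractError(f"covariation undefined for pair ({i}, {j})")
    values = np.array(
        [c] + _window_triplets(i, tracks) + _window_triplets(j, tracks), dtype=float
    )
    assert values.shape == (PAIR_VECTOR_SIZE,)
    return PairFeatureVector(i=i, j=j, values=values)


def build_pair_vector_extended(
    i: int,
    j: int,
    pssm: PSSMProfile,
    tracks: ResidueFeatureTracks,
    cov: CovariationMatrix,
) -> np.ndarray:
    """Non-default extended mode: the full 20-dim PSSM row replaces the
    conservation scalar at each window position (1 + 2x5x22 = 221 values)."""
    base = build_pair_vector(i, j, tracks, cov)
    L = len(tracks)
    out: list[float] = [base.values[0]]
    for pos in (i, j):
        for off in WINDOW_OFFSETS:
            k = pos + off
            if 0 <= k < L:
                out.extend(pssm.scores[k].astype(float))
                out.extend((tracks.T[k], tracks.R[k]))
            else:
                out.extend([0.0] * 20)
                out.extend((-1.0, -1.0))
    return np.asarray(out, dtype=float)
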