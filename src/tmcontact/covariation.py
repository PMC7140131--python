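"""Evolutionary covariation scores between alignment columns.

Three column-pair scorers — mutual information (MI, bits), the
observed-minus-expected-squared statistic (OMES, normalised by the number
of valid rows) and the explicit likelihood of subset covariation (ELSC,
symmetrised) — plus per-protein z-score standardisation of the resulting
matrix.

Gap handling is pairwise deletion throughout: a row contributes to a
column pair only when it is ungapped (and a standard residue) in both
columns.  No pseudocounts, sequence weighting or APC correction are
applied.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .errors import ConfigurationError, ContractError, DegenerateColumnError
from .seqio import AA20, MultipleAlignment

METHODS = ("ELSC", "MI", "OMES")

_AA_INDEX = {aa: k for k, aa in enumerate(AA20)}


@dataclasses.dataclass(frozen=True)
class CovariationMatrix:
    """Symmetric L x L pair scores; the diagonal is undefined (NaN)."""

    length: int
    scores: np.ndarray
    method: str
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.scores.shape != (self.length, self.length):
            raise ContractError("covariation matrix shape mismatch")
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown covariation method {self.method!r}")


def encode_alignment(msa: MultipleAlignment) -> np.ndarray:
    """Integer-encode an MSA: 0..19 for the standard residues, -1 otherwise."""
    arr = np.full((msa.nrows, msa.ncols), -1, dtype=np.int8)
    for r, (_, seq) in enumerate(msa.rows):
        for c, ch in enumerate(seq):
            arr[r, c] = _AA_INDEX.get(ch, -1)
    return arr


def _valid_rows(encoded: np.ndarray, i: int, j: int) -> np.ndarray:
    return (encoded[:, i] >= 0) & (encoded[:, j] >= 0)


def column_pair_counts(
    msa: MultipleAlignment | np.ndarray, i: int, j: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Joint (20 x 20) and marginal residue counts over rows ungapped in both
    columns.  Returns ``(joint, counts_i, counts_j, n_valid)``."""
    enc = msa if isinstance(msa, np.ndarray) else encode_alignment(msa)
    if not (0 <= i < enc.shape[1] and 0 <= j < enc.shape[1]):
        raise ContractError(f"column indices ({i}, {j}) out of range")
    mask = _valid_rows(enc, i, j)
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise DegenerateColumnError(
            f"no row is ungapped in both columns {i} and {j}"
        )
    ci = enc[mask, i].astype(np.intp)
    cj = enc[mask, j].astype(np.intp)
    joint = np.zeros((20, 20), dtype=np.int64)
    np.add.at(joint, (ci, cj), 1)
    return joint, joint.sum(axis=1), joint.sum(axis=0), n_valid


def mutual_information(msa: MultipleAlignment | np.ndarray, i: int, j: int) -> float:
    """MI between columns i and j in bits, no pseudocounts."""
    joint, ni, nj, n = column_pair_counts(msa, i, j)
    p = joint / n
    pi = ni / n
    pj = nj / n
    nz = p > 0
    outer = np.outer(pi, pj)
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def omes(msa: MultipleAlignment | np.ndarray, i: int, j: int) -> float:
    """OMES = sum (N_obs - N_exp)^2 / N_valid over residue-type pairs."""
    joint, ni, nj, n = column_pair_counts(msa, i, j)
    expected = np.outer(ni, nj) / n
    nz = expected > 0
    return float(np.sum((joint[nz] - expected[nz]) ** 2) / n)


def _proportional_rounding(n_full: np.ndarray, subset_size: int, n_total: int) -> np.ndarray:
    """Expected subset composition: round half-up, then largest-remainder
    repair so the counts sum to ``subset_size`` within ``0 <= m_y <= N_y``."""
    ideal = n_full * (subset_size / n_total)
    m = np.floor(ideal + 0.5).astype(np.int64)
    np.minimum(m, n_full, out=m)
    remainder = ideal - m
    deficit = subset_size - int(m.sum())
    if deficit > 0:
        order = np.lexsort((np.arange(20), -remainder))
        for y in order:
            if deficit == 0:
                break
            if m[y] < n_full[y]:
                m[y] += 1
                deficit -= 1
    elif deficit < 0:
        order = np.lexsort((np.arange(20), remainder))
        for y in order:
            if deficit == 0:
                break
            if m[y] > 0:
                m[y] -= 1
                deficit += 1
    return m


def _elsc_directed(enc: np.ndarray, i: int, j: int) -> float:
    mask = _valid_rows(enc, i, j)
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise DegenerateColumnError(f"no row is ungapped in both columns {i} and {j}")
    ci = enc[mask, i].astype(np.intp)
    cj = enc[mask, j].astype(np.intp)
    counts_i = np.bincount(ci, minlength=20)
    modal = int(np.argmax(counts_i))  # argmax → alphabetically first on ties
    subset = cj[ci == modal]
    n_sub = np.bincount(subset, minlength=20).astype(np.int64)
    n_full = np.bincount(cj, minlength=20).astype(np.int64)
    m = _proportional_rounding(n_full, subset.size, n_valid)

    def log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    # -ln prod C(N_y, n_y) / C(N_y, m_y)
    return float(np.sum(log_comb(n_full, m) - log_comb(n_full, n_sub)))


def elsc(msa: MultipleAlignment | np.ndarray, i: int, j: int) -> float:
    """Symmetrised ELSC score: (score(i→j) + score(j→i)) / 2.

    The perturbation subset for the directed score i→j is the set of rows
    whose column-i residue is the modal residue of column i (alphabetical
    tie-break); the comparison composition is proportional sampling from
    column j, rounded half-up with largest-remainder repair.
    """
    enc = msa if isinstance(msa, np.ndarray) else encode_alignment(msa)
    if not (0 <= i < enc.shape[1] and 0 <= j < enc.shape[1]):
        raise ContractError(f"column indices ({i}, {j}) out of range")
    return 0.5 * (_elsc_directed(enc, i, j) + _elsc_directed(enc, j, i))


_SCORERS = {"MI": mutual_information, "OMES": omes, "ELSC": elsc}


def covariation_matrix(msa: MultipleAlignment, method: str = "ELSC") -> CovariationMatrix:
    """Score all column pairs of the alignment with one method."""
    method = method.upper()
    if method not in _SCORERS:
        raise ConfigurationError(
            f"unknown covariation method {method!r}; choose from {METHODS}"
        )
    if msa.ncols < 2:
        raise ContractError("alignment must have at least 2 columns")
    enc = encode_alignment(msa)
    scorer = _SCORERS[method]
    L = msa.ncols
    scores = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            s = scorer(enc, i, j)
            scores[i, j] = s
            scores[j, i] = s
    return CovariationMatrix(length=L, scores=scores, method=method)


def zscore_standardize(matrix: CovariationMatrix) -> CovariationMatrix:
    """Replace each defined entry by its z-score over all defined entries of
    this protein's matrix (population sd); a constant matrix maps to zeros."""
    if matrix.standardized:
        raise ContractError("covariation matrix is already standardized")
    iu = np.triu_indices(matrix.length, k=1)
    vals = matrix.scores[iu]
    defined = ~np.isnan(vals)
    out = np.full_like(matrix.scores, np.nan)
    if defined.any():
        mean = float(vals[defined].mean())
        sd = float(vals[defined].std())  # population sd
        z = np.zeros_like(vals)
        if sd > 0:
            z[defined] = (vals[defined] - mean) / sd
        out[iu] = z
        out[(iu[1], iu[0])] = z
    return CovariationMatrix(
        length=matrix.length, scores=out, method=matrix.method, standardized=True
    )


def export_tsv(path: str | Path, raw: CovariationMatrix, z: CovariationMatrix | None = None) -> None:
    """Dump (i, j, raw[, z]) rows, 1-based, for inspection or re-ingestion."""
    with Path(path).open("w") as fh:
        header = "i\tj\traw" + ("\tz" if z is not None else "")
        fh.write(header + "\n")
        for i in range(raw.length):
            for j in range(i + 1, raw.length):
                line = f"{i + 1}\t{j + 1}\t{raw.scores[i, j]:.10g}"
                if z is not None:
                    line += f"\t{z.scores[i, j]:.10g}"
                fh.write(line + "\n")


def read_tsv(path: str | Path, length: int, method: str = "ELSC") -> CovariationMatrix:
    """Ingest a covariation matrix from the TSV dialect of :func:`export_tsv`
    (raw column), allowing external covariation tools to feed the pipeline."""
    scores = np.full((length, length), np.nan)
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        parts = line.split("\t")
        i, j, val = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])
        scores[i, j] = val
        scores[j, i] = val
    return CovariationMatrix(length=length, scores=scores, method=method.upper())
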