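"""End-to-end orchestration: per-protein prediction, cross-validation and
the controlled covariation-method comparison."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import model as model_mod
from .covariation import CovariationMatrix, covariation_matrix, zscore_standardize
from .errors import ConsistencyError
from .features import (
    TopologyString,
    build_pair_vector,
    build_tracks,
    enumerate_candidate_pairs,
)
from .model import Metrics, ModelConfig, TrainedModel
from .seqio import (
    MultipleAlignment,
    PSSMProfile,
    ProteinSequence,
    read_contact_matrix,
    read_pair_list,
    write_contact_matrix,
    write_pair_list,
)

logger = logging.getLogger(__name__)


def check_input_consistency(
    sequence: ProteinSequence,
    topology: TopologyString,
    pssm: PSSMProfile,
    msa: MultipleAlignment,
) -> None:
    """All inputs must agree on the sequence length L."""
    L = len(sequence)
    if len(topology) != L:
        raise ConsistencyError(
            f"topology length {len(topology)} != sequence length {L}"
        )
    if pssm.length != L:
        raise ConsistencyError(f"PSSM length {pssm.length} != sequence length {L}")
    if len(msa.query) != L:
        raise ConsistencyError(
            f"MSA query length {len(msa.query)} != sequence length {L}"
        )


def verify_output_consistency(pair_path: Path, matrix_path: Path) -> None:
    """Every '1' matrix cell must have a label-1 pair row and vice versa."""
    pairs = read_pair_list(pair_path)
    grid = read_contact_matrix(matrix_path)
    from_pairs = {(i, j) for i, j, _, label in pairs if label == 1}
    from_grid = {
        (i + 1, j + 1)
        for i, row in enumerate(grid)
        for j, cell in enumerate(row)
        if cell == "1"
    }
    if from_pairs != from_grid:
        raise ConsistencyError(
            "pair-list and matrix outputs disagree: "
            f"{sorted(from_pairs ^ from_grid)[:5]} ..."
        )


def predict_protein(
    sequence: ProteinSequence,
    msa: MultipleAlignment,
    topology: TopologyString,
    pssm: PSSMProfile,
    trained: TrainedModel,
    method: str = "ELSC",
    out_prefix: str | Path = "prediction",
    all_pairs: bool = False,
    threshold: float | None = None,
    cov: CovariationMatrix | None = None,
) -> tuple[Path, Path]:
    """Featurise one protein, score every candidate pair, write both output
    files (TSV pair list + upper-triangular matrix) and cross-check them.

    A pre-computed (unstandardised) covariation matrix may be supplied to
    bypass the built-in scorers.
    """
    check_input_consistency(sequence, topology, pssm, msa)
    if cov is None:
        cov = covariation_matrix(msa, method)
    z = cov if cov.standardized else zscore_standardize(cov)
    tracks = build_tracks(pssm, topology)
    candidates = enumerate_candidate_pairs(topology, all_pairs=all_pairs)

    pair_path = Path(f"{out_prefix}.pairs.tsv")
    matrix_path = Path(f"{out_prefix}.matrix.txt")
    predictions: list[tuple[int, int, float, int]] = []
    if candidates:
        vectors = [build_pair_vector(i, j, tracks, z) for i, j in candidates]
        scored = model_mod.predict(trained, vectors, threshold=threshold)
        predictions = [
            (i + 1, j + 1, prob, label)
            for (i, j), (prob, label) in zip(candidates, scored)
        ]
    write_pair_list(pair_path, predictions)
    write_contact_matrix(matrix_path, len(sequence), predictions)
    verify_output_consistency(pair_path, matrix_path)
    logger.info(
        "%s: %d candidate pairs, %d predicted contacts",
        sequence.id,
        len(predictions),
        sum(label for *_, label in predictions),
    )
    return pair_path, matrix_path


@dataclasses.dataclass(frozen=True)
class CvResult:
    fold_metrics: tuple[Metrics, ...]
    mean_mcc: float
    std_mcc: float
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]


def run_cv(
    vectors,
    labels: np.ndarray,
    protein_ids: Sequence[str],
    k: int = 5,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> CvResult:
    """Protein-level k-fold cross-validation: one model per fold."""
    config = config or ModelConfig(seed=seed)
    x = model_mod._as_matrix(vectors)
    y = np.asarray(labels, dtype=int)
    owners = np.asarray(protein_ids)
    folds = model_mod.kfold_split(protein_ids, k=k, seed=seed)
    fold_metrics: list[Metrics] = []
    for fold_id, (train_ids, test_ids) in enumerate(folds):
        train_mask = np.isin(owners, train_ids)
        test_mask = np.isin(owners, test_ids)
        try:
            trained = model_mod.train(x[train_mask], y[train_mask], config)
        except Exception as exc:
            raise type(exc)(f"fold {fold_id}: {exc}") from exc
        scored = model_mod.predict(trained, x[test_mask])
        fold_metrics.append(
            model_mod.evaluate([lab for _, lab in scored], y[test_mask])
        )
        logger.info("fold %d: MCC %.4f", fold_id, fold_metrics[-1].mcc)
    mccs = np.array([m.mcc for m in fold_metrics])
    return CvResult(
        fold_metrics=tuple(fold_metrics),
        mean_mcc=float(mccs.mean()),
        std_mcc=float(mccs.std()),
        folds=tuple((tuple(tr), tuple(te)) for tr, te in folds),
    )


def train_test_split_by_protein(
    protein_ids: Sequence[str], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded protein-level 80/20 split."""
    unique = sorted(set(protein_ids))
    order = list(np.random.default_rng(seed).permutation(unique))
    n_test = max(1, int(round(test_fraction * len(unique))))
    return sorted(order[n_test:]), sorted(order[:n_test])


def compare_covariation_methods(
    datasets: dict[str, tuple[list, np.ndarray, list[str]]],
    config: ModelConfig | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> dict[str, Metrics]:
    """Controlled comparison: identical protein split, seed and model config
    for every method; only the covariation feature differs.

    ``datasets`` maps a method name to (vectors, labels, protein_ids) built
    from the same underlying proteins.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 methods to compare")
    ref_ids = None
    results: dict[str, Metrics] = {}
    for method, (vectors, labels, owners) in datasets.items():
        ids = sorted(set(owners))
        if ref_ids is None:
            ref_ids = ids
        elif ids != ref_ids:
            raise ConsistencyError("datasets do not cover the same proteins")
        train_ids, test_ids = train_test_split_by_protein(ids, test_fraction, seed)
        x = model_mod._as_matrix(vectors)
        y = np.asarray(labels, dtype=int)
        owner_arr = np.asarray(owners)
        train_mask = np.isin(owner_arr, train_ids)
        test_mask = np.isin(owner_arr, test_ids)
        cfg = config or ModelConfig(seed=seed)
        trained = model_mod.train(x[train_mask], y[train_mask], cfg)
        scored = model_mod.predict(trained, x[test_mask])
        results[method] = model_mod.evaluate([lab for _, lab in scored], y[test_mask])
        logger.info(
            "method %s: test MCC %.4f (folds identical across methods)",
            method,
            results[method].mcc,
        )
    return results
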