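"""Sequence-identity matrix and the homology-aware train/test split.

To prevent homology leakage into a regression test set, each protein's
maximum pairwise sequence identity to any other dataset protein is computed;
proteins above the 50% identity threshold form the training set and the
rest the test set. Identity comes from a global (Needleman–Wunsch, affine
gaps) alignment — matched identical positions over alignment length — which
replaces an external local-alignment search while preserving the splitting
semantics; externally computed matrices can be imported instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .errors import ConfDeltaError, EmptyInputError
from .records import MutationRecord, ProteinEntry


@dataclass(frozen=True)
class AlignParams:
    """Scoring for the global aligner used to compute identities."""

    match: float = 1.0
    mismatch: float = -1.0
    open_gap: float = -10.0
    extend_gap: float = -0.5


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.open_gap
    aligner.extend_gap_score = params.extend_gap
    return aligner


def pairwise_identity(
    seq_a: str, seq_b: str, params: AlignParams | None = None
) -> float:
    """Fraction of identical matched positions over global-alignment length."""
    if not seq_a or not seq_b:
        raise EmptyInputError("cannot align an empty sequence")
    if seq_a == seq_b:
        return 1.0
    aligner = _aligner(params or AlignParams())
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric all-vs-all identity fractions with unit diagonal."""

    protein_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.protein_ids)
        if m.shape != (n, n):
            raise ConfDeltaError(f"matrix shape {m.shape} for {n} proteins")
        if not np.allclose(m, m.T):
            raise ConfDeltaError("identity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ConfDeltaError("identity matrix diagonal must be 1")
        if m.min() < 0 or m.max() > 1 + 1e-12:
            raise ConfDeltaError("identities must lie in [0, 1]")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    def max_offdiagonal(self) -> dict[str, float]:
        """Each protein's highest identity to any *other* protein (0 if alone)."""
        n = len(self.protein_ids)
        if n == 1:
            return {self.protein_ids[0]: 0.0}
        masked = self.matrix - 2.0 * np.eye(n)  # push diagonal below any entry
        return dict(zip(self.protein_ids, masked.max(axis=1)))


def identity_matrix(
    entries: Mapping[str, ProteinEntry] | Sequence[ProteinEntry],
    params: AlignParams | None = None,
) -> IdentityMatrix:
    """All-vs-all pairwise identities for the dataset proteins."""
    if isinstance(entries, Mapping):
        entries = list(entries.values())
    ids = tuple(e.protein_id for e in entries)
    n = len(ids)
    if n == 0:
        raise EmptyInputError("no proteins to compare")
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(
                entries[i].sequence, entries[j].sequence, params
            )
    return IdentityMatrix(protein_ids=ids, matrix=m)


@dataclass(frozen=True)
class SplitAssignment:
    """train/test label per protein, plus the max-identity evidence."""

    labels: dict[str, str]
    max_identity: dict[str, float]
    threshold: float

    def label_for(self, record: MutationRecord) -> str:
        return self.labels[record.protein_id]

    def mutation_labels(self, records: Sequence[MutationRecord]) -> list[str]:
        return [self.label_for(r) for r in records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": list(self.labels),
                "max_identity": [self.max_identity[p] for p in self.labels],
                "label": [self.labels[p] for p in self.labels],
            }
        )


def split_by_identity(
    matrix: IdentityMatrix,
    threshold: float = 0.5,
    boundary_to_train: bool = False,
) -> SplitAssignment:
    """Assign proteins to train/test by their maximum off-diagonal identity.

    A protein joins the training set iff its identity to some other protein
    exceeds ``threshold``; proteins below — including those with no partner —
    form the test set. A protein at exactly the threshold goes to test by
    default; set ``boundary_to_train`` to flip that convention.
    """
    max_id = matrix.max_offdiagonal()
    if len(matrix.protein_ids) == 1:
        warnings.warn("single-protein matrix: no off-diagonal partner, all test")
    labels = {}
    for pid, value in max_id.items():
        above = value >= threshold if boundary_to_train else value > threshold
        labels[pid] = "train" if above else "test"
    return SplitAssignment(labels=labels, max_identity=max_id, threshold=threshold)


def write_identity_matrix(matrix: IdentityMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.matrix, index=matrix.protein_ids, columns=matrix.protein_ids
    ).to_csv(path, sep="\t")


def read_identity_matrix(path: str | Path) -> IdentityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return IdentityMatrix(
        protein_ids=tuple(str(c) for c in df.columns), matrix=df.to_numpy(float)
    )
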