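"""Per-residue confidence profiles and the two delta metrics.

Structure predictors report a per-residue confidence score (pLDDT, 0–100)
and conventionally store it in the B-factor column of the output PDB file,
one identical value on every atom of a residue. The two quantities this
package evaluates as mutation-effect predictors are

* ``site_delta``  — ΔpLDDT: mutant minus wild-type score at the mutated residue;
* ``global_delta`` — Δ⟨pLDDT⟩: mutant minus wild-type chain-mean score.

Under this orientation a confidence drop upon mutation is negative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

from .errors import (
    EmptyProfileError,
    InconsistentModelsError,
    MalformedModelError,
    ScoreRangeError,
)


@dataclass(frozen=True)
class ConfidenceProfile:
    """A protein's ordered per-residue confidence scores.

    ``model_index`` distinguishes the (typically five) models a predictor
    emits for one sequence.
    """

    protein_id: str
    scores: np.ndarray
    sequence: str | None = None
    model_index: int | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size == 0:
            raise EmptyProfileError(f"profile {self.protein_id} has no residues")
        if np.any(scores < 0.0) or np.any(scores > 100.0):
            raise ScoreRangeError(
                f"profile {self.protein_id} has scores outside [0, 100]"
            )
        if self.sequence is not None and len(self.sequence) != scores.size:
            raise InconsistentModelsError(
                f"profile {self.protein_id}: {scores.size} scores for "
                f"{len(self.sequence)} residues"
            )
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return int(self.scores.size)

    @property
    def mean_score(self) -> float:
        """⟨pLDDT⟩: the chain-mean confidence."""
        return float(self.scores.mean())


@dataclass(frozen=True)
class DeltaMetrics:
    """The two predictors for one mutation: ΔpLDDT and Δ⟨pLDDT⟩."""

    site_delta: float
    global_delta: float

    def __neg__(self) -> "DeltaMetrics":
        return DeltaMetrics(-self.site_delta, -self.global_delta)


def read_profile_from_coordinates(
    pdb_file: str | Path,
    protein_id: str | None = None,
    model_index: int | None = None,
) -> ConfidenceProfile:
    """Extract the per-residue score from the B-factor field of a PDB file.

    One score per residue is taken from the alpha-carbon record, in residue
    order; the sequence is inferred from the residue names. Files with more
    than one chain or with insertion codes are rejected (single-sequence
    models only). Predictors write one value per residue on every atom, so a
    residue whose atoms disagree triggers a warning, not an error.
    """
    path = Path(pdb_file)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise MalformedModelError(f"{path}: no models")
    chains = [c for c in models[0]]
    if len(chains) != 1:
        raise MalformedModelError(f"{path}: expected one chain, found {len(chains)}")
    scores: list[float] = []
    letters: list[str] = []
    for residue in chains[0]:
        hetflag, _, icode = residue.id
        if hetflag.strip():
            continue  # waters / heteroatoms carry no chain residue
        if icode.strip():
            raise MalformedModelError(f"{path}: insertion code at {residue.id}")
        if "CA" not in residue:
            raise MalformedModelError(
                f"{path}: residue {residue.id[1]} lacks an alpha-carbon record"
            )
        b = float(residue["CA"].get_bfactor())
        others = {float(a.get_bfactor()) for a in residue}
        if len(others) > 1:
            warnings.warn(
                f"{path}: residue {residue.id[1]} carries differing B-factors; "
                "using the CA value"
            )
        if not 0.0 <= b <= 100.0:
            raise ScoreRangeError(f"{path}: score {b} outside [0, 100]")
        scores.append(b)
        letters.append(seq1(residue.get_resname(), undef_code="X"))
    if not scores:
        raise EmptyProfileError(f"{path}: no residues")
    return ConfidenceProfile(
        protein_id=protein_id or path.stem,
        scores=np.array(scores),
        sequence="".join(letters),
        model_index=model_index,
    )


def read_profile_from_array(
    array_file: str | Path,
    protein_id: str | None = None,
    model_index: int | None = None,
) -> ConfidenceProfile:
    """Read a plain score array: a JSON list or one value per line."""
    path = Path(array_file)
    text = path.read_text().strip()
    if not text or text in {"[]"}:
        raise EmptyProfileError(f"{path}: empty score array")
    if text.startswith("["):
        values = json.loads(text)
    else:
        values = [float(line) for line in text.splitlines() if line.strip()]
    if not values:
        raise EmptyProfileError(f"{path}: empty score array")
    return ConfidenceProfile(
        protein_id=protein_id or path.stem.removesuffix(".scores"),
        scores=np.asarray(values, dtype=float),
        model_index=model_index,
    )


def select_best_model(profiles: Sequence[ConfidenceProfile]) -> ConfidenceProfile:
    """Return the model with the highest chain-mean score.

    When several models emerge for one sequence, downstream deltas use only
    the most confident one. Ties go to the lowest ``model_index`` (inputs
    without an index sort after indexed ones, by input order).
    """
    if not profiles:
        raise EmptyProfileError("no profiles to select from")
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise InconsistentModelsError(f"model lengths differ: {sorted(lengths)}")
    big = len(profiles) + 1

    def key(item: tuple[int, ConfidenceProfile]):
        order, p = item
        idx = p.model_index if p.model_index is not None else big + order
        return (-p.mean_score, idx, order)

    return min(enumerate(profiles), key=key)[1]


def compute_deltas(
    wt: ConfidenceProfile, mut: ConfidenceProfile, position: int
) -> DeltaMetrics:
    """Compute (ΔpLDDT at ``position``, Δ⟨pLDDT⟩), mutant minus wild type.

    ``position`` is 1-based, matching mutation-code numbering.
    """
    if len(wt) != len(mut):
        raise InconsistentModelsError(
            f"profile lengths differ: {len(wt)} vs {len(mut)}"
        )
    if not 1 <= position <= len(wt):
        raise IndexError(f"position {position} outside 1..{len(wt)}")
    i = position - 1
    return DeltaMetrics(
        site_delta=float(mut.scores[i] - wt.scores[i]),
        global_delta=mut.mean_score - wt.mean_score,
    )
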