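"""Mutation tables, protein sequences, and the curation rules.

Curation mirrors how thermodynamic mutation databases are filtered before
benchmarking: keep single-point mutations measured near physiological
conditions (pH 3–9 inclusive, 293–300 K inclusive) in small proteins
(length strictly below 250 residues), and orient the sign of ΔΔG so that
stabilizing mutations are negative and destabilizing positive (ThermoMutDB
stores the opposite convention, hence the optional sign flip on import).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    EmptyInputError,
    MissingSequenceError,
    MutationParseError,
    ReferenceMismatchError,
    SynonymousMutationError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class EffectKind(str, Enum):
    """What the response variable measures."""

    STABILITY = "stability"  # ΔΔG in kcal/mol
    FUNCTION = "function"    # e.g. fluorescence level


@dataclass(frozen=True)
class MutationRecord:
    """One single-point mutation with its measured effect and assay conditions.

    ``effect_value`` is ΔΔG in kcal/mol under the convention stabilizing < 0 <
    destabilizing (for ``effect_kind='stability'``), or the functional readout
    (``'function'``). Positions are 1-based, as in mutation codes like A123G.
    """

    protein_id: str
    wt_aa: str
    position: int
    mut_aa: str
    effect_value: float
    ph: float | None = None
    temperature: float | None = None
    effect_kind: EffectKind = EffectKind.STABILITY

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS or self.mut_aa not in AMINO_ACIDS:
            raise MutationParseError(
                f"non-canonical residue in {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise SynonymousMutationError(
                f"synonymous mutation {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")

    @property
    def mutation_code(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class ProteinEntry:
    """A protein identifier and its amino-acid sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise EmptyInputError(f"empty sequence for {self.protein_id}")
        seq = self.sequence.upper()
        bad = set(seq) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise MutationParseError(
                f"non-canonical residues {sorted(bad)} in {self.protein_id}"
            )
        if "X" in seq:
            warnings.warn(f"sequence {self.protein_id} contains X residues")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CurationFilter:
    """Record-selection bounds.

    pH and temperature bounds are inclusive; ``max_length`` is exclusive
    ("less than 250 amino acids"). Set a bound pair to ``None`` to disable it.
    Records missing pH or temperature are excluded while the corresponding
    bounds are active, because the assay conditions are part of the selection.
    """

    ph_min: float | None = 3.0
    ph_max: float | None = 9.0
    temp_min: float | None = 293.0
    temp_max: float | None = 300.0
    max_length: int | None = 250
    single_point_only: bool = True

    def __post_init__(self) -> None:
        if self.ph_min is not None and self.ph_max is not None and self.ph_min > self.ph_max:
            raise EmptyInputError("ph_min > ph_max")
        if (
            self.temp_min is not None
            and self.temp_max is not None
            and self.temp_min > self.temp_max
        ):
            raise EmptyInputError("temp_min > temp_max")
        if self.max_length is not None and self.max_length <= 0:
            raise EmptyInputError("max_length must be positive")


def parse_mutation_code(code: str) -> tuple[str, int, str]:
    """Split a code like ``A123G`` into ``('A', 123, 'G')``.

    Raises :class:`MutationParseError` for malformed codes and
    :class:`SynonymousMutationError` when both residues are identical.
    """
    m = _MUTATION_RE.match(code.strip())
    if m is None:
        raise MutationParseError(f"malformed mutation code {code!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
        raise MutationParseError(f"non-canonical residue in {code!r}")
    if wt == mut:
        raise SynonymousMutationError(f"synonymous mutation code {code!r}")
    if pos < 1:
        raise MutationParseError(f"position must be >= 1 in {code!r}")
    return wt, pos, mut


def apply_mutation(entry: ProteinEntry, record: MutationRecord) -> ProteinEntry:
    """Return the mutant sequence, checking the wild-type residue first.

    A mismatch between the sequence and ``record.wt_aa`` signals a wrong
    sequence or an off-by-one numbering and raises
    :class:`ReferenceMismatchError`.
    """
    i = record.position - 1
    if record.position > len(entry.sequence):
        raise ReferenceMismatchError(
            f"{record.mutation_code}: position beyond sequence of length {len(entry)}"
        )
    if entry.sequence[i] != record.wt_aa:
        raise ReferenceMismatchError(
            f"{entry.protein_id} position {record.position} is "
            f"{entry.sequence[i]}, expected {record.wt_aa}"
        )
    mutated = entry.sequence[:i] + record.mut_aa + entry.sequence[i + 1 :]
    return replace(entry, sequence=mutated)


def _in_bounds(value: float | None, lo: float | None, hi: float | None) -> bool:
    if lo is None and hi is None:
        return True
    if value is None:
        return False
    if lo is not None and value < lo:
        return False
    if hi is not None and value > hi:
        return False
    return True


def curate_records(
    records: Sequence[MutationRecord],
    sequences: Mapping[str, ProteinEntry],
    filt: CurationFilter | None = None,
    flip_sign: bool = False,
) -> list[MutationRecord]:
    """Apply the selection bounds and, optionally, the ΔΔG sign flip.

    Order is stable and no field other than the sign of ``effect_value``
    is ever modified. Curation is idempotent for ``flip_sign=False``;
    the sign flip belongs to import from source-convention tables and
    is applied exactly once there.
    """
    filt = filt or CurationFilter()
    out: list[MutationRecord] = []
    for rec in records:
        entry = sequences.get(rec.protein_id)
        if entry is None:
            raise MissingSequenceError(f"no sequence for {rec.protein_id}")
        if not _in_bounds(rec.ph, filt.ph_min, filt.ph_max):
            continue
        if not _in_bounds(rec.temperature, filt.temp_min, filt.temp_max):
            continue
        if filt.max_length is not None and len(entry) >= filt.max_length:
            continue
        if rec.position > len(entry):
            raise ReferenceMismatchError(
                f"{rec.protein_id} {rec.mutation_code}: position beyond sequence"
            )
        if flip_sign:
            rec = replace(rec, effect_value=-rec.effect_value)
        out.append(rec)
    return out


def subsample_records(
    records: Sequence[MutationRecord], n: int, seed: int
) -> list[MutationRecord]:
    """Draw ``n`` records without replacement, reproducibly.

    The published analyses used random subsets (1154 of 1779 stability
    mutations; 796 fluorescence mutants) without recording the draw, so
    the draw here is an explicit, seeded operation.
    """
    if n > len(records):
        raise EmptyInputError(f"cannot subsample {n} of {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=n, replace=False))
    return [records[i] for i in idx]


# ---------------------------------------------------------------------------
# File I/O


def read_mutation_table(
    path: str | Path,
    effect_kind: EffectKind | str = EffectKind.STABILITY,
) -> list[MutationRecord]:
    """Read a delimited (or XLSX) mutation table.

    Expected columns: ``protein_id``, ``mutation`` (code like A123G),
    ``effect``, and optional ``ph`` and ``temperature`` (Kelvin).
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep, comment="#")
    return records_from_frame(df, effect_kind=effect_kind)


def records_from_frame(
    df: pd.DataFrame, effect_kind: EffectKind | str = EffectKind.STABILITY
) -> list[MutationRecord]:
    required = {"protein_id", "mutation", "effect"}
    missing = required - set(df.columns)
    if missing:
        raise EmptyInputError(f"mutation table missing columns {sorted(missing)}")
    if df.empty:
        raise EmptyInputError("mutation table is empty")
    kind = EffectKind(effect_kind)
    out = []
    for row in df.itertuples(index=False):
        wt, pos, mut = parse_mutation_code(str(row.mutation))
        ph = getattr(row, "ph", None)
        temp = getattr(row, "temperature", None)
        out.append(
            MutationRecord(
                protein_id=str(row.protein_id),
                wt_aa=wt,
                position=pos,
                mut_aa=mut,
                effect_value=float(row.effect),
                ph=None if ph is None or pd.isna(ph) else float(ph),
                temperature=None if temp is None or pd.isna(temp) else float(temp),
                effect_kind=kind,
            )
        )
    return out


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "mutation": [r.mutation_code for r in records],
            "effect": [r.effect_value for r in records],
            "ph": [r.ph for r in records],
            "temperature": [r.temperature for r in records],
        }
    )


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, ProteinEntry]:
    """Read a multi-record FASTA; record ids are the protein ids."""
    entries = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        entries[rec.id] = ProteinEntry(protein_id=rec.id, sequence=str(rec.seq))
    if not entries:
        raise EmptyInputError(f"no FASTA records in {path}")
    return entries


def write_fasta(entries: Mapping[str, ProteinEntry] | Iterable[ProteinEntry], path: str | Path) -> None:
    if isinstance(entries, Mapping):
        entries = entries.values()
    seq_records = [
        SeqRecord(Seq(e.sequence), id=e.protein_id, description="") for e in entries
    ]
    SeqIO.write(seq_records, str(path), "fasta")
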