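"""Physicochemical annotation of mutated sites.

Relative solvent accessibility (RSA) is the residue's accessible surface
area divided by its maximum possible value, RSA = ASA / maxASA; sites with
RSA ≥ 25% are called exposed, below that buried. ASA and secondary
structure come from external tools (Stride-like) as inputs — this module
never computes them from coordinates. Side-chain volume classes (1 = very
small … 5 = very large), hydropathy, polarity, and charge follow the IMGT
amino-acid aide-mémoire, shipped as an editable TSV config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConfDeltaError, LookupError_
from .records import AMINO_ACIDS, MutationRecord

EXPOSURE_THRESHOLD = 0.25  # RSA at or above this is "exposed"

_SS_MAP = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand", "b": "strand",
    "C": "coil", "T": "coil", "S": "coil",
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("confdelta.data").joinpath(name)))


def load_max_asa(path: str | Path | None = None) -> dict[str, float]:
    """Load a maxASA table (Å²); defaults to the bundled theoretical scale."""
    path = Path(path) if path is not None else _data_path("max_asa_tien2013.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    table = dict(zip(df["aa"], df["max_asa"].astype(float)))
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ConfDeltaError(f"maxASA table missing residues {sorted(missing)}")
    if any(v <= 0 for v in table.values()):
        raise ConfDeltaError("maxASA values must be positive")
    return table


def load_residue_classes(path: str | Path | None = None) -> pd.DataFrame:
    """Load the per-residue class table (volume 1–5, hydropathy, polarity, charge)."""
    path = Path(path) if path is not None else _data_path("imgt_classes.tsv")
    df = pd.read_csv(path, sep="\t", comment="#").set_index("aa")
    missing = set(AMINO_ACIDS) - set(df.index)
    if missing:
        raise ConfDeltaError(f"class table missing residues {sorted(missing)}")
    return df


@dataclass(frozen=True)
class ResidueAnnotation:
    """Annotation of one mutated site and the substitution made there."""

    rsa: float | None
    exposure: str | None          # buried / exposed
    ss_class: str | None          # helix / strand / coil / other
    wt_size_class: int
    mut_size_class: int
    size_change: str              # no / small / large
    hydrophobicity_change: str    # e.g. "hydrophobic->neutral"
    polarity_change: str
    charge_change: str
    effect_direction: str | None = None  # stabilizing / neutral / destabilizing


def compute_rsa(asa: float, residue: str, table: Mapping[str, float]) -> float:
    """RSA = ASA / maxASA for the residue. Values above 1 are kept, flagged."""
    if asa < 0:
        raise ConfDeltaError(f"negative ASA {asa}")
    if residue not in table:
        raise LookupError_(f"residue {residue!r} not in maxASA table")
    rsa = asa / table[residue]
    if rsa > 1.0:
        warnings.warn(f"RSA {rsa:.2f} above 1 for {residue} (ASA {asa})")
    return rsa


def classify_exposure(rsa: float) -> str:
    """Buried below 25% RSA, exposed at or above it."""
    if rsa < 0:
        raise ConfDeltaError(f"negative RSA {rsa}")
    return "exposed" if rsa >= EXPOSURE_THRESHOLD else "buried"


def normalize_ss(label: str | None) -> str | None:
    """Collapse a one-letter secondary-structure code to helix/strand/coil/other."""
    if label is None:
        return None
    return _SS_MAP.get(label.strip()[:1], "other") if label.strip() else "other"


def size_change_class(
    wt_aa: str, mut_aa: str, classes: pd.DataFrame | None = None
) -> str:
    """Category of the side-chain volume change.

    Absolute difference in volume class of 0 → 'no', 1 or 2 → 'small',
    3 or 4 → 'large'. Symmetric in the two residues.
    """
    classes = classes if classes is not None else load_residue_classes()
    for aa in (wt_aa, mut_aa):
        if aa not in classes.index:
            raise LookupError_(f"residue {aa!r} not in class table")
    diff = abs(int(classes.at[wt_aa, "volume_class"]) - int(classes.at[mut_aa, "volume_class"]))
    if diff == 0:
        return "no"
    return "small" if diff <= 2 else "large"


def size_change_direction(
    wt_aa: str, mut_aa: str, classes: pd.DataFrame | None = None
) -> str:
    """Signed variant of :func:`size_change_class`: e.g. 'large increase'."""
    classes = classes if classes is not None else load_residue_classes()
    diff = int(classes.at[mut_aa, "volume_class"]) - int(classes.at[wt_aa, "volume_class"])
    if diff == 0:
        return "no"
    magnitude = "small" if abs(diff) <= 2 else "large"
    return f"{magnitude} {'increase' if diff > 0 else 'decrease'}"


def _transition(classes: pd.DataFrame, column: str, wt: str, mut: str) -> str:
    return f"{classes.at[wt, column]}->{classes.at[mut, column]}"


def annotate_mutation(
    record: MutationRecord,
    asa: float | None = None,
    ss_label: str | None = None,
    max_asa: Mapping[str, float] | None = None,
    classes: pd.DataFrame | None = None,
) -> ResidueAnnotation:
    """Annotate one mutation; absent ASA/SS inputs yield absent fields."""
    max_asa = max_asa if max_asa is not None else load_max_asa()
    classes = classes if classes is not None else load_residue_classes()
    for aa in (record.wt_aa, record.mut_aa):
        if aa not in classes.index:
            raise LookupError_(f"residue {aa!r} not in class table")
    rsa = exposure = None
    if asa is not None:
        rsa = compute_rsa(asa, record.wt_aa, max_asa)
        exposure = classify_exposure(rsa)
    if record.effect_value > 0:
        direction = "destabilizing"
    elif record.effect_value < 0:
        direction = "stabilizing"
    else:
        direction = "neutral"
    return ResidueAnnotation(
        rsa=rsa,
        exposure=exposure,
        ss_class=normalize_ss(ss_label),
        wt_size_class=int(classes.at[record.wt_aa, "volume_class"]),
        mut_size_class=int(classes.at[record.mut_aa, "volume_class"]),
        size_change=size_change_class(record.wt_aa, record.mut_aa, classes),
        hydrophobicity_change=_transition(classes, "hydropathy", record.wt_aa, record.mut_aa),
        polarity_change=_transition(classes, "polarity", record.wt_aa, record.mut_aa),
        charge_change=_transition(classes, "charge", record.wt_aa, record.mut_aa),
        effect_direction=direction,
    )


def read_annotation_table(path: str | Path) -> dict[tuple[str, int], dict]:
    """Read per-residue ASA / secondary-structure annotations.

    Delimited text with columns ``protein_id``, ``position`` (1-based),
    ``asa`` (Å²), ``ss`` (one-letter code); keyed by (protein_id, position).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[tuple[str, int], dict] = {}
    for row in df.itertuples(index=False):
        asa = getattr(row, "asa", None)
        ss = getattr(row, "ss", None)
        out[(str(row.protein_id), int(row.position))] = {
            "asa": None if asa is None or pd.isna(asa) else float(asa),
            "ss": None if ss is None or pd.isna(ss) else str(ss),
        }
    return out
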