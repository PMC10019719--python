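"""One-command orchestration: curation → deltas → annotation → split → statistics.

The unit of exchange between stages is a per-mutation metrics table
(a DataFrame with ``effect``, ``site_delta``, ``global_delta`` and optional
category columns), so every stage can also be run standalone on files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    annotate_mutation,
    load_max_asa,
    load_residue_classes,
    read_annotation_table,
)
from .errors import ConfDeltaError, EmptyInputError
from .identity import identity_matrix, split_by_identity, write_identity_matrix
from .profiles import (
    compute_deltas,
    read_profile_from_array,
    read_profile_from_coordinates,
    select_best_model,
)
from .records import (
    CurationFilter,
    EffectKind,
    MutationRecord,
    curate_records,
    read_fasta,
    read_mutation_table,
    subsample_records,
)
from .stats import (
    RegressionFit,
    StratifiedReport,
    bh_adjust,
    correlation,
    fit_two_term_regression,
    sign_enrichment,
    stratified_report,
)

log = logging.getLogger("confdelta")

DEFAULT_CATEGORIES = (
    "exposure",
    "ss_class",
    "size_change",
    "size_direction",
    "hydrophobicity_change",
    "polarity_change",
    "charge_change",
)


@dataclass
class RunConfig:
    """Declarative description of one evaluation run."""

    mutation_table: Path
    fasta: Path
    model_dir: Path
    output_dir: Path
    annotation_table: Path | None = None
    curation: CurationFilter = field(default_factory=CurationFilter)
    flip_sign: bool = False
    effect_kind: EffectKind = EffectKind.STABILITY
    subsample: int | None = None
    split_threshold: float = 0.5
    boundary_to_train: bool = False
    regression_scope: str = "train"  # "train" or "all"
    boot_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_table", "fasta", "model_dir"):
            path = Path(getattr(self, name))
            setattr(self, name, path)
            if not path.exists():
                raise EmptyInputError(f"{name} does not exist: {path}")
        self.output_dir = Path(self.output_dir)
        if self.annotation_table is not None:
            self.annotation_table = Path(self.annotation_table)
            if not self.annotation_table.exists():
                raise EmptyInputError(
                    f"annotation_table does not exist: {self.annotation_table}"
                )
        if self.regression_scope not in {"train", "all"}:
            raise EmptyInputError(f"unknown regression scope {self.regression_scope!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "curation" in raw and isinstance(raw["curation"], dict):
            raw["curation"] = CurationFilter(**raw["curation"])
        if "effect_kind" in raw:
            raw["effect_kind"] = EffectKind(raw["effect_kind"])
        return cls(**raw)


@dataclass
class EvaluationReport:
    """The outputs of one run, in memory."""

    table: pd.DataFrame
    correlations: pd.DataFrame
    enrichment: tuple[float, float] | None
    regression: RegressionFit | None
    stratified: StratifiedReport | None
    split: pd.DataFrame | None
    exclusions: pd.DataFrame
    counts: dict[str, int]
    manifest: dict


def _find_model_files(model_dir: Path, stem: str) -> list[Path]:
    hits: list[Path] = []
    for pattern in (
        f"{stem}.pdb",
        f"{stem}_model*.pdb",
        f"{stem}.scores.json",
        f"{stem}_model*.scores.json",
    ):
        hits.extend(sorted(model_dir.glob(pattern)))
    return hits


def load_variant_profile(model_dir: str | Path, stem: str):
    """Load every model for a variant and keep the most confident one."""
    model_dir = Path(model_dir)
    paths = _find_model_files(model_dir, stem)
    if not paths:
        return None
    profiles = []
    for k, path in enumerate(paths):
        if path.name.endswith(".scores.json"):
            profiles.append(read_profile_from_array(path, protein_id=stem, model_index=k))
        else:
            profiles.append(
                read_profile_from_coordinates(path, protein_id=stem, model_index=k)
            )
    return select_best_model(profiles)


def compute_delta_table(
    records: Sequence[MutationRecord], model_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mutation delta metrics from model files on disk.

    Returns (metrics table, exclusions table). Mutations whose wild-type or
    mutant models are missing are excluded and recorded; if more than half
    of the input cannot be matched the run is aborted.
    """
    rows = []
    excluded = []
    wt_cache: dict[str, object] = {}
    for rec in records:
        if rec.protein_id not in wt_cache:
            wt_cache[rec.protein_id] = load_variant_profile(model_dir, rec.protein_id)
        wt = wt_cache[rec.protein_id]
        mut = load_variant_profile(model_dir, f"{rec.protein_id}_{rec.mutation_code}")
        if wt is None or mut is None:
            missing = "wild-type" if wt is None else "mutant"
            excluded.append(
                {
                    "protein_id": rec.protein_id,
                    "mutation": rec.mutation_code,
                    "reason": f"missing {missing} model",
                }
            )
            continue
        deltas = compute_deltas(wt, mut, rec.position)
        rows.append(
            {
                "protein_id": rec.protein_id,
                "mutation": rec.mutation_code,
                "effect": rec.effect_value,
                "site_delta": deltas.site_delta,
                "global_delta": deltas.global_delta,
            }
        )
    if excluded and len(excluded) > len(records) / 2:
        raise ConfDeltaError(
            f"{len(excluded)} of {len(records)} mutations lack model files"
        )
    return pd.DataFrame(rows), pd.DataFrame(excluded, columns=["protein_id", "mutation", "reason"])


def global_statistics(
    table: pd.DataFrame,
    boot_reps: int = 1000,
    seed: int = 0,
    with_enrichment: bool = True,
) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """The headline statistics of a metrics table.

    Pearson and Spearman correlations of each delta with the effect, the
    Pearson correlation between the two deltas, BH adjustment across the
    table as one family, and (for stability effects) the exact-binomial
    sign enrichment among destabilizing mutations.
    """
    pairs = [
        ("site_delta", "effect"),
        ("global_delta", "effect"),
        ("site_delta", "global_delta"),
    ]
    rows = []
    rng = np.random.default_rng(seed)
    for x_col, y_col in pairs:
        methods = ("pearson", "spearman") if y_col == "effect" else ("pearson",)
        for method in methods:
            res = correlation(
                table[x_col],
                table[y_col],
                method=method,
                boot_reps=boot_reps,
                seed=int(rng.integers(2**31)),
            )
            rows.append(
                {
                    "x": x_col,
                    "y": y_col,
                    "method": method,
                    "estimate": res.estimate,
                    "se": res.uncertainty,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    df = pd.DataFrame(rows)
    df["p_bh"] = bh_adjust(df["p_value"].to_numpy())
    enrich = None
    if with_enrichment:
        enrich = sign_enrichment(
            table["site_delta"].to_numpy(), table["effect"].to_numpy()
        )
    return df, enrich


def run_evaluation(config: RunConfig) -> EvaluationReport:
    """Execute the full pipeline described by ``config`` and write reports."""
    records = read_mutation_table(config.mutation_table, effect_kind=config.effect_kind)
    sequences = read_fasta(config.fasta)
    counts = {"input": len(records)}
    log.info("loaded %d mutations, %d sequences", len(records), len(sequences))

    curated = curate_records(records, sequences, config.curation, config.flip_sign)
    if not curated:
        raise EmptyInputError("no mutations survive curation")
    counts["curated"] = len(curated)
    if config.subsample is not None:
        curated = subsample_records(curated, config.subsample, config.seed)
        counts["subsampled"] = len(curated)
    log.info("curated down to %d mutations", len(curated))

    table, exclusions = compute_delta_table(curated, config.model_dir)
    counts["with_deltas"] = len(table)
    counts["excluded_no_model"] = len(exclusions)

    annotations = None
    stratified = None
    if config.annotation_table is not None:
        site_info = read_annotation_table(config.annotation_table)
        max_asa = load_max_asa()
        classes = load_residue_classes()
        by_code = {(r.protein_id, r.mutation_code): r for r in curated}
        ann_rows = []
        from .annotation import size_change_direction

        for row in table.itertuples(index=False):
            rec = by_code[(row.protein_id, row.mutation)]
            info = site_info.get((rec.protein_id, rec.position), {})
            ann = annotate_mutation(
                rec, info.get("asa"), info.get("ss"), max_asa, classes
            )
            ann_rows.append(
                {
                    "rsa": ann.rsa,
                    "exposure": ann.exposure,
                    "ss_class": ann.ss_class,
                    "size_change": ann.size_change,
                    "size_direction": size_change_direction(rec.wt_aa, rec.mut_aa, classes),
                    "hydrophobicity_change": ann.hydrophobicity_change,
                    "polarity_change": ann.polarity_change,
                    "charge_change": ann.charge_change,
                    "effect_direction": ann.effect_direction,
                }
            )
        annotations = pd.DataFrame(ann_rows)
        table = pd.concat([table.reset_index(drop=True), annotations], axis=1)

    split_frame = None
    labels = None
    curated_ids = sorted({r.protein_id for r in curated})
    if len(curated_ids) >= 2:
        matrix = identity_matrix({pid: sequences[pid] for pid in curated_ids})
        assignment = split_by_identity(
            matrix, config.split_threshold, config.boundary_to_train
        )
        labels = {pid: assignment.labels[pid] for pid in curated_ids}
        table["split"] = table["protein_id"].map(labels)
        split_frame = assignment.to_frame()
    else:
        warnings.warn("fewer than two proteins: no identity split performed")
        matrix = None

    boot = config.boot_reps
    correlations, enrichment = global_statistics(
        table,
        boot_reps=boot,
        seed=config.seed,
        with_enrichment=config.effect_kind == EffectKind.STABILITY,
    )

    regression = None
    triple = lambda df: (
        df["site_delta"].to_numpy(),
        df["global_delta"].to_numpy(),
        df["effect"].to_numpy(),
    )
    if config.regression_scope == "train" and labels is not None:
        train = table[table["split"] == "train"]
        test = table[table["split"] == "test"]
        if len(train) >= 3:
            regression = fit_two_term_regression(
                triple(train),
                triple(test) if len(test) >= 3 else None,
                boot_reps=boot,
                seed=config.seed,
            )
        else:
            warnings.warn("training set smaller than 3: regression fit on all data")
    if regression is None:
        regression = fit_two_term_regression(
            triple(table), boot_reps=boot, seed=config.seed
        )

    if annotations is not None:
        categories = [c for c in DEFAULT_CATEGORIES if c in table.columns]
        stratified = stratified_report(
            table, categories, boot_reps=min(boot, 200), seed=config.seed
        )

    manifest = {
        "package": "confdelta",
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "mutation_table": str(config.mutation_table),
            "fasta": str(config.fasta),
            "model_dir": str(config.model_dir),
            "annotation_table": (
                str(config.annotation_table) if config.annotation_table else None
            ),
        },
        "curation": dataclasses.asdict(config.curation),
        "flip_sign": config.flip_sign,
        "effect_kind": config.effect_kind.value,
        "subsample": config.subsample,
        "split_threshold": config.split_threshold,
        "boundary_to_train": config.boundary_to_train,
        "regression_scope": config.regression_scope,
        "boot_reps": config.boot_reps,
        "counts": counts,
    }

    report = EvaluationReport(
        table=table,
        correlations=correlations,
        enrichment=enrichment,
        regression=regression,
        stratified=stratified,
        split=split_frame,
        exclusions=exclusions,
        counts=counts,
        manifest=manifest,
    )
    if config.output_dir:
        write_report(report, config.output_dir, matrix)
    return report


def _corr_dict(res) -> dict:
    return {
        "estimate": res.estimate,
        "se": res.uncertainty,
        "p_value": res.p_value,
        "n": res.n,
    }


def write_report(
    report: EvaluationReport, outdir: str | Path, matrix=None
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = lambda df: df.map(lambda v: f"{v:.10g}" if isinstance(v, float) else v)
    fmt(report.table).to_csv(outdir / "mutations_with_deltas.tsv", sep="\t", index=False)
    fmt(report.correlations).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    fmt(report.exclusions).to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    if report.split is not None:
        fmt(report.split).to_csv(outdir / "split.tsv", sep="\t", index=False)
    if matrix is not None:
        write_identity_matrix(matrix, outdir / "identity_matrix.tsv")
    if report.stratified is not None:
        fmt(report.stratified.rows).to_csv(outdir / "stratified.tsv", sep="\t", index=False)
        fmt(report.stratified.kruskal).to_csv(
            outdir / "kruskal_wallis.tsv", sep="\t", index=False
        )
    payload = {"manifest": report.manifest}
    if report.enrichment is not None:
        frac, p = report.enrichment
        payload["sign_enrichment"] = {
            "fraction_negative_among_destabilizing": frac,
            "p_value": p,
        }
    if report.regression is not None:
        reg = report.regression
        payload["regression"] = {
            "intercept": reg.intercept,
            "coef_site": reg.coef_site,
            "coef_global": reg.coef_global,
            "train_pcc": _corr_dict(reg.train_pcc),
            "test_pcc": _corr_dict(reg.test_pcc) if reg.test_pcc else None,
        }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
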