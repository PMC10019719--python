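"""Synthetic cohorts with known ground-truth coupling.

Running a structure predictor over thousands of mutants is not something a
test suite can do, so this module fabricates everything downstream code
consumes: protein sequences, wild-type/mutant per-residue confidence
profiles (five re-noised models per variant, as predictors emit), mutation
tables with true effects, and per-residue ASA/secondary-structure
annotations. The construction plants a linear coupling between the effect
and the confidence drop at the mutated site,

    site perturbation = -beta_site * effect + Normal(0, sigma_site),

spread to neighbouring residues with exponential decay, plus a uniform
chain shift of ``-beta_glob * effect / length``. The implied correlation
between the site delta and the effect has the closed form in
:func:`expected_site_correlation`, which parameter-recovery tests check
against the empirical pipeline output.

Two deterministic table factories support end-to-end checks of the
statistics and curation stages: :func:`synthetic_metrics_table` (a
synthetic stand-in for a published per-mutation metrics table, with an
imposed sample correlation structure) and :func:`synthetic_curation_table`
(a raw-table funnel with controlled in-filter/out-of-filter composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .annotation import load_max_asa
from .errors import EmptyInputError
from .profiles import ConfidenceProfile
from .records import (
    AMINO_ACIDS,
    CurationFilter,
    EffectKind,
    MutationRecord,
    ProteinEntry,
    write_fasta,
    write_mutation_table,
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort.

    Defaults emulate the benchmark regime this package targets: small
    proteins (< 250 residues), a destabilizing-dominated ΔΔG mixture
    (20% stabilizing at mean −0.5 ± 0.5 kcal/mol, 80% destabilizing at
    +1.5 ± 1.0), and a site coupling/noise ratio whose implied
    site-delta–effect correlation is ≈ −0.17 — weak signal, as real
    confidence deltas show. Couplings are in confidence units per
    effect unit; noise SDs in confidence units.
    """

    n_proteins: int = 20
    length_range: tuple[int, int] = (60, 240)
    n_mutations_per_protein: int = 10
    stabilizing_fraction: float = 0.2
    stabilizing_mean: float = -0.5
    stabilizing_sd: float = 0.5
    destabilizing_mean: float = 1.5
    destabilizing_sd: float = 1.0
    site_coupling: float = 0.5
    global_coupling: float = 0.5
    site_noise_sd: float = 3.52
    neighbor_decay: float = 2.0
    base_quality_range: tuple[float, float] = (70.0, 95.0)
    ar_corr: float = 0.8
    ar_sd: float = 3.0
    model_noise_sd: float = 0.2
    n_models: int = 5
    effect_kind: EffectKind = EffectKind.STABILITY
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (10 <= lo <= hi):
            raise EmptyInputError("length range must satisfy 10 <= lo <= hi")
        if not 0.0 <= self.stabilizing_fraction <= 1.0:
            raise EmptyInputError("stabilizing_fraction must lie in [0, 1]")
        for sd in (
            self.stabilizing_sd,
            self.destabilizing_sd,
            self.site_noise_sd,
            self.ar_sd,
            self.model_noise_sd,
        ):
            if sd < 0:
                raise EmptyInputError("standard deviations must be >= 0")
        if self.n_proteins < 1 or self.n_mutations_per_protein < 1 or self.n_models < 1:
            raise EmptyInputError("counts must be >= 1")


def effect_mixture_sd(params: GeneratorParams) -> float:
    """SD of the two-component Gaussian effect mixture."""
    w = params.stabilizing_fraction
    m1, s1 = params.stabilizing_mean, params.stabilizing_sd
    m2, s2 = params.destabilizing_mean, params.destabilizing_sd
    mean = w * m1 + (1 - w) * m2
    second = w * (s1**2 + m1**2) + (1 - w) * (s2**2 + m2**2)
    return float(np.sqrt(second - mean**2))


def expected_site_correlation(params: GeneratorParams) -> float:
    """Closed-form correlation between the site delta and the effect.

    With site delta = -beta*G + eps, G the effect (SD sigma_G) and eps
    independent noise (SD sigma_site), the correlation is
    ``-beta*sigma_G / sqrt(beta^2 sigma_G^2 + sigma_site^2)``. Model
    re-noising adds a further ~2*model_noise_sd^2 of variance, negligible
    at the defaults.
    """
    sigma_g = effect_mixture_sd(params)
    beta = params.site_coupling
    denom = np.hypot(beta * sigma_g, params.site_noise_sd)
    if denom == 0:
        raise EmptyInputError("zero total variance: correlation undefined")
    return float(-beta * sigma_g / denom)


def site_noise_for_expected_correlation(
    params: GeneratorParams, target: float
) -> GeneratorParams:
    """Return params with ``site_noise_sd`` solved so the closed-form
    site correlation equals ``target`` (sign must oppose the coupling)."""
    if not 0 < abs(target) < 1:
        raise EmptyInputError("target correlation must lie in (0, 1) in magnitude")
    if target * params.site_coupling >= 0:
        raise EmptyInputError("target sign must oppose the site coupling sign")
    sigma_g = effect_mixture_sd(params)
    sd = abs(params.site_coupling) * sigma_g * np.sqrt(1.0 / target**2 - 1.0)
    return replace(params, site_noise_sd=float(sd))


@dataclass
class SyntheticCohort:
    """Everything a pipeline run consumes, plus the ground truth."""

    params: GeneratorParams
    proteins: dict[str, ProteinEntry]
    records: list[MutationRecord]
    wt_models: dict[str, list[ConfidenceProfile]]
    mut_models: dict[tuple[str, str], list[ConfidenceProfile]]
    annotations: dict[tuple[str, int], dict]
    clip_fraction: float

    @property
    def n_mutations(self) -> int:
        return len(self.records)


_MAX_ASA = load_max_asa()


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _ar1(rng: np.random.Generator, length: int, rho: float, sd: float) -> np.ndarray:
    """First-order autoregressive noise: confidence varies smoothly along a chain."""
    eps = np.empty(length)
    eps[0] = rng.normal(0.0, sd)
    innovations = rng.normal(0.0, sd, size=length - 1) if length > 1 else []
    for i in range(1, length):
        eps[i] = rho * eps[i - 1] + np.sqrt(1.0 - rho**2) * innovations[i - 1]
    return eps


def generate_cohort(params: GeneratorParams | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort, bit-reproducible under the seed."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.length_range
    proteins: dict[str, ProteinEntry] = {}
    records: list[MutationRecord] = []
    wt_models: dict[str, list[ConfidenceProfile]] = {}
    mut_models: dict[tuple[str, str], list[ConfidenceProfile]] = {}
    annotations: dict[tuple[str, int], dict] = {}
    clipped = 0
    total = 0

    def make_models(pid: str, latent: np.ndarray, base_index: int = 0):
        nonlocal clipped, total
        models = []
        for k in range(params.n_models):
            noisy = latent + rng.normal(0.0, params.model_noise_sd, size=latent.size)
            clipped += int(((noisy < 0) | (noisy > 100)).sum())
            total += noisy.size
            models.append(
                ConfidenceProfile(
                    protein_id=pid,
                    scores=np.clip(noisy, 0.0, 100.0),
                    model_index=base_index + k,
                )
            )
        return models

    for p in range(params.n_proteins):
        pid = f"SYN{p + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        entry = ProteinEntry(protein_id=pid, sequence=_random_sequence(rng, length))
        proteins[pid] = entry
        base = rng.uniform(*params.base_quality_range)
        latent_wt = base + _ar1(rng, length, params.ar_corr, params.ar_sd)
        wt_models[pid] = make_models(pid, latent_wt)
        for pos0 in range(length):
            # ASA drawn as a fraction of the residue's maximum, so RSA spans [0, 1]
            cap = _MAX_ASA[entry.sequence[pos0]]
            annotations[(pid, pos0 + 1)] = {
                "asa": float(rng.uniform(0.0, cap)),
                "ss": str(rng.choice(list("HEC"), p=[0.35, 0.25, 0.40])),
            }
        used_codes: set[str] = set()
        offsets = np.arange(length)
        for _ in range(params.n_mutations_per_protein):
            while True:
                pos = int(rng.integers(1, length + 1))
                wt_aa = entry.sequence[pos - 1]
                mut_aa = str(rng.choice([a for a in AMINO_ACIDS if a != wt_aa]))
                code = f"{wt_aa}{pos}{mut_aa}"
                if code not in used_codes:
                    used_codes.add(code)
                    break
            if rng.uniform() < params.stabilizing_fraction:
                effect = rng.normal(params.stabilizing_mean, params.stabilizing_sd)
            else:
                effect = rng.normal(params.destabilizing_mean, params.destabilizing_sd)
            record = MutationRecord(
                protein_id=pid,
                wt_aa=wt_aa,
                position=pos,
                mut_aa=mut_aa,
                effect_value=float(effect),
                ph=float(rng.uniform(4.0, 8.0)),
                temperature=float(rng.uniform(294.0, 299.0)),
                effect_kind=params.effect_kind,
            )
            records.append(record)
            site_perturb = -params.site_coupling * effect + rng.normal(
                0.0, params.site_noise_sd
            )
            decay = np.exp(-np.abs(offsets - (pos - 1)) / params.neighbor_decay)
            latent_mut = (
                latent_wt
                + site_perturb * decay
                - params.global_coupling * effect / length
            )
            mut_models[(pid, code)] = make_models(pid, latent_mut)

    return SyntheticCohort(
        params=params,
        proteins=proteins,
        records=records,
        wt_models=wt_models,
        mut_models=mut_models,
        annotations=annotations,
        clip_fraction=clipped / total if total else 0.0,
    )


# ---------------------------------------------------------------------------
# Deterministic table factories


def synthetic_metrics_table(
    n: int = 1154,
    r_site_effect: float = -0.17,
    r_global_effect: float = 0.02,
    r_site_global: float = 0.21,
    frac_negative_among_destabilizing: float = 0.87,
    site_scale: float = 3.5,
    global_scale: float = 0.8,
    seed: int = 0,
    params: GeneratorParams | None = None,
) -> pd.DataFrame:
    """Synthetic stand-in for a published per-mutation metrics table.

    Builds ``n`` rows of (effect, site_delta, global_delta) whose *sample*
    correlation matrix equals the requested one exactly (to float
    precision), and in which the requested fraction of destabilizing rows
    (effect > 0) has a negative site delta, exact to the nearest achievable
    count. The effect column is drawn from the cohort's ΔΔG mixture;
    the deltas are then built by seeded Gram–Schmidt construction, so the
    statistics stage can be validated against known moments. This is a
    synthetic object — it reproduces published summary statistics by
    construction, not the underlying measurements.
    """
    params = params or GeneratorParams()
    if n < 10:
        raise EmptyInputError("need n >= 10 rows")
    rng = np.random.default_rng(seed)
    effect = np.where(
        rng.uniform(size=n) < params.stabilizing_fraction,
        rng.normal(params.stabilizing_mean, params.stabilizing_sd, size=n),
        rng.normal(params.destabilizing_mean, params.destabilizing_sd, size=n),
    )

    def unit(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / np.sqrt(np.mean(v**2))

    z1 = unit(effect)
    g2 = rng.normal(size=n)
    g2 = g2 - g2.mean()
    g2 = unit(g2 - np.mean(g2 * z1) * z1)
    g3 = rng.normal(size=n)
    g3 = g3 - g3.mean()
    g3 = unit(g3 - np.mean(g3 * z1) * z1 - np.mean(g3 * g2) * g2)

    r12, r13, r23 = r_site_effect, r_global_effect, r_site_global
    site_std = r12 * z1 + np.sqrt(1.0 - r12**2) * g2
    a = (r23 - r12 * r13) / np.sqrt(1.0 - r12**2)
    resid = 1.0 - r13**2 - a**2
    if resid <= 0:
        raise EmptyInputError("requested correlation matrix is not positive definite")
    global_std = r13 * z1 + a * g2 + np.sqrt(resid) * g3

    site_raw = site_scale * site_std
    destab = effect > 0
    m = int(destab.sum())
    if m < 2:
        raise EmptyInputError("too few destabilizing rows for the enrichment target")
    k = int(round(frac_negative_among_destabilizing * m))
    k = min(max(k, 1), m - 1)
    ordered = np.sort(site_raw[destab])
    shift = 0.5 * (ordered[k - 1] + ordered[k])
    return pd.DataFrame(
        {
            "effect": effect,
            "site_delta": site_raw - shift,
            "global_delta": global_scale * global_std - 0.05,
        }
    )


def synthetic_curation_table(
    seed: int = 0,
    n_pass: int = 1779,
    n_proteins: int = 80,
    n_bad_ph: int = 300,
    n_bad_temp: int = 200,
    n_long_proteins: int = 5,
    n_long_records: int = 120,
    params: GeneratorParams | None = None,
) -> tuple[list[MutationRecord], dict[str, ProteinEntry]]:
    """A raw mutation table with a controlled curation funnel.

    Emulates a source-convention database extract: ``n_pass`` records meet
    every selection bound (pH 3–9, 293–300 K, protein length < 250), the
    rest violate exactly one (pH out of range, temperature out of range, or
    an over-length protein). Effects are written in the source convention
    (stabilizing positive), so curation with ``flip_sign=True`` restores the
    analysis orientation. Record order is shuffled, reproducibly.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    sequences: dict[str, ProteinEntry] = {}
    for p in range(n_proteins):
        pid = f"CUR{p + 1:04d}"
        sequences[pid] = ProteinEntry(
            pid, _random_sequence(rng, int(rng.integers(60, 250)))
        )
    long_ids = []
    for p in range(n_long_proteins):
        pid = f"LONG{p + 1:03d}"
        sequences[pid] = ProteinEntry(
            pid, _random_sequence(rng, int(rng.integers(250, 400)))
        )
        long_ids.append(pid)

    def draw_record(pid: str, ph: float, temp: float) -> MutationRecord:
        seq = sequences[pid].sequence
        pos = int(rng.integers(1, len(seq) + 1))
        wt_aa = seq[pos - 1]
        mut_aa = str(rng.choice([a for a in AMINO_ACIDS if a != wt_aa]))
        if rng.uniform() < params.stabilizing_fraction:
            effect = rng.normal(params.stabilizing_mean, params.stabilizing_sd)
        else:
            effect = rng.normal(params.destabilizing_mean, params.destabilizing_sd)
        return MutationRecord(
            protein_id=pid,
            wt_aa=wt_aa,
            position=pos,
            mut_aa=mut_aa,
            effect_value=-float(effect),  # source convention: stabilizing > 0
            ph=ph,
            temperature=temp,
        )

    short_ids = [p for p in sequences if p not in long_ids]
    records = []
    for _ in range(n_pass):
        pid = str(rng.choice(short_ids))
        records.append(
            draw_record(pid, float(rng.uniform(3.0, 9.0)), float(rng.uniform(293.0, 300.0)))
        )
    for _ in range(n_bad_ph):
        pid = str(rng.choice(short_ids))
        ph = float(rng.uniform(0.5, 2.9)) if rng.uniform() < 0.5 else float(rng.uniform(9.1, 12.0))
        records.append(draw_record(pid, ph, float(rng.uniform(293.0, 300.0))))
    for _ in range(n_bad_temp):
        pid = str(rng.choice(short_ids))
        temp = float(rng.uniform(274.0, 292.9)) if rng.uniform() < 0.5 else float(rng.uniform(300.1, 330.0))
        records.append(draw_record(pid, float(rng.uniform(3.0, 9.0)), temp))
    for _ in range(n_long_records):
        pid = str(rng.choice(long_ids))
        records.append(
            draw_record(pid, float(rng.uniform(3.0, 9.0)), float(rng.uniform(293.0, 300.0)))
        )
    order = rng.permutation(len(records))
    return [records[i] for i in order], sequences


# ---------------------------------------------------------------------------
# On-disk fixture factory


def _write_pdb(profile: ConfidenceProfile, sequence: str, path: Path) -> None:
    builder = StructureBuilder()
    builder.init_structure(profile.protein_id)
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for i, (aa, score) in enumerate(zip(sequence, profile.scores)):
        resname = protein_letters_1to3[aa].upper()
        builder.init_residue(resname, " ", i + 1, " ")
        builder.init_atom(
            "CA",
            np.array([3.8 * i, 0.0, 0.0]),
            round(float(score), 2),
            1.0,
            " ",
            " CA ",
            element="C",
        )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def write_cohort(
    cohort: SyntheticCohort, outdir: str | Path, model_format: str = "json"
) -> dict[str, Path]:
    """Write the cohort as the files the real pipeline consumes.

    FASTA sequences, a TSV mutation table, a TSV annotation table, and one
    model file per variant model, named ``<pid>_model<k>`` (wild type) or
    ``<pid>_<code>_model<k>`` (mutant) with suffix ``.pdb`` or
    ``.scores.json``. PDB B-factors are fixed-width, so scores round-trip
    at two decimals in that format.
    """
    if model_format not in {"json", "pdb"}:
        raise EmptyInputError(f"unknown model format {model_format!r}")
    outdir = Path(outdir)
    models_dir = outdir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(cohort.proteins, outdir / "sequences.fasta")
    write_mutation_table(cohort.records, outdir / "mutations.tsv")
    ann = pd.DataFrame(
        [
            {"protein_id": pid, "position": pos, "asa": v["asa"], "ss": v["ss"]}
            for (pid, pos), v in cohort.annotations.items()
        ]
    )
    ann.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    def dump(name: str, models: list[ConfidenceProfile], sequence: str) -> None:
        for k, profile in enumerate(models):
            if model_format == "pdb":
                _write_pdb(profile, sequence, models_dir / f"{name}_model{k}.pdb")
            else:
                path = models_dir / f"{name}_model{k}.scores.json"
                path.write_text(
                    "[" + ", ".join(f"{s:.6f}" for s in profile.scores) + "]"
                )

    for pid, models in cohort.wt_models.items():
        dump(pid, models, cohort.proteins[pid].sequence)
    for (pid, code), models in cohort.mut_models.items():
        seq = cohort.proteins[pid].sequence
        i = int(code[1:-1]) - 1
        mut_seq = seq[:i] + code[-1] + seq[i + 1 :]
        dump(f"{pid}_{code}", models, mut_seq)
    return {
        "fasta": outdir / "sequences.fasta",
        "mutations": outdir / "mutations.tsv",
        "annotations": outdir / "annotations.tsv",
        "models": models_dir,
    }
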