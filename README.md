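# confdelta

Do the confidence scores of protein structure predictors carry information
about the effect of a point mutation? Predictors such as AlphaFold report a
per-residue confidence, pLDDT (0–100, stored in the B-factor field of the
output PDB file), and its chain mean ⟨pLDDT⟩. `confdelta` evaluates the two
mutant-minus-wild-type deltas

- **ΔpLDDT** — the confidence change at the mutated residue, and
- **Δ⟨pLDDT⟩** — the change in mean chain confidence,

as predictors of measured stability changes (ΔΔG, kcal/mol; stabilizing < 0)
and of functional readouts (e.g. fluorescence of GFP mutants). It is aimed at
structural bioinformaticians who want to benchmark, stress-test, or extend
this kind of confidence-delta analysis without re-running a structure
predictor for every question.

The package provides the full evaluation pipeline as tested, composable
stages:

| stage | module | what it does |
|---|---|---|
| curation | `confdelta.records` | parse mutation codes (`A123G`), filter by assay pH (3–9), temperature (293–300 K) and protein length (< 250), flip the ΔΔG sign convention of source databases, seeded subsampling |
| metrics | `confdelta.profiles` | read per-residue scores from PDB B-factors or plain score arrays, keep the best of several models (highest ⟨pLDDT⟩), compute ΔpLDDT and Δ⟨pLDDT⟩ |
| annotation | `confdelta.annotation` | RSA = ASA/maxASA with the 25% buried/exposed threshold; side-chain volume classes 1–5 (no/small/large change = diff 0 / 1–2 / 3–4); hydropathy, polarity and charge transitions |
| split | `confdelta.identity` | all-vs-all global-alignment sequence identity and the 50% homology train/test split |
| statistics | `confdelta.stats` | Pearson/Spearman correlations with seeded-bootstrap uncertainties, two-predictor OLS (`DeltaRegressor`, scikit-learn compatible), Kruskal–Wallis across categories, exact-binomial sign enrichment, Benjamini–Hochberg adjustment, stratified reports |
| simulation | `confdelta.simulate` | synthetic wild-type/mutant profile cohorts with a known, tunable coupling between effect and confidence drop, plus a closed form for the implied correlation |
| orchestration | `confdelta.pipeline`, `confdelta` CLI | one-command run from files to a report bundle with a reproducibility manifest |

## Worked example

Simulate a cohort of 200 mutations in 20 proteins (five re-noised models per
variant, as a predictor would emit), pick the best model per variant, and ask
whether the site delta tracks the planted ΔΔG:

```python
import confdelta as cd

params = cd.GeneratorParams(n_proteins=20, n_mutations_per_protein=10, seed=0)
cohort = cd.generate_cohort(params)
print("expected site PCC:", round(cd.expected_site_correlation(params), 3))

site, effect = [], []
for rec in cohort.records:
    wt = cd.select_best_model(cohort.wt_models[rec.protein_id])
    mut = cd.select_best_model(cohort.mut_models[(rec.protein_id, rec.mutation_code)])
    site.append(cd.compute_deltas(wt, mut, rec.position).site_delta)
    effect.append(rec.effect_value)

res = cd.correlation(site, effect, boot_reps=1000, seed=0)
print(f"site-delta PCC = {res.estimate:.3f} +/- {res.uncertainty:.3f} "
      f"(p = {res.p_value:.2g}, n = {res.n})")
frac, p = cd.sign_enrichment(site, effect)
print(f"destabilizing with negative site delta: {100*frac:.1f}% (p = {p:.2g})")
```

which prints

```
expected site PCC: -0.171
site-delta PCC = -0.188 +/- 0.063 (p = 0.0076, n = 200)
destabilizing with negative site delta: 56.7% (p = 0.092)
```

The generator's default regime plants a weak coupling whose closed-form
correlation is −0.171; the empirical estimate (−0.188 ± 0.063) recovers it
within its bootstrap uncertainty, and the sign enrichment among destabilizing
mutations is correspondingly mild at this sample size. Statistically
significant yet far too weak to predict individual ΔΔG values — which is
exactly the kind of conclusion the pipeline is built to make auditable.

The same analysis runs from files. `confdelta simulate --out cohort/` writes
FASTA, model files, mutation and annotation tables; `confdelta run --config
run.yaml` executes curation → deltas → annotation → split → statistics and
writes a report bundle (`correlations.tsv`, `stratified.tsv`,
`kruskal_wallis.tsv`, `split.tsv`, `report.json` with regression,
enrichment, and a manifest sufficient to reproduce the run).

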