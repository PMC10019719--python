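"""The synthetic cohort generator and its closed-form check targets."""

import numpy as np
import pytest

import confdelta as cd
from confdelta.errors import EmptyInputError
from confdelta.simulate import effect_mixture_sd


def _empirical_site_correlation(cohort):
    """Site-delta/effect correlation through the real analysis path."""
    site, effect = [], []
    for rec in cohort.records:
        wt = cd.select_best_model(cohort.wt_models[rec.protein_id])
        mut = cd.select_best_model(cohort.mut_models[(rec.protein_id, rec.mutation_code)])
        site.append(cd.compute_deltas(wt, mut, rec.position).site_delta)
        effect.append(rec.effect_value)
    return float(np.corrcoef(site, effect)[0, 1])


class TestExpectedSiteCorrelation:
    def test_limits(self):
        base = cd.GeneratorParams()
        assert cd.expected_site_correlation(
            cd.GeneratorParams(site_noise_sd=0.0)
        ) == pytest.approx(-1.0)
        assert cd.expected_site_correlation(
            cd.GeneratorParams(site_coupling=0.0)
        ) == pytest.approx(0.0)
        # equal signal and noise scales -> -1/sqrt(2)
        sigma_g = effect_mixture_sd(base)
        tuned = cd.GeneratorParams(site_coupling=1.0, site_noise_sd=sigma_g)
        assert cd.expected_site_correlation(tuned) == pytest.approx(
            -1 / np.sqrt(2), abs=1e-12
        )

    def test_solver_inverts_the_closed_form(self):
        params = cd.site_noise_for_expected_correlation(cd.GeneratorParams(), -0.3)
        assert cd.expected_site_correlation(params) == pytest.approx(-0.3, abs=1e-12)
        with pytest.raises(EmptyInputError):
            cd.site_noise_for_expected_correlation(cd.GeneratorParams(), 0.3)


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self):
        p = cd.GeneratorParams(n_proteins=4, n_mutations_per_protein=3, seed=9)
        a, b = cd.generate_cohort(p), cd.generate_cohort(p)
        assert a.records == b.records
        assert a.proteins == b.proteins
        for key in a.mut_models:
            for ma, mb in zip(a.mut_models[key], b.mut_models[key]):
                assert np.array_equal(ma.scores, mb.scores)

    def test_noiseless_site_delta_is_planted_exactly(self):
        p = cd.GeneratorParams(
            n_proteins=5, n_mutations_per_protein=4, site_noise_sd=0.0,
            model_noise_sd=0.0, n_models=1, ar_sd=0.0, site_coupling=1.0, seed=2,
        )
        cohort = cd.generate_cohort(p)
        for rec in cohort.records:
            wt = cohort.wt_models[rec.protein_id][0]
            mut = cohort.mut_models[(rec.protein_id, rec.mutation_code)][0]
            d = cd.compute_deltas(wt, mut, rec.position)
            planted = -rec.effect_value - 0.5 * rec.effect_value / len(wt)
            assert d.site_delta == pytest.approx(planted, abs=1e-9)

    def test_uncoupled_regime_has_no_correlation(self):
        p = cd.GeneratorParams(
            n_proteins=60, n_mutations_per_protein=10,
            site_coupling=0.0, global_coupling=0.0, seed=3,
        )
        assert abs(_empirical_site_correlation(cd.generate_cohort(p))) < 0.1

    def test_mutant_sequences_differ_at_one_site(self, small_cohort):
        for rec in small_cohort.records:
            entry = small_cohort.proteins[rec.protein_id]
            mutated = cd.apply_mutation(entry, rec)  # raises on wt mismatch
            assert sum(a != b for a, b in zip(entry.sequence, mutated.sequence)) == 1

    def test_clipping_is_rare_under_defaults(self):
        p = cd.GeneratorParams(n_proteins=30, n_mutations_per_protein=5, seed=6)
        assert cd.generate_cohort(p).clip_fraction < 0.01

    def test_degenerate_params_rejected(self):
        with pytest.raises(EmptyInputError):
            cd.GeneratorParams(length_range=(5, 5))
        with pytest.raises(EmptyInputError):
            cd.GeneratorParams(site_noise_sd=-1.0)


class TestSyntheticMetricsTable:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_imposed_sample_moments_are_exact(self, seed):
        t = cd.synthetic_metrics_table(n=500, seed=seed)
        corr = np.corrcoef(np.column_stack([t.effect, t.site_delta, t.global_delta]).T)
        assert corr[0, 1] == pytest.approx(-0.17, abs=1e-9)
        assert corr[0, 2] == pytest.approx(0.02, abs=1e-9)
        assert corr[1, 2] == pytest.approx(0.21, abs=1e-9)

    def test_enrichment_fraction_is_exact_to_the_count(self):
        t = cd.synthetic_metrics_table(n=800, seed=1)
        destab = t[t.effect > 0]
        frac = (destab.site_delta < 0).mean()
        m = len(destab)
        assert frac == pytest.approx(round(0.87 * m) / m, abs=1e-12)

    def test_other_target_matrices(self):
        t = cd.synthetic_metrics_table(
            n=300, r_site_effect=-0.5, r_global_effect=0.1, r_site_global=0.4, seed=2
        )
        corr = np.corrcoef(np.column_stack([t.effect, t.site_delta, t.global_delta]).T)
        assert corr[0, 1] == pytest.approx(-0.5, abs=1e-9)
        assert corr[1, 2] == pytest.approx(0.4, abs=1e-9)


class TestSyntheticCurationTable:
    def test_funnel_composition(self):
        records, sequences = cd.synthetic_curation_table(
            seed=5, n_pass=200, n_bad_ph=30, n_bad_temp=20, n_long_records=15
        )
        assert len(records) == 265
        curated = cd.curate_records(records, sequences, flip_sign=True)
        assert len(curated) == 200

    def test_sign_convention_restored_by_flip(self):
        records, sequences = cd.synthetic_curation_table(
            seed=5, n_pass=300, n_bad_ph=0, n_bad_temp=0, n_long_records=0
        )
        curated = cd.curate_records(records, sequences, flip_sign=True)
        frac_destab = np.mean([r.effect_value > 0 for r in curated])
        assert frac_destab > 0.6  # mixture is destabilizing-dominated


def test_write_cohort_round_trips_profiles(small_cohort, tmp_path):
    for fmt, tol in (("json", 1e-6), ("pdb", 5e-3)):
        outdir = tmp_path / fmt
        paths = cd.write_cohort(small_cohort, outdir, model_format=fmt)
        rec = small_cohort.records[0]
        stem = f"{rec.protein_id}_{rec.mutation_code}_model0"
        suffix = ".scores.json" if fmt == "json" else ".pdb"
        reader = (
            cd.read_profile_from_array if fmt == "json" else cd.read_profile_from_coordinates
        )
        profile = reader(paths["models"] / f"{stem}{suffix}")
        original = small_cohort.mut_models[(rec.protein_id, rec.mutation_code)][0]
        assert np.allclose(profile.scores, original.scores, atol=tol)
        assert (outdir / "sequences.fasta").exists()
        assert (outdir / "mutations.tsv").exists()
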