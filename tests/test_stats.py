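"""Correlation, regression, Kruskal–Wallis, sign enrichment, BH adjustment.

Oracles here are hand-written textbook formulas, independent of the
scipy/statsmodels/sklearn routines the implementation uses.
"""

import math

import numpy as np
import pandas as pd
import pytest

import confdelta as cd
from confdelta.errors import (
    EmptyInputError,
    UndefinedCorrelationError,
    UndefinedFractionError,
)


# --- independent oracles ----------------------------------------------------

def oracle_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / math.sqrt(np.sum(dx**2) * np.sum(dy**2)))


def oracle_ranks(v):
    """Average ranks, written from the definition."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def oracle_bh(p):
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def oracle_binom_two_sided(k, n):
    """Two-sided exact binomial p against 0.5 by direct enumeration."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    return sum(v for v in pmf if v <= pmf[k] * (1 + 1e-12))


# --- correlation ------------------------------------------------------------

class TestCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(5.0)
        assert cd.correlation(x, 2 * x + 1, boot_reps=10).estimate == pytest.approx(1.0)
        assert cd.correlation(x, -x, boot_reps=10).estimate == pytest.approx(-1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_textbook_oracle(self, method, rng):
        for n in (3, 5, 17, 50):
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = cd.correlation(x, y, method=method, boot_reps=10)
            if method == "pearson":
                expected = oracle_pearson(x, y)
            else:
                expected = oracle_pearson(oracle_ranks(x), oracle_ranks(y))
            assert res.estimate == pytest.approx(expected, abs=1e-12)
            assert res.n == n and 0 < res.p_value <= 1

    def test_degenerate_inputs(self):
        with pytest.raises(UndefinedCorrelationError):
            cd.correlation([1.0, 1.0, 1.0], [1, 2, 3])
        with pytest.raises(EmptyInputError):
            cd.correlation([1, 2], [3, 4])

    def test_bootstrap_is_seed_reproducible(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = cd.correlation(x, y, boot_reps=200, seed=5)
        b = cd.correlation(x, y, boot_reps=200, seed=5)
        c = cd.correlation(x, y, boot_reps=200, seed=6)
        assert a.uncertainty == b.uncertainty
        assert a.uncertainty != c.uncertainty

    def test_bootstrap_se_approaches_fisher_se(self, rng):
        """On bivariate normal data at n=1000 the bootstrap SD and the
        Fisher-z standard error agree to ~20%."""
        n, r = 1000, 0.3
        cov = [[1, r], [r, 1]]
        x, y = rng.multivariate_normal([0, 0], cov, size=n).T
        boot = cd.correlation(x, y, boot_reps=1000, seed=0).uncertainty
        fisher = cd.correlation(x, y, uncertainty="fisher").uncertainty
        assert boot == pytest.approx(fisher, rel=0.2)


# --- regression -------------------------------------------------------------

class TestRegression:
    def _planted(self, rng, n=40):
        site = rng.normal(size=n)
        glob = rng.normal(size=n)
        effect = 1.0 - 0.5 * site + 0.1 * glob
        return site, glob, effect

    def test_noiseless_recovery_to_machine_precision(self, rng):
        triple = self._planted(rng)
        fit = cd.fit_two_term_regression(triple, boot_reps=10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.coef_site == pytest.approx(-0.5, abs=1e-12)
        assert fit.coef_global == pytest.approx(0.1, abs=1e-12)

    def test_train_equals_test_on_noiseless_data(self, rng):
        triple = self._planted(rng)
        fit = cd.fit_two_term_regression(triple, test=triple, boot_reps=10)
        assert fit.train_pcc.estimate == pytest.approx(1.0)
        assert fit.test_pcc.estimate == pytest.approx(1.0)

    def test_residuals_orthogonal_to_predictors(self, rng):
        site, glob, effect = self._planted(rng)
        effect = effect + rng.normal(size=len(effect))
        fit = cd.fit_two_term_regression((site, glob, effect), boot_reps=10)
        resid = effect - (fit.intercept + fit.coef_site * site + fit.coef_global * glob)
        assert abs(resid.sum()) < 1e-9
        assert abs(np.dot(resid, site)) < 1e-9
        assert abs(np.dot(resid, glob)) < 1e-9

    def test_collinear_predictors_warn(self, rng):
        site = rng.normal(size=20)
        with pytest.warns(UserWarning, match="rank-deficient"):
            cd.fit_two_term_regression((site, 2 * site, site), boot_reps=10)

    def test_estimator_follows_sklearn_protocol(self, rng):
        from sklearn.base import clone

        site, glob, effect = self._planted(rng)
        X = np.column_stack([site, glob])
        est = cd.DeltaRegressor()
        clone(est)  # get_params/set_params round trip
        est.fit(X, effect)
        assert est.coef_site_ == pytest.approx(-0.5, abs=1e-12)
        assert np.allclose(est.predict(X), effect)
        assert est.score(X, effect) == pytest.approx(1.0)


# --- Kruskal–Wallis ---------------------------------------------------------

class TestKruskalWallis:
    def test_no_separation(self):
        h, p = cd.kruskal_wallis([[3.0, 3.0, 3.0], [3.0, 3.0]])
        assert h == 0.0 and p == 1.0
        h, _ = cd.kruskal_wallis([[7.0], [7.0], [7.0]])
        assert h == 0.0

    def test_hand_ranked_example(self):
        h, p = cd.kruskal_wallis([[1, 2, 3], [101, 102, 103]])
        # ranks 1..6, H = 12/(6*7) * (6 + 75/... ) computed by hand = 3.857...
        assert h == pytest.approx(3.857142857, abs=1e-6)
        assert p < 0.1

    def test_input_validation(self):
        with pytest.raises(EmptyInputError):
            cd.kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(EmptyInputError):
            cd.kruskal_wallis([[1.0], []])


# --- sign enrichment --------------------------------------------------------

class TestSignEnrichment:
    def test_extreme_case(self):
        frac, p = cd.sign_enrichment([-1.0] * 10, [1.0] * 10)
        assert frac == 1.0
        assert p == pytest.approx(2 * 0.5**10)

    def test_null_case(self):
        deltas = [-1.0] * 50 + [1.0] * 50
        frac, p = cd.sign_enrichment(deltas, [1.0] * 100)
        assert frac == 0.5
        assert p == pytest.approx(1.0, abs=0.2)

    def test_zeros_and_stabilizing_excluded(self):
        deltas = [-1, -1, 5, 5]
        effects = [2.0, 2.0, 0.0, -1.0]  # only the first two are destabilizing
        frac, _ = cd.sign_enrichment(deltas, effects)
        assert frac == 1.0

    def test_no_destabilizing_is_undefined(self):
        with pytest.raises(UndefinedFractionError):
            cd.sign_enrichment([1.0, -1.0], [-1.0, 0.0])

    def test_p_matches_brute_force_binomial(self, rng):
        for n in (1, 2, 5, 11, 20):
            deltas = rng.normal(size=n)
            _, p = cd.sign_enrichment(deltas, np.ones(n))
            k = int((deltas < 0).sum())
            assert p == pytest.approx(oracle_binom_two_sided(k, n), abs=1e-12)


# --- Benjamini–Hochberg -----------------------------------------------------

class TestBhAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5, 1.0], [1.0, 1.0]),
            ([0.3], [0.3]),
        ],
    )
    def test_hand_examples(self, raw, expected):
        assert np.allclose(cd.bh_adjust(raw), expected)

    def test_matches_oracle_on_random_inputs(self, rng):
        for n in (1, 2, 7, 25):
            p = rng.uniform(1e-6, 1.0, size=n)
            assert np.allclose(cd.bh_adjust(p), oracle_bh(p), atol=1e-12)

    def test_adjusted_dominates_raw_and_is_monotone(self, rng):
        p = np.sort(rng.uniform(1e-6, 1.0, size=20))
        adj = cd.bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        assert np.all(np.diff(adj) >= -1e-15)

    def test_domain(self):
        for bad in ([0.0, 0.5], [1.1], [-0.2], [np.nan]):
            with pytest.raises(EmptyInputError):
                cd.bh_adjust(bad)


# --- stratified report ------------------------------------------------------

def _metrics_frame(rng, n=120, coupled_level=None, category="exposure"):
    effect = rng.normal(1.0, 1.0, size=n)
    levels = rng.choice(["buried", "exposed"], size=n)
    noise = rng.normal(0, 1.0, size=n)
    if coupled_level is None:
        site = noise
    else:
        site = np.where(levels == coupled_level, -2.0 * effect + 0.3 * noise, 3.0 * noise)
    return pd.DataFrame(
        {
            "effect": effect,
            "site_delta": site,
            "global_delta": rng.normal(size=n),
            category: levels,
        }
    )


class TestStratifiedReport:
    def test_single_level_reproduces_global_correlation(self, rng):
        df = _metrics_frame(rng)
        df["category"] = "all"
        report = cd.stratified_report(df, ["category"], boot_reps=20, seed=0)
        row = report.rows[
            (report.rows.predictor == "site_delta") & (report.rows.level == "all")
        ].iloc[0]
        assert row["pcc"] == pytest.approx(oracle_pearson(df.site_delta, df.effect), abs=1e-12)
        assert row["n"] == len(df)

    def test_signal_concentrates_in_coupled_level(self, rng):
        df = _metrics_frame(rng, n=400, coupled_level="buried")
        report = cd.stratified_report(df, ["exposure"], boot_reps=20, seed=0)
        rows = report.rows[report.rows.predictor == "site_delta"].set_index("level")
        assert abs(rows.loc["buried", "pcc"]) > abs(rows.loc["exposed", "pcc"])
        assert report.kruskal.iloc[0]["category"] == "exposure"

    def test_small_levels_flagged_and_counts_conserved(self, rng):
        df = _metrics_frame(rng, n=30)
        df.loc[df.index[:2], "exposure"] = "rare"
        df.loc[df.index[2:], "exposure"] = "common"
        report = cd.stratified_report(df, ["exposure"], boot_reps=20, seed=0)
        rows = report.rows[report.rows.predictor == "site_delta"]
        assert bool(rows[rows.level == "rare"].iloc[0]["flagged"])
        assert rows["n"].sum() == len(df)

    def test_bh_family_spans_whole_report(self, rng):
        df = _metrics_frame(rng, n=200, coupled_level="buried")
        report = cd.stratified_report(df, ["exposure"], boot_reps=20, seed=0)
        rows = report.rows.dropna(subset=["pcc_p"])
        raws = list(rows["pcc_p"]) + list(rows.dropna(subset=["scc_p"])["scc_p"])
        adjusted = list(rows["pcc_p_bh"]) + list(rows.dropna(subset=["scc_p"])["scc_p_bh"])
        expected = oracle_bh(raws)
        assert np.allclose(sorted(adjusted), sorted(expected), atol=1e-12)
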