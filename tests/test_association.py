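"""Odds ratios, logistic regression, Spearman, scans and cross-region rho."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vagitopics import (GeneratorParams, cross_region_correlation, fit_gom,
                        generate_cohort, logistic_fit, odds_ratio, spearman,
                        table_from_counts, topic_clinical_scan)
from vagitopics.association import TwoByTwo
from vagitopics.exceptions import SeparationError

from conftest import make_cm


class TestOddsRatio:
    def test_symmetric_table_square_law(self):
        res = odds_ratio(TwoByTwo(4, 2, 2, 4))
        assert res.or_ == pytest.approx(4.0)

    def test_woolf_ci_brackets_estimate(self):
        res = odds_ratio(TwoByTwo(24, 26, 11, 38))
        assert res.ci_low < res.or_ < res.ci_high
        assert res.ci_low == pytest.approx(np.exp(np.log(res.or_) - 1.96 * res.se))

    def test_zero_cell_without_correction_flagged_infinite(self):
        res = odds_ratio(TwoByTwo(5, 0, 3, 4))
        assert np.isinf(res.or_)

    def test_haldane_correction_gives_finite_or(self):
        res = odds_ratio(TwoByTwo(5, 0, 3, 4), correction="haldane")
        assert np.isfinite(res.or_)
        assert res.corrected

    def test_invariance_under_population_scaling(self):
        """The population OR is invariant to arm sizes: estimate it from a
        large simulated 2x2 with scaled margins."""
        rng = np.random.default_rng(0)
        p1, p0 = 0.4, 0.2   # exposure prevalences -> OR = (0.4/0.6)/(0.2/0.8)
        target = (p1 / (1 - p1)) / (p0 / (1 - p0))
        for n1, n0 in [(20000, 20000), (40000, 10000)]:
            a = rng.binomial(n1, p1)
            c = rng.binomial(n0, p0)
            res = odds_ratio(TwoByTwo(a, n1 - a, c, n0 - c))
            assert res.or_ == pytest.approx(target, rel=0.1)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)


class TestLogisticFit:
    def test_binary_predictor_matches_cross_product_or(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=400)
        y = rng.binomial(1, np.where(x == 1, 0.6, 0.3))
        fit = logistic_fit(y, x)
        t = table_from_counts(int(x[y == 1].sum()), int(y.sum()),
                              int(x[y == 0].sum()), int((1 - y).sum()))
        assert fit["odds_ratio"].iloc[0] == pytest.approx(odds_ratio(t).or_, abs=1e-6)

    def test_null_coefficient_small_at_large_n(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10_000)
        y = rng.integers(0, 2, size=10_000)
        fit = logistic_fit(y, x)
        assert abs(fit["coef"].iloc[0]) < 0.07

    def test_perfect_separation_raises(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        with pytest.raises(SeparationError):
            logistic_fit(y, x)

    def test_multivariate_design_supported(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 3))
        lp = 0.8 * X[:, 0] - 0.5 * X[:, 2]
        y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
        fit = logistic_fit(y, X, names=["a", "b", "c"])
        assert fit.loc["a", "coef"] > 0.4
        assert fit.loc["c", "coef"] < -0.2
        assert fit.loc["a", "ci_low"] < fit.loc["a", "odds_ratio"] < fit.loc["a", "ci_high"]


def _exact_spearman_p(x, y):
    from scipy.stats import rankdata
    rho_obs, _ = __import__("scipy.stats", fromlist=["spearmanr"]).spearmanr(x, y)
    rx, ry = rankdata(x), rankdata(y)
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_increase_is_one(self):
        x = np.array([1.0, 2, 5, 9])
        assert spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_example_minus_half(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p = spearman(x, y)
            assert p == pytest.approx(_exact_spearman_p(x, y), abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestTopicClinicalScan:
    def test_bonferroni_over_topics_arithmetic(self):
        rng = np.random.default_rng(5)
        omega = pd.DataFrame(rng.dirichlet(np.ones(4), size=60),
                             columns=[f"topic_{k}" for k in range(1, 5)],
                             index=[f"S{i}" for i in range(60)])
        clin = pd.DataFrame({
            "fever_status": rng.integers(0, 2, 60),
            "labor_hours": rng.gamma(2, 10, 60),
        }, index=omega.index)
        scan = topic_clinical_scan(omega, clin)
        assert (scan["m"] == 4).all()
        finite = scan.dropna(subset=["p_raw"])
        np.testing.assert_allclose(
            finite["p_adjusted"], np.minimum(1.0, 4 * finite["p_raw"]))

    def test_planted_pathogen_topic_fever_association(self):
        """In a cohort where the pathogen-topic weight drives fever, the
        scan surfaces that topic with OR > 1 and adjusted significance at
        n=300."""
        effects = {"pathogen_topic": float(np.log(9.77))}
        c = generate_cohort(GeneratorParams(n_samples=300, seed=77,
                                            clinical_effects=effects,
                                            library_size_logmean=8.0))
        fit = fit_gom(c.cm, 4, seed=0)
        scan = topic_clinical_scan(fit, c.clinical[["fever_status"]])
        from vagitopics import match_topics
        perm, _ = match_topics(fit.theta.to_numpy(), c.theta_true.to_numpy())
        pathogen_est = fit.omega.columns[perm[c.pathogen_topic]]
        row = scan[(scan["variable"] == "fever_status") & (scan["topic"] == pathogen_est)]
        assert row["estimate"].iloc[0] > 1.0
        assert row["p_adjusted"].iloc[0] < 0.05

    def test_null_scan_false_positive_rate(self):
        """Independent clinical variable: adjusted rejections stay near the
        Bonferroni-controlled level across replicates."""
        rng = np.random.default_rng(6)
        hits = 0
        reps = 60
        for _ in range(reps):
            omega = pd.DataFrame(rng.dirichlet(np.ones(4), size=50),
                                 columns=list("abcd"),
                                 index=[f"S{i}" for i in range(50)])
            clin = pd.DataFrame({"x": rng.integers(0, 2, 50)}, index=omega.index)
            scan = topic_clinical_scan(omega, clin, binary_vars=["x"],
                                       continuous_vars=[])
            hits += (scan["p_adjusted"].dropna() < 0.05).any()
        assert hits / reps < 0.15


class TestCrossRegion:
    def test_identical_tables_rho_one(self):
        rng = np.random.default_rng(7)
        cm = make_cm(rng.integers(0, 50, size=(8, 20)))
        out = cross_region_correlation(cm, cm)
        defined = out["rho"].dropna()
        assert len(defined) > 0
        np.testing.assert_allclose(defined, 1.0)

    def test_monotone_transform_rho_one(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 60, size=(6, 15))
        cmA = make_cm(counts)
        cmB = make_cm(counts ** 2)
        out = cross_region_correlation(cmA, cmB)
        np.testing.assert_allclose(out["rho"].dropna(), 1.0)

    def test_few_qualifying_samples_reported_na(self):
        counts = np.zeros((2, 10), dtype=int)
        counts[0, :3] = 5   # only 3 shared nonzero samples
        counts[1, :] = 5
        cm = make_cm(counts)
        out = cross_region_correlation(cm, cm, min_samples=5)
        assert np.isnan(out.loc["OTU0", "rho"])

    def test_paired_multinomials_correlate_for_common_taxa(self):
        """Two multinomial draws per sample from one expected profile: taxa
        above ~1% expected abundance correlate strongly across regions."""
        rng = np.random.default_rng(9)
        profile = rng.dirichlet(np.ones(30))
        common = profile > 0.01
        n = 60
        depth = 5000
        mix = rng.dirichlet(profile * 80, size=n)   # per-sample composition
        A = np.array([rng.multinomial(depth, m) for m in mix]).T
        B = np.array([rng.multinomial(depth, m) for m in mix]).T
        out = cross_region_correlation(make_cm(A), make_cm(B))
        rhos = out.loc[[f"OTU{i}" for i in np.where(common)[0]], "rho"].dropna()
        assert rhos.median() > 0.5

    def test_disjoint_samples_rejected(self):
        rng = np.random.default_rng(10)
        cmA = make_cm(rng.integers(0, 9, size=(3, 4)))
        cmB = make_cm(rng.integers(0, 9, size=(3, 4)))
        cmB.counts.columns = pd.Index(["X0", "X1", "X2", "X3"])
        cmB.metadata.index = cmB.counts.columns
        with pytest.raises(ValueError):
            cross_region_correlation(cmA, cmB)
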