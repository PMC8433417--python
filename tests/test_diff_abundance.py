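"""NB Wald differential abundance: size factors, inference, concordance."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vagitopics import (nb_wald_test, region_concordance, size_factors,
                        volcano_classify)
from vagitopics.count_matrix import CountMatrix

from conftest import make_cm


def _nb_counts(rng, mu, alpha, size):
    """NB draws via gamma-Poisson mixture."""
    lam = rng.gamma(1.0 / alpha, mu * alpha, size=size)
    return rng.poisson(lam)


def _sim_cm(rng, m=20, n=60, outcome=None, lfc=None, alpha=0.3, base=40.0):
    mu = rng.lognormal(np.log(base), 0.7, size=m)
    depth = rng.lognormal(0, 0.3, size=n)
    lam = np.outer(mu, depth)
    if outcome is not None and lfc is not None:
        lam = lam * np.exp(np.outer(lfc, outcome))
    Y = _nb_counts(rng, lam, alpha, lam.shape)
    return make_cm(Y)


class TestSizeFactors:
    def test_hand_computed_two_sample_case(self):
        cm = make_cm(np.array([[2, 4], [4, 8]]))
        sf = size_factors(cm)
        np.testing.assert_allclose(sf.to_numpy(), [2 ** -0.5, 2 ** 0.5], rtol=1e-12)

    def test_identical_columns_all_one(self):
        cm = make_cm(np.tile([[7], [3], [12]], (1, 4)))
        np.testing.assert_allclose(size_factors(cm).to_numpy(), 1.0)

    def test_doubling_a_column_doubles_its_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 50, size=(10, 4))
        doubled = base.copy()
        doubled[:, 2] *= 2
        f_base = size_factors(make_cm(base))
        f_doub = size_factors(make_cm(doubled))
        ratio = f_doub.to_numpy() / f_base.to_numpy()
        assert ratio[2] / ratio[0] == pytest.approx(2.0, rel=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        sf = size_factors(make_cm(rng.integers(1, 100, size=(15, 8))))
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_fallback_warns_without_all_positive_taxon(self):
        counts = np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        with pytest.warns(UserWarning):
            sf = size_factors(make_cm(counts))
        assert (sf > 0).all()


class TestNBWald:
    def test_matches_statsmodels_glm_oracle(self):
        """Same likelihood, independent optimizer: coefficients and SEs of
        the batched IRLS agree with statsmodels GLM per taxon."""
        rng = np.random.default_rng(2)
        outcome = np.repeat([0, 1], 25)
        cm = _sim_cm(rng, m=6, n=50, outcome=outcome, lfc=rng.normal(0, 0.5, 6))
        res = nb_wald_test(cm, outcome)
        sf = size_factors(cm).to_numpy()
        X = sm.add_constant(outcome.astype(float))
        for i in range(6):
            y = cm.counts.iloc[i].to_numpy()
            q = y / sf
            a = max((q.var(ddof=1) - q.mean()) / q.mean() ** 2, 1e-8)
            glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=a),
                         offset=np.log(sf)).fit()
            mine = res.table.iloc[i]
            assert mine["log2fc"] * np.log(2) == pytest.approx(glm.params[1], abs=1e-5)
            assert mine["se"] == pytest.approx(glm.bse[1], abs=1e-5)

    def test_planted_fourfold_change_recovered(self):
        """Taxa planted at 4x abundance in cases: log2FC near 2 and
        Bonferroni-significant in nearly all replicates."""
        hits, reps = 0, 10
        for seed in range(reps):
            rng = np.random.default_rng(50 + seed)
            outcome = rng.permutation(np.repeat([0, 1], 50))
            lfc = np.zeros(50)
            lfc[:5] = np.log(4.0)
            cm = _sim_cm(rng, m=50, n=100, outcome=outcome, lfc=lfc, alpha=0.2)
            res = nb_wald_test(cm, outcome)
            planted = res.table.iloc[:5]
            if ((planted["log2fc"] - 2.0).abs() < 0.5).all() and \
                    (planted["p_bonferroni"] < 0.05).all():
                hits += 1
        assert hits >= 0.9 * reps

    def test_permuted_outcome_log2fc_centered_at_zero(self):
        rng = np.random.default_rng(3)
        outcome = rng.permutation(np.repeat([0, 1], 30))
        cm = _sim_cm(rng, m=40, n=60)
        res = nb_wald_test(cm, outcome)
        assert abs(res.table["log2fc"].mean()) < 0.25

    def test_high_depth_estimate_approaches_log_ratio_of_means(self):
        outcome = np.repeat([0, 1], 4)
        row0 = np.where(outcome == 1, 400_000, 100_000)
        counts = np.vstack([row0, np.full(8, 1_000_000)])
        res = nb_wald_test(make_cm(counts), outcome)
        # size factors absorb part of the shift; compare to the size-factor
        # normalized group means the model actually sees
        q = counts[0] / res.size_factors.to_numpy()
        expected = np.log2(q[outcome == 1].mean() / q[outcome == 0].mean())
        assert res.table["log2fc"].iloc[0] == pytest.approx(expected, abs=0.05)

    def test_covariate_adjustment_absorbs_site_effect(self):
        rng = np.random.default_rng(4)
        site = np.tile([0, 1], 40)
        outcome = np.repeat([0, 1], 40)
        lfc_site = np.zeros(30)
        lfc_site[:10] = 1.0
        mu = rng.lognormal(3.5, 0.5, 30)
        lam = np.outer(mu, np.ones(80)) * np.exp(np.outer(lfc_site, site))
        cm = make_cm(_nb_counts(rng, lam, 0.2, lam.shape))
        adj = nb_wald_test(cm, outcome, covariates={"site": site})
        unadj = nb_wald_test(cm, outcome)
        assert "site" in adj.covariates and unadj.covariates == []
        assert adj.table["p_raw"].notna().sum() > 25

    def test_constant_outcome_rejected(self):
        cm = make_cm(np.ones((3, 6), dtype=int))
        with pytest.raises(ValueError):
            nb_wald_test(cm, np.zeros(6))


class TestVolcano:
    def test_bonferroni_arithmetic_classes(self):
        table = pd.DataFrame({
            "p_raw": [0.01, 1e-5, 0.5],
            "p_bonferroni": [1.0, 1e-3, 1.0],
            "log2fc": [1, 2, 0.1],
        }, index=["a", "b", "c"])
        from vagitopics.diff_abundance import DifferentialAbundanceResult
        res = DifferentialAbundanceResult(table=table, m=100)
        cls = volcano_classify(res)
        assert cls["a"] == "nominal"
        assert cls["b"] == "bonferroni"
        assert cls["c"] == "ns"

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(5)
        cm = _sim_cm(rng, m=30, n=40)
        res = nb_wald_test(cm, rng.permutation(np.repeat([0, 1], 20)))
        ok = res.table.dropna(subset=["p_raw"])
        assert (ok["p_bonferroni"] >= ok["p_raw"] - 1e-15).all()
        cls = volcano_classify(res)
        assert (cls == "bonferroni").sum() <= (cls != "ns").sum()


class TestConcordance:
    def test_identical_results_fully_concordant(self):
        rng = np.random.default_rng(6)
        outcome = np.repeat([0, 1], 30)
        lfc = np.zeros(20)
        lfc[:4] = np.log(5)
        cm = _sim_cm(rng, m=20, n=60, outcome=outcome, lfc=lfc)
        res = nb_wald_test(cm, outcome)
        table = region_concordance(res, res)
        assert len(table) > 0
        assert set(table["status"]) <= {"both_up", "both_down"}

    def test_flipped_signs_all_discordant(self):
        rng = np.random.default_rng(7)
        outcome = np.repeat([0, 1], 30)
        lfc = np.concatenate([np.full(4, np.log(5)), np.zeros(16)])
        cm = _sim_cm(rng, m=20, n=60, outcome=outcome, lfc=lfc)
        res = nb_wald_test(cm, outcome)
        import copy
        flipped = copy.deepcopy(res)
        flipped.table["log2fc"] *= -1
        table = region_concordance(res, flipped)
        both = table[table["status"] != "single_region"]
        assert len(both) > 0
        assert (both["status"] == "discordant").all()

    def test_paired_regions_from_shared_truth_concord(self):
        """Two 'regions' resampled from the same composition agree in
        direction for strongly planted taxa."""
        rng = np.random.default_rng(8)
        outcome = np.repeat([0, 1], 40)
        lfc = np.zeros(25)
        lfc[:5] = np.log(6)
        mu = rng.lognormal(3.5, 0.5, 25)
        lam = np.outer(mu, np.ones(80)) * np.exp(np.outer(lfc, outcome))
        cmA = make_cm(_nb_counts(rng, lam, 0.15, lam.shape))
        cmB = make_cm(_nb_counts(rng, lam, 0.15, lam.shape))
        resA = nb_wald_test(cmA, outcome)
        resB = nb_wald_test(cmB, outcome)
        table = region_concordance(resA, resB)
        planted = table.loc[table.index.intersection([f"OTU{i}" for i in range(5)])]
        frac = (planted["status"].isin(["both_up", "both_down"])).mean()
        assert frac > 0.8
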