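"""Negative-binomial Wald differential abundance of taxa vs a binary outcome.

A deliberately lean NB framework: median-of-ratios size factors, per-taxon
method-of-moments dispersion (floored), a batched IRLS fit of the NB
log-linear model with size-factor offsets, Wald z tests, and Bonferroni
adjustment over taxa.  No empirical-Bayes dispersion shrinkage, independent
filtering or outlier replacement — significance and direction are the
quantities of interest here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .count_matrix import CountMatrix

_LN2 = np.log(2.0)


def size_factors(cm) -> pd.Series:
    """Median-of-ratios per-sample normalization factors (geometric mean 1).

    For each sample, the median over all-positive taxa of the ratio of its
    count to that taxon's geometric mean across samples.  When no taxon is
    positive in every sample, falls back to ratios over each taxon's
    positive part, with a warning.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else pd.DataFrame(cm)
    X = counts.to_numpy(dtype=float)
    all_pos = (X > 0).all(axis=1)
    if all_pos.any():
        sub = X[all_pos]
        logs = np.log(sub)
        ratios = logs - logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn("no taxon positive in all samples; using positive-part "
                      "geometric means for size factors")
        with np.errstate(divide="ignore"):
            logs = np.where(X > 0, np.log(X), np.nan)
        gm = np.nanmean(logs, axis=1, keepdims=True)
        ratios = logs - gm
        sf = np.exp(np.nanmedian(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass
class DifferentialAbundanceResult:
    """Per-taxon NB Wald results with the model design recorded."""

    table: pd.DataFrame = field(repr=False)     # baseMean, log2fc, se, wald, p_raw, p_bonferroni
    covariates: list = field(default_factory=list)
    size_factors: pd.Series = field(default=None, repr=False)
    m: int = 0                                  # Bonferroni family size

    def summary(self, n: int = 10) -> str:
        top = self.table.sort_values("p_raw").head(n)
        lines = [
            "NB Wald differential abundance".center(70),
            "=" * 70,
            f"taxa tested: {self.m}   covariates: {self.covariates or ['(none)']}",
            "-" * 70,
            top.to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)


class NegativeBinomialDA:
    """NB log-linear differential abundance model for a CountMatrix.

    Design: intercept + outcome indicator (+ CMT indicators and/or a site
    indicator when supplied).  ``fit()`` returns a
    :class:`DifferentialAbundanceResult`.
    """

    def __init__(self, cm: CountMatrix, outcome, covariates: dict | None = None,
                 dispersion_floor: float = 1e-8):
        self.cm = cm
        y = np.asarray(pd.Series(outcome).reindex(cm.sample_ids)
                       if isinstance(outcome, pd.Series) else outcome, dtype=float)
        if pd.unique(y[np.isfinite(y)]).size < 2:
            raise ValueError("outcome is constant")
        self.outcome = y
        self.covariates = covariates or {}
        self.dispersion_floor = dispersion_floor
        self._design()

    def _design(self):
        n = self.cm.n_samples
        cols = [np.ones(n), self.outcome]
        names = ["intercept", "outcome"]
        if "cmt" in self.covariates:
            labels = np.asarray(self.covariates["cmt"])
            levels = np.sort(pd.unique(labels))
            for lev in levels[1:]:           # k-1 indicators, first level baseline
                cols.append((labels == lev).astype(float))
                names.append(f"cmt_{lev}")
        if "site" in self.covariates:
            cols.append(np.asarray(self.covariates["site"], dtype=float))
            names.append("site")
        self.X = np.column_stack(cols)
        self.coef_names = names
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("rank-deficient design matrix")

    def fit(self, max_iter: int = 50, tol: float = 1e-8) -> DifferentialAbundanceResult:
        cm = self.cm
        sf = size_factors(cm)
        Y = cm.counts.to_numpy(dtype=float)            # taxa x samples
        s = sf.to_numpy()
        offset = np.log(s)
        X = self.X
        n, p = X.shape
        m_taxa = Y.shape[0]

        # method-of-moments dispersion on normalized counts
        Q = Y / s
        mu_bar = Q.mean(axis=1)
        var = Q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (var - mu_bar) / mu_bar ** 2
        alpha = np.where(np.isfinite(alpha), alpha, self.dispersion_floor)
        alpha = np.maximum(alpha, self.dispersion_floor)

        # batched IRLS, one NB GLM per taxon, shared design
        beta = np.zeros((m_taxa, p))
        beta[:, 0] = np.log(np.clip(mu_bar, 1e-8, None))
        converged = np.zeros(m_taxa, dtype=bool)
        a = alpha[:, None]
        for _ in range(max_iter):
            eta = beta @ X.T + offset                   # m x n
            eta = np.clip(eta, -30, 30)
            mu = np.exp(eta)
            W = mu / (1.0 + a * mu)
            z = eta - offset + (Y - mu) / mu
            XtWX = np.einsum("ni,mn,nj->mij", X, W, X)
            XtWz = np.einsum("ni,mn,mn->mi", X, W, z)
            try:
                new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
            except np.linalg.LinAlgError:
                new = np.array([np.linalg.lstsq(XtWX[i], XtWz[i], rcond=None)[0]
                                for i in range(m_taxa)])
            step = np.abs(new - beta).max(axis=1)
            beta = new
            converged |= step < tol
            if converged.all():
                break

        eta = np.clip(beta @ X.T + offset, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + a * mu)
        XtWX = np.einsum("ni,mn,nj->mij", X, W, X)
        se = np.full(m_taxa, np.nan)
        ok = np.isfinite(beta).all(axis=1)
        for i in range(m_taxa):
            if not ok[i]:
                continue
            try:
                cov = np.linalg.inv(XtWX[i])
                se[i] = np.sqrt(cov[1, 1])
            except np.linalg.LinAlgError:
                ok[i] = False
        ok &= np.isfinite(se) & (se > 0) & (se < 1e3)

        coef = beta[:, 1]
        wald = np.where(ok, coef / se, np.nan)
        p_raw = np.where(ok, 2 * norm.sf(np.abs(wald)), np.nan)
        m_tested = int(ok.sum())
        p_bonf = np.minimum(1.0, m_tested * p_raw)

        log2fc = coef / _LN2
        # Haldane-smoothed fold change for taxa with an all-zero group
        y1 = self.outcome == 1
        zero_group = (Y[:, y1].sum(axis=1) == 0) | (Y[:, ~y1].sum(axis=1) == 0)
        if zero_group.any():
            m1 = (Q[:, y1] + 0.5).mean(axis=1)
            m0 = (Q[:, ~y1] + 0.5).mean(axis=1)
            log2fc = np.where(zero_group, np.log2(m1 / m0), log2fc)

        table = pd.DataFrame({
            "lineage": cm.lineages.to_numpy(),
            "baseMean": Q.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "converged": ok,
        }, index=cm.taxa_ids)
        return DifferentialAbundanceResult(
            table=table, covariates=self.coef_names[2:],
            size_factors=sf, m=m_tested)


def nb_wald_test(cm: CountMatrix, outcome, covariates: dict | None = None,
                 **fit_kwargs) -> DifferentialAbundanceResult:
    """Fit the NB Wald model; see :class:`NegativeBinomialDA`."""
    return NegativeBinomialDA(cm, outcome, covariates=covariates).fit(**fit_kwargs)


def volcano_classify(res: DifferentialAbundanceResult,
                     p_thresh: float = 0.05) -> pd.Series:
    """Volcano classes: 'bonferroni' if adjusted p < threshold, 'nominal' if
    only the raw p is, otherwise 'ns' (non-significant or untested)."""
    t = res.table
    cls = pd.Series("ns", index=t.index, name="class")
    nominal = t["p_raw"] < p_thresh
    bonf = t["p_bonferroni"] < p_thresh
    cls[nominal.fillna(False)] = "nominal"
    cls[bonf.fillna(False)] = "bonferroni"
    return cls


def region_concordance(resA: DifferentialAbundanceResult,
                       resB: DifferentialAbundanceResult,
                       p_thresh: float = 0.05) -> pd.DataFrame:
    """Direction agreement of taxa significant in either of two regions.

    For every taxon with raw p < threshold in region A or B, classify as
    both_up / both_down / discordant (significant in both, opposite signs)
    or single_region.
    """
    shared = resA.table.index.intersection(resB.table.index)
    if len(shared) == 0:
        warnings.warn("no shared taxa between regions")
        return pd.DataFrame(columns=["log2fc_A", "log2fc_B", "status"])
    A = resA.table.loc[shared]
    B = resB.table.loc[shared]
    sigA = A["p_raw"] < p_thresh
    sigB = B["p_raw"] < p_thresh
    either = sigA.fillna(False) | sigB.fillna(False)
    rows = []
    for taxon in shared[either]:
        fa, fb = A.loc[taxon, "log2fc"], B.loc[taxon, "log2fc"]
        in_both = bool(sigA[taxon]) and bool(sigB[taxon])
        if not in_both:
            status = "single_region"
        elif fa > 0 and fb > 0:
            status = "both_up"
        elif fa < 0 and fb < 0:
            status = "both_down"
        else:
            status = "discordant"
        rows.append((taxon, fa, fb, status))
    return pd.DataFrame(rows, columns=["taxon", "log2fc_A", "log2fc_B", "status"]
                        ).set_index("taxon")
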