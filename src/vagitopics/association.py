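"""Epidemiologic association statistics.

2x2 odds ratios with Woolf confidence intervals, logistic regression,
Spearman correlation with an exact small-sample permutation p, the
topic-by-clinical Bonferroni scan, and the per-taxon cross-region
correlation used for hypervariable-region concordance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata, spearmanr

from .count_matrix import CountMatrix
from .diversity import mann_whitney  # single source of truth, re-exported
from .exceptions import SeparationError

__all__ = [
    "TwoByTwo", "odds_ratio", "OddsRatioResult", "logistic_fit",
    "spearman", "topic_clinical_scan", "cross_region_correlation",
    "mann_whitney", "table_from_counts",
]


@dataclass(frozen=True)
class TwoByTwo:
    """a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def table_from_counts(exposed_cases, cases_n, exposed_controls, controls_n) -> TwoByTwo:
    """Build a TwoByTwo from '24 of 50 cases exposed, 11 of 49 controls'."""
    return TwoByTwo(exposed_cases, cases_n - exposed_cases,
                    exposed_controls, controls_n - exposed_controls)


@dataclass
class OddsRatioResult:
    or_: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    corrected: bool

    def round2(self) -> float:
        return round(self.or_, 2)


def odds_ratio(t: TwoByTwo, correction: str = "none") -> OddsRatioResult:
    """Cross-product odds ratio (a*d)/(b*c) with a Woolf logit 95% CI.

    ``correction="haldane"`` adds 0.5 to every cell when any cell is zero.
    Without correction a zero in b or c yields an infinite OR (flagged by
    ``or_ = inf``); a zero in a or d yields 0.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if correction == "haldane" and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    elif correction not in ("none", "haldane"):
        raise ValueError("correction must be 'none' or 'haldane'")
    if b * c == 0:
        return OddsRatioResult(np.inf, np.nan, np.nan, np.inf, np.nan, corrected)
    orv = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        return OddsRatioResult(orv, np.nan, np.nan,
                               np.log(orv) if orv > 0 else -np.inf, np.nan, corrected)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orv) - 1.96 * se), np.exp(np.log(orv) + 1.96 * se)
    return OddsRatioResult(float(orv), float(lo), float(hi),
                           float(np.log(orv)), float(se), corrected)


def logistic_fit(y, X, names=None):
    """Maximum-likelihood logistic regression (IRLS via statsmodels Logit).

    Returns a DataFrame with coefficients, exponentiated odds ratios, Wald
    95% CIs and p-values (constant excluded).  Exact separation raises
    :class:`SeparationError` naming the offending predictor.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if pd.unique(y).size < 2:
        raise ValueError("outcome is constant")
    names = list(names) if names is not None else [f"x{i + 1}" for i in range(X.shape[1])]
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
        raise SeparationError(f"perfect separation in predictors {names}: {err}") from err
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params[1:]).max() > 15:
        raise SeparationError(f"logistic fit did not converge; predictors {names} "
                              "may separate the outcome")
    coef = fit.params[1:]
    se = fit.bse[1:]
    ci = fit.conf_int()[1:]
    return pd.DataFrame({
        "coef": coef,
        "se": se,
        "odds_ratio": np.exp(coef),
        "ci_low": np.exp(ci[:, 0]),
        "ci_high": np.exp(ci[:, 1]),
        "p": fit.pvalues[1:],
    }, index=names)


def _exact_spearman_p(x, y, rho_obs) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum(axis=1))
    rhos = num / den
    return float((np.abs(rhos) >= np.abs(rho_obs) - 1e-12).mean())


def spearman(x, y, exact_below: int = 10):
    """Spearman rank correlation with a two-sided p-value.

    For n below *exact_below* the p comes from exhaustive permutation of
    one vector; otherwise from the t approximation.  Constant input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p_t = spearmanr(x, y)
    if x.size < exact_below:
        return float(rho), _exact_spearman_p(x, y, rho)
    return float(rho), float(p_t)


def topic_clinical_scan(omega, clinical: pd.DataFrame,
                        binary_vars=None, continuous_vars=None) -> pd.DataFrame:
    """Per-topic association scan against clinical variables.

    Binary outcomes are regressed (logistic) on the topic weight — the OR
    is per unit weight; continuous variables get a Spearman correlation
    with the weight.  Bonferroni m = number of topics per variable family.
    Missing values are dropped pairwise.  Separated or degenerate fits are
    recorded with NaN estimates rather than aborting the scan.
    """
    omega = omega.omega if hasattr(omega, "omega") else omega
    omega = omega.loc[clinical.index]
    K = omega.shape[1]
    if binary_vars is None:
        binary_vars = [c for c in clinical.columns
                       if clinical[c].dropna().isin([0, 1]).all()]
    if continuous_vars is None:
        continuous_vars = [c for c in clinical.columns if c not in binary_vars]
    rows = []
    for var in binary_vars:
        mask = clinical[var].notna()
        for topic in omega.columns:
            w = omega.loc[mask, topic].to_numpy()
            yv = clinical.loc[mask, var].to_numpy(dtype=float)
            try:
                fit = logistic_fit(yv, w, names=[topic])
                est, lo, hi, p = (fit.loc[topic, c] for c in
                                  ("odds_ratio", "ci_low", "ci_high", "p"))
            except (SeparationError, ValueError):
                est = lo = hi = p = np.nan
            rows.append((var, topic, "logistic_or", est, lo, hi, p))
    for var in continuous_vars:
        mask = clinical[var].notna()
        for topic in omega.columns:
            w = omega.loc[mask, topic].to_numpy()
            v = clinical.loc[mask, var].to_numpy(dtype=float)
            try:
                rho, p = spearman(w, v)
            except ValueError:
                rho, p = np.nan, np.nan
            rows.append((var, topic, "spearman_rho", rho, np.nan, np.nan, p))
    scan = pd.DataFrame(rows, columns=["variable", "topic", "statistic",
                                       "estimate", "ci_low", "ci_high", "p_raw"])
    scan["m"] = K
    scan["p_adjusted"] = np.minimum(1.0, K * scan["p_raw"])
    return scan


def cross_region_correlation(cmA: CountMatrix, cmB: CountMatrix,
                             min_samples: int = 5) -> pd.DataFrame:
    """Per-taxon Spearman correlation of abundances across two regions.

    For each taxon present in both tables, the correlation runs over the
    shared samples where that taxon is nonzero in both regions; taxa with
    fewer than *min_samples* qualifying samples report NaN.
    """
    samples = cmA.sample_ids.intersection(cmB.sample_ids)
    if len(samples) == 0:
        raise ValueError("no shared samples between regions")
    taxa = cmA.taxa_ids.intersection(cmB.taxa_ids)
    rows = []
    for taxon in taxa:
        xa = cmA.counts.loc[taxon, samples].to_numpy(dtype=float)
        xb = cmB.counts.loc[taxon, samples].to_numpy(dtype=float)
        mask = (xa > 0) & (xb > 0)
        n = int(mask.sum())
        if n < min_samples:
            rows.append((taxon, np.nan, np.nan, n))
            continue
        try:
            rho, p = spearman(xa[mask], xb[mask])
        except ValueError:
            rho, p = np.nan, np.nan
        rows.append((taxon, rho, p, n))
    out = pd.DataFrame(rows, columns=["taxon", "rho", "p", "n_samples"]).set_index("taxon")
    return out.sort_values("rho", ascending=False)
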