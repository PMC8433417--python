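"""Grades-of-membership (LDA) topic models for taxon count tables.

Each sample is modeled as a mixture over K latent community "topics":
``p(s_i) = sum_j p(s_i | z_i = j) p(z_i = j)``, with ``theta`` the K x V
matrix of topic-specific taxon distributions (rows on the simplex) and
``omega`` the N x K per-sample topic weights (rows on the simplex).

Two estimation backends are provided:

``em`` (default)
    MAP expectation-maximization with symmetric Dirichlet priors entering
    as pseudocounts (the estimator family behind grades-of-membership
    fits of count tables).  Deterministic given the seed, with a
    monotonically non-decreasing log-posterior trace.
``gibbs``
    Collapsed Gibbs sampling over token-level topic assignments with
    posterior-mean ``theta``/``omega`` from post-burn-in averaged counts.
    Practical at modest sequencing depth.

Topic-number selection is by the discrete-second-difference elbow of a
decreasing criterion (k-means inertia or negative model log-likelihood)
and, independently, by the elbow of NMF reconstruction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF

from .count_matrix import CountMatrix, log10_normalize, relative_abundance

_EPS = 1e-300


def _to_doc_term(data):
    """Coerce input to (X samples x taxa float array, sample ids, taxon ids)."""
    if isinstance(data, CountMatrix):
        return data.counts.T.to_numpy(dtype=float), list(data.sample_ids), list(data.taxa_ids)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index), list(data.columns)
    X = np.asarray(data, dtype=float)
    return X, [f"S{i}" for i in range(X.shape[0])], [f"t{j}" for j in range(X.shape[1])]


class GradesOfMembership:
    """Mixed-membership multinomial model of a taxon count table.

    Parameters
    ----------
    data : CountMatrix, DataFrame or array
        A CountMatrix (taxa x samples) or a samples x taxa count table.
    n_topics : int
        Number of latent topics K (>= 1).
    prior_omega, prior_theta : float
        Symmetric Dirichlet pseudocounts for sample weights and topic
        distributions; ``prior_omega`` defaults to 1/K.
    backend : {"em", "gibbs"}
    """

    def __init__(self, data, n_topics: int, prior_omega: float | None = None,
                 prior_theta: float = 0.1, backend: str = "em"):
        X, samples, taxa = _to_doc_term(data)
        if X.size == 0:
            raise ValueError("empty count matrix")
        if (X < 0).any():
            raise ValueError("negative counts")
        if n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if n_topics > X.shape[1]:
            raise ValueError(f"n_topics={n_topics} exceeds n_taxa={X.shape[1]}")
        if backend not in ("em", "gibbs"):
            raise ValueError("backend must be 'em' or 'gibbs'")
        self.X = X
        self.sample_ids = samples
        self.taxa_ids = taxa
        self.n_topics = int(n_topics)
        self.prior_omega = 1.0 / n_topics if prior_omega is None else float(prior_omega)
        self.prior_theta = float(prior_theta)
        self.backend = backend

    # -- EM backend ----------------------------------------------------
    def _fit_em_once(self, rng, max_iter, tol):
        X, K = self.X, self.n_topics
        N, V = X.shape
        omega = rng.dirichlet(np.ones(K), size=N)
        theta = rng.dirichlet(np.ones(V), size=K)
        trace = []
        prev = -np.inf
        converged = False
        for _ in range(max_iter):
            P = np.clip(omega @ theta, _EPS, None)
            obj = float((X * np.log(P)).sum()
                        + self.prior_omega * np.log(np.clip(omega, _EPS, None)).sum()
                        + self.prior_theta * np.log(np.clip(theta, _EPS, None)).sum())
            trace.append(obj)
            A = X / P
            omega = omega * (A @ theta.T) + self.prior_omega
            omega /= omega.sum(axis=1, keepdims=True)
            theta = theta * (omega.T @ A) + self.prior_theta
            theta /= theta.sum(axis=1, keepdims=True)
            if obj - prev < tol * (abs(prev) + 1.0) and len(trace) > 2:
                converged = True
                break
            prev = obj
        P = np.clip(omega @ theta, _EPS, None)
        loglik = float((X * np.log(P)).sum())
        return omega, theta, np.asarray(trace), loglik, converged

    # -- collapsed Gibbs backend --------------------------------------
    def _fit_gibbs_once(self, rng, n_sweeps, burn_in, thin):
        X, K = self.X.astype(np.int64), self.n_topics
        N, V = X.shape
        docs_nz, words_nz = np.nonzero(X)
        reps = X[docs_nz, words_nz]
        docs = np.repeat(docs_nz, reps)
        words = np.repeat(words_nz, reps)
        T = docs.size
        z = rng.integers(0, K, size=T)
        ndk = np.zeros((N, K), dtype=np.int64)
        nkv = np.zeros((K, V), dtype=np.int64)
        nk = np.zeros(K, dtype=np.int64)
        np.add.at(ndk, (docs, z), 1)
        np.add.at(nkv, (z, words), 1)
        np.add.at(nk, z, 1)
        a, b = self.prior_omega, self.prior_theta
        acc_ndk = np.zeros((N, K))
        acc_nkv = np.zeros((K, V))
        n_acc = 0
        for sweep in range(n_sweeps):
            us = rng.random(T)
            for t in range(T):
                d, w, kz = docs[t], words[t], z[t]
                ndk[d, kz] -= 1
                nkv[kz, w] -= 1
                nk[kz] -= 1
                p = (ndk[d] + a) * (nkv[:, w] + b) / (nk + V * b)
                cum = np.cumsum(p)
                kz = int(np.searchsorted(cum, us[t] * cum[-1]))
                z[t] = kz
                ndk[d, kz] += 1
                nkv[kz, w] += 1
                nk[kz] += 1
            if sweep >= burn_in and (sweep - burn_in) % thin == 0:
                acc_ndk += ndk
                acc_nkv += nkv
                n_acc += 1
        omega = acc_ndk / n_acc + a
        omega /= omega.sum(axis=1, keepdims=True)
        theta = acc_nkv / n_acc + b
        theta /= theta.sum(axis=1, keepdims=True)
        P = np.clip(omega @ theta, _EPS, None)
        loglik = float((self.X * np.log(P)).sum())
        obj = float(loglik
                    + a * np.log(np.clip(omega, _EPS, None)).sum()
                    + b * np.log(np.clip(theta, _EPS, None)).sum())
        return omega, theta, np.asarray([obj]), loglik, True

    def fit(self, seed: int = 0, n_restarts: int = 3, max_iter: int = 500,
            tol: float = 1e-7, n_sweeps: int = 2000, burn_in: int = 500,
            thin: int = 10) -> "GradesOfMembershipResults":
        """Fit the model, keeping the best of *n_restarts* by log posterior."""
        root = np.random.SeedSequence(seed)
        best = None
        for child in root.spawn(max(1, n_restarts)):
            rng = np.random.default_rng(child)
            if self.backend == "em":
                out = self._fit_em_once(rng, max_iter, tol)
            else:
                out = self._fit_gibbs_once(rng, n_sweeps, burn_in, thin)
            if best is None or out[2][-1] > best[2][-1]:
                best = out
        omega, theta, trace, loglik, converged = best
        topic_names = [f"topic_{k + 1}" for k in range(self.n_topics)]
        return GradesOfMembershipResults(
            model=self,
            theta=pd.DataFrame(theta, index=topic_names, columns=self.taxa_ids),
            omega=pd.DataFrame(omega, index=self.sample_ids, columns=topic_names),
            loglik=loglik,
            loglik_trace=trace,
            seed=seed,
            n_restarts=n_restarts,
            converged=converged,
        )


@dataclass
class GradesOfMembershipResults:
    """Fitted theta/omega with diagnostics; rows of both are on the simplex."""

    model: GradesOfMembership = field(repr=False)
    theta: pd.DataFrame = field(repr=False)
    omega: pd.DataFrame = field(repr=False)
    loglik: float = 0.0
    loglik_trace: np.ndarray = field(default=None, repr=False)
    seed: int = 0
    n_restarts: int = 1
    converged: bool = True

    @property
    def n_topics(self) -> int:
        return self.theta.shape[0]

    def top_taxa(self, n: int = 8) -> dict:
        """Per topic, the n highest-weight taxa with their theta values."""
        return {t: self.theta.loc[t].nlargest(n) for t in self.theta.index}

    def zscore(self) -> pd.DataFrame:
        return topic_zscore(self.theta)

    def score(self, data, max_iter: int = 200) -> float:
        """Per-token held-out log-likelihood: theta fixed, omega folded in by EM."""
        Xn, _, _ = _to_doc_term(data)
        theta = self.theta.to_numpy()
        K = theta.shape[0]
        omega = np.full((Xn.shape[0], K), 1.0 / K)
        for _ in range(max_iter):
            P = np.clip(omega @ theta, _EPS, None)
            omega = omega * ((Xn / P) @ theta.T) + self.model.prior_omega
            omega /= omega.sum(axis=1, keepdims=True)
        P = np.clip(omega @ theta, _EPS, None)
        return float((Xn * np.log(P)).sum() / Xn.sum())

    def summary(self) -> str:
        lines = [
            "Grades-of-Membership model".center(62),
            "=" * 62,
            f"No. samples: {self.omega.shape[0]:>6}    backend: {self.model.backend}",
            f"No. taxa:    {self.theta.shape[1]:>6}    restarts: {self.n_restarts}",
            f"No. topics:  {self.n_topics:>6}    log-likelihood: {self.loglik:.1f}",
            f"converged:   {str(self.converged):>6}    seed: {self.seed}",
            "-" * 62,
            "mean sample weight per topic:",
        ]
        for t, w in self.omega.mean(axis=0).items():
            lines.append(f"  {t:<12} {w:.3f}")
        lines.append("-" * 62)
        lines.append("top taxa per topic (theta):")
        for t, top in self.top_taxa(5).items():
            taxa = ", ".join(f"{i} ({v:.2f})" for i, v in top.items())
            lines.append(f"  {t}: {taxa}")
        return "\n".join(lines)


def fit_gom(cm, K: int, prior_omega: float | None = None, prior_theta: float = 0.1,
            seed: int = 0, n_restarts: int = 3, max_iter: int = 500,
            tol: float = 1e-7, backend: str = "em",
            **gibbs_kwargs) -> GradesOfMembershipResults:
    """Convenience wrapper: build a :class:`GradesOfMembership` and fit it."""
    model = GradesOfMembership(cm, K, prior_omega=prior_omega,
                               prior_theta=prior_theta, backend=backend)
    return model.fit(seed=seed, n_restarts=n_restarts, max_iter=max_iter,
                     tol=tol, **gibbs_kwargs)


# ----------------------------------------------------------------------
# Label switching / topic matching
# ----------------------------------------------------------------------

def match_topics(theta_est, theta_ref):
    """Optimal one-to-one matching of estimated to reference topics.

    Solves the assignment problem maximizing summed Pearson row
    correlations (Hungarian algorithm).  Returns ``(perm, corrs)`` where
    ``perm[j]`` is the estimated-topic index matched to reference topic j
    and ``corrs[j]`` the corresponding correlation.
    """
    A = np.asarray(theta_est, dtype=float)
    B = np.asarray(theta_ref, dtype=float)
    if A.shape != B.shape:
        raise ValueError("theta matrices must have identical shape")
    K = A.shape[0]
    C = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            C[i, j] = np.corrcoef(A[i], B[j])[0, 1]
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=int)
    corrs = np.empty(K)
    for i, j in zip(rows, cols):
        perm[j] = i
        corrs[j] = C[i, j]
    return perm, corrs


# ----------------------------------------------------------------------
# Topic-number selection
# ----------------------------------------------------------------------

@dataclass
class KSelection:
    """Selected topic number with the criterion curve behind the choice."""

    k: int
    curve: pd.DataFrame          # columns: k, criterion, second_difference
    method: str
    warning: str | None = None


def elbow_select(values, ks) -> KSelection:
    """Second-difference elbow of a decreasing criterion curve.

    Selects ``argmax f(K-1) - 2 f(K) + f(K+1)`` over interior K; ties go
    to the smallest K.  A flat or non-monotone curve still returns the
    argmax but carries a warning.
    """
    f = np.asarray(values, dtype=float)
    ks = np.asarray(ks, dtype=int)
    if f.size != ks.size or f.size < 3:
        raise ValueError("need a curve over at least 3 K values")
    d2 = np.full(f.size, np.nan)
    d2[1:-1] = f[:-2] - 2 * f[1:-1] + f[2:]
    interior = d2[1:-1]
    best = int(np.nanargmax(interior)) + 1
    warning = None
    if np.nanmax(np.abs(interior)) < 1e-12:
        warning = "criterion curve is linear; elbow undefined, smallest K returned"
        best = 1
    elif np.any(np.diff(f) > 1e-12 * max(1.0, np.abs(f).max())):
        warning = "criterion curve is not monotonically decreasing"
    if warning:
        warnings.warn(warning)
    curve = pd.DataFrame({"k": ks, "criterion": f, "second_difference": d2})
    return KSelection(int(ks[best]), curve, method="elbow", warning=warning)


def select_k_elbow(cm, k_range=range(1, 9), seed: int = 0,
                   criterion: str = "loglik", **fit_kwargs) -> KSelection:
    """Choose K by the elbow of a decreasing fit criterion.

    ``criterion="loglik"`` (default) fits the GoM model at each K and uses
    the negative log-likelihood — for mixed-membership data this flattens
    sharply past the true K.  ``criterion="inertia"`` scores each K by
    k-means within-cluster inertia on log10-normalized abundances (cheap,
    but samples that are genuine topic mixtures blur any cluster elbow).
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if criterion == "inertia":
        X = log10_normalize(cm).T.to_numpy() if isinstance(cm, CountMatrix) \
            else np.log10(np.asarray(cm, dtype=float) + 1.0)
        f = [KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X).inertia_
             for k in ks]
    elif criterion == "loglik":
        fit_kwargs.setdefault("n_restarts", 2)
        f = [-fit_gom(cm, k, seed=seed, **fit_kwargs).loglik for k in ks]
    else:
        raise ValueError("criterion must be 'inertia' or 'loglik'")
    sel = elbow_select(f, ks)
    sel.method = f"elbow_{criterion}"
    return sel


def select_k_nmf(cm, k_range=range(1, 9), seed: int = 0,
                 max_iter: int = 400) -> KSelection:
    """Choose the NMF rank by the elbow of Frobenius reconstruction error.

    NMF (multiplicative updates) runs on library-size-normalized counts;
    the selected rank is the second-difference elbow of the error curve.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if isinstance(cm, CountMatrix):
        X = relative_abundance(cm).T.to_numpy()
    else:
        X = np.asarray(cm, dtype=float)
        totals = X.sum(axis=1, keepdims=True)
        if (totals == 0).all():
            raise ValueError("zero matrix")
        X = X / np.clip(totals, 1e-12, None)
    if not X.any():
        raise ValueError("zero matrix")
    errs = []
    for k in ks:
        nmf = NMF(n_components=k, init="nndsvda", solver="mu",
                  beta_loss="frobenius", max_iter=max_iter, tol=1e-7,
                  random_state=seed)
        nmf.fit(X)
        errs.append(float(nmf.reconstruction_err_))
    sel = elbow_select(errs, ks)
    sel.method = "nmf_elbow"
    return sel


def topic_zscore(theta) -> pd.DataFrame:
    """Row-wise z-score of theta-transpose: per taxon, standardize its
    weights across topics (sample sd, ddof=1); constant taxa map to zeros."""
    T = theta.T if isinstance(theta, pd.DataFrame) else pd.DataFrame(np.asarray(theta).T)
    if T.shape[1] < 2:
        raise ValueError("need at least 2 topics")
    vals = T.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (vals - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(z, index=T.index, columns=T.columns)
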