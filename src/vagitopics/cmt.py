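"""Community state type (CMT) assignment by hierarchical clustering with
Kruskal-Wallis taxon-selection refinement.

The refinement clusters samples on all taxa, asks per taxon whether its
(log-normalized) abundance differs across the initial clusters, keeps the
Bonferroni-significant taxa, and re-clusters on that marker subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency, kruskal

from .count_matrix import CountMatrix, log10_normalize
from .exceptions import EmptyResultError, ValidationError


def hierarchical_cluster(matrix, k: int, method: str = "complete") -> np.ndarray:
    """Agglomerative clustering (Euclidean) of rows, tree cut into k clusters.

    Returns integer labels in 1..k, renumbered by order of first occurrence
    so the result is deterministic given the input row order.
    """
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("matrix must be finite")
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    Z = linkage(X, method=method, metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    remap, labels = {}, np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    return labels


def kruskal_wallis(values, groups):
    """Tie-corrected Kruskal-Wallis H with a chi-square p (g-1 df).

    Values constant across all samples give H = 0, p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    parts = [values[groups == g] for g in levels]
    if any(p.size == 0 for p in parts):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0
    res = kruskal(*parts)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CMTAssignment:
    """Final CMT labels plus the Kruskal-Wallis taxon-selection table."""

    labels: pd.Series                # per-sample integer in 1..k
    selected_taxa: pd.Index
    kw_table: pd.DataFrame           # per taxon: H, p_raw, p_bonferroni, selected
    k: int
    initial_labels: pd.Series | None = None

    def indicator_matrix(self) -> pd.DataFrame:
        """One-hot CMT membership (samples x k), for feature fusion."""
        cols = {f"cmt_{j}": (self.labels == j).astype(int) for j in range(1, self.k + 1)}
        return pd.DataFrame(cols, index=self.labels.index)


def refine_cmt(cm: CountMatrix, k: int = 5, alpha: float = 0.05,
               method: str = "complete", pseudocount: float = 1.0) -> CMTAssignment:
    """Two-pass CMT assignment refined on Kruskal-Wallis-selected taxa.

    (1) cluster samples on log10-normalized abundances of all taxa;
    (2) per-taxon Kruskal-Wallis across the initial labels, Bonferroni
    family = number of taxa; (3) keep taxa with adjusted p < *alpha*;
    (4) re-cluster on the retained submatrix with the same k.
    """
    X = log10_normalize(cm, pseudocount=pseudocount).T  # samples x taxa
    init = hierarchical_cluster(X.to_numpy(), k, method=method)
    m = cm.n_taxa
    stats = []
    for taxon in cm.taxa_ids:
        h, p = kruskal_wallis(X[taxon].to_numpy(), init)
        stats.append((taxon, h, p, min(1.0, m * p)))
    kw = pd.DataFrame(stats, columns=["taxon", "H", "p_raw", "p_bonferroni"])
    kw = kw.set_index("taxon")
    kw["selected"] = kw["p_bonferroni"] < alpha
    selected = kw.index[kw["selected"]]
    if len(selected) == 0:
        raise EmptyResultError(
            f"no taxon is Bonferroni-significant at alpha={alpha}; raise alpha")
    final = hierarchical_cluster(X[selected].to_numpy(), k, method=method)
    sample_index = pd.Index(cm.sample_ids)
    return CMTAssignment(
        labels=pd.Series(final, index=sample_index, name="cmt"),
        selected_taxa=selected,
        kw_table=kw,
        k=k,
        initial_labels=pd.Series(init, index=sample_index, name="cmt_initial"),
    )


def cmt_outcome_test(labels, outcome, seed: int = 0, n_permutations: int = 4999):
    """Independence of CMT labels and a binary outcome.

    Chi-square on the k x 2 contingency table; when any expected cell is
    below 5, the p-value comes from a Monte-Carlo permutation null of the
    chi-square statistic instead.
    """
    labels = np.asarray(labels)
    outcome = np.asarray(outcome)
    if pd.unique(outcome).size < 2:
        raise ValueError("outcome is constant")
    if pd.unique(labels).size < 2:
        raise ValueError("need >= 2 clusters")
    table = pd.crosstab(labels, outcome).to_numpy()
    chi2, p, _, expected = chi2_contingency(table, correction=False)
    if (expected >= 5).all():
        return float(chi2), float(p)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(outcome)
        t = pd.crosstab(labels, perm).to_numpy()
        c, _, _, _ = chi2_contingency(t, correction=False)
        hits += c >= chi2 - 1e-12
    return float(chi2), float((hits + 1) / (n_permutations + 1))
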