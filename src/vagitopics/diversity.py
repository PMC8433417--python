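"""Alpha diversity, dissimilarity, NMDS ordination and group tests.

Shannon entropy uses the natural log.  NMDS is non-metric (Kruskal
stress-1 with isotonic regression of fitted distances on dissimilarities),
run from multiple seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu
from sklearn.manifold import MDS

from .count_matrix import CountMatrix, relative_abundance
from .exceptions import ValidationError


def _as_proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count vector has undefined diversity")
    return x / total


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over positive proportions."""
    p = _as_proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    p = _as_proportions(counts)
    return float(1.0 - (p ** 2).sum())


def alpha_diversity_table(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample Shannon and Simpson indices."""
    rows = {s: (shannon(cm.counts[s]), simpson(cm.counts[s])) for s in cm.sample_ids}
    return pd.DataFrame.from_dict(rows, orient="index", columns=["shannon", "simpson"])


def dissimilarity_matrix(cm: CountMatrix, metric: str = "bray_curtis",
                         relative: bool = True) -> pd.DataFrame:
    """Symmetric sample-by-sample dissimilarities.

    Bray-Curtis defaults to relative abundances (each column scaled to sum
    one); ``relative=False`` computes it on raw counts.  Euclidean is
    computed on the columns as given.
    """
    if cm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if metric == "bray_curtis":
        data = relative_abundance(cm).T.to_numpy() if relative else cm.counts.T.to_numpy(dtype=float)
        if not relative and (data.sum(axis=1) == 0).any():
            raise ValueError("zero-total sample under bray_curtis")
        d = pdist(data, metric="braycurtis")
    elif metric == "euclidean":
        d = pdist(cm.counts.T.to_numpy(dtype=float), metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(squareform(d), index=cm.sample_ids, columns=cm.sample_ids)


@dataclass
class OrdinationResult:
    """NMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_iterations: int
    converged: bool

    def __repr__(self):
        k = self.coordinates.shape[1]
        return f"OrdinationResult(k={k}, stress={self.stress:.4f})"


def nmds(d, k: int = 2, seed: int = 0, n_restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-6) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Minimizes Kruskal stress-1, ``sqrt(sum (dhat - fitted)^2 / sum fitted^2)``,
    by SMACOF majorization with isotonic regression, keeping the best of
    *n_restarts* seeded starts.  Coordinates are centered at the origin.
    """
    index = d.index if isinstance(d, pd.DataFrame) else None
    dm = np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-10):
        raise ValidationError("dissimilarity matrix must be square and symmetric")
    if k < 1:
        raise ValueError("k must be >= 1")
    model = MDS(n_components=k, metric="precomputed", metric_mds=False,
                n_init=n_restarts, max_iter=max_iter, eps=tol,
                random_state=seed, normalized_stress=True)
    coords = model.fit_transform(dm)
    coords = coords - coords.mean(axis=0)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    frame = pd.DataFrame(coords, columns=cols, index=index)
    n_iter = int(getattr(model, "n_iter_", max_iter))
    return OrdinationResult(frame, float(model.stress_), n_iter, n_iter < max_iter)


def mann_whitney(x, y, use_exact_limit: int = 8):
    """Two-sided Mann-Whitney U.

    Exact null enumeration when both groups have <= *use_exact_limit*
    observations and no ties are present; otherwise the tie-corrected
    normal approximation (no continuity correction, matching the exact
    test in the small-sample regime).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= use_exact_limit and y.size <= use_exact_limit and not ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def alpha_group_test(values, groups):
    """Group comparison of a diversity vector: Mann-Whitney for two groups,
    Kruskal-Wallis for more."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    parts = [values[groups == g] for g in levels]
    if any(p.size == 0 for p in parts):
        raise ValueError("empty group")
    if len(levels) == 2:
        return mann_whitney(parts[0], parts[1])
    res = kruskal(*parts)
    return float(res.statistic), float(res.pvalue)
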