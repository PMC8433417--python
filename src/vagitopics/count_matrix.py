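"""Taxon-by-sample count tables: container, I/O, filtering and normalization.

The central object is :class:`CountMatrix`, a validated bundle of a
non-negative integer count table (taxa x samples), Greengenes-style
taxonomy lineage strings, and per-sample clinical metadata.  The on-disk
dialect is the "classic" tab-separated OTU table (first column the taxon
id, last column ``taxonomy``), with metadata in a plain CSV keyed by
sample id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, FormatError, ValidationError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
_PREFIX_TO_RANK = dict(zip(RANK_PREFIXES, RANKS))

#: Clinical metadata columns written/read by the standard dialect.
CLINICAL_COLUMNS = [
    "fever_status",
    "site",
    "age_years",
    "labor_hours",
    "prior_fever_7d",
    "vaginal_infection_1mo",
    "antimicrobial_use",
    "cesarean",
    "malaria_positive",
    "hiv_positive",
    "cmv_positive",
    "parity",
]


def parse_lineage(lineage: str) -> dict:
    """Parse a 7-rank lineage string into a ``{rank: name}`` dict.

    Accepts the prefixed form ``k__Bacteria;...;g__Lactobacillus;s__iners``;
    a bare (unprefixed) final token is tolerated and assigned to the first
    unfilled rank.  Missing ranks map to the empty string.

    Raises
    ------
    FormatError
        If a non-final token lacks a rank prefix, or no token carries one.
    """
    out = {r: "" for r in RANKS}
    tokens = [t.strip() for t in str(lineage).split(";")]
    tokens = [t for t in tokens if t != ""] or [""]
    any_prefix = False
    filled = []
    for i, tok in enumerate(tokens):
        prefix = tok[:3]
        if prefix in _PREFIX_TO_RANK:
            any_prefix = True
            out[_PREFIX_TO_RANK[prefix]] = tok[3:].strip()
            filled.append(_PREFIX_TO_RANK[prefix])
        elif tok == "":
            continue
        elif i == len(tokens) - 1 and any_prefix:
            # bare trailing name: next rank after the deepest filled one
            last = max(RANKS.index(r) for r in filled) if filled else -1
            if last + 1 < len(RANKS):
                out[RANKS[last + 1]] = tok
        else:
            raise FormatError(f"lineage token {tok!r} has no rank prefix in {lineage!r}")
    if not any_prefix:
        raise FormatError(f"lineage {lineage!r} has no rank prefixes")
    return out


def truncate_lineage(lineage: str, rank: str) -> str:
    """Lineage string truncated at *rank* (inclusive), prefixes preserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    parsed = parse_lineage(lineage)
    upto = RANKS[: RANKS.index(rank) + 1]
    return ";".join(p + parsed[r] for p, r in zip(RANK_PREFIXES, upto))


@dataclass
class CountMatrix:
    """Validated taxa x samples count table with lineages and metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integers, index = taxon ids, columns = sample ids.
    lineages : Series
        Per-taxon lineage string, indexed like ``counts``.
    metadata : DataFrame
        Per-sample records indexed by sample id; must cover every sample.
    """

    counts: pd.DataFrame
    lineages: pd.Series = field(repr=False)
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64, copy=False)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate taxon ids")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if not self.lineages.index.equals(self.counts.index):
            self.lineages = self.lineages.reindex(self.counts.index)
            if self.lineages.isna().any():
                raise ValidationError("lineages missing for some taxa")
        missing = self.counts.columns.difference(self.metadata.index)
        if len(missing):
            raise ValidationError(f"samples absent from metadata: {list(missing)[:5]}")
        self.metadata = self.metadata.loc[self.counts.columns]
        for lin in self.lineages:
            parse_lineage(lin)  # raises FormatError on malformed input

    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self):
        return self.counts.shape

    @property
    def taxa_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.lineages.copy(), self.metadata.copy())

    def __repr__(self):
        return f"CountMatrix({self.n_taxa} taxa x {self.n_samples} samples)"


# ----------------------------------------------------------------------
# I/O — classic tab-separated OTU table + CSV metadata
# ----------------------------------------------------------------------

def read_count_table(path, metadata_path) -> CountMatrix:
    """Read a classic TSV count table and its CSV metadata into a CountMatrix.

    The count file is tab-separated with the taxon id in the first column
    and the lineage string in a column named ``taxonomy`` (conventionally
    last); all other columns are integer counts per sample.  The metadata
    CSV must have a ``sample_id`` column (or its first column is taken as
    the sample id) and cover every sample in the count table.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    tax_col = None
    for c in table.columns:
        if str(c).lower() == "taxonomy":
            tax_col = c
            break
    if tax_col is None:
        raise FormatError("count table has no 'taxonomy' column")
    lineages = table[tax_col].astype(str)
    counts = table.drop(columns=[tax_col])
    try:
        counts = counts.astype(np.int64)
    except (ValueError, TypeError) as err:
        raise FormatError(f"non-integer counts: {err}") from err

    meta = pd.read_csv(metadata_path)
    key = "sample_id" if "sample_id" in meta.columns else meta.columns[0]
    if meta[key].duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    meta = meta.set_index(key)
    meta.index = meta.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(counts, lineages, meta)


def write_count_table(cm: CountMatrix, path, metadata_path=None) -> None:
    """Write *cm* in the identical classic TSV dialect (and metadata CSV)."""
    out = cm.counts.copy()
    out["taxonomy"] = cm.lineages
    out.index.name = out.index.name or "taxon_id"
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        meta = cm.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path)


# ----------------------------------------------------------------------
# Filtering and normalization
# ----------------------------------------------------------------------

def filter_samples(cm: CountMatrix, min_reads: int) -> CountMatrix:
    """Retain samples whose total read count is at least *min_reads*."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = cm.library_sizes >= min_reads
    if not keep.any():
        raise EmptyResultError(f"no sample has >= {min_reads} reads")
    cols = cm.sample_ids[keep]
    return CountMatrix(cm.counts[cols], cm.lineages.copy(), cm.metadata.loc[cols])


def prevalence_threshold(fraction: float, n_samples: int) -> int:
    """ceil(fraction * n) with a guard against float round-up artifacts."""
    return max(1, math.ceil(fraction * n_samples - 1e-9))


def filter_taxa(cm: CountMatrix, min_count: int = 2, min_prevalence: float = 0.10) -> CountMatrix:
    """Keep taxa observed at >= *min_count* reads in >= *min_prevalence* of samples.

    The default (2, 0.10) is the strict study filter; the relaxed preset for
    cross-region comparisons is (1, 0.05).  ``min_count=0`` is the identity.
    """
    if not (0 < min_prevalence <= 1):
        raise ValueError("min_prevalence must be in (0, 1]")
    if min_count == 0:
        return cm.copy()
    need = prevalence_threshold(min_prevalence, cm.n_samples)
    hits = (cm.counts.to_numpy() >= min_count).sum(axis=1)
    keep = hits >= need
    if not keep.any():
        raise EmptyResultError("no taxon passes the prevalence filter")
    idx = cm.taxa_ids[keep]
    return CountMatrix(cm.counts.loc[idx], cm.lineages.loc[idx], cm.metadata.copy())


def agglomerate(cm: CountMatrix, rank: str) -> CountMatrix:
    """Sum counts over taxa sharing the lineage truncated at *rank*.

    Taxa with an empty value at *rank* pool into one unassigned row per
    distinct parent lineage (their truncated lineage string, which ends in
    an empty rank prefix, becomes the shared key).  Grand totals are
    conserved exactly.
    """
    if rank not in ("genus", "species"):
        raise ValueError("rank must be 'genus' or 'species'")
    keys = cm.lineages.map(lambda lin: truncate_lineage(lin, rank))
    grouped = cm.counts.groupby(keys.to_numpy()).sum()
    grouped.index.name = cm.counts.index.name
    lineages = pd.Series(grouped.index, index=grouped.index)
    return CountMatrix(grouped, lineages, cm.metadata.copy())


def relative_abundance(cm: CountMatrix, percent: bool = False) -> pd.DataFrame:
    """Per-sample proportions (columns sum to 1, or 100 when *percent*)."""
    totals = cm.library_sizes
    if (totals == 0).any():
        bad = list(cm.sample_ids[totals == 0])[:5]
        raise EmptyResultError(f"zero-total samples (filter first): {bad}")
    rel = cm.counts / totals
    return rel * 100.0 if percent else rel


def log10_normalize(cm: CountMatrix, pseudocount: float = 1.0, scale: bool = True) -> pd.DataFrame:
    """log10(count + pseudocount) after optional library-size scaling.

    With ``scale=True`` each column is first rescaled to the median library
    size so that depth differences do not masquerade as abundance; zeros map
    to ``log10(pseudocount)`` and stay distinguishable.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = cm.counts.astype(float)
    if scale:
        totals = cm.library_sizes.astype(float)
        if (totals == 0).any():
            raise EmptyResultError("zero-total samples (filter first)")
        x = x * (float(np.median(totals)) / totals)
    return np.log10(x + pseudocount)
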