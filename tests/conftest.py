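"""Shared fixtures: small hand-built count matrices and synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from vagitopics import CountMatrix, GeneratorParams, generate_cohort


@pytest.fixture
def toy_cm():
    """3 taxa x 4 samples with hand-checkable counts."""
    counts = pd.DataFrame(
        [[5, 0, 2, 1],
         [3, 7, 0, 4],
         [2, 1, 8, 0]],
        index=["t1", "t2", "t3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    lineages = pd.Series(
        ["k__Bacteria;p__Firmicutes;c__;o__;f__;g__Lactobacillus;s__iners",
         "k__Bacteria;p__Firmicutes;c__;o__;f__;g__Lactobacillus;s__crispatus",
         "k__Bacteria;p__Fusobacteria;c__;o__;f__;g__Sneathia;s__"],
        index=counts.index,
    )
    meta = pd.DataFrame({"fever_status": [0, 1, 0, 1], "site": [0, 0, 1, 1]},
                        index=counts.columns)
    return CountMatrix(counts, lineages, meta)


@pytest.fixture(scope="session")
def template_cohort():
    """Template-mode cohort at the identifiability scale (N=150, depth ~3000)."""
    params = GeneratorParams(n_samples=150, seed=11, library_size_logmean=8.0)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort (N=99)."""
    return generate_cohort(GeneratorParams(seed=5))


def make_cm(counts: np.ndarray, prefix="OTU") -> CountMatrix:
    """Wrap a raw taxa x samples array in a CountMatrix with dummy lineages."""
    m, n = counts.shape
    idx = [f"{prefix}{i}" for i in range(m)]
    cols = [f"S{j}" for j in range(n)]
    frame = pd.DataFrame(counts, index=idx, columns=cols)
    lineages = pd.Series([f"k__Bacteria;p__;c__;o__;f__;g__G{i};s__sp{i}" for i in range(m)],
                         index=idx)
    meta = pd.DataFrame(index=pd.Index(cols))
    return CountMatrix(frame, lineages, meta)
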