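"""Synthetic intrapartum-cohort generator.

Implements the generative law the downstream analysis presumes: each
sample's community is a Dirichlet-weighted mixture (``omega``) of K latent
topics, each topic a multinomial distribution over taxa (``theta``);
library sizes are log-normal; counts are multinomial draws.  Clinical
covariates are linked to a binary fever label through a logistic model
whose intercept is calibrated by bisection to a target prevalence, and a
separate epidemiologic generator produces binary exposures with exact
population odds ratios against fever.

Template mode plants four topics mirroring the canonical vaginal
community structures: a *Lactobacillus crispatus*-dominant topic, an
*L. iners*-dominant topic, a diverse BV-like topic, and a
pathogen-enriched topic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_matrix import CountMatrix

# Named taxa for the four template topics (genus, species).
_CRISPATUS_BLOCK = [
    ("Lactobacillus", "crispatus"), ("Lactobacillus", "jensenii"),
    ("Lactobacillus", "reuteri"), ("Lactobacillus", "gasseri"),
    ("Aerococcus", "sp"),
]
_INERS_BLOCK = [
    ("Lactobacillus", "iners"), ("Ureaplasma", "sp"),
    ("Staphylococcus", "sp"), ("Enterobacter", "sp"), ("Micrococcus", "sp"),
]
_BV_BLOCK = [
    ("Sneathia", "sanguinegens"), ("Prevotella", "copri"), ("Prevotella", "bivia"),
    ("Gardnerella", "vaginalis"), ("Atopobium", "vaginae"), ("Megasphaera", "sp"),
    ("Dialister", "sp"), ("Shuttleworthia", "sp"), ("Mycoplasma", "sp"),
    ("Finegoldia", "magna"), ("Adlercreutzia", "sp"), ("Bulleidia", "sp"),
    ("Mobiluncus", "curtisii"), ("Parvimonas", "micra"), ("Peptoniphilus", "sp"),
]
_PATHOGEN_BLOCK = [
    ("Granulicatella", "sp"), ("Streptococcus", "agalactiae"),
    ("Fusobacterium", "nucleatum"), ("Veillonella", "sp"),
    ("Anaerococcus", "sp"), ("Gemella", "sp"), ("Clostridium", "sp"),
    ("Sneathia", "amnii"),
]
_TEMPLATE_BLOCKS = [_CRISPATUS_BLOCK, _INERS_BLOCK, _BV_BLOCK, _PATHOGEN_BLOCK]
TEMPLATE_TOPIC_NAMES = ("crispatus", "iners", "diverse_bv", "pathogen")

#: Index of the pathogen-enriched template topic (drives the fever label).
PATHOGEN_TOPIC = 3

#: Binary exposures with (population odds ratio vs fever, control prevalence),
#: magnitudes taken from the cohort's univariate characterization table.
DEFAULT_TABLE1_TARGETS = {
    "hiv_positive": (1.00, 5 / 49),
    "cesarean": (3.19, 11 / 49),
    "antimicrobial_use": (2.82, 2 / 46),
    "site": (1.04, 24 / 49),
    "cmv_positive": (1.06, 16 / 49),
    "malaria_positive": (5.05, 4 / 47),
    "prior_fever_7d": (10.56, 4 / 49),
    "vaginal_infection_1mo": (1.70, 3 / 48),
}


@dataclass
class GeneratorParams:
    """Study-condition defaults for cohort simulation.

    ``clinical_effects`` are log-odds coefficients of the fever model:
    negative per-year age effect, positive prior-fever and labor-duration
    effects at the magnitudes of the cohort table (ln 10.56 for prior
    fever, ln 1.19 per 10 labor hours), and a positive pathogen-topic
    effect of ln 9.77 per unit weight — the printed magnitude of a
    per-unit-topic-weight odds ratio in this cohort.

    ``labor_pathogen_interaction`` is a synergy term (per 10 centered labor
    hours x pathogen-topic weight): prolonged labor with a dysbiotic,
    pathogen-dominated community raises fever risk beyond either factor
    alone.  Because labor hours are centered, the term contributes almost
    nothing to the marginal microbial signal; it is the "combinatory"
    clinical-microbial structure that only a fused model can exploit.
    """

    n_samples: int = 99
    n_taxa: int = 60
    n_topics: int = 4
    template: bool = True
    topic_concentration: float = 0.1     # Dirichlet for theta rows (non-template)
    weight_concentration: float = 0.3    # symmetric Dirichlet for omega rows
    library_size_logmean: float = 8.5
    library_size_logsd: float = 0.6
    fever_prevalence: float = 0.5
    clinical_effects: dict = field(default_factory=lambda: {
        "age_years": -0.20,
        "labor_hours": float(np.log(1.19) / 10.0),
        "prior_fever_7d": float(np.log(10.56)),
        "pathogen_topic": float(np.log(9.77)),
        "labor_pathogen_interaction": float(np.log(9.77)),
    })
    exposure_prevalences: dict = field(default_factory=lambda: {
        "site": 0.49,
        "prior_fever_7d": 0.29,
        "vaginal_infection_1mo": 0.06,
        "antimicrobial_use": 0.08,
        "cesarean": 0.35,
        "malaria_positive": 0.20,
        "hiv_positive": 0.10,
        "cmv_positive": 0.33,
    })
    #: univariate ORs vs fever for the exposures drawn conditional on the
    #: label (the cohort table's magnitudes); prior fever acts causally
    #: through the logistic model instead.
    exposure_odds_ratios: dict = field(default_factory=lambda: {
        "site": 1.04,
        "vaginal_infection_1mo": 1.70,
        "antimicrobial_use": 2.82,
        "cesarean": 3.19,
        "malaria_positive": 5.05,
        "hiv_positive": 1.00,
        "cmv_positive": 1.06,
    })
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.n_taxa < self.n_topics:
            raise ValueError("n_taxa must be >= n_topics")
        if self.topic_concentration <= 0 or self.weight_concentration <= 0:
            raise ValueError("concentrations must be > 0")


@dataclass
class SyntheticCohort:
    """A generated CountMatrix plus the ground truth that produced it."""

    cm: CountMatrix
    theta_true: pd.DataFrame        # topics x taxa, rows on the simplex
    omega_true: pd.DataFrame        # samples x topics, rows on the simplex
    clinical: pd.DataFrame
    fever: pd.Series
    params: GeneratorParams
    intercept: float
    pathogen_topic: int = PATHOGEN_TOPIC


def _default_lineages(n_taxa: int):
    pairs = []
    for block in _TEMPLATE_BLOCKS:
        pairs.extend(block)
    while len(pairs) < n_taxa:
        i = len(pairs)
        pairs.append((f"Genus{i}", f"sp{i}"))
    pairs = pairs[:n_taxa]
    lineages, ids = [], []
    for i, (g, s) in enumerate(pairs):
        lineages.append(f"k__Bacteria;p__;c__;o__;f__;g__{g};s__{s}")
        ids.append(f"OTU{i:03d}_{g}_{s}")
    return ids, lineages


def generate_topics(params: GeneratorParams, rng=None) -> np.ndarray:
    """Draw the K x V topic matrix ``theta`` (rows on the taxon simplex).

    Template mode concentrates topics on nearly disjoint taxon blocks
    (dominant-taxon topics for crispatus/iners, spread Dirichlet blocks for
    the diverse and pathogen topics), which makes the mixture identifiable;
    non-template mode draws each row from a symmetric Dirichlet.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    K, V = params.n_topics, params.n_taxa
    if not params.template:
        return rng.dirichlet(np.full(V, params.topic_concentration), size=K)

    blocks = []
    used = 0
    for k in range(K):
        if k < len(_TEMPLATE_BLOCKS):
            size = len(_TEMPLATE_BLOCKS[k])
        else:
            size = 5
        if used + size > V:
            raise ValueError(
                f"template mode needs {used + size} taxa for {K} topics, have {V}")
        blocks.append(np.arange(used, used + size))
        used += size

    theta = np.full((K, V), 1e-5)
    for k, idx in enumerate(blocks):
        if k in (0, 1) and k < len(_TEMPLATE_BLOCKS):
            # dominant single taxon plus a thin tail over its block
            w = rng.dirichlet(np.full(len(idx) - 1, 1.0)) * 0.15
            theta[k, idx[0]] += 0.85
            theta[k, idx[1:]] += w
        else:
            conc = 1.0 if k == 2 else 0.8
            theta[k, idx] += rng.dirichlet(np.full(len(idx), conc))
    return theta / theta.sum(axis=1, keepdims=True)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _solve_control_prevalence(marginal: float, oratio: float, f_rate: float) -> float:
    """Control-arm prevalence p0 such that the fever/afebrile mixture has the
    requested marginal prevalence at the given odds ratio (bisection)."""
    if marginal <= 0:
        return 0.0
    lo, hi = 1e-9, 1 - 1e-9
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        odds1 = oratio * mid / (1 - mid)
        p1 = odds1 / (1 + odds1)
        if (1 - f_rate) * mid + f_rate * p1 < marginal:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Bisection on the intercept so mean predicted probability hits *target*."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _logistic(lp + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(params: GeneratorParams | None = None) -> SyntheticCohort:
    """Simulate a full cohort: counts, ground-truth topics, clinical data, fever.

    For each sample i: ``omega_i ~ Dirichlet(alpha0)``, library size
    ``L_i ~ round(LogNormal)``, ``counts_i ~ Multinomial(L_i, omega_i @ theta)``.
    The fever label follows a logistic model on centered age and labor
    duration, prior fever, and the pathogen-topic weight, with the intercept
    bisection-calibrated to the target prevalence.  A fixed seed reproduces
    the cohort bit for bit.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    K, V, N = params.n_topics, params.n_taxa, params.n_samples

    theta = generate_topics(params, rng)
    omega = rng.dirichlet(np.full(K, params.weight_concentration), size=N)
    libs = np.maximum(
        1, np.round(rng.lognormal(params.library_size_logmean,
                                  params.library_size_logsd, size=N))).astype(np.int64)
    probs = omega @ theta
    counts = np.empty((N, V), dtype=np.int64)
    for i in range(N):
        counts[i] = rng.multinomial(libs[i], probs[i])

    # clinical covariates that enter the fever model causally
    prev = params.exposure_prevalences
    clin = pd.DataFrame(index=[f"S{i:03d}" for i in range(N)])
    clin.index.name = "sample_id"
    clin["age_years"] = np.round(np.clip(rng.normal(24.0, 4.5, size=N), 18, 45), 1)
    clin["labor_hours"] = np.round(rng.gamma(2.0, 13.0, size=N), 1)
    clin["parity"] = rng.poisson(2.0, size=N)
    clin["prior_fever_7d"] = rng.binomial(
        1, prev.get("prior_fever_7d", 0.29), size=N).astype(float)

    eff = params.clinical_effects
    labor_c = clin["labor_hours"] - clin["labor_hours"].mean()
    w_path = omega[:, min(PATHOGEN_TOPIC, K - 1)]
    lp = (eff.get("age_years", 0.0) * (clin["age_years"] - clin["age_years"].mean())
          + eff.get("labor_hours", 0.0) * labor_c
          + eff.get("prior_fever_7d", 0.0) * clin["prior_fever_7d"]
          + eff.get("pathogen_topic", 0.0) * w_path
          + eff.get("labor_pathogen_interaction", 0.0) * (labor_c / 10.0) * w_path)
    lp = lp.to_numpy(dtype=float)
    intercept = _calibrate_intercept(lp, params.fever_prevalence)
    fever = rng.binomial(1, _logistic(lp + intercept))
    clin.insert(0, "fever_status", fever)

    # exposures associated with (not causal for) fever: drawn conditional
    # on the label so their population odds ratio hits the table magnitude
    # while the marginal prevalence is preserved
    f_rate = fever.mean()
    for name, oratio in params.exposure_odds_ratios.items():
        q = prev.get(name, 0.1)
        p0 = _solve_control_prevalence(q, oratio, f_rate)
        odds1 = oratio * p0 / max(1 - p0, 1e-12)
        p1 = odds1 / (1 + odds1)
        clin[name] = rng.binomial(1, np.where(fever == 1, p1, p0)).astype(float)
    clin["site"] = clin["site"].astype(int)

    # inject realistic missingness into self-reported / assay binaries
    if params.missing_rate > 0:
        for name in ("vaginal_infection_1mo", "antimicrobial_use",
                     "malaria_positive", "hiv_positive"):
            mask = rng.random(N) < params.missing_rate
            clin.loc[mask, name] = np.nan

    taxa_ids, lineages = _default_lineages(V)
    cm = CountMatrix(
        pd.DataFrame(counts.T, index=taxa_ids, columns=clin.index),
        pd.Series(lineages, index=taxa_ids),
        clin,
    )
    topic_names = [
        TEMPLATE_TOPIC_NAMES[k] if params.template and k < len(TEMPLATE_TOPIC_NAMES)
        else f"topic_{k + 1}" for k in range(K)
    ]
    return SyntheticCohort(
        cm=cm,
        theta_true=pd.DataFrame(theta, index=topic_names, columns=taxa_ids),
        omega_true=pd.DataFrame(omega, index=clin.index, columns=topic_names),
        clinical=clin,
        fever=pd.Series(fever, index=clin.index, name="fever_status"),
        params=params,
        intercept=intercept,
    )


def generate_table1_cohort(n_per_arm: int = 50, target_or: dict | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Binary exposures with exact population odds ratios against fever.

    Each exposure has its afebrile-arm prevalence ``p0``; the febrile-arm
    prevalence is set so the population cross-product odds ratio equals the
    target.  Finite-sample estimates are random around the target.
    """
    targets = target_or if target_or is not None else DEFAULT_TABLE1_TARGETS
    rng = np.random.default_rng(seed)
    fever = np.concatenate([np.zeros(n_per_arm, dtype=int), np.ones(n_per_arm, dtype=int)])
    out = pd.DataFrame({"fever_status": fever},
                       index=[f"S{i:03d}" for i in range(2 * n_per_arm)])
    out.index.name = "sample_id"
    for name, (oratio, p0) in targets.items():
        if oratio <= 0:
            raise ValueError(f"target OR for {name} must be > 0")
        odds1 = oratio * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        p = np.where(fever == 1, p1, p0)
        out[name] = rng.binomial(1, p)
    return out


def write_cohort(cohort: SyntheticCohort, counts_path, metadata_path, truth_path=None):
    """Write the cohort in the dialects core I/O reads, plus a truth sidecar."""
    from .count_matrix import write_count_table

    write_count_table(cohort.cm, counts_path, metadata_path)
    if truth_path is not None:
        truth = {
            "theta": cohort.theta_true.round(10).to_dict(orient="split"),
            "omega": cohort.omega_true.round(10).to_dict(orient="split"),
            "clinical_effects": cohort.params.clinical_effects,
            "intercept": cohort.intercept,
            "pathogen_topic": cohort.pathogen_topic,
            "seed": cohort.params.seed,
        }
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
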