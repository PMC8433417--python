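"""Maternal fever prediction from fused clinical + microbial features.

Clinical covariates (11), topic weights (K) and CMT one-hot indicators (k)
are fused into one feature table; a random forest is evaluated over many
random train/test resamples, reporting round-averaged AUC, a vertically
averaged ROC on a fixed FPR grid, and mean impurity importances.  Missing
clinical values are imputed per round by the training split's median/mode
only — the test split never informs imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

#: The 11 clinical/environmental predictors of the feature table.
CLINICAL_FEATURES = [
    "age_years", "parity", "prior_fever_7d", "vaginal_infection_1mo",
    "antimicrobial_use", "labor_hours", "cesarean", "malaria_positive",
    "hiv_positive", "cmv_positive", "site",
]

DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


@dataclass
class FeatureTable:
    """Samples x features matrix partitioned into clinical and microbial blocks."""

    X: pd.DataFrame = field(repr=False)
    labels: pd.Series = field(repr=False)
    clinical_features: list = field(default_factory=list)
    microbial_features: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def columns_for(self, feature_set: str) -> list:
        if feature_set == "all":
            return self.clinical_features + self.microbial_features
        if feature_set == "clinical":
            return list(self.clinical_features)
        if feature_set == "microbial":
            return list(self.microbial_features)
        raise ValueError("feature_set must be 'all', 'clinical' or 'microbial'")


def build_feature_table(clinical: pd.DataFrame, fit, cmt) -> FeatureTable:
    """Fuse clinical covariates, topic weights and CMT indicators.

    *fit* is a GradesOfMembershipResults (or an omega DataFrame); *cmt* a
    CMTAssignment (or a label Series).  Sample ids must align exactly.
    """
    omega = fit.omega if hasattr(fit, "omega") else fit
    if hasattr(cmt, "indicator_matrix"):
        ind = cmt.indicator_matrix()
    else:
        labels = pd.Series(cmt)
        k = int(labels.max())
        ind = pd.DataFrame({f"cmt_{j}": (labels == j).astype(int)
                            for j in range(1, k + 1)}, index=labels.index)
    idx = clinical.index
    if not (idx.equals(omega.index) and idx.equals(ind.index)):
        if set(idx) != set(omega.index) or set(idx) != set(ind.index):
            raise ValueError("sample ids of clinical, omega and CMT inputs differ")
        omega = omega.loc[idx]
        ind = ind.loc[idx]
    missing = [c for c in CLINICAL_FEATURES if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns: {missing}")
    X = pd.concat([clinical[CLINICAL_FEATURES].astype(float), omega, ind], axis=1)
    return FeatureTable(
        X=X,
        labels=clinical["fever_status"].astype(int),
        clinical_features=list(CLINICAL_FEATURES),
        microbial_features=list(omega.columns) + list(ind.columns),
    )


def roc_auc(scores, labels):
    """ROC points and trapezoid AUC; ties earn half credit, so the AUC
    equals the Mann-Whitney U statistic divided by n1*n2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if pd.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}), \
        float(roc_auc_score(labels, scores))


@dataclass
class PredictionReport:
    """Resampled random-forest evaluation for one feature set."""

    feature_set: str
    aucs: np.ndarray = field(repr=False)
    mean_roc: pd.DataFrame = field(repr=False)      # fpr grid + mean tpr
    importances: pd.DataFrame = field(repr=False)   # mean, sd per feature
    n_rounds: int = 0
    n_train: int = 0
    n_test: int = 0
    seed: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    def summary(self) -> str:
        lines = [
            f"Random-forest fever prediction ({self.feature_set} features)".center(64),
            "=" * 64,
            f"rounds: {self.n_rounds}  train/test: {self.n_train}/{self.n_test}"
            f"  seed: {self.seed}",
            f"mean AUC: {self.mean_auc:.3f}  (sd over rounds {np.std(self.aucs):.3f})",
            "-" * 64,
            "top features by mean importance:",
            self.importances.head(8).to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "mean_auc": self.mean_auc,
            "auc_sd": float(np.std(self.aucs)),
            "n_rounds": self.n_rounds,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "roc_fpr": self.mean_roc["fpr"].tolist(),
            "roc_tpr": self.mean_roc["tpr"].tolist(),
            "importances": self.importances["mean"].to_dict(),
        }


def _impute_train_stats(train: pd.DataFrame):
    stats = {}
    for col in train.columns:
        vals = train[col].dropna()
        if vals.empty:
            stats[col] = 0.0
        elif vals.isin([0, 1]).all():
            stats[col] = float(vals.mode().iloc[0])
        else:
            stats[col] = float(vals.median())
    return stats


class ResampledForest:
    """Random forest evaluated over repeated random train/test partitions."""

    def __init__(self, ft: FeatureTable, feature_set: str = "all",
                 rf_params: dict | None = None):
        self.ft = ft
        self.feature_set = feature_set
        self.columns = ft.columns_for(feature_set)
        self.rf_params = dict(DEFAULT_RF_PARAMS, **(rf_params or {}))

    def fit(self, n_rounds: int = 1000, n_train: int = 69, n_test: int = 30,
            seed: int = 0, fpr_grid_points: int = 101) -> PredictionReport:
        X = self.ft.X[self.columns]
        y = self.ft.labels.to_numpy()
        n = len(y)
        if n_train + n_test > n:
            raise ValueError("n_train + n_test exceeds the number of samples")
        if pd.unique(y).size < 2:
            raise ValueError("labels are single-class; no split can work")
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 1, fpr_grid_points)
        aucs = np.empty(n_rounds)
        tprs = np.zeros(fpr_grid_points)
        imps = np.zeros(len(self.columns))
        imps2 = np.zeros(len(self.columns))
        for r in range(n_rounds):
            for _ in range(1000):
                perm = rng.permutation(n)
                tr, te = perm[:n_train], perm[n_train:n_train + n_test]
                if pd.unique(y[tr]).size == 2 and pd.unique(y[te]).size == 2:
                    break
            else:
                raise ValueError("could not draw a split with both classes")
            Xtr, Xte = X.iloc[tr].copy(), X.iloc[te].copy()
            stats = _impute_train_stats(Xtr)
            Xtr = Xtr.fillna(stats)
            Xte = Xte.fillna(stats)
            clf = RandomForestClassifier(
                random_state=int(rng.integers(0, 2 ** 31 - 1)), **self.rf_params)
            clf.fit(Xtr.to_numpy(), y[tr])
            scores = clf.predict_proba(Xte.to_numpy())[:, 1]
            aucs[r] = roc_auc_score(y[te], scores)
            fpr, tpr, _ = roc_curve(y[te], scores)
            tprs += np.interp(grid, fpr, tpr)
            imps += clf.feature_importances_
            imps2 += clf.feature_importances_ ** 2
        imp_mean = imps / n_rounds
        imp_sd = np.sqrt(np.maximum(imps2 / n_rounds - imp_mean ** 2, 0.0))
        total = imp_mean.sum()
        if total > 0:
            imp_mean = imp_mean / total
        importances = pd.DataFrame({"mean": imp_mean, "sd": imp_sd}, index=self.columns)
        importances = importances.sort_values("mean", ascending=False)
        mean_roc = pd.DataFrame({"fpr": grid, "tpr": tprs / n_rounds})
        mean_roc.loc[0, "tpr"] = 0.0
        return PredictionReport(
            feature_set=self.feature_set, aucs=aucs, mean_roc=mean_roc,
            importances=importances, n_rounds=n_rounds, n_train=n_train,
            n_test=n_test, seed=seed)


def rf_resample_evaluate(ft: FeatureTable, feature_set: str = "all",
                         n_rounds: int = 1000, n_train: int = 69,
                         n_test: int = 30, rf_params: dict | None = None,
                         seed: int = 0) -> PredictionReport:
    """Evaluate a random forest over *n_rounds* random train/test splits."""
    return ResampledForest(ft, feature_set, rf_params).fit(
        n_rounds=n_rounds, n_train=n_train, n_test=n_test, seed=seed)


def feature_importance_report(report: PredictionReport) -> pd.DataFrame:
    """Features ranked by mean impurity importance (normalized to sum 1)."""
    out = report.importances.copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out
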