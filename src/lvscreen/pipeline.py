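"""Training procedure for the LVSD screening models.

The procedure mirrors a screening-model development protocol:

1. label subjects by an LVEF endpoint (below the sex-specific normal
   cutoff, 52% men / 54% women, or below 40%);
2. seeded stratified 70/30 train/test split (default split seed 9843587);
3. quantile-transform the real-valued features using the training set
   only; binary covariates pass through as 0/1 indicators;
4. select features by 20-fold shuffled cross-validation with three
   rankers — |L1-logistic coefficients|, gradient-boosting gain
   importance, and mean |SHAP| of the boosted model on held-out folds —
   taking the union of the three top-10 lists;
5. per architecture, small-grid hyperparameter search with 3-fold CV,
   isotonic calibration fitted on out-of-fold scores, and a decision
   threshold maximising the Youden index on the training set;
6. a soft-voting ensemble averaging the members' calibrated
   probabilities, thresholded the same way.

The test partition is never touched by any fitting step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     cross_val_predict, train_test_split)
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import QuantileTransformer
from sklearn.svm import SVC

from .errors import LVScreenError
from .features import ALL_FEATURES

DEFAULT_SPLIT_SEED = 9_843_587
BINARY_FEATURES = ["male_gender", "smoking", "diabetes", "hypertension"]

ARCHITECTURES = ["lasso", "ridge", "svc", "random_forest", "extra_trees",
                 "gradient_boosting", "mlp"]


@dataclass(frozen=True)
class EndpointRule:
    """LVEF endpoint: below-normal (sex-specific) or below 40%."""

    endpoint_id: str            # "below_normal" | "below_40"
    male_cutoff: float
    female_cutoff: float

    @staticmethod
    def below_normal() -> "EndpointRule":
        return EndpointRule("below_normal", 52.0, 54.0)

    @staticmethod
    def below_40() -> "EndpointRule":
        return EndpointRule("below_40", 40.0, 40.0)

    @staticmethod
    def from_id(endpoint_id: str) -> "EndpointRule":
        if endpoint_id == "below_normal":
            return EndpointRule.below_normal()
        if endpoint_id == "below_40":
            return EndpointRule.below_40()
        raise LVScreenError(f"unknown endpoint {endpoint_id!r}")


def assign_labels(table: pd.DataFrame, rule: EndpointRule) -> pd.DataFrame:
    """Add a binary ``label`` column: 1 iff LVEF strictly below the cutoff.

    Rows missing sex (male_gender) or LVEF are dropped with a warning.
    """
    df = table.copy()
    ok = df["LVEF"].notna() & df["male_gender"].notna()
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} rows missing sex/LVEF rejected")
        df = df[ok]
    cutoff = np.where(df["male_gender"] == 1, rule.male_cutoff,
                      rule.female_cutoff)
    df["label"] = (df["LVEF"].to_numpy() < cutoff).astype(int)
    return df


def split_train_test(table: pd.DataFrame, test_fraction: float = 0.3,
                     seed: int = DEFAULT_SPLIT_SEED
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified split; test size = ceil(n * test_fraction)."""
    if len(table) < 20:
        raise LVScreenError("need at least 20 rows to split")
    n_test = int(np.ceil(len(table) * test_fraction))
    train, test = train_test_split(
        table, test_size=n_test, stratify=table["label"], random_state=seed)
    if train["label"].nunique() < 2 or test["label"].nunique() < 2:
        raise LVScreenError("a class is absent from one partition")
    return train, test


class Preprocessor:
    """Train-referenced normalisation: quantile maps + binary passthrough.

    Real-valued features are rank-normalised to [0, 1] with a
    QuantileTransformer fitted on the training set only; binary covariates
    are cast to {0,1}; features constant on the training set map to 0.5
    (with a warning). Missing values are imputed with the train median
    before the quantile map.
    """

    def __init__(self, feature_columns: list[str] | None = None) -> None:
        self.feature_columns = list(feature_columns or ALL_FEATURES)
        self.binary_cols = [c for c in self.feature_columns
                            if c in BINARY_FEATURES]
        self.numeric_cols = [c for c in self.feature_columns
                             if c not in BINARY_FEATURES]
        self._qt: QuantileTransformer | None = None
        self._constant: dict[str, float] = {}
        self._medians: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "Preprocessor":
        num = train[self.numeric_cols].astype(float)
        self._medians = num.median()
        num = num.fillna(self._medians)
        nunique = num.nunique()
        self._constant = {c: 0.5 for c in num.columns[nunique <= 1]}
        if self._constant:
            warnings.warn(
                f"constant features mapped to 0.5: {sorted(self._constant)}")
        self._active = [c for c in self.numeric_cols if c not in self._constant]
        self._qt = QuantileTransformer(
            n_quantiles=min(len(train), 1000), output_distribution="uniform",
            subsample=10**9, random_state=0)
        self._qt.fit(num[self._active].to_numpy())
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self._qt is None:
            raise LVScreenError("preprocessor not fitted")
        num = table[self.numeric_cols].astype(float).fillna(self._medians)
        out = pd.DataFrame(index=table.index)
        vals = self._qt.transform(num[self._active].to_numpy())
        for j, c in enumerate(self._active):
            out[c] = vals[:, j]
        for c, v in self._constant.items():
            out[c] = v
        for c in self.binary_cols:
            out[c] = table[c].astype(float).fillna(0.0).clip(0, 1).round()
        return out[self.feature_columns]


@dataclass
class SelectionResult:
    """Top-10 feature lists per ranking method and their union."""

    by_lasso: list[str]
    by_gain: list[str]
    by_shap: list[str]

    @property
    def union(self) -> list[str]:
        return sorted(set(self.by_lasso) | set(self.by_gain) | set(self.by_shap))


def _xgb(seed: int, **kw) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        n_estimators=kw.pop("n_estimators", 100),
        max_depth=kw.pop("max_depth", 3),
        learning_rate=kw.pop("learning_rate", 0.3),
        tree_method="hist", n_jobs=1, random_state=seed,
        eval_metric="logloss", **kw)


def select_features(X: pd.DataFrame, y: np.ndarray, n_folds: int = 20,
                    seed: int = 0, top_k: int = 10) -> SelectionResult:
    """Three-method feature selection with 20-fold shuffled CV.

    Per fold, an L1 logistic model and a gradient-boosted tree model are
    fitted on the fold's training part; importance scores (|coefficients|,
    boosting gain, and mean |SHAP value| of the boosted model evaluated on
    the held-out part) are averaged over folds before ranking.
    """
    cols = list(X.columns)
    if len(cols) < top_k:
        warnings.warn(f"only {len(cols)} candidate features; lists truncated")
    Xa, ya = X.to_numpy(), np.asarray(y).astype(int)
    min_class = int(np.bincount(ya).min())
    if min_class < n_folds:
        warnings.warn(f"minority class has {min_class} members; "
                      f"reducing selection CV folds from {n_folds}")
        n_folds = max(2, min_class)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    lasso_scores = np.zeros(len(cols))
    gain_scores = np.zeros(len(cols))
    shap_scores = np.zeros(len(cols))
    for tr, te in skf.split(Xa, ya):
        lr = LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                                max_iter=2000, random_state=seed)
        lr.fit(Xa[tr], ya[tr])
        lasso_scores += np.abs(lr.coef_[0])
        booster = _xgb(seed)
        booster.fit(Xa[tr], ya[tr])
        gain = booster.get_booster().get_score(importance_type="total_gain")
        for j in range(len(cols)):
            gain_scores[j] += gain.get(f"f{j}", 0.0)
        contrib = booster.get_booster().predict(
            xgb.DMatrix(Xa[te]), pred_contribs=True)
        shap_scores += np.mean(np.abs(contrib[:, :-1]), axis=0)
    k = min(top_k, len(cols))

    def top(scores: np.ndarray) -> list[str]:
        order = np.argsort(-scores, kind="stable")
        return [cols[j] for j in order[:k]]

    return SelectionResult(by_lasso=top(lasso_scores),
                           by_gain=top(gain_scores),
                           by_shap=top(shap_scores))


#: Small, fixed hyperparameter grids (<= 12 points per architecture).
GRIDS: dict[str, dict] = {
    "lasso": {"C": [0.01, 0.1, 1.0, 10.0]},
    "ridge": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svc": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
    "random_forest": {"max_depth": [None, 5], "min_samples_leaf": [1, 3]},
    "extra_trees": {"max_depth": [None, 5], "min_samples_leaf": [1, 3]},
    "gradient_boosting": {"max_depth": [2, 3], "learning_rate": [0.1, 0.3]},
    "mlp": {"hidden_layer_sizes": [(32,), (64,)], "alpha": [1e-3, 1e-2]},
}


def _base_estimator(architecture: str, seed: int):
    if architecture == "lasso":
        return LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                  max_iter=5000, random_state=seed)
    if architecture == "ridge":
        return LogisticRegression(l1_ratio=0.0, solver="liblinear",
                                  max_iter=5000, random_state=seed)
    if architecture == "svc":
        return SVC(kernel="rbf", random_state=seed)
    if architecture == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed,
                                      n_jobs=1)
    if architecture == "extra_trees":
        return ExtraTreesClassifier(n_estimators=300, random_state=seed,
                                    n_jobs=1)
    if architecture == "gradient_boosting":
        return _xgb(seed, n_estimators=200)
    if architecture == "mlp":
        # the network variant holds out 30% of train for early stopping
        return MLPClassifier(max_iter=1000, early_stopping=True,
                             validation_fraction=0.3, random_state=seed)
    raise LVScreenError(f"unknown architecture {architecture!r}")


def _raw_scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


@dataclass
class TrainedScreeningModel:
    """One fitted screening classifier with calibration and threshold."""

    architecture: str
    features: list[str]
    classifier: object
    calibrator: IsotonicRegression
    threshold: float
    preprocessor: Preprocessor | None = None
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Calibrated probability of the positive (reduced-EF) class."""
        X = (self.preprocessor.transform(table) if self.preprocessor
             else table)
        raw = _raw_scores(self.classifier, X[self.features].to_numpy())
        return self.calibrator.predict(raw)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table) >= self.threshold).astype(int)


@dataclass
class EnsembleModel:
    """Soft-voting ensemble: mean of member calibrated probabilities."""

    members: list[TrainedScreeningModel]
    threshold: float = 0.5

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if not self.members:
            raise LVScreenError("ensemble needs >= 1 member")
        return np.mean([m.predict_proba(table) for m in self.members], axis=0)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table) >= self.threshold).astype(int)


def pick_threshold_youden(labels: np.ndarray, probabilities: np.ndarray
                          ) -> tuple[float, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    Candidate cutpoints are the midpoints of sorted unique probabilities;
    ties are broken toward the higher threshold (higher specificity).
    Returns (threshold, J at threshold).
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise LVScreenError("Youden threshold needs both classes")
    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    # degenerate cuts (everything positive / everything negative) give the
    # J = 0 floor and are legal screening thresholds
    cands = np.concatenate([[uniq[0]], mids,
                            [np.nextafter(uniq[-1], np.inf)]])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    best_t, best_j = cands[0], -np.inf
    for t in cands:                      # ascending: later wins ties -> higher t
        pred = p >= t
        sens = np.sum(pred & (y == 1)) / n_pos
        spec = np.sum(~pred & (y == 0)) / n_neg
        j = sens + spec - 1.0
        if j >= best_j:
            best_j, best_t = j, float(t)
    if best_j <= 0:
        warnings.warn("Youden index <= 0: scores do not separate the classes")
    return best_t, float(best_j)


def train_model(train_X: pd.DataFrame, train_y: np.ndarray,
                architecture: str, features: list[str],
                n_folds: int = 3, seed: int = 0,
                preprocessor: Preprocessor | None = None
                ) -> TrainedScreeningModel:
    """Grid-searched, isotonic-calibrated, Youden-thresholded classifier.

    ``train_X`` must already be preprocessed. Hyperparameters come from a
    fixed small grid via stratified 3-fold CV (ROC AUC); the isotonic
    calibrator is fitted on out-of-fold scores of the selected
    configuration, then the classifier is refitted on the full training
    set and the decision threshold maximises the Youden index on train.
    """
    y = np.asarray(train_y).astype(int)
    if len(np.unique(y)) < 2:
        raise LVScreenError("training set has a single class")
    X = train_X[features].to_numpy()
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(_base_estimator(architecture, seed), GRIDS[architecture],
                      cv=cv, scoring="roc_auc", n_jobs=1, refit=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gs.fit(X, y)
    best = _base_estimator(architecture, seed).set_params(**gs.best_params_)
    method = ("predict_proba" if hasattr(best, "predict_proba")
              else "decision_function")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oof = cross_val_predict(best, X, y, cv=cv, method=method, n_jobs=1)
    oof_scores = oof[:, 1] if oof.ndim == 2 else oof
    calibrator = IsotonicRegression(y_min=0.0, y_max=1.0,
                                    out_of_bounds="clip")
    calibrator.fit(oof_scores, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best.fit(X, y)
    probs = calibrator.predict(_raw_scores(best, X))
    threshold, j = pick_threshold_youden(y, probs)
    return TrainedScreeningModel(
        architecture=architecture, features=list(features), classifier=best,
        calibrator=calibrator, threshold=threshold,
        preprocessor=preprocessor,
        metadata={"seed": seed, "n_folds": n_folds,
                  "best_params": gs.best_params_, "train_youden_j": j})


@dataclass
class TrainingRun:
    """Everything produced by one end-to-end training procedure."""

    endpoint: EndpointRule
    selection: SelectionResult
    preprocessor: Preprocessor
    models: dict[str, TrainedScreeningModel]
    ensemble: EnsembleModel
    train: pd.DataFrame
    test: pd.DataFrame


def run_training(table: pd.DataFrame, endpoint: EndpointRule,
                 architectures: list[str] | None = None,
                 seed: int = 0, split_seed: int = DEFAULT_SPLIT_SEED,
                 feature_columns: list[str] | None = None) -> TrainingRun:
    """The full training procedure on a labelled-able feature table."""
    architectures = architectures or ARCHITECTURES
    labelled = assign_labels(table, endpoint)
    train, test = split_train_test(labelled, seed=split_seed)
    pre = Preprocessor(feature_columns).fit(train)
    Xtr = pre.transform(train)
    ytr = train["label"].to_numpy()
    selection = select_features(Xtr, ytr, seed=seed)
    models = {}
    for arch in architectures:
        models[arch] = train_model(Xtr, ytr, arch, selection.union,
                                   seed=seed, preprocessor=pre)
    member_probs = np.mean(
        [m.predict_proba(train) for m in models.values()], axis=0)
    ens_threshold, _ = pick_threshold_youden(ytr, member_probs)
    ensemble = EnsembleModel(members=list(models.values()),
                             threshold=ens_threshold)
    return TrainingRun(endpoint=endpoint, selection=selection,
                       preprocessor=pre, models=models, ensemble=ensemble,
                       train=train, test=test)
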