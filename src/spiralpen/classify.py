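"""Leave-one-out classification of patients vs controls and per-indicator
attribution.

Four model families are exposed behind one interface: a logistic-regression
reference, a random forest and two gradient-boosted tree flavors
(LightGBM and XGBoost).  Evaluation is leave-one-out cross-validation
(LOOCV) — appropriate at cohort sizes of a few dozen — with the patient
group as the positive class.  When classification is restricted to the
statistically significant indicators ("subset 2"), the significant set is
recomputed inside every fold on the training subjects only, so the held-out
subject never influences its own feature selection.

Attribution is Shapley-based for the tree ensembles (the exact TreeSHAP
values computed by the boosting libraries themselves) and
coefficient-times-standardized-value for the linear reference; positive
values push the prediction toward the patient class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import ALL_INDICATORS
from .stats import significant_indicators

MODELS = ("lr", "rf", "lgbm", "xgb")
SUBSETS = ("all_45", "significant")

POSITIVE_GROUP = "PD"


def _build_model(name: str, seed: int):
    if name == "lr":
        return Pipeline([
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=5000, random_state=seed)),
        ])
    if name == "rf":
        return Pipeline([
            ("impute", SimpleImputer(strategy="median")),
            ("clf", RandomForestClassifier(n_estimators=300, random_state=seed)),
        ])
    if name == "lgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(n_estimators=200, learning_rate=0.1,
                              min_child_samples=5, random_state=seed,
                              verbosity=-1)
    if name == "xgb":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=200, learning_rate=0.1, max_depth=3,
                             random_state=seed, eval_metric="logloss")
    raise ValueError(f"unknown model {name!r}; choose from {MODELS}")


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, precision, recall and f1 from confusion counts.

    f1 is the harmonic mean 2PR/(P+R); all four are exact functions of the
    counts (fractions in [0, 1]).
    """
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total if total else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    if np.isfinite(precision) and np.isfinite(recall) and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan")
    return {"accuracy": accuracy, "precision": precision,
            "recall": recall, "f1": f1}


@dataclass
class ClassificationReport:
    """Pooled LOOCV outcome for one model / indicator subset."""

    model: str
    subset: str
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    predictions: pd.DataFrame = field(repr=False)  # subject_id, truth, predicted
    seed: int = 0


def _feature_matrix(table: pd.DataFrame,
                    indicators: list[str] | None = None
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    if indicators is None:
        indicators = [c for c in table.columns if c in ALL_INDICATORS]
    X = table[indicators].apply(pd.to_numeric, errors="coerce")
    X = X.loc[:, X.notna().any()]  # drop all-missing indicators
    y = (table["group"] == POSITIVE_GROUP).to_numpy()
    return X, y


def loocv_classify(table: pd.DataFrame, model: str = "lgbm",
                   subset: str = "all_45", alpha: float = 0.05,
                   seed: int = 0) -> ClassificationReport:
    """Leave-one-out classification of the cohort table.

    ``subset="significant"`` restricts each fold to the indicators that
    differ between groups (p < ``alpha``) in that fold's training subjects;
    a fold whose training selection comes back empty falls back to all
    indicators.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; choose from {SUBSETS}")
    X, y = _feature_matrix(table)
    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 subjects for LOOCV")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    preds = np.zeros(n, dtype=bool)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if not (y[train].any() and (~y[train]).any()):
            raise ValueError("a training fold contains one class only")
        cols = list(X.columns)
        if subset == "significant":
            sel = significant_indicators(table.iloc[train], alpha=alpha,
                                         indicators=cols)
            if sel:
                cols = sel
        clf = _build_model(model, seed)
        clf.fit(X.iloc[train][cols], y[train])
        preds[i] = bool(clf.predict(X.iloc[[i]][cols])[0])

    tp = int(np.sum(preds & y))
    fp = int(np.sum(preds & ~y))
    tn = int(np.sum(~preds & ~y))
    fn = int(np.sum(~preds & y))
    m = metrics_from_counts(tp, fp, tn, fn)
    pred_df = pd.DataFrame({
        "subject_id": table["subject_id"].to_numpy(),
        "truth": np.where(y, POSITIVE_GROUP, "control"),
        "predicted": np.where(preds, POSITIVE_GROUP, "control"),
    })
    return ClassificationReport(model=model, subset=subset, tp=tp, fp=fp,
                                tn=tn, fn=fn, predictions=pred_df, seed=seed,
                                **m)


@dataclass
class AttributionSummary:
    """Per-subject, per-indicator signed attributions for one fitted model.

    ``values[i, j]`` pushes subject ``i`` toward the patient class when
    positive; ``values.sum(axis=1) + base`` reproduces the model's raw
    margin (log-odds) for the tree backends.
    """

    model: str
    indicators: list[str]
    values: np.ndarray          # (n_subjects, n_indicators)
    base: float
    feature_values: pd.DataFrame = field(repr=False)
    subject_ids: list[str] = field(default_factory=list)

    @property
    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0),
                         index=self.indicators).sort_values(ascending=False)

    @property
    def ranks(self) -> pd.Series:
        """1 = most influential; a permutation of 1..p."""
        ma = pd.Series(np.abs(self.values).mean(axis=0), index=self.indicators)
        return ma.rank(ascending=False, method="first").astype(int)


def attribute(table: pd.DataFrame, model: str = "lgbm",
              indicators: list[str] | None = None,
              seed: int = 0) -> AttributionSummary:
    """Fit ``model`` on the full table and attribute its decisions.

    Tree ensembles (``lgbm``, ``xgb``) use their exact built-in Shapley
    value computation on the margin scale; the logistic reference uses
    coefficient x standardized value.  Random forest has no exact Shapley
    backend here: an error names the supported models.
    """
    X, y = _feature_matrix(table, indicators)
    cols = list(X.columns)
    clf = _build_model(model, seed)
    clf.fit(X, y)
    if model == "lgbm":
        contrib = clf.predict(X, pred_contrib=True)
        values, base = contrib[:, :-1], float(contrib[0, -1])
    elif model == "xgb":
        from xgboost import DMatrix
        contrib = clf.get_booster().predict(DMatrix(X), pred_contribs=True)
        values, base = contrib[:, :-1], float(contrib[0, -1])
    elif model == "lr":
        z = clf.named_steps["scale"].transform(
            clf.named_steps["impute"].transform(X))
        coef = clf.named_steps["clf"].coef_[0]
        values = z * coef
        base = float(clf.named_steps["clf"].intercept_[0])
    else:
        raise ValueError(
            f"attribution not supported for {model!r}; supported backends: "
            "lgbm, xgb (TreeSHAP), lr (linear)")
    return AttributionSummary(model=model, indicators=cols,
                              values=np.asarray(values), base=base,
                              feature_values=X,
                              subject_ids=list(table["subject_id"]))
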