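"""Transparent logistic models and the baseline comparison harness.

The EL-LR model refits a plain maximum-likelihood logistic regression on
the small feature subset selected by the evolutionary search, yielding a
closed-form risk score (a printable formula) at essentially the same
discrimination as the SVM that found the subset.

A registry ships the four published visit-level formulas (cognitive/motor
delay at 12 months, cognitive/motor score regression at 6 months) as data.
Baselines (lasso, logistic regression, linear SVM, random forest) are a
harness over scikit-learn estimators tuned by repeated stratified CV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import LabeledCohort
from .errors import ConfigurationError, InvalidInputError, SchemaError
from .metrics import MetricsReport, evaluate_scores

__all__ = [
    "ELLRModel",
    "BaselineSpec",
    "fit_el_lr",
    "predict_logit",
    "load_published_model",
    "published_model_names",
    "run_baselines",
]


@dataclass
class ELLRModel:
    """A logistic formula: intercept plus ordered (feature, coefficient) terms.

    ``input_scaling`` declares the normalisation the inputs must carry
    before entering the linear predictor ("none" for freshly fitted models,
    "minmax_unit" for the published registry formulas).
    """

    outcome: str
    intercept: float
    terms: list[tuple[str, float]]
    input_scaling: str = "none"
    separation_flag: bool = False
    conf_int: Optional[pd.DataFrame] = None  # statsmodels 95% Wald CIs, when fitted
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.terms]

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(self.terms)

    def linear_predictor(self, record: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        if isinstance(record, pd.DataFrame):
            missing = [f for f in self.features if f not in record.columns]
            if missing:
                raise InvalidInputError(f"record lacks model features: {missing}")
            eta = np.full(len(record), self.intercept, dtype=float)
            for f, c in self.terms:
                eta += c * record[f].to_numpy(dtype=float)
            return eta
        missing = [f for f in self.features if f not in record]
        if missing:
            raise InvalidInputError(f"record lacks model features: {missing}")
        return np.asarray(
            self.intercept + sum(c * float(record[f]) for f, c in self.terms)
        )

    def model_card(self) -> dict:
        return {
            "model": "EL-LR",
            "outcome": self.outcome,
            "intercept": self.intercept,
            "terms": [[f, c] for f, c in self.terms],
            "input_scaling": self.input_scaling,
            "separation_flag": self.separation_flag,
        }


def predict_logit(model: ELLRModel, record: Mapping[str, float] | pd.DataFrame):
    """Predicted outcome probability p = 1 / (1 + exp(-(b0 + sum b_j x_j))).

    Inputs must already be on the scale declared by ``model.input_scaling``.
    """
    eta = model.linear_predictor(record)
    p = 1.0 / (1.0 + np.exp(-eta))
    if np.ndim(p) == 0:
        return float(p)
    return p


def fit_el_lr(data: LabeledCohort, features: Sequence[str]) -> ELLRModel:
    """Maximum-likelihood logistic regression on a restricted feature set.

    Coefficients are in logit units on the raw feature scale.  Perfect or
    quasi-perfect separation is flagged and resolved with a ridge-penalised
    fallback fit so a usable (if shrunken) formula is always returned.
    """
    feats = list(features)
    missing = [f for f in feats if f not in data.features.columns]
    if missing:
        raise SchemaError(f"features not in cohort: {missing}")
    X = data.features[feats].to_numpy(dtype=float)
    y = data.labels.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes required to fit a logistic model")
    Xc = sm.add_constant(X, has_constant="add")

    separated = False
    params = None
    conf = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.ConvergenceWarning)
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            if not np.all(np.isfinite(res.bse)) or np.abs(params).max() > 1e3:
                separated = True
            else:
                conf = pd.DataFrame(
                    res.conf_int(), index=["const"] + feats, columns=["low", "high"]
                )
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
                np.linalg.LinAlgError):
            separated = True

    if separated or params is None:
        ridge = LogisticRegression(C=1.0, max_iter=2000)
        ridge.fit(X, y)
        params = np.concatenate([ridge.intercept_, ridge.coef_.ravel()])
        separated = True

    return ELLRModel(
        outcome=data.outcome.name,
        intercept=float(params[0]),
        terms=[(f, float(c)) for f, c in zip(feats, params[1:])],
        input_scaling="none",
        separation_flag=separated,
        conf_int=conf,
    )


# ---------------------------------------------------------------------------
# Published registry
# ---------------------------------------------------------------------------


def _load_registry() -> dict:
    text = resources.files("elndi.data").joinpath("published_models.json").read_text()
    return json.loads(text)


def published_model_names() -> list[str]:
    return list(_load_registry()["models"].keys())


def load_published_model(name: str) -> ELLRModel:
    """Return one of the four published visit-level logistic formulas.

    Coefficients are reproduced exactly as printed; the registry declares
    min-max [0,1] input normalisation as an explicit assumption (the source
    does not state the covariate scaling).
    """
    registry = _load_registry()
    try:
        entry = registry["models"][name]
    except KeyError:
        raise SchemaError(
            f"unknown model {name!r}; expected one of {list(registry['models'])}"
        )
    return ELLRModel(
        outcome=name,
        intercept=float(entry["intercept"]),
        terms=[(f, float(c)) for f, c, _desc in entry["terms"]],
        input_scaling=registry["input_scaling"],
        descriptions={f: d for f, _c, d in entry["terms"]},
    )


# ---------------------------------------------------------------------------
# Baseline harness
# ---------------------------------------------------------------------------

_FAMILIES = ("lasso", "logistic", "linear-svm", "random-forest")


@dataclass
class BaselineSpec:
    """Tuning plan for the comparison families (harness over scikit-learn)."""

    families: tuple[str, ...] = _FAMILIES
    feature_strategy: str = "coarse-to-fine"  # or "all-features-in"
    cv_folds: int = 10
    cv_repeats: int = 5
    grids: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [f for f in self.families if f not in _FAMILIES]
        if unknown:
            raise ConfigurationError(f"unknown baseline families: {unknown}")


def _make_estimator(family: str, spec: BaselineSpec):
    seed = spec.seed % (2**31)
    if family == "lasso":
        est = Pipeline(
            [("scale", StandardScaler()),
             ("clf", LogisticRegression(solver="liblinear", l1_ratio=1.0, max_iter=2000))]
        )
        grid = spec.grids.get(family, {"clf__C": [0.01, 0.1, 1.0, 10.0]})
    elif family == "logistic":
        est = Pipeline(
            [("scale", StandardScaler()),
             ("clf", LogisticRegression(C=np.inf, max_iter=2000))]
        )
        grid = spec.grids.get(family, {})
    elif family == "linear-svm":
        est = Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="linear"))]
        )
        grid = spec.grids.get(family, {"clf__C": [0.01, 0.1, 1.0, 10.0]})
    else:  # random-forest
        est = RandomForestClassifier(n_estimators=300, random_state=seed)
        grid = spec.grids.get(family, {"max_features": ["sqrt", None]})
    if not grid:
        return est, None
    cv = RepeatedStratifiedKFold(
        n_splits=spec.cv_folds, n_repeats=spec.cv_repeats, random_state=seed
    )
    return GridSearchCV(est, grid, cv=cv, scoring="roc_auc", n_jobs=1), grid


def _scores(fitted, X: np.ndarray) -> np.ndarray:
    if hasattr(fitted, "predict_proba"):
        return fitted.predict_proba(X)[:, 1]
    raw = fitted.decision_function(X)
    return 1.0 / (1.0 + np.exp(-raw))  # squash to (0,1) so threshold 0.5 applies


def run_baselines(
    development: LabeledCohort, test: LabeledCohort, spec: BaselineSpec
) -> dict[str, MetricsReport]:
    """Tune each family on the development cohort, evaluate on held-out data.

    Returns a MetricsReport per family (threshold 0.5 on the probability
    scale, AUC with DeLong CI).  All estimators are established
    scikit-learn implementations; this function only orchestrates.
    """
    Xd = development.features.to_numpy(dtype=float)
    yd = development.labels.to_numpy(dtype=int)
    Xt = test.features[development.features.columns].to_numpy(dtype=float)
    yt = test.labels.to_numpy(dtype=int)
    reports = {}
    for family in spec.families:
        search, _ = _make_estimator(family, spec)
        search.fit(Xd, yd)
        fitted = search.best_estimator_ if isinstance(search, GridSearchCV) else search
        reports[family] = evaluate_scores(_scores(fitted, Xt), yt, seed=spec.seed)
    return reports
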