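"""Synthetic very-preterm-infant cohorts with known ground truth.

The generator emulates the statistical shape of a national VPI follow-up
registry: gestational age around 28 +/- 2 weeks, birth weight 401-1500 g
correlated with gestational age, a mix of continuous and binary clinical
predictors with configurable missingness, and longitudinally correlated
Bayley (BSID-III) composite scores at the 6-, 12- and 24-month visits.

A single latent logistic risk links everything: configured informative
features shift the risk through their log-odds coefficients, and each
Bayley score is pulled down in proportion to the risk.  Score noise splits
into a shared per-subject shift plus per-visit measurement noise, totalling
about 15 points (the composite-score SD).  Both outcome families therefore
fire on the same latent liability - threshold outcomes (score < 85 at 24
months) and decline outcomes (drop >= 15 points from 6 to 24 months) - and
the 6/12-month scores are, by construction, the strongest predictors, as
observed on real follow-up data.  The intercept of the risk model is
calibrated so the 24-month cognitive threshold outcome hits
``prevalence_target`` in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
import json

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortTable, VariableSpec, bayley_column
from .errors import ConfigurationError, ConvergenceError, InvalidInputError

#: default informative clinical features: (name, kind, visit, log-odds coefficient)
DEFAULT_INFORMATIVE: tuple[tuple[str, str, str, float], ...] = (
    ("ippv_days", "continuous", "hospitalization", 1.2),
    ("ivh_severe", "binary", "hospitalization", 1.4),
    ("neonatal_sepsis", "binary", "hospitalization", 1.1),
)

#: risk-to-score effect (points of composite score per unit risk) per visit
DEFAULT_SCORE_EFFECTS: dict[str, float] = {"6m": 14.0, "12m": 24.0, "24m": 34.0}


@dataclass
class SimConfig:
    n_subjects: int = 600
    n_noise_features: int = 25
    informative: tuple[tuple[str, str, str, float], ...] = DEFAULT_INFORMATIVE
    prevalence_target: float = 0.16
    missing_rate: float = 0.0
    score_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCORE_EFFECTS))
    score_baseline: float = 106.0  # zero-risk mean composite score
    score_noise_sd: float = 11.0  # per-visit measurement noise
    subject_sd: float = 10.0  # shared per-subject shift; total score SD ~= 15
    motor_scale: float = 1.15  # motor risk loading relative to cognitive
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_target < 1:
            raise ConfigurationError("prevalence_target must lie in (0, 1)")
        if not 0 <= self.missing_rate <= 0.9:
            raise ConfigurationError("missing_rate must lie in [0, 0.9]")


@dataclass
class GroundTruth:
    risk: np.ndarray  # latent P(outcome-liability) per subject
    linear_predictor: np.ndarray
    informative_features: list[str]
    coefficients: dict[str, float]
    intercept: float


_NOISE_VISITS = ("birth", "admission", "discharge", "6m", "12m")


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort plus the ground truth that generated it.

    Deterministic given ``config.seed``.  Raises ConvergenceError if no
    intercept can reach the requested prevalence (e.g. a target of 0.9
    with score effects too weak to push scores below threshold).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # perinatal frame: GA ~ N(28, 2) truncated to the VPI window, BW correlated
    ga = stats.truncnorm.rvs(
        (22.0 - 28.0) / 2.0, (31.86 - 28.0) / 2.0, loc=28.0, scale=2.0,
        size=n, random_state=rng,
    )
    bw_mean = 401.0 + (1500.0 - 401.0) * (ga - 22.0) / (31.86 - 22.0)
    bw = np.clip(bw_mean + rng.normal(0.0, 150.0, n), 401.0, 1500.0)
    male = rng.binomial(1, 0.51, n).astype(float)

    columns: dict[str, np.ndarray] = {"ga_weeks": ga, "bbw_g": bw, "male": male}
    dictionary = [
        VariableSpec("ga_weeks", "continuous", "birth", "weeks"),
        VariableSpec("bbw_g", "continuous", "birth", "g"),
        VariableSpec("male", "binary", "birth"),
    ]

    # informative predictors drive the latent risk
    eta = np.zeros(n)
    coefficients: dict[str, float] = {}
    for name, kind, visit, coef in config.informative:
        if kind == "binary":
            x = rng.binomial(1, 0.25, n).astype(float)
            eta += coef * x
        else:
            x = rng.normal(0.0, 1.0, n)
            eta += coef * x
        columns[name] = x
        dictionary.append(VariableSpec(name, kind, visit))
        coefficients[name] = coef

    for i in range(config.n_noise_features):
        name = f"noise_{i:02d}"
        visit = _NOISE_VISITS[i % len(_NOISE_VISITS)]
        if i % 3 == 2:
            x = rng.binomial(1, 0.3, n).astype(float)
            kind = "binary"
        else:
            x = rng.normal(0.0, 1.0, n)
            kind = "continuous"
        columns[name] = x
        dictionary.append(VariableSpec(name, kind, visit))

    # calibrate the risk intercept so the 24m cognitive threshold outcome
    # has the requested expected prevalence
    sd_total = float(np.hypot(config.score_noise_sd, config.subject_sd))
    e24 = config.score_effects["24m"]

    def expected_prevalence(alpha: float) -> float:
        risk = 1.0 / (1.0 + np.exp(-(alpha + eta)))
        mu24 = config.score_baseline - e24 * risk
        return float(np.mean(stats.norm.cdf((85.0 - mu24) / sd_total)))

    lo, hi = -30.0, 30.0
    target = config.prevalence_target
    if not expected_prevalence(lo) < target < expected_prevalence(hi):
        raise ConvergenceError(
            f"prevalence target {target} unreachable with score effect {e24}"
        )
    alpha = float(optimize.brentq(lambda a: expected_prevalence(a) - target, lo, hi))
    risk = 1.0 / (1.0 + np.exp(-(alpha + eta)))

    # Bayley trajectories: shared latent risk + per-subject shift + noise
    for scale, loading in (("cognitive", 1.0), ("motor", config.motor_scale)):
        subject_shift = rng.normal(0.0, config.subject_sd, n)
        for visit, effect in config.score_effects.items():
            score = (
                config.score_baseline
                - loading * effect * risk
                + subject_shift
                + rng.normal(0.0, config.score_noise_sd, n)
            )
            col = bayley_column(scale, visit)
            columns[col] = score
            dictionary.append(VariableSpec(col, "score", visit, "BSID-III composite"))

    data = pd.DataFrame(columns, index=pd.RangeIndex(n, name="subject_id"))
    cohort = CohortTable(data, dictionary)
    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate, seed=int(rng.integers(2**31)))
    truth = GroundTruth(
        risk=risk,
        linear_predictor=alpha + eta,
        informative_features=[name for name, *_ in config.informative],
        coefficients=coefficients,
        intercept=alpha,
    )
    return cohort, truth


#: Bayley columns that define outcomes; never masked by inject_missingness
PROTECTED_COLUMNS = tuple(
    bayley_column(s, v) for s in ("cognitive", "motor") for v in ("6m", "24m")
)


def inject_missingness(cohort: CohortTable, rate: float, seed: int = 0) -> CohortTable:
    """Mask cells completely at random at ``rate`` per maskable variable.

    Outcome-defining Bayley columns (6- and 24-month scores) are never
    masked, so the labellers stay total on generated data.
    """
    if not 0 <= rate < 1:
        raise InvalidInputError("rate must lie in [0, 1)")
    if rate == 0:
        return cohort
    rng = np.random.default_rng(seed)
    data = cohort.data.copy()
    for col in data.columns:
        if col in PROTECTED_COLUMNS:
            continue
        mask = rng.random(len(data)) < rate
        data.loc[mask, col] = np.nan
    return CohortTable(data, list(cohort.dictionary.values()))


# ---------------------------------------------------------------------------
# Plain logistic draws (for coefficient-recovery and ranking oracles)
# ---------------------------------------------------------------------------


def simulate_logistic(
    n: int,
    coefficients: dict[str, float],
    intercept: float = 0.0,
    n_noise: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Labels ~ Bernoulli(sigmoid(b0 + sum b_j x_j)), x_j ~ N(0, 1).

    A direct generating process for tests that must recover known
    coefficients or coefficient orderings exactly.
    """
    rng = np.random.default_rng(seed)
    names = list(coefficients) + [f"noise_{i:02d}" for i in range(n_noise)]
    X = pd.DataFrame(
        rng.normal(0.0, 1.0, (n, len(names))), columns=names,
        index=pd.RangeIndex(n, name="subject_id"),
    )
    eta = intercept + sum(c * X[f].values for f, c in coefficients.items())
    y = pd.Series(
        rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))), index=X.index, name="label"
    )
    return X, y, dict(coefficients)


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "informative_features": truth.informative_features,
        "coefficients": truth.coefficients,
        "intercept": truth.intercept,
        "risk": truth.risk.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
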