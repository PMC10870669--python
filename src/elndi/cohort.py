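"""Cohort data model, outcome labellers and visit-horizon feature assembly.

A cohort is a subjects x variables table with an explicit variable
dictionary.  Each variable carries a *visit* tag (birth, admission,
hospitalization, discharge, 6m, 12m, 24m) so that models developed for an
early follow-up visit can be prevented from seeing data collected later.

Four neurodevelopmental-impairment outcomes are supported, all defined on
Bayley Scales of Infant Development 3rd edition (BSID-III) composite scores
(population mean 100, SD 15):

* delay models (``CDelay``, ``MDelay``): composite score < 85 at the
  24-month corrected-age visit; predictors may use data up to 12 months.
* regression models (``CRegres``, ``MRegres``): a decline of >= 15 points
  (one SD) between the 6- and 24-month visits; predictors up to 6 months.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, SchemaError

#: Chronological ordering of visit tags; later tags may not feed earlier models.
VISIT_ORDER: tuple[str, ...] = (
    "birth",
    "admission",
    "hospitalization",
    "discharge",
    "6m",
    "12m",
    "24m",
)

VARIABLE_KINDS: tuple[str, ...] = ("continuous", "binary", "ordinal", "score")


def visit_index(visit: str) -> int:
    try:
        return VISIT_ORDER.index(visit)
    except ValueError:
        raise SchemaError(f"unknown visit tag {visit!r}; expected one of {VISIT_ORDER}")


@dataclass(frozen=True)
class VariableSpec:
    """One entry of the variable dictionary."""

    name: str
    kind: str
    visit: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise SchemaError(f"unknown variable kind {self.kind!r}")
        visit_index(self.visit)  # validates


def bayley_column(scale: str, visit: str) -> str:
    """Canonical column name for a BSID-III composite score, e.g. ``bsid_cog_24m``."""
    short = {"cognitive": "cog", "motor": "mot"}[scale]
    return f"bsid_{short}_{visit}"


class CohortTable:
    """Subjects x variables table with a dictionary and missingness mask.

    Missing cells are represented as NaN in the underlying DataFrame; the
    boolean mask is derived from it, so a cell is either valued or missing,
    never both.
    """

    def __init__(self, data: pd.DataFrame, dictionary: Sequence[VariableSpec]):
        names = [v.name for v in dictionary]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in dictionary")
        missing = [c for c in data.columns if c not in set(names)]
        if missing:
            raise SchemaError(f"columns without dictionary entry: {missing}")
        self.data = data.astype(float)
        self.dictionary: dict[str, VariableSpec] = {v.name: v for v in dictionary if v.name in data.columns}

    # -- basic protocol ----------------------------------------------------
    @property
    def subjects(self) -> pd.Index:
        return self.data.index

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def __len__(self) -> int:
        return len(self.data)

    def spec(self, name: str) -> VariableSpec:
        return self.dictionary[name]

    def subset(self, columns: Iterable[str]) -> "CohortTable":
        cols = list(columns)
        return CohortTable(self.data[cols], [self.dictionary[c] for c in cols])

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, data_path: str | Path, dict_path: str | Path) -> None:
        self.data.to_csv(data_path, index_label="subject_id")
        entries = [
            {"name": v.name, "kind": v.kind, "visit": v.visit, "units": v.units}
            for v in self.dictionary.values()
        ]
        Path(dict_path).write_text(json.dumps(entries, indent=1, sort_keys=True))

    @classmethod
    def from_csv(cls, data_path: str | Path, dict_path: str | Path) -> "CohortTable":
        data = pd.read_csv(data_path, index_col="subject_id")
        entries = json.loads(Path(dict_path).read_text())
        dictionary = [VariableSpec(**e) for e in entries]
        return cls(data, dictionary)


@dataclass(frozen=True)
class OutcomeSpec:
    """Definition of one neurodevelopmental-impairment outcome.

    ``rule`` is ``"threshold"`` (score at 24 months below ``cutoff``) or
    ``"decline"`` (drop of at least ``sd_points`` between 6 and 24 months).
    ``horizon`` is the latest visit whose variables may serve as predictors.
    """

    name: str
    scale: str  # "cognitive" | "motor"
    rule: str  # "threshold" | "decline"
    horizon: str
    cutoff: float = 85.0
    sd_points: float = 15.0

    def __post_init__(self) -> None:
        if self.scale not in ("cognitive", "motor"):
            raise SchemaError(f"unknown scale {self.scale!r}")
        if self.rule not in ("threshold", "decline"):
            raise SchemaError(f"unknown rule {self.rule!r}")
        if self.rule == "threshold" and self.horizon != "12m":
            raise SchemaError("delay (threshold) models use predictors up to 12m")
        if self.rule == "decline" and self.horizon != "6m":
            raise SchemaError("regression (decline) models use predictors up to 6m")

    @property
    def required_columns(self) -> tuple[str, ...]:
        if self.rule == "threshold":
            return (bayley_column(self.scale, "24m"),)
        return (bayley_column(self.scale, "6m"), bayley_column(self.scale, "24m"))


#: The four visit-level models: delay at 12 months, score regression at 6 months.
OUTCOMES: dict[str, OutcomeSpec] = {
    "CDelay": OutcomeSpec("CDelay", "cognitive", "threshold", "12m"),
    "MDelay": OutcomeSpec("MDelay", "motor", "threshold", "12m"),
    "CRegres": OutcomeSpec("CRegres", "cognitive", "decline", "6m"),
    "MRegres": OutcomeSpec("MRegres", "motor", "decline", "6m"),
}


@dataclass
class LabeledCohort:
    """Feature matrix plus binary outcome labels for one outcome definition."""

    features: pd.DataFrame
    labels: pd.Series
    outcome: OutcomeSpec
    dictionary: dict[str, VariableSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise SchemaError("features and labels must share the subject index")
        vals = set(pd.unique(self.labels))
        if not vals <= {0, 1}:
            raise SchemaError(f"labels must be binary 0/1, got {sorted(vals)}")
        self.labels = self.labels.astype(int)

    @property
    def subjects(self) -> pd.Index:
        return self.features.index

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def take(self, subjects: pd.Index) -> "LabeledCohort":
        return LabeledCohort(
            self.features.loc[subjects], self.labels.loc[subjects], self.outcome, self.dictionary
        )


# ---------------------------------------------------------------------------
# Growth references and anthropometric z-binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthReference:
    """Seven z-score cut points (-3Z .. +3Z) for one measure/visit/sex cell.

    The tables shipped with the package are synthetic stand-ins with
    plausible magnitudes; production use should load the INTERGROWTH-21st
    (admission/discharge) and WHO (6m/12m) charts through the same interface.
    """

    measure: str
    context: str
    sex: str
    z_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.z_edges) != 7:
            raise InvalidInputError("a growth reference needs exactly 7 cut points")
        if not all(a < b for a, b in zip(self.z_edges, self.z_edges[1:])):
            raise InvalidInputError("z_edges must be strictly increasing")


def load_growth_references(path: str | Path) -> dict[tuple[str, str, str], GrowthReference]:
    """Load a reference table CSV with columns measure, context, sex, edge_1..edge_7."""
    df = pd.read_csv(path)
    refs = {}
    for _, row in df.iterrows():
        edges = tuple(float(row[f"edge_{i}"]) for i in range(1, 8))
        ref = GrowthReference(row["measure"], row["context"], row["sex"], edges)
        refs[(ref.measure, ref.context, ref.sex)] = ref
    return refs


def zscore_bin(value, ref: GrowthReference):
    """Assign a measurement to one of 8 ordinal z-score intervals.

    Intervals are lower-exclusive / upper-inclusive: bin 1 is value <= -3Z,
    bin k (2..7) is edge_{k-1} < value <= edge_k, bin 8 is value > +3Z.
    A value exactly on the mean edge therefore falls in bin 4.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("zscore_bin requires finite measurements")
    edges = np.asarray(ref.z_edges)
    bins = 1 + (edges[None, :] < arr.reshape(-1, 1)).sum(axis=1)
    if np.isscalar(value) or arr.ndim == 0:
        return int(bins[0])
    return bins.reshape(arr.shape)


# ---------------------------------------------------------------------------
# Labelling and feature assembly
# ---------------------------------------------------------------------------


def label_outcome(cohort: CohortTable, spec: OutcomeSpec) -> LabeledCohort:
    """Compute binary outcome labels, excluding subjects missing a defining score.

    Delay rule: positive iff score at 24 months < cutoff (strict).
    Decline rule: positive iff (score at 6 months - score at 24 months)
    >= sd_points.  Subjects lacking any required Bayley score are dropped
    rather than imputed, since the scores define the outcome itself.
    """
    for col in spec.required_columns:
        if col not in cohort.data.columns:
            raise SchemaError(f"outcome {spec.name} needs column {col!r}")
    scores = cohort.data[list(spec.required_columns)]
    keep = scores.notna().all(axis=1)
    retained = cohort.data.loc[keep]
    if spec.rule == "threshold":
        labels = (retained[bayley_column(spec.scale, "24m")] < spec.cutoff).astype(int)
    else:
        decline = retained[bayley_column(spec.scale, "6m")] - retained[bayley_column(spec.scale, "24m")]
        labels = (decline >= spec.sd_points).astype(int)
    # 24m scores define the outcome; they are never legitimate predictors.
    outcome_cols = {bayley_column(s, "24m") for s in ("cognitive", "motor")}
    feat_cols = [c for c in cohort.variables if c not in outcome_cols]
    return LabeledCohort(retained[feat_cols], labels, spec, dict(cohort.dictionary))


def assemble_features(cohort: CohortTable, spec: OutcomeSpec) -> LabeledCohort:
    """Label the cohort and restrict predictors to visits up to the horizon.

    Drops every variable whose visit tag is later than ``spec.horizon``
    (which also removes all 24-month columns, the label's ingredients).
    """
    labeled = label_outcome(cohort, spec)
    h = visit_index(spec.horizon)
    keep = [
        c for c in labeled.features.columns if visit_index(cohort.spec(c).visit) <= h
    ]
    if not keep:
        raise ConfigurationError(
            f"no predictors remain at or before horizon {spec.horizon!r}"
        )
    return LabeledCohort(labeled.features[keep], labeled.labels, spec, labeled.dictionary)
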