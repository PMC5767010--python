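"""Subject-level cohort handling: CSV I/O, preprocessing, analysis-matrix construction.

A cohort holds, per subject, a center label, 23 candidate predictors (22
postoperative biomarkers plus cardiopulmonary-bypass time), the two AKI
outcomes (sustained mild, severe) and the two mortality outcomes (death at 1
and 3 years).  Predictors may be missing; the modelling stages operate on
complete cases only.  The analysis matrix applies the standard transforms
(natural log for concentration-scale biomarkers, identity for signed or
duration-scale variables) and encodes center as reference-cell indicator
columns that every model is forced to carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictorSpec",
    "Cohort",
    "AnalysisMatrix",
    "CompleteCaseCounts",
    "default_predictor_specs",
    "read_cohort",
    "write_cohort",
    "complete_case_filter",
    "build_analysis_matrix",
]

#: Canonical candidate-predictor order.  22 biomarkers measured 0-6 h after
#: surgery plus CPB time.  Signed change in serum creatinine and CPB minutes
#: stay on their natural scale; everything else is log-transformed.
_IDENTITY_PREDICTORS = ("creatinine_serum_change", "cpb_minutes")

CANDIDATE_PREDICTORS: tuple[str, ...] = (
    # urine markers
    "kim1_urine",
    "lfabp_urine",
    "cystatin_c_urine",
    "albumin_urine",
    "ngal_urine",
    "il18_urine",
    "creatinine_urine",
    # serum creatinine variants (0-6 h postoperative)
    "creatinine_serum_post",
    "creatinine_serum_change",
    "creatinine_serum_avg",
    # plasma markers
    "ngal_plasma",
    "hfabp_plasma",
    "bnp_plasma",
    "tnths_plasma",
    "ntprobnp_plasma",
    "ckmb_plasma",
    "tni_plasma",
    "il6_plasma",
    "il10_plasma",
    "mcp1_plasma",
    "egf_plasma",
    "vegf_plasma",
    # degree-of-insult proxy
    "cpb_minutes",
)

OUTCOME_COLUMNS = ("mild_aki", "severe_aki", "death_1y", "death_3y")
ID_COLUMN = "subject_id"
CENTER_COLUMN = "center"


@dataclass(frozen=True)
class PredictorSpec:
    """One candidate predictor: its name, transform and forced status.

    ``forced`` is true only for center indicators, which are generated
    internally and never appear in user-facing schemas.
    """

    name: str
    transform: str = "log"  # "log" | "identity"
    forced: bool = False

    def __post_init__(self) -> None:
        if self.transform not in ("log", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")


def default_predictor_specs() -> list[PredictorSpec]:
    """The 23 candidate predictors with their default transforms."""
    specs = []
    for name in CANDIDATE_PREDICTORS:
        transform = "identity" if name in _IDENTITY_PREDICTORS else "log"
        specs.append(PredictorSpec(name=name, transform=transform))
    return specs


class Cohort:
    """Validated subject-level cohort backed by a :class:`pandas.DataFrame`.

    Columns: ``subject_id, center, <predictors...>, mild_aki, severe_aki,
    death_1y, death_3y``.  Predictor and mortality cells may be missing
    (``NaN``); the AKI outcomes must be fully observed 0/1.
    """

    def __init__(self, data: pd.DataFrame, predictor_names: Sequence[str] | None = None):
        if predictor_names is None:
            predictor_names = [c for c in CANDIDATE_PREDICTORS if c in data.columns]
        self.predictor_names = list(predictor_names)
        required = [ID_COLUMN, CENTER_COLUMN, *self.predictor_names, "mild_aki", "severe_aki"]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise ValueError(f"cohort is missing required columns: {missing}")
        dup = data[ID_COLUMN][data[ID_COLUMN].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject_id values: {sorted(set(dup.astype(str)))[:5]}")
        if data[CENTER_COLUMN].isna().any():
            raise ValueError("center labels must not be missing")
        for col in ("mild_aki", "severe_aki"):
            vals = data[col].dropna().unique()
            if data[col].isna().any() or not set(np.asarray(vals)) <= {0, 1}:
                raise ValueError(f"outcome column {col!r} must be fully observed binary 0/1")
        self.data = data.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def centers(self) -> list[str]:
        return sorted(self.data[CENTER_COLUMN].astype(str).unique())

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        if self.predictor_names != other.predictor_names:
            return False
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind in "fc" or y.dtype.kind in "fc":
                xa, ya = x.to_numpy(float), y.to_numpy(float)
                same = (xa == ya) | (np.isnan(xa) & np.isnan(ya))
                if not same.all():
                    return False
            elif not (x.astype(str) == y.astype(str)).all():
                return False
        return True


@dataclass(frozen=True)
class CompleteCaseCounts:
    removed: int
    retained: int
    cases_retained: int


@dataclass
class AnalysisMatrix:
    """Complete-case design matrix ready for model fitting.

    Columns are the transformed candidate predictors (in schema order) followed
    by the C-1 forced center indicators; the intercept is added by the fitting
    code.  ``is_forced`` marks the indicator columns; ``center`` keeps the raw
    labels for center-stratified resampling and adjusted-AUC computation.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    is_forced: np.ndarray
    center: np.ndarray
    outcome: str
    subject_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def candidate_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_forced)

    @property
    def forced_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_forced)

    @property
    def candidate_names(self) -> list[str]:
        return [self.columns[i] for i in self.candidate_idx]

    def subset_rows(self, idx: np.ndarray) -> "AnalysisMatrix":
        return AnalysisMatrix(
            X=self.X[idx],
            y=self.y[idx],
            columns=list(self.columns),
            is_forced=self.is_forced.copy(),
            center=self.center[idx],
            outcome=self.outcome,
            subject_id=self.subject_id[idx] if len(self.subject_id) else self.subject_id,
        )


# ---------------------------------------------------------------------------
# CSV I/O


def read_cohort(path, schema: Sequence[PredictorSpec] | None = None) -> Cohort:
    """Read a cohort CSV (comma-separated, UTF-8, empty cell = missing)."""
    if schema is None:
        schema = default_predictor_specs()
    names = [s.name for s in schema]
    df = pd.read_csv(path, dtype={ID_COLUMN: str, CENTER_COLUMN: str},
                     float_precision="round_trip")
    known = {ID_COLUMN, CENTER_COLUMN, *names, *OUTCOME_COLUMNS}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown columns in cohort file: {unknown}")
    for col in names:
        if col not in df.columns:
            raise ValueError(f"schema column {col!r} absent from cohort file")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}: {df[col][row]!r}")
        df[col] = coerced
    for col in OUTCOME_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return Cohort(df, predictor_names=names)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV; missing values become empty cells (round-trip safe).

    Floats use the shortest round-trip representation, so write/read is
    lossless for finite values and the missingness pattern.
    """
    cohort.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing


def complete_case_filter(
    cohort: Cohort, predictors: Iterable[str] | None = None
) -> tuple[Cohort, CompleteCaseCounts]:
    """Drop subjects missing any of the named predictors.

    Idempotent and order-preserving.  Raises if nothing survives.
    """
    if predictors is None:
        predictors = cohort.predictor_names
    predictors = list(predictors)
    unknown = set(predictors) - set(cohort.predictor_names)
    if unknown:
        raise ValueError(f"predictors not in cohort schema: {sorted(unknown)}")
    keep = ~cohort.data[predictors].isna().any(axis=1)
    retained = cohort.data[keep]
    if len(retained) == 0:
        raise ValueError("complete-case filter removed every subject")
    counts = CompleteCaseCounts(
        removed=int((~keep).sum()),
        retained=int(keep.sum()),
        cases_retained=int(retained["mild_aki"].sum()),
    )
    return Cohort(retained, predictor_names=cohort.predictor_names), counts


def build_analysis_matrix(
    cohort: Cohort,
    schema: Sequence[PredictorSpec] | None = None,
    outcome: str = "mild_aki",
) -> AnalysisMatrix:
    """Transform predictors and encode centers into a complete design matrix.

    The cohort must already be complete-case filtered on the schema
    predictors; rows missing the *outcome* are dropped here (relevant for the
    mortality outcomes only).  Center is encoded as C-1 indicators against the
    lexicographically first label.
    """
    if schema is None:
        schema = default_predictor_specs()
    if outcome not in cohort.data.columns:
        raise ValueError(f"outcome column {outcome!r} absent from cohort")
    df = cohort.data
    y_raw = df[outcome]
    df = df[y_raw.notna()]
    y = df[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary")

    cols: list[np.ndarray] = []
    names: list[str] = []
    for spec in schema:
        vals = df[spec.name].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(
                f"predictor {spec.name!r} has missing values; apply complete_case_filter first"
            )
        if spec.transform == "log":
            if (vals <= 0).any():
                rows = np.flatnonzero(vals <= 0)[:5].tolist()
                raise ValueError(
                    f"nonpositive values under log transform for {spec.name!r} at rows {rows}"
                )
            vals = np.log(vals)
        cols.append(vals)
        names.append(spec.name)

    centers = df[CENTER_COLUMN].astype(str).to_numpy()
    levels = sorted(set(centers))
    for level in levels[1:]:  # reference = first sorted label
        cols.append((centers == level).astype(float))
        names.append(f"center_{level}")

    X = np.column_stack(cols)
    is_forced = np.array([n.startswith("center_") for n in names])
    return AnalysisMatrix(
        X=X,
        y=y,
        columns=names,
        is_forced=is_forced,
        center=centers,
        outcome=outcome,
        subject_id=df[ID_COLUMN].to_numpy(dtype=object),
    )
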