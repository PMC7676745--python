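"""Cohort tables of non-invasive features and invasive AAA wall properties.

The regression database pairs, per tissue sample, eight clinically accessible
features (geometry + hemogram) with four invasive vessel-wall properties
(wall thickness t [mm], stiffnesses alpha and beta [kPa], wall strength
sigma_gamma [kPa]) obtained from tensile tests.  A patient can contribute
several samples, so records are grouped by a patient index; that grouping
drives leave-one-patient-out validation downstream.

This module reads/writes the paired delimited tables, applies the
missingness filters / median imputation / z-score normalization used to
prepare the database, computes feature-property rank correlations and runs
greedy sequential forward feature selection.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEATURE_COLUMNS",
    "PROPERTY_COLUMNS",
    "FeatureVector",
    "InvasiveProperties",
    "CohortDataset",
    "NormalizationStats",
    "CohortError",
    "CohortAlignmentError",
    "CohortParseError",
    "EmptyCohortError",
    "read_cohort",
    "write_cohort",
    "preprocess",
    "spearman_correlations",
    "order_candidates_by_correlation",
    "forward_feature_selection",
]

#: canonical column order of the non-invasive (S2-schema) table
FEATURE_COLUMNS = [
    "max_diameter",
    "thrombus_thickness",
    "aaa_length",
    "subrenal_diameter",
    "thrombocytes",
    "hemoglobin",
    "mch",
    "mcv",
]

#: canonical column order of the invasive (S3-schema) table
PROPERTY_COLUMNS = ["t", "alpha", "beta", "sigma_gamma"]

PATIENT_COLUMN = "patient_id"


class CohortError(ValueError):
    """Base class for cohort-table problems."""


class CohortAlignmentError(CohortError):
    """The two tables do not describe the same records in the same order."""


class CohortParseError(CohortError):
    """A cell that must be numeric is not."""


class EmptyCohortError(CohortError):
    """Every record was filtered away."""


@dataclass(frozen=True)
class InvasiveProperties:
    """One sample's wall properties; all strictly positive (log is taken)."""

    t: float            # wall thickness [mm]
    alpha: float        # alpha stiffness [kPa]
    beta: float         # beta stiffness [kPa]
    sigma_gamma: float  # wall strength [kPa]

    def __post_init__(self) -> None:
        for name in PROPERTY_COLUMNS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"invasive property {name!r} must be finite and > 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.t, self.alpha, self.beta, self.sigma_gamma], dtype=float)


@dataclass(frozen=True)
class FeatureVector:
    """The eight non-invasive features; ``nan`` marks a missing value."""

    max_diameter: float = math.nan       # [mm]
    thrombus_thickness: float = math.nan  # [mm]
    aaa_length: float = math.nan         # [mm]
    subrenal_diameter: float = math.nan  # [mm]
    thrombocytes: float = math.nan       # [1,000/ul]
    hemoglobin: float = math.nan         # [g/dl]
    mch: float = math.nan                # [pg/cell]
    mcv: float = math.nan                # [fl]

    def __post_init__(self) -> None:
        for name in ("max_diameter", "thrombus_thickness", "aaa_length", "subrenal_diameter"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name in FEATURE_COLUMNS:
            v = getattr(self, name)
            if not math.isnan(v) and not np.isfinite(v):
                raise ValueError(f"{name} must be finite or missing, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS], dtype=float)


@dataclass
class CohortDataset:
    """Row-aligned feature/property records with a patient grouping.

    ``features`` may contain NaN (missing); ``properties`` must be strictly
    positive throughout.  Both frames share a plain RangeIndex; row ``i`` of
    each belongs to ``patient_ids[i]``.
    """

    patient_ids: np.ndarray
    features: pd.DataFrame
    properties: pd.DataFrame

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        if len(self.patient_ids) == 0:
            raise EmptyCohortError("cohort has no records")
        if not (len(self.patient_ids) == len(self.features) == len(self.properties)):
            raise CohortAlignmentError("patient_ids, features and properties differ in length")
        props = self.properties[PROPERTY_COLUMNS].to_numpy(dtype=float)
        if not np.all(np.isfinite(props)) or np.any(props <= 0):
            bad = np.argwhere(~(np.isfinite(props) & (props > 0)))[0]
            raise ValueError(
                f"invasive property {PROPERTY_COLUMNS[bad[1]]!r} in record {bad[0]} "
                "is not finite and strictly positive"
            )
        self.features = self.features.reset_index(drop=True)
        self.properties = self.properties.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.patient_ids)

    @property
    def n_patients(self) -> int:
        return len(np.unique(self.patient_ids))

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def records_of(self, patient_id) -> np.ndarray:
        """Row positions belonging to one patient."""
        return np.flatnonzero(self.patient_ids == patient_id)

    def subset(self, rows: np.ndarray) -> "CohortDataset":
        rows = np.asarray(rows)
        return CohortDataset(
            patient_ids=self.patient_ids[rows],
            features=self.features.iloc[rows].reset_index(drop=True),
            properties=self.properties.iloc[rows].reset_index(drop=True),
        )

    def drop_patient(self, patient_id) -> "CohortDataset":
        return self.subset(np.flatnonzero(self.patient_ids != patient_id))

    def feature_matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def log_properties(self) -> np.ndarray:
        """n_records x 4 matrix of log [t, alpha, beta, sigma_gamma]."""
        return np.log(self.properties[PROPERTY_COLUMNS].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_numeric_table(path, required_columns: Sequence[str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != PATIENT_COLUMN:
        # tolerate any first-column name; it is the patient index by contract
        df = df.rename(columns={df.columns[0]: PATIENT_COLUMN})
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise CohortParseError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if col == PATIENT_COLUMN:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in row {row}, column {col!r}"
            )
        df[col] = coerced.astype(float)
    return df


def read_cohort(noninvasive_table, invasive_table) -> CohortDataset:
    """Read the paired S2-schema (features) and S3-schema (properties) tables.

    Both tables must have the same number of rows and identical, row-aligned
    patient indices in their first column.  Empty cells become NaN.
    """
    feat = _read_numeric_table(noninvasive_table, None)
    prop = _read_numeric_table(invasive_table, PROPERTY_COLUMNS)
    if len(feat) != len(prop):
        raise CohortAlignmentError(
            f"row-count mismatch: {len(feat)} feature rows vs {len(prop)} property rows"
        )
    ids_f = feat[PATIENT_COLUMN].to_numpy()
    ids_p = prop[PATIENT_COLUMN].to_numpy()
    if not np.array_equal(ids_f, ids_p):
        i = int(np.flatnonzero(ids_f != ids_p)[0])
        raise CohortAlignmentError(
            f"patient-index mismatch at row {i}: {ids_f[i]!r} vs {ids_p[i]!r}"
        )
    feature_cols = [c for c in feat.columns if c != PATIENT_COLUMN]
    return CohortDataset(
        patient_ids=ids_f,
        features=feat[feature_cols],
        properties=prop[PROPERTY_COLUMNS],
    )


def write_cohort(dataset: CohortDataset, noninvasive_table, invasive_table) -> None:
    """Write a dataset back out in the same paired delimited schema."""
    feat = dataset.features.copy()
    feat.insert(0, PATIENT_COLUMN, dataset.patient_ids)
    prop = dataset.properties[PROPERTY_COLUMNS].copy()
    prop.insert(0, PATIENT_COLUMN, dataset.patient_ids)
    feat.to_csv(noninvasive_table, index=False)
    prop.to_csv(invasive_table, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-feature median / mean / scale frozen at preprocessing time.

    Scale is the population standard deviation (ddof=0).  New patients are
    imputed and normalized with exactly these numbers so that training and
    deployment transforms agree.
    """

    median: dict[str, float] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.median)

    def transform(self, features: pd.DataFrame | FeatureVector) -> pd.DataFrame:
        if isinstance(features, FeatureVector):
            features = pd.DataFrame([features.as_array()], columns=FEATURE_COLUMNS)
        out = {}
        for name in self.feature_names:
            col = features[name].astype(float).fillna(self.median[name])
            out[name] = (col - self.mean[name]) / self.scale[name]
        return pd.DataFrame(out)

    def to_json(self) -> str:
        return json.dumps(
            {
                name: {
                    "median": self.median[name],
                    "mean": self.mean[name],
                    "scale": self.scale[name],
                }
                for name in self.feature_names
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationStats":
        doc = json.loads(text)
        return cls(
            median={k: v["median"] for k, v in doc.items()},
            mean={k: v["mean"] for k, v in doc.items()},
            scale={k: v["scale"] for k, v in doc.items()},
        )


def preprocess(
    dataset: CohortDataset,
    feature_missing_threshold: float = 0.30,
    patient_missing_threshold: float = 0.30,
) -> tuple[CohortDataset, NormalizationStats]:
    """Missingness filters, median imputation and z-score normalization.

    In order: (1) drop every feature missing in more than
    ``feature_missing_threshold`` of records, (2) drop every record missing
    more than ``patient_missing_threshold`` of the surviving features,
    (3) impute remaining gaps with the per-feature median over surviving
    records, (4) z-score each surviving feature (population std).
    """
    for thr in (feature_missing_threshold, patient_missing_threshold):
        if not 0 < thr < 1:
            raise ValueError("thresholds must lie in (0, 1)")

    feats = dataset.features.astype(float)
    frac_missing = feats.isna().mean(axis=0)
    keep_cols = [c for c in feats.columns if frac_missing[c] <= feature_missing_threshold]
    feats = feats[keep_cols]
    if not keep_cols:
        raise EmptyCohortError("all features exceeded the missingness threshold")

    rec_missing = feats.isna().mean(axis=1).to_numpy()
    keep_rows = np.flatnonzero(rec_missing <= patient_missing_threshold)
    if keep_rows.size == 0:
        raise EmptyCohortError("all records exceeded the missingness threshold")
    feats = feats.iloc[keep_rows].reset_index(drop=True)

    stats_out = NormalizationStats()
    for c in keep_cols:
        med = float(feats[c].median())  # even count: mean of central pair
        col = feats[c].fillna(med)
        mu = float(col.mean())
        sd = float(col.std(ddof=0))
        if sd == 0.0:
            warnings.warn(f"feature {c!r} is constant after imputation; scale set to 1")
            sd = 1.0
        stats_out.median[c] = med
        stats_out.mean[c] = mu
        stats_out.scale[c] = sd
        feats[c] = (col - mu) / sd

    out = CohortDataset(
        patient_ids=dataset.patient_ids[keep_rows],
        features=feats,
        properties=dataset.properties.iloc[keep_rows].reset_index(drop=True),
    )
    return out, stats_out


# ---------------------------------------------------------------------------
# Correlation analysis and feature selection
# ---------------------------------------------------------------------------

def spearman_correlations(dataset: CohortDataset) -> pd.DataFrame:
    """Spearman rank correlations, features (rows) x invasive properties.

    Ties receive average ranks.  A constant column yields NaN (undefined),
    never a silent zero.
    """
    if dataset.n_records < 3:
        raise ValueError("need at least 3 records for rank correlations")
    feats = dataset.features
    if feats.isna().any().any():
        raise ValueError("run preprocess first: features contain missing values")
    out = pd.DataFrame(index=feats.columns, columns=PROPERTY_COLUMNS, dtype=float)
    props = dataset.properties
    for f in feats.columns:
        x = feats[f].to_numpy()
        for p in PROPERTY_COLUMNS:
            y = props[p].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                out.loc[f, p] = np.nan
            else:
                out.loc[f, p] = stats.spearmanr(x, y).statistic
    return out


def order_candidates_by_correlation(dataset: CohortDataset) -> list[str]:
    """Features sorted by descending max |Spearman| over the four properties.

    Ties keep the original column order (stable sort).
    """
    corr = spearman_correlations(dataset).abs()
    score = corr.max(axis=1).fillna(-np.inf)
    order = np.argsort(-score.to_numpy(), kind="stable")
    return [score.index[i] for i in order]


def forward_feature_selection(
    dataset: CohortDataset,
    candidate_features: Sequence[str],
    score: Callable[[CohortDataset, list[str]], float] | None = None,
    **score_kwargs,
) -> list[str]:
    """Greedy sequential forward selection over an ordered candidate list.

    Candidates must already be ordered (descending absolute rank correlation;
    see :func:`order_candidates_by_correlation`).  Each candidate in turn is
    appended while ``score(dataset, selected + [candidate])`` improves
    (strictly decreases); the first non-improvement stops the search.  The
    empty model scores +inf, so the first candidate is always accepted.

    ``score`` defaults to the leave-one-patient-out mean patient standardized
    mean square error of the multi-output GP (lower is better).
    """
    candidates = list(candidate_features)
    if not candidates:
        raise ValueError("candidate_features must not be empty")
    if score is None:
        from .mgp import loocv_psmse_score

        score = loocv_psmse_score

    selected: list[str] = []
    best = np.inf
    for cand in candidates:
        trial = selected + [cand]
        s = float(score(dataset, trial, **score_kwargs))
        if s < best:
            selected = trial
            best = s
        else:
            break
    return selected
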