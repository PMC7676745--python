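"""Case-control evaluation of rupture-risk indices.

Given per-patient indices for a diameter-matched asymptomatic vs
symptomatic/ruptured cohort, this layer produces group summaries (mean,
population std, quartiles), relative mean/median differences between the
groups, and ROC/AUC discrimination per index.  It can consume a
ready-made index table (the printed case-control values ship as a package
fixture) or run the full prospective pipeline per patient: drop the patient
from the database, refit the regression model, actively train a surrogate
and compute all four indices.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort_data import CohortDataset
from .mgp import PredictiveDistribution, mgp_fit, model1_cohort_lognormal
from .risk import compute_risk

__all__ = [
    "GROUP_ASYMPTOMATIC",
    "GROUP_SYMPTOMATIC",
    "INDEX_COLUMNS",
    "load_printed_case_control",
    "load_index_table",
    "group_summary",
    "relative_difference",
    "relative_differences",
    "roc_curve",
    "run_case_control",
    "run_case_control_from_cohort",
]

GROUP_ASYMPTOMATIC = "asymptomatic"
GROUP_SYMPTOMATIC = "symptomatic/ruptured"
INDEX_COLUMNS = ["d_max", "sigma_vm", "rpi", "prri", "p_rupt"]
_SUMMARY_ROWS = ["mean", "std", "p25", "p50", "p75"]


def load_index_table(path) -> pd.DataFrame:
    """Read a per-patient index table (columns: patient, group, indices)."""
    table = pd.read_csv(path)
    missing = [c for c in ("group", *INDEX_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"index table lacks columns {missing}")
    groups = set(table["group"].unique())
    if not groups <= {GROUP_ASYMPTOMATIC, GROUP_SYMPTOMATIC}:
        raise ValueError(f"unknown group labels {groups - {GROUP_ASYMPTOMATIC, GROUP_SYMPTOMATIC}}")
    if not np.all(np.isfinite(table[INDEX_COLUMNS].to_numpy(float))):
        raise ValueError("index values must be finite")
    return table


def load_printed_case_control() -> pd.DataFrame:
    """The bundled printed per-patient case-control table (36 AAAs).

    Stress in kPa, RPI dimensionless, PRRI and P_rupt in percent; the
    ``ruptured`` flag marks the 11 known-ruptured aneurysms within the
    symptomatic/ruptured group.
    """
    ref = importlib.resources.files("aaarisk.data") / "case_control_printed.csv"
    with importlib.resources.as_file(ref) as path:
        return load_index_table(path)


def _summary_frame(df: pd.DataFrame) -> pd.DataFrame:
    vals = df[INDEX_COLUMNS]
    out = pd.DataFrame(
        {
            "mean": vals.mean(),
            "std": vals.std(ddof=0),  # population convention (sample std also derivable)
            "p25": vals.quantile(0.25),  # linear interpolation between order statistics
            "p50": vals.quantile(0.50),
            "p75": vals.quantile(0.75),
        }
    ).T
    out.index.name = "statistic"
    return out


def group_summary(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mean / population std / quartiles per index, for each group."""
    out = {}
    for grp, df in table.groupby("group"):
        if df.empty:
            raise ValueError(f"group {grp!r} is empty")
        out[grp] = _summary_frame(df)
    for grp in (GROUP_ASYMPTOMATIC, GROUP_SYMPTOMATIC):
        if grp not in out:
            raise ValueError(f"group {grp!r} is empty")
    return out


def relative_difference(q_a: float, q_sr: float) -> float:
    """100 * |q_sr - q_a| / q_a (asymptomatic group as the reference)."""
    if q_a == 0:
        raise ZeroDivisionError("asymptomatic reference value is zero")
    return 100.0 * abs(q_sr - q_a) / q_a


def relative_differences(
    summary_a: pd.DataFrame, summary_sr: pd.DataFrame, statistic: str = "mean"
) -> pd.Series:
    """Relative group differences [%] of one statistic across all indices."""
    stat_row = {"mean": "mean", "median": "p50"}.get(statistic, statistic)
    out = {}
    for idx in INDEX_COLUMNS:
        q_a = summary_a.loc[stat_row, idx]
        q_sr = summary_sr.loc[stat_row, idx]
        if q_a == 0:
            warnings.warn(f"zero asymptomatic reference for {idx!r}; delta undefined")
            out[idx] = np.nan
        else:
            out[idx] = relative_difference(q_a, q_sr)
    return pd.Series(out, name=f"delta_{statistic}_pct")


def roc_curve(table: pd.DataFrame, index: str):
    """Threshold sweep, TPR/FPR and trapezoid AUC for one index column.

    The symptomatic/ruptured group is the positive class; tied index values
    contribute half credit (Mann-Whitney convention).  A constant index
    degenerates to AUC 0.5 with a warning.
    """
    labels = (table["group"] == GROUP_SYMPTOMATIC).to_numpy(int)
    if labels.min() == labels.max():
        raise ValueError("both groups must be non-empty")
    scores = table[index].to_numpy(float)
    if np.ptp(scores) == 0:
        warnings.warn(f"index {index!r} is constant; degenerate ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    return thresholds, tpr, fpr, float(_trapezoid_auc(fpr, tpr))


@dataclass
class CaseControlReport:
    """Summaries, relative differences and discrimination for one study."""

    table: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    delta_mean_pct: pd.Series
    delta_median_pct: pd.Series
    auc: dict[str, float]
    roc: dict[str, dict] = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "summaries": {g: s.to_dict() for g, s in self.summaries.items()},
            "delta_mean_pct": self.delta_mean_pct.to_dict(),
            "delta_median_pct": self.delta_median_pct.to_dict(),
            "auc": self.auc,
            "roc": self.roc,
            "failures": [str(f) for f in self.failures],
        }


def run_case_control(table: pd.DataFrame, failures: list | None = None) -> CaseControlReport:
    """Evaluation layer over a ready-made per-patient index table."""
    summaries = group_summary(table)
    roc = {}
    aucs = {}
    for idx in INDEX_COLUMNS:
        thresholds, tpr, fpr, a = roc_curve(table, idx)
        aucs[idx] = a
        roc[idx] = {
            "thresholds": thresholds.tolist(),
            "tpr": tpr.tolist(),
            "fpr": fpr.tolist(),
        }
    return CaseControlReport(
        table=table,
        summaries=summaries,
        delta_mean_pct=relative_differences(
            summaries[GROUP_ASYMPTOMATIC], summaries[GROUP_SYMPTOMATIC], "mean"
        ),
        delta_median_pct=relative_differences(
            summaries[GROUP_ASYMPTOMATIC], summaries[GROUP_SYMPTOMATIC], "median"
        ),
        auc=aucs,
        roc=roc,
        failures=failures or [],
    )


def run_case_control_from_cohort(
    cohort: CohortDataset,
    group_labels: dict,
    forward,
    d_max: dict | None = None,
    seed: int = 0,
    n_eval: int = 10_000,
    model_kind: str = "model3",
    al_config=None,
    **fit_kwargs,
) -> CaseControlReport:
    """Full prospective pipeline per patient, then the evaluation layer.

    For each patient: remove them from the database, fit the predictive
    model on the remainder (``model3``/``model2`` refit a GP; ``model1``
    recomputes cohort statistics), predict their wall properties, actively
    train a surrogate against ``forward`` and compute all four indices.
    ``group_labels`` maps patient_id -> group name; ``d_max`` optionally
    maps patient_id -> maximum diameter [mm] (defaults to the patient's
    max_diameter feature if present).  Per-patient failures are collected
    and reported, not raised.
    """
    from .active_learning import ActiveLearningConfig, train_surrogate_active

    al_config = al_config or ActiveLearningConfig()
    rows, failures = [], []
    for k, pid in enumerate(pd.unique(pd.Series(cohort.patient_ids))):
        try:
            rest = cohort.drop_patient(pid)
            held = cohort.records_of(pid)
            if model_kind == "model1":
                predictive: PredictiveDistribution = model1_cohort_lognormal(rest)
            else:
                model = mgp_fit(rest, independent=(model_kind == "model2"), **fit_kwargs)
                x_star = cohort.feature_matrix()[held].mean(axis=0)
                predictive = model.predict(x_star)
            cfg = type(al_config)(**{**al_config.__dict__, "seed": al_config.seed + k})
            surrogate, _ = train_surrogate_active(forward, predictive, cfg)
            result = compute_risk(surrogate, predictive, n_eval=n_eval, seed=seed + k)
            dmax = (
                d_max[pid]
                if d_max is not None
                else float(cohort.features.iloc[held[0]].get("max_diameter", np.nan))
            )
            rows.append(
                {
                    "patient": pid,
                    "group": group_labels[pid],
                    "d_max": dmax,
                    "sigma_vm": result.sigma_at_mean,
                    "rpi": result.rpi,
                    "prri": 100.0 * result.prri,
                    "p_rupt": 100.0 * result.p_rupt,
                }
            )
        except Exception as exc:  # collected, reported downstream
            failures.append((pid, exc))
    if not rows:
        raise RuntimeError(f"every patient failed: {failures}")
    table = pd.DataFrame(rows)
    return run_case_control(table, failures=failures)
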