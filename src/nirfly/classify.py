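"""Dummy coding, cut-off classification, age binning, and report summaries.

Each binary trait is dummy-coded with a pair of arbitrary numeric codes and
the PLS prediction — a continuous value — is thresholded at their midpoint:

* species:   D. melanogaster -> 1, D. simulans -> 2, cut-off 1.5
* sex:       male -> 3, female -> 4, cut-off 3.5
* Wolbachia: infected -> 5, uninfected -> 6, cut-off 5.5

A prediction below the cut-off takes the low-code class; a prediction equal
to or greater than the cut-off takes the high-code class.  Age is regressed
directly in days and graded into young (< 9 d), middle-aged (9–18 d,
boundaries included) and old (> 18 d), plus the coarser < 9 vs >= 9
dichotomy.  Predictions are never clamped: a negative predicted age simply
grades as young.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ValidationError

AGE_YOUNG_MAX = 9.0    # young: predicted age < 9 d
AGE_MIDDLE_MAX = 18.0  # middle: 9 <= predicted <= 18 d; old: > 18 d
AGE_DICHOTOMY = 9.0


@dataclass(frozen=True)
class ClassTask:
    """One classification task: which metadata field, which codes, which cut."""

    name: str
    field: str
    code_map: dict | None       # label -> numeric code; None for age
    cutoff: float | None        # midpoint of the two codes; None for age

    def __post_init__(self) -> None:
        if self.code_map is not None:
            codes = sorted(self.code_map.values())
            if len(codes) != 2 or codes[0] == codes[1]:
                raise DesignError("binary tasks need exactly two distinct codes")
            mid = 0.5 * (codes[0] + codes[1])
            if self.cutoff != mid:
                raise DesignError(
                    f"cutoff {self.cutoff} is not the code midpoint {mid}"
                )

    @property
    def is_age(self) -> bool:
        return self.code_map is None

    @property
    def low_label(self):
        return min(self.code_map, key=self.code_map.get)

    @property
    def high_label(self):
        return max(self.code_map, key=self.code_map.get)


TASKS: dict[str, ClassTask] = {
    "species": ClassTask("species", "species",
                         {"melanogaster": 1.0, "simulans": 2.0}, 1.5),
    "gender": ClassTask("gender", "sex", {"male": 3.0, "female": 4.0}, 3.5),
    "wolbachia": ClassTask("wolbachia", "infection",
                           {"infected": 5.0, "uninfected": 6.0}, 5.5),
    "age": ClassTask("age", "age_days", None, None),
}


def encode_labels(meta: pd.DataFrame, task: ClassTask) -> np.ndarray:
    """Numeric response vector for the task (dummy codes, or age in days)."""
    col = meta[task.field]
    if task.is_age:
        return col.to_numpy(dtype=float)
    y = np.empty(len(col), dtype=float)
    for i, label in enumerate(col):
        if label not in task.code_map:
            sid = meta["sample_id"].iloc[i] if "sample_id" in meta.columns else i
            raise ValidationError(
                f"sample {sid!r}: label {label!r} not in the {task.name} code map"
            )
        y[i] = task.code_map[label]
    return y


def threshold_classify(yhat: np.ndarray, task: ClassTask) -> np.ndarray:
    """Threshold continuous predictions at the cut-off.

    Below the cut-off -> low-code class; equal or above -> high-code class.
    """
    if task.is_age:
        raise DesignError("the age task is graded with bin_age, not a cut-off")
    yhat = np.asarray(yhat, dtype=float)
    return np.where(yhat < task.cutoff, task.low_label, task.high_label)


def bin_age(yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Grade predicted ages into three bins and the <9 / >=9 dichotomy."""
    yhat = np.asarray(yhat, dtype=float)
    bins = np.where(yhat < AGE_YOUNG_MAX, "young",
                    np.where(yhat <= AGE_MIDDLE_MAX, "middle", "old"))
    dichotomy = np.where(yhat < AGE_DICHOTOMY, "<9", ">=9")
    return bins, dichotomy


def age_bin_of_actual(age_days: np.ndarray) -> np.ndarray:
    """The bin an actual age belongs to (same edges as predictions)."""
    return bin_age(np.asarray(age_days, dtype=float))[0]


@dataclass
class PredictionReport:
    """Per-task accounting of predictions against truth."""

    task: str
    per_sample: pd.DataFrame                 # sample_id, truth, prediction, ...
    confusion: pd.DataFrame | None = None    # true x predicted counts
    group_accuracy: pd.DataFrame | None = None
    cohort_stats: pd.DataFrame | None = None      # age: mean/SD of yhat per cohort
    bin_accuracy: pd.DataFrame | None = None      # age: 3-bin accuracy per cohort
    dichotomy_accuracy: pd.DataFrame | None = None
    regression: dict | None = None                # age: slope/intercept/r2

    def to_csvs(self, outdir, prefix: str = "") -> list[str]:
        import os
        written = []
        for name in ("per_sample", "confusion", "group_accuracy", "cohort_stats",
                     "bin_accuracy", "dichotomy_accuracy"):
            obj = getattr(self, name)
            if obj is not None:
                path = os.path.join(outdir, f"{prefix}{self.task}_{name}.csv")
                obj.to_csv(path, index=name == "confusion")
                written.append(path)
        if self.regression is not None:
            path = os.path.join(outdir, f"{prefix}{self.task}_regression.csv")
            pd.DataFrame([self.regression]).to_csv(path, index=False)
            written.append(path)
        return written


def _accuracy_table(df: pd.DataFrame, truth_col: str, correct_col: str,
                    by: Sequence[str]) -> pd.DataFrame:
    rows = []
    for keys, sub in df.groupby(list(by), dropna=False, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        rows.append({**dict(zip(by, keys)), "n": len(sub),
                     "accuracy_pct": 100.0 * sub[correct_col].mean()})
    return pd.DataFrame(rows)


def summarize(meta: pd.DataFrame, yhat: np.ndarray, task: ClassTask,
              group_by: Sequence[str] | None = None) -> PredictionReport:
    """Build the full accounting for one validated task.

    For binary tasks: a confusion table and per-class (optionally
    per-``group_by``) accuracies in percent.  For age: per-cohort mean and SD
    of the predicted age, three-bin and dichotomy accuracies, and the
    ordinary least-squares regression of predicted on actual age with its
    slope, intercept and r² (squared Pearson correlation).
    """
    yhat = np.asarray(yhat, dtype=float)
    if len(meta) != yhat.size:
        raise ValidationError(f"{len(meta)} metadata rows but {yhat.size} predictions")
    if len(meta) == 0:
        return PredictionReport(task=task.name, per_sample=pd.DataFrame())

    if not task.is_age:
        truth = meta[task.field].to_numpy()
        pred = threshold_classify(yhat, task)
        per_sample = pd.DataFrame({
            "sample_id": meta["sample_id"].to_numpy(),
            "true_label": truth,
            "predicted_value": yhat,
            "predicted_label": pred,
            "correct": truth == pred,
        })
        confusion = pd.crosstab(per_sample["true_label"],
                                per_sample["predicted_label"], dropna=False)
        by = [("true_label")] if group_by is None else list(group_by)
        if group_by is not None:
            for col in group_by:
                per_sample[col] = meta[col].to_numpy()
            per_sample["true_label"] = truth
            by = list(group_by) + ["true_label"]
        acc = _accuracy_table(per_sample, "true_label", "correct", by)
        return PredictionReport(task=task.name, per_sample=per_sample,
                                confusion=confusion, group_accuracy=acc)

    # --- age grading ---
    actual = meta["age_days"].to_numpy(dtype=float)
    pred_bin, pred_dich = bin_age(yhat)
    true_bin = age_bin_of_actual(actual)
    true_dich = np.where(actual < AGE_DICHOTOMY, "<9", ">=9")
    per_sample = pd.DataFrame({
        "sample_id": meta["sample_id"].to_numpy(),
        "actual_age": actual,
        "predicted_age": yhat,
        "predicted_bin": pred_bin,
        "bin_correct": pred_bin == true_bin,
        "dichotomy_correct": pred_dich == true_dich,
    })
    cohort_stats = (per_sample.groupby("actual_age")["predicted_age"]
                    .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
                    .reset_index())
    bin_acc = _accuracy_table(per_sample, "actual_age", "bin_correct",
                              ["actual_age"])
    per_sample["_dich_group"] = true_dich
    dich_acc = _accuracy_table(per_sample, "_dich_group", "dichotomy_correct",
                               ["_dich_group"]).rename(
        columns={"_dich_group": "actual_age_group"})
    per_sample = per_sample.drop(columns="_dich_group")
    if np.ptp(actual) > 0 and len(actual) > 2:
        if np.ptp(yhat) == 0:
            # constant predictions: flat line, no explained variance
            regression = {"slope": 0.0, "intercept": float(yhat[0]), "r2": 0.0}
        else:
            res = stats.linregress(actual, yhat)
            regression = {"slope": float(res.slope),
                          "intercept": float(res.intercept),
                          "r2": float(res.rvalue ** 2)}
    else:
        regression = {"slope": float("nan"), "intercept": float("nan"),
                      "r2": float("nan")}
    return PredictionReport(task=task.name, per_sample=per_sample,
                            cohort_stats=cohort_stats, bin_accuracy=bin_acc,
                            dichotomy_accuracy=dich_acc, regression=regression)
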