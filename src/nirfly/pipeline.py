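"""End-to-end study orchestration: calibrate, screen outliers, validate.

One study = one preprocessing preset, one dummy-coded (or continuous-age)
response, a leave-one-out PRESS curve for factor selection, a single-pass
Mahalanobis outlier screen, and a validation on independent flies whose
spectra are centered by the *calibration* statistics only.  The four study
protocols are wired as in the original designs:

* species — one model on all calibration lines, validated on the
  independent Dah/Ky cohorts;
* gender — one model per species (trained on the Alst resp. Hw line),
  validated on the other line of that species;
* age — four models, one per calibration line x sex, each validated on the
  matching independent line and sex;
* wolbachia — one model on the infected/uninfected calibration pairs.

Factor selection uses calibration PRESS only (smallest factor count within
tolerance of the minimum); the independent set never influences
preprocessing statistics, factor choice or outlier removal, and any
sample-id overlap between calibration and validation is a hard error.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import TASKS, ClassTask, PredictionReport, encode_labels, summarize
from .errors import ConfigError, DesignError, ValidationError
from .outliers import OutlierReport, remove_and_refit
from .pls import PLSModel, PRESSCurve, loo_cross_validate, predict, select_factors
from .preprocess import PRESETS, PreprocessConfig, preprocess
from .spectra_io import SpectrumSet


@dataclass(frozen=True)
class StudyConfig:
    """Settings for one calibration/validation run."""

    task: str
    preprocess: PreprocessConfig | None = None   # None -> task preset
    k_max: int = 20
    press_tolerance: float = 0.02
    outlier_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}; choose from {sorted(TASKS)}")
        if self.k_max < 1:
            raise ConfigError("k_max must be >= 1")

    @property
    def preprocess_config(self) -> PreprocessConfig:
        return self.preprocess if self.preprocess is not None else PRESETS[self.task]

    @property
    def class_task(self) -> ClassTask:
        return TASKS[self.task]


@dataclass
class CalibrationResult:
    """Everything produced by one calibration, with full provenance."""

    model: PLSModel
    press_curve: PRESSCurve
    chosen_k: int
    outlier_report: OutlierReport
    config: StudyConfig
    cal_meta: pd.DataFrame
    loo_pred: np.ndarray        # held-out predictions at chosen_k, all cal flies

    @property
    def dropped_ids(self) -> list[str]:
        return self.outlier_report.dropped_ids

    def loo_report(self, group_by=None) -> PredictionReport:
        """Summary of the cross-validated calibration predictions."""
        return summarize(self.cal_meta, self.loo_pred, self.config.class_task,
                         group_by=group_by)

    def provenance(self) -> dict:
        return {
            "task": self.config.task,
            "preprocess_fingerprint": self.config.preprocess_config.fingerprint,
            "k_max": self.config.k_max,
            "chosen_k": self.chosen_k,
            "press": self.press_curve.press.tolist(),
            "n_calibration": int(self.press_curve.n),
            "outliers_dropped": self.dropped_ids,
            "outlier_threshold": self.config.outlier_threshold,
        }


def run_calibration(cal: SpectrumSet, cfg: StudyConfig) -> CalibrationResult:
    """Preprocess, cross-validate, select factors, screen outliers, fit.

    Leave-one-out folds re-center on the retained flies only.  If the
    calibration is too small for ``k_max``, the cap is reduced (n - 2).
    """
    task = cfg.class_task
    if cal.n_samples == 0:
        raise DesignError("empty calibration set")
    if task.is_age:
        if cal.meta["age_days"].nunique() < 3:
            raise DesignError("age calibration needs at least 3 distinct ages")
    else:
        if cal.meta[task.field].nunique() < 2:
            raise DesignError(f"{cfg.task} calibration has a single class")

    pcfg = cfg.preprocess_config
    pset = preprocess(cal, pcfg)
    y = encode_labels(cal.meta, task)
    k_max = min(cfg.k_max, pset.n_samples - 2, pset.n_wavelengths)
    curve = loo_cross_validate(pset.values, y, k_max)
    k = select_factors(curve, cfg.press_tolerance)
    model, outlier_report = remove_and_refit(
        pset.values, y, k, threshold=cfg.outlier_threshold,
        sample_ids=pset.sample_ids, wavelengths=pset.wavelengths,
        fingerprint=pcfg.fingerprint)
    return CalibrationResult(model=model, press_curve=curve, chosen_k=k,
                             outlier_report=outlier_report, config=cfg,
                             cal_meta=cal.meta.copy(),
                             loo_pred=curve.loo_pred[:, k - 1].copy())


def run_validation(calres: CalibrationResult, ind: SpectrumSet, *,
                   group_by=None, allow_overlap: bool = False) -> PredictionReport:
    """Predict an independent set with a fitted calibration and summarize.

    Raises on any sample-id overlap with the calibration set unless
    ``allow_overlap=True`` (used only for training-set self-checks).
    """
    overlap = set(ind.sample_ids) & set(calres.cal_meta["sample_id"].astype(str))
    if overlap and not allow_overlap:
        raise DesignError(
            f"{len(overlap)} sample(s) appear in both calibration and "
            f"validation sets, e.g. {sorted(overlap)[:3]}"
        )
    pcfg = calres.config.preprocess_config
    pset = preprocess(ind, pcfg)
    wl_model = calres.model.wavelengths
    if wl_model is not None and (
            pset.n_wavelengths != wl_model.size
            or not np.allclose(pset.wavelengths, wl_model)):
        raise ValidationError("validation grid does not match the model grid")
    yhat = predict(calres.model, pset.values, fingerprint=pcfg.fingerprint)
    return summarize(ind.meta, yhat, calres.config.class_task, group_by=group_by)


@dataclass
class StudyResult:
    """Calibration + validation output of one fitted model."""

    name: str
    calibration: CalibrationResult
    validation: PredictionReport
    calibration_loo: PredictionReport


def run_species_study(population: SpectrumSet,
                      cfg: StudyConfig | None = None) -> StudyResult:
    cfg = cfg or StudyConfig("species")
    cal = population.where(split="calibration")
    ind = population.where(split="independent")
    calres = run_calibration(cal, cfg)
    report = run_validation(calres, ind, group_by=("species",))
    return StudyResult("species", calres, report, calres.loo_report())


def run_gender_study(population: SpectrumSet, species: str,
                     cal_line: str, ind_line: str,
                     cfg: StudyConfig | None = None) -> StudyResult:
    """One per-species sex model: calibrate on one line, validate on the other."""
    cfg = cfg or StudyConfig("gender")
    cal = population.where(split="calibration", line=cal_line)
    ind = population.where(split="independent", line=ind_line)
    calres = run_calibration(cal, cfg)
    report = run_validation(calres, ind, group_by=("sex",))
    return StudyResult(f"gender_{species}", calres, report, calres.loo_report())


def run_age_study(population: SpectrumSet, cal_line: str, ind_line: str,
                  sex: str, cfg: StudyConfig | None = None) -> StudyResult:
    """One per-line-and-sex age model."""
    cfg = cfg or StudyConfig("age")
    cal = population.where(split="calibration", line=cal_line, sex=sex)
    ind = population.where(split="independent", line=ind_line, sex=sex)
    calres = run_calibration(cal, cfg)
    report = run_validation(calres, ind)
    return StudyResult(f"age_{cal_line}_{sex}", calres, report, calres.loo_report())


def run_wolbachia_study(population: SpectrumSet,
                        cfg: StudyConfig | None = None) -> StudyResult:
    cfg = cfg or StudyConfig("wolbachia")
    cal = population.where(split="calibration")
    ind = population.where(split="independent")
    calres = run_calibration(cal, cfg)
    report = run_validation(calres, ind, group_by=("infection",))
    return StudyResult("wolbachia", calres, report, calres.loo_report())


# study wiring: (cal_line, ind_line) per species
_GENDER_PAIRS = {"melanogaster": ("Alst", "Dah"), "simulans": ("Hw", "Ky")}


def run_all_studies(population: SpectrumSet,
                    wolbachia_population: SpectrumSet,
                    k_max: int = 20) -> dict[str, StudyResult]:
    """Run the four protocols end to end; returns results keyed by model name."""
    results: dict[str, StudyResult] = {}
    results["species"] = run_species_study(
        population, StudyConfig("species", k_max=k_max))
    for species, (cal_line, ind_line) in _GENDER_PAIRS.items():
        res = run_gender_study(population, species, cal_line, ind_line,
                               StudyConfig("gender", k_max=k_max))
        results[res.name] = res
    for species, (cal_line, ind_line) in _GENDER_PAIRS.items():
        for sex in ("male", "female"):
            res = run_age_study(population, cal_line, ind_line, sex,
                                StudyConfig("age", k_max=k_max))
            results[res.name] = res
    results["wolbachia"] = run_wolbachia_study(
        wolbachia_population, StudyConfig("wolbachia", k_max=k_max))
    return results


def write_reports(results: dict[str, StudyResult], outdir) -> str:
    """Write per-model CSV reports plus a JSON run log; returns the log path."""
    os.makedirs(outdir, exist_ok=True)
    log = []
    for name, res in sorted(results.items()):
        res.validation.to_csvs(outdir, prefix=f"{name}_independent_")
        res.calibration_loo.to_csvs(outdir, prefix=f"{name}_calibration_")
        res.calibration.outlier_report.to_frame().to_csv(
            os.path.join(outdir, f"{name}_outliers.csv"), index=False)
        log.append({"model": name, **res.calibration.provenance()})
    log_path = os.path.join(outdir, "run_log.json")
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log_path
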