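"""Calibration outlier diagnostics on PLS scores.

Two complementary diagnostics: the Mahalanobis distance of a fly's latent
scores from the calibration centroid (covariance-scaled, so a distance of 3
means "3 standard deviations out" regardless of factor scaling), and the
spectral reconstruction residual (how much of the preprocessed spectrum the
latent factors fail to explain).  A calibration sample is flagged when its
distance spreads outside the threshold (default 3, strict inequality) and
the model is refitted once without the flagged flies — a single pass, no
iterative re-flagging, so the procedure is deterministic and auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pls import PLSModel, fit_pls1


@dataclass
class OutlierReport:
    sample_ids: list[str]
    distances: np.ndarray
    residuals: np.ndarray
    flagged: np.ndarray
    threshold: float
    warning: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "mahalanobis_distance": self.distances,
            "spectral_residual": self.residuals,
            "flagged": self.flagged,
        })

    @property
    def dropped_ids(self) -> list[str]:
        return [sid for sid, f in zip(self.sample_ids, self.flagged) if f]


def mahalanobis_scores(model: PLSModel, X: np.ndarray | None = None) -> np.ndarray:
    """Mahalanobis distance of each sample's scores from the score centroid.

    With ``X=None`` the stored calibration scores are used; otherwise the
    rows of X (preprocessed, uncentered) are projected first.  The covariance
    is always the calibration score covariance (ddof=1).
    """
    T = model.T if X is None else model.project(X)
    if model.k == 0:
        return np.zeros(T.shape[0])
    S = np.atleast_2d(model.score_cov)
    centred = T - model.T.mean(axis=0)
    try:
        sol = np.linalg.solve(S, centred.T)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular score covariance; refit with fewer factors"
        ) from exc
    d2 = np.einsum("ij,ji->i", centred, sol)
    return np.sqrt(np.maximum(d2, 0.0))


def spectral_residuals(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Squared reconstruction residual ||x_c - t P'||^2 per sample."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    model._check_grid(X)
    Xc = X - model.x_mean
    if model.k == 0:
        return np.einsum("ij,ij->i", Xc, Xc)
    T = Xc @ model.R
    resid = Xc - T @ model.P.T
    return np.einsum("ij,ij->i", resid, resid)


def remove_and_refit(X: np.ndarray, y: np.ndarray, k: int, *,
                     threshold: float = 3.0,
                     sample_ids: list[str] | None = None,
                     wavelengths: np.ndarray | None = None,
                     fingerprint: str = "") -> tuple[PLSModel, OutlierReport]:
    """Fit, flag calibration flies beyond the distance threshold, refit once.

    Flagging is strict (> threshold); a sample at exactly the threshold is
    kept.  If more than 20% of the calibration would be dropped a warning is
    attached to the report (and emitted), but the refitted model is still
    returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 5:
        raise ValidationError("outlier screening needs at least 5 samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]

    model = fit_pls1(X, y, k, wavelengths=wavelengths, fingerprint=fingerprint)
    dist = mahalanobis_scores(model)
    resid = spectral_residuals(model, X)
    flagged = dist > threshold

    warning = None
    frac = flagged.mean()
    if frac > 0.20:
        warning = (f"{flagged.sum()} of {n} calibration samples "
                   f"({100 * frac:.1f}%) flagged as outliers")
        warnings.warn(warning, stacklevel=2)

    report = OutlierReport(sample_ids=list(sample_ids), distances=dist,
                           residuals=resid, flagged=flagged,
                           threshold=threshold, warning=warning)
    keep = ~flagged
    # refit once without the flagged flies; if flagging was so aggressive
    # that no meaningful refit is possible, keep the initial model (the
    # mass-flagging warning above already marks the run as suspect)
    if flagged.any() and keep.sum() >= 3 and np.ptp(y[keep]) > 0:
        k_refit = min(k, keep.sum() - 1)
        model = fit_pls1(X[keep], y[keep], k_refit,
                         wavelengths=wavelengths, fingerprint=fingerprint)
    return model, report
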