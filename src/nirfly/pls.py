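"""Partial least squares regression (PLS1, NIPALS) with leave-one-out PRESS.

The calibration core of the package.  A single dummy-coded or continuous
response y is regressed on the preprocessed spectra X by extracting latent
factors that maximise covariance with y:

    for a = 1..k:
        w_a = X'y / ||X'y||          (weights)
        t_a = X w_a                  (scores)
        p_a = X't_a / (t_a't_a)      (x-loadings)
        q_a = y't_a / (t_a't_a)      (y-loading)
        X <- X - t_a p_a',  y <- y - q_a t_a   (deflation)

NIPALS for a single response is deterministic — no iteration, no random
start.  The factors collapse into a coefficient vector b = W (P'W)^{-1} q so
that predictions are (x - x_mean)·b + y_mean.

Factor count is chosen from the PRESS curve of a leave-one-out
cross-validation in which every fold is re-centered and refitted without the
held-out fly.  :func:`loo_cross_validate` computes all n folds exactly but
without materialising n refits: fold cross-products are rank-one downdates
of the full X'X and X'y, and the per-factor recursion needs only those
products (the kernel form of Dayal & MacGregor).  Agreement with a naive
refit loop is exact to numerical precision and is enforced in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

_STALL_REL = 1e-13  # relative ||X'y|| threshold below which extraction stops


@dataclass
class PLSModel:
    """A fitted PLS1 calibration.

    Attributes
    ----------
    k : int
        Number of latent factors actually extracted.
    W, P : ndarray, shape (p, k)
        X-weights (unit norm) and x-loadings.
    q : ndarray, shape (k,)
        Y-loadings.
    T : ndarray, shape (n, k)
        Calibration scores.
    R : ndarray, shape (p, k)
        Projection matrix W (P'W)^{-1}; scores of new data are (X - x_mean) R.
    b : ndarray, shape (p,)
        Collapsed regression coefficient vector.
    x_mean, y_mean :
        Calibration means used for centering.
    score_cov : ndarray, shape (k, k)
        Covariance of calibration scores (ddof=1), used for Mahalanobis
        distances.
    wavelengths : ndarray or None
        Grid the model was trained on (after preprocessing), if known.
    fingerprint : str
        PreprocessConfig fingerprint the model expects on incoming data.
    """

    k: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    R: np.ndarray
    b: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    score_cov: np.ndarray
    wavelengths: np.ndarray | None = None
    fingerprint: str = ""

    @property
    def fitted(self) -> np.ndarray:
        """Training predictions."""
        return self.T @ self.q + self.y_mean

    def project(self, X: np.ndarray) -> np.ndarray:
        """Latent scores of (rows of) X under this model."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_grid(X)
        return (X - self.x_mean) @ self.R

    def _check_grid(self, X: np.ndarray) -> None:
        if X.shape[1] != self.x_mean.size:
            raise ValidationError(
                f"model expects {self.x_mean.size} wavelengths, got {X.shape[1]}"
            )

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "format": "nirfly-pls-model/1",
            "k": int(self.k),
            "y_mean": float(self.y_mean),
            "fingerprint": self.fingerprint,
            "wavelengths": None if self.wavelengths is None
            else np.asarray(self.wavelengths).tolist(),
        }
        for name in ("W", "P", "q", "T", "R", "b", "x_mean", "score_cov"):
            d[name] = np.asarray(getattr(self, name)).tolist()
        return d

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("format") != "nirfly-pls-model/1":
            raise ValidationError(f"{path}: not a nirfly PLS model bundle")
        arrays = {n: np.asarray(d[n], dtype=float)
                  for n in ("W", "P", "q", "T", "R", "b", "x_mean", "score_cov")}
        wl = d["wavelengths"]
        return cls(k=int(d["k"]), y_mean=float(d["y_mean"]),
                   fingerprint=d["fingerprint"],
                   wavelengths=None if wl is None else np.asarray(wl, dtype=float),
                   **arrays)


@dataclass
class PRESSCurve:
    """Leave-one-out PRESS as a function of factor count.

    ``press[a]`` is the PRESS with a+1 factors; ``loo_pred[i, a]`` the
    held-out prediction of sample i with a+1 factors.
    """

    press: np.ndarray
    loo_pred: np.ndarray
    k_max: int
    n: int
    y_tss: float = 0.0      # total sum of squares of y, for tie floors
    selection_rule: str = "smallest k within tolerance of the minimum PRESS"


def _nipals(Xc: np.ndarray, yc: np.ndarray, k: int):
    """NIPALS PLS1 on centered data; returns W, P, q, T (k may shrink)."""
    X = Xc.copy()
    y = yc.copy()
    n, p = X.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((n, k))
    ns_first = None
    a = 0
    while a < k:
        s = X.T @ y
        ns = float(np.linalg.norm(s))
        if ns_first is None:
            ns_first = ns
        if ns <= _STALL_REL * max(ns_first, np.finfo(float).tiny):
            break  # no extractable covariance left
        w = s / ns
        t = X @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        W[:, a] = w
        T[:, a] = t
        P[:, a] = (X.T @ t) / tt
        q[a] = float(y @ t) / tt
        X -= np.outer(t, P[:, a])
        y = y - q[a] * t
        a += 1
    return W[:, :a], P[:, :a], q[:a], T[:, :a]


def fit_pls1(X: np.ndarray, y: np.ndarray, k: int, *, center: bool = True,
             wavelengths: np.ndarray | None = None,
             fingerprint: str = "") -> PLSModel:
    """Fit a PLS1 model with ``k`` latent factors.

    With ``center=True`` (the default) X and y are centered on their own
    means, which are stored on the model; with ``center=False`` the data are
    taken as already centered and zero means are stored.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError(f"{n} spectra but {y.size} response values")
    if not 1 <= k <= min(n - 1, p):
        raise ConfigError(f"k={k} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise ValidationError("response has zero variance; nothing to calibrate")
    if center:
        x_mean = X.mean(axis=0)
        y_mean = float(y.mean())
    else:
        x_mean = np.zeros(p)
        y_mean = 0.0
    Xc = X - x_mean
    yc = y - y_mean

    W, P, q, T = _nipals(Xc, yc, k)
    k_eff = W.shape[1]
    if k_eff == 0:
        R = np.zeros((p, 0))
        b = np.zeros(p)
        score_cov = np.zeros((0, 0))
    else:
        R = W @ np.linalg.inv(P.T @ W)
        b = R @ q
        if n > 1:
            score_cov = np.atleast_2d(np.cov(T, rowvar=False, ddof=1))
        else:
            score_cov = np.zeros((k_eff, k_eff))
    return PLSModel(k=k_eff, W=W, P=P, q=q, T=T, R=R, b=b,
                    x_mean=x_mean, y_mean=y_mean, score_cov=score_cov,
                    wavelengths=None if wavelengths is None
                    else np.asarray(wavelengths, dtype=float),
                    fingerprint=fingerprint)


def predict(model: PLSModel, X: np.ndarray, *, fingerprint: str | None = None
            ) -> np.ndarray:
    """Predict the response for preprocessed (uncentered) spectra."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    model._check_grid(X)
    if fingerprint is not None and model.fingerprint and fingerprint != model.fingerprint:
        raise ValidationError(
            "preprocessing fingerprint mismatch between model and data"
        )
    return (X - model.x_mean) @ model.b + model.y_mean


def loo_cross_validate(X: np.ndarray, y: np.ndarray, k_max: int) -> PRESSCurve:
    """Exact leave-one-out PRESS for 1..k_max factors.

    Every fold is centered on the mean of its n-1 retained samples (the
    held-out fly never touches the centering statistics) and refitted.  The
    implementation runs all folds simultaneously on rank-one-downdated
    cross-products; it is algebraically identical to a naive refit loop.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError(f"{n} spectra but {y.size} response values")
    if n < 3:
        raise ValidationError("leave-one-out cross-validation needs n >= 3")
    if not 1 <= k_max <= n - 2:
        raise ConfigError(f"k_max={k_max} outside [1, n-2] = [1, {n - 2}]")
    if k_max > p:
        raise ConfigError(f"k_max={k_max} exceeds {p} wavelengths")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = np.ascontiguousarray(X - x_mean)
    yc = y - y_mean
    c = n / (n - 1.0)  # rank-one downdate weight for fold cross-products

    A0 = Xc.T @ Xc                       # (p, p) full-data cross-product
    s0 = Xc.T @ yc                       # (p,)
    # Column i holds the fold-i centered cross-product X'_{-i} y_{-i}.
    S = s0[:, None] - c * (Xc.T * yc[None, :])          # (p, n)

    norms0 = np.linalg.norm(S, axis=0)
    stall = _STALL_REL * np.maximum(norms0, np.finfo(float).tiny)

    B = np.zeros((p, n))                 # cumulative coefficient per fold
    loo_pred = np.empty((n, k_max))
    press = np.empty(k_max)
    R_list: list[np.ndarray] = []
    P_list: list[np.ndarray] = []

    for a in range(k_max):
        norms = np.linalg.norm(S, axis=0)
        active = norms > stall
        Wa = np.where(active, S / np.where(active, norms, 1.0), 0.0)
        Ra = Wa.copy()
        for Pj, Rj in zip(P_list, R_list):
            Ra -= Rj * np.einsum("ij,ij->j", Pj, Wa)
        # Fold matvec A_{-i} r_i = A0 r_i - c x_i (x_i . r_i), all folds at once
        d = np.einsum("ij,ji->i", Xc, Ra)
        M = A0 @ Ra - Xc.T * (c * d)
        tt = np.einsum("ij,ij->j", Ra, M)
        ok = active & (tt > 0)
        tt_safe = np.where(ok, tt, 1.0)
        Pa = np.where(ok, M / tt_safe, 0.0)
        qa = np.where(ok, np.einsum("ij,ij->j", Ra, S) / tt_safe, 0.0)
        S = S - Pa * (tt * qa)
        B += Ra * qa
        P_list.append(Pa)
        R_list.append(Ra)
        # Held-out prediction: (x_i - m_{-i}) . b_i + ybar_{-i}
        loo_pred[:, a] = c * np.einsum("ij,ji->i", Xc, B) + y_mean - yc / (n - 1.0)
        press[a] = float(np.sum((loo_pred[:, a] - y) ** 2))

    return PRESSCurve(press=press, loo_pred=loo_pred, k_max=k_max, n=n,
                      y_tss=float(yc @ yc))


def select_factors(curve: PRESSCurve | np.ndarray, tolerance: float = 0.02) -> int:
    """Smallest factor count whose PRESS is within ``tolerance`` of the minimum.

    Returns a 1-based factor count: the parsimonious model whose PRESS does
    not exceed (1 + tolerance) times the best PRESS on the curve.  When a
    :class:`PRESSCurve` is given, PRESS values within 1e-10 of the response
    total sum of squares count as exact ties (a perfectly predictable
    response should not buy extra factors from rounding noise).
    """
    if isinstance(curve, PRESSCurve):
        press = curve.press
        floor = 1e-10 * curve.y_tss
    else:
        press = np.asarray(curve, dtype=float)
        floor = 0.0
    if press.size == 0:
        raise ConfigError("empty PRESS curve")
    threshold = (1.0 + tolerance) * float(np.min(press)) + floor
    return int(np.argmax(press <= threshold)) + 1


def regression_coefficients(model: PLSModel,
                            smooth_window: int | None = None) -> pd.DataFrame:
    """Coefficient spectrum (wavelength, b) for plotting and band inspection.

    ``smooth_window`` applies a centred moving average for display only
    (the model itself is never smoothed); window 1 or ``None`` is identity.
    """
    if model.wavelengths is None:
        wl = np.arange(model.b.size, dtype=float)
    else:
        wl = model.wavelengths
    b = model.b
    if smooth_window is not None and smooth_window > 1:
        b = (pd.Series(b).rolling(int(smooth_window), center=True, min_periods=1)
             .mean().to_numpy())
    return pd.DataFrame({"wavelength_nm": wl, "coefficient": b})
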