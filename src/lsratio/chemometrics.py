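"""From-scratch latent-variable calibration: PCR and NIPALS PLS2 regression.

Both methods regress responses (analyte concentrations, in mM) on a
low-dimensional representation of mean-centered spectra.  PCR projects onto
the principal components of X (directions of greatest spectral variance,
via SVD); PLSR builds factors that maximize covariance between spectra and
concentrations (NIPALS algorithm).  Spectra are centered but not
variance-scaled: absorbance channels share units, and scaling would amplify
noise-only channels such as zapped regions.

A fitted :class:`LatentModel` stores the full factor decomposition up to the
requested count, so models with fewer factors can be obtained by truncation
without refitting — the basis of fast cross-validated factor scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    InvalidParameterError,
    UndefinedMetricError,
)

__all__ = [
    "LatentModel",
    "Metrics",
    "fit_pcr",
    "fit_plsr",
    "predict",
    "score",
]

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class Metrics:
    """Coefficient of determination and mean squared error."""

    r2: float
    mse: float


@dataclass
class LatentModel:
    """A fitted PCR or PLSR calibration model.

    ``x_loadings`` has one column per factor (principal components for PCR,
    P-loadings for PLSR).  ``factor_coefs`` holds the per-factor response
    regression (PCR: OLS of Y on scores; PLSR: Q y-loadings), so the
    regression coefficient matrix for any truncated factor count can be
    reassembled without refitting.
    """

    kind: Literal["pcr", "plsr"]
    n_factors: int
    x_mean: np.ndarray          # (p,)
    y_mean: np.ndarray          # (m,)
    x_loadings: np.ndarray      # (p, k)
    factor_coefs: np.ndarray    # (k, m)
    coefficients: np.ndarray    # (p, m), for n_factors factors
    weights: np.ndarray | None = None  # (p, k), PLSR only
    response_names: tuple[str, ...] = ()
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.x_mean.size

    @property
    def n_responses(self) -> int:
        return self.y_mean.size

    def coefficients_for(self, k: int) -> np.ndarray:
        """Regression coefficients using only the first k factors."""
        if not (1 <= k <= self.n_factors):
            raise InvalidParameterError(
                f"k must be in [1, {self.n_factors}], got {k}"
            )
        if self.kind == "pcr":
            return self.x_loadings[:, :k] @ self.factor_coefs[:k]
        # PLSR: B_k = W_k (P_k' W_k)^-1 Q_k'.  Trailing all-zero factors
        # (data exhausted before the requested count) are dropped first.
        nz = np.flatnonzero(np.linalg.norm(self.weights[:, :k], axis=0) > 0)
        if nz.size == 0:
            return np.zeros((self.n_features, self.n_responses))
        W, P, Q = self.weights[:, nz], self.x_loadings[:, nz], self.factor_coefs[nz]
        return W @ np.linalg.solve(P.T @ W, Q)

    def truncated(self, k: int) -> "LatentModel":
        """A view of this model restricted to its first k factors."""
        return LatentModel(
            kind=self.kind,
            n_factors=k,
            x_mean=self.x_mean,
            y_mean=self.y_mean,
            x_loadings=self.x_loadings[:, :k],
            factor_coefs=self.factor_coefs[:k],
            coefficients=self.coefficients_for(k),
            weights=None if self.weights is None else self.weights[:, :k],
            response_names=self.response_names,
            training_meta=self.training_meta,
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": SERIALIZATION_VERSION,
            "kind": self.kind,
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "factor_coefs": self.factor_coefs.tolist(),
            "coefficients": self.coefficients.tolist(),
            "weights": None if self.weights is None else self.weights.tolist(),
            "response_names": list(self.response_names),
            "training_meta": self.training_meta,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LatentModel":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and not source.lstrip().startswith("{")):
            source = Path(source).read_text()
        payload = json.loads(source)
        if payload.get("version") != SERIALIZATION_VERSION:
            raise InvalidParameterError(
                f"unsupported model file version {payload.get('version')!r}"
            )
        return cls(
            kind=payload["kind"],
            n_factors=payload["n_factors"],
            x_mean=np.array(payload["x_mean"]),
            y_mean=np.array(payload["y_mean"]),
            x_loadings=np.array(payload["x_loadings"]),
            factor_coefs=np.array(payload["factor_coefs"]),
            coefficients=np.array(payload["coefficients"]),
            weights=None if payload["weights"] is None else np.array(payload["weights"]),
            response_names=tuple(payload["response_names"]),
            training_meta=payload["training_meta"],
        )


def _validate_xy(X: np.ndarray, Y: np.ndarray, n_factors: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise InvalidParameterError(f"X has {n} rows but Y has {Y.shape[0]}")
    if n < 2:
        raise InvalidParameterError("at least 2 training samples are required")
    if not (1 <= n_factors <= min(n - 1, p)):
        raise InvalidParameterError(
            f"n_factors must be in [1, {min(n - 1, p)}] for {n}x{p} data, "
            f"got {n_factors}"
        )
    return X, Y


def fit_pcr(
    X: np.ndarray,
    Y: np.ndarray,
    n_pc: int,
    response_names: tuple[str, ...] = (),
    training_meta: dict | None = None,
) -> LatentModel:
    """Principal component regression.

    Mean-centers X and Y, takes the SVD of centered X, and regresses centered
    Y on the first ``n_pc`` score vectors by ordinary least squares.  Because
    scores are orthogonal, the per-component regression coefficients are
    independent of ``n_pc``, so the model can later be truncated freely.
    """
    X, Y = _validate_xy(X, Y, n_pc)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    if not np.any(np.abs(Xc) > 0):
        raise DegenerateInputError("X has zero variance in every channel")

    try:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    except np.linalg.LinAlgError:
        # gesdd occasionally fails on near-degenerate (e.g. resampled) data;
        # the slower gesvd driver is more robust.
        from scipy.linalg import svd as _svd

        U, s, Vt = _svd(Xc, full_matrices=False, lapack_driver="gesvd")
    # Keep only numerically nonzero components.
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_pc, rank)
    V = Vt[:k].T                       # (p, k) principal directions
    # OLS of Yc on scores T = U S: gamma = S^-1 U' Yc (scores orthogonal).
    gamma = (U[:, :k].T @ Yc) / s[:k, None]
    if k < n_pc:
        # Pad with zero directions so the factor count contract holds.
        V = np.hstack([V, np.zeros((V.shape[0], n_pc - k))])
        gamma = np.vstack([gamma, np.zeros((n_pc - k, Yc.shape[1]))])
    model = LatentModel(
        kind="pcr",
        n_factors=n_pc,
        x_mean=x_mean,
        y_mean=y_mean,
        x_loadings=V,
        factor_coefs=gamma,
        coefficients=V @ gamma,
        response_names=tuple(response_names),
        training_meta=training_meta or {},
    )
    return model


def fit_plsr(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    response_names: tuple[str, ...] = (),
    training_meta: dict | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> LatentModel:
    """NIPALS PLS2 regression on mean-centered X and Y.

    Per factor: the weight vector is the dominant direction of X'Y (found by
    the NIPALS inner power iteration), scores t = Xw, X-loadings
    p = X't/(t't), Y-loadings q = Y't/(t't), then X is deflated by t p' and
    Y by t q'.  The coefficient matrix is B = W (P'W)^-1 Q'.  A response
    column with zero variance (a constant analyte concentration) contributes
    nothing to X'Y and is handled without special-casing: its coefficients
    are zero and its predictions equal the training mean.
    """
    X, Y = _validate_xy(X, Y, n_lv)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    if not np.any(np.abs(Xc) > 0):
        raise DegenerateInputError("X has zero variance in every channel")

    n, p = Xc.shape
    m = Yc.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((n_lv, m))
    x_scale = np.abs(Xc).max() or 1.0

    Xd, Yd = Xc.copy(), Yc.copy()
    n_effective = 0
    for a in range(n_lv):
        y_norms = np.linalg.norm(Yd, axis=0)
        if np.all(y_norms < 1e-14) or np.abs(Xd).max() < 1e-14 * x_scale:
            break  # nothing left to model; remaining factors stay zero
        u = Yd[:, int(np.argmax(y_norms))]
        w_old = np.zeros(p)
        for it in range(max_iter):
            w = Xd.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm < 1e-300:
                raise ConvergenceError(
                    f"factor {a + 1}: weight vector collapsed (no X-Y covariance)"
                )
            w /= w_norm
            t = Xd @ w
            tt = float(t @ t)
            q = (Yd.T @ t) / tt
            if np.linalg.norm(w - w_old) <= tol:
                break
            w_old = w
            q_norm = float(q @ q)
            if q_norm < 1e-300:
                break  # Y exhausted; accept current direction
            u = (Yd @ q) / q_norm
        else:
            raise ConvergenceError(
                f"factor {a + 1}: NIPALS inner loop did not converge "
                f"in {max_iter} iterations"
            )
        p_load = (Xd.T @ t) / tt
        W[:, a] = w
        P[:, a] = p_load
        Q[a] = q
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q)
        n_effective += 1

    if n_effective == 0:
        coefficients = np.zeros((p, m))
    else:
        We, Pe, Qe = W[:, :n_effective], P[:, :n_effective], Q[:n_effective]
        coefficients = We @ np.linalg.solve(Pe.T @ We, Qe)
    model = LatentModel(
        kind="plsr",
        n_factors=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        x_loadings=P,
        factor_coefs=Q,
        coefficients=coefficients,
        weights=W,
        response_names=tuple(response_names),
        training_meta=training_meta or {},
    )
    return model


def predict(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses: (X_new - x_mean) @ B + y_mean."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise InvalidParameterError(
            f"X_new has {X_new.shape[1]} features, model expects {model.n_features}"
        )
    return (X_new - model.x_mean) @ model.coefficients + model.y_mean


def score(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """R^2 and MSE of predictions against known values (single response)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise InvalidParameterError("y_true and y_pred lengths differ")
    if y_true.size < 2:
        raise InvalidParameterError("at least 2 values are required")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 is undefined for constant y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return Metrics(r2=1.0 - ss_res / ss_tot, mse=ss_res / y_true.size)
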