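"""Session-grouped splitting, cross-validated factor scans, factor selection.

Calibration/test splitting is by whole measurement sessions, never by
individual spectra: replicate spectra from one session share background and
gain state, so splitting within a session would leak session information
into the test set and overstate performance.  Within the calibration set,
K-fold cross-validation over spectra drives the choice of factor count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .chemometrics import LatentModel, fit_pcr, fit_plsr, predict, score
from .errors import CannotSplitError, InvalidParameterError
from .synthetic import Spectrum

__all__ = [
    "SplitPlan",
    "CVResult",
    "grouped_half_split",
    "apply_split",
    "spectra_matrix",
    "cv_factor_scan",
    "select_factors",
]

RESPONSE_NAMES = ("DPPC", "SM")


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of whole sessions to calibration and test sets."""

    calibration_sessions: frozenset[str]
    test_sessions: frozenset[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.calibration_sessions & self.test_sessions:
            raise InvalidParameterError("calibration and test sessions overlap")


@dataclass(frozen=True)
class CVResult:
    """Per-factor-count training and cross-validation performance curves."""

    factor_counts: tuple[int, ...]
    r2_train: tuple[float, ...]
    mse_train: tuple[float, ...]
    r2_cv: tuple[float, ...]
    mse_cv: tuple[float, ...]
    k: int
    n_repeats: int
    seed: int
    model_kind: str = ""
    preprocessing: str = ""


def grouped_half_split(
    spectra: Sequence[Spectrum],
    seed: int | None = None,
    assignment: Sequence[str] | None = None,
) -> SplitPlan:
    """Randomly assign half the sessions to calibration (ceil(n/2) when odd).

    An explicit ``assignment`` of calibration session ids bypasses the
    randomness (used to pin a documented split).
    """
    sessions = sorted({sp.session_id for sp in spectra})
    if len(sessions) < 2:
        raise CannotSplitError("need at least 2 sessions to split")
    if assignment is not None:
        cal = frozenset(assignment)
        unknown = cal - set(sessions)
        if unknown:
            raise InvalidParameterError(f"unknown sessions in assignment: {sorted(unknown)}")
        return SplitPlan(cal, frozenset(sessions) - cal, seed=None)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sessions))
    n_cal = (len(sessions) + 1) // 2  # calibration gets the larger half
    cal = frozenset(sessions[i] for i in order[:n_cal])
    return SplitPlan(cal, frozenset(sessions) - cal, seed=seed)


def apply_split(
    spectra: Sequence[Spectrum], plan: SplitPlan
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Partition spectra according to a split plan (order preserved)."""
    cal = [sp for sp in spectra if sp.session_id in plan.calibration_sessions]
    test = [sp for sp in spectra if sp.session_id in plan.test_sessions]
    return cal, test


def spectra_matrix(spectra: Sequence[Spectrum]) -> tuple[np.ndarray, np.ndarray]:
    """Stack spectra into X (n x p) and true concentrations Y (n x 2, mM)."""
    if not spectra:
        raise InvalidParameterError("empty spectrum list")
    grid = spectra[0].wavenumbers
    for sp in spectra[1:]:
        if sp.wavenumbers.size != grid.size or not np.allclose(sp.wavenumbers, grid):
            raise InvalidParameterError("spectra are not on a common grid")
    X = np.vstack([sp.absorbances for sp in spectra])
    Y = np.array(
        [
            [
                sp.true_dppc if sp.true_dppc is not None else np.nan,
                sp.true_sm if sp.true_sm is not None else np.nan,
            ]
            for sp in spectra
        ]
    )
    return X, Y


def _fit(kind: str, X: np.ndarray, Y: np.ndarray, n_factors: int) -> LatentModel:
    if kind == "pcr":
        return fit_pcr(X, Y, n_factors, response_names=RESPONSE_NAMES)
    if kind == "plsr":
        return fit_plsr(X, Y, n_factors, response_names=RESPONSE_NAMES)
    raise InvalidParameterError(f"unknown model kind {kind!r}")


def cv_factor_scan(
    calibration: Sequence[Spectrum] | tuple[np.ndarray, np.ndarray],
    model_kind: Literal["pcr", "plsr"],
    max_factors: int = 14,
    k: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    response: int = 0,
    preprocessing: str = "",
) -> CVResult:
    """K-fold cross-validated R^2/MSE curves over factor counts 1..max_factors.

    For each fold a single model with ``max_factors`` factors is fitted on
    the training portion and truncated to every smaller count, so the scan
    costs one fit per fold.  Metrics are computed on the given response
    column (default DPPC, the varying analyte) and averaged over folds and
    repeats.  Fold membership is drawn over spectra (not sessions) and
    re-randomized per repeat; fixed seed gives identical results.
    """
    if isinstance(calibration, tuple):
        X, Y = calibration
    else:
        X, Y = spectra_matrix(calibration)
    n = X.shape[0]
    if not (2 <= k <= n):
        raise InvalidParameterError(f"k must be in [2, {n}], got {k}")
    min_train = n - (n // k + (1 if n % k else 0))
    if max_factors > min(min_train - 1, X.shape[1]):
        raise InvalidParameterError(
            f"max_factors={max_factors} infeasible for folds of training size {min_train}"
        )

    rng = np.random.default_rng(seed)
    counts = np.arange(1, max_factors + 1)
    y_all = Y[:, response]
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    if ss_tot == 0.0:
        raise InvalidParameterError("CV response is constant; R^2 undefined")

    # Training metrics are averaged over folds; held-out metrics are pooled
    # over all held-out predictions of a repeat (PRESS form), so fold sizes
    # down to one spectrum (leave-one-out) are well defined.
    r2_tr = np.zeros(max_factors)
    mse_tr = np.zeros(max_factors)
    press = np.zeros(max_factors)
    n_folds_total = 0
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold in folds:
            held = np.zeros(n, dtype=bool)
            held[fold] = True
            model = _fit(model_kind, X[~held], Y[~held], max_factors)
            Xc_tr, Xc_cv = X[~held], X[held]
            y_tr, y_cv = Y[~held, response], Y[held, response]
            for i, kk in enumerate(counts):
                B = model.coefficients_for(int(kk))
                pred_tr = (Xc_tr - model.x_mean) @ B[:, response] + model.y_mean[response]
                pred_cv = (Xc_cv - model.x_mean) @ B[:, response] + model.y_mean[response]
                m_tr = score(y_tr, pred_tr)
                r2_tr[i] += m_tr.r2
                mse_tr[i] += m_tr.mse
                press[i] += float(np.sum((y_cv - pred_cv) ** 2))
            n_folds_total += 1

    return CVResult(
        factor_counts=tuple(int(c) for c in counts),
        r2_train=tuple(r2_tr / n_folds_total),
        mse_train=tuple(mse_tr / n_folds_total),
        r2_cv=tuple(1.0 - (press / n_repeats) / ss_tot),
        mse_cv=tuple((press / n_repeats) / n),
        k=k,
        n_repeats=n_repeats,
        seed=seed,
        model_kind=model_kind,
        preprocessing=preprocessing,
    )


def select_factors(cv_result: CVResult, rule: str = "parsimony", tol: float = 0.10) -> int:
    """Choose a factor count from a CV scan.

    Rules: ``min_cv_mse`` takes the argmin of the CV MSE curve;
    ``parsimony`` (default) takes the smallest count whose CV MSE is within
    ``tol`` (relative) of the minimum, codifying the preference for fewer
    factors; ``fixed:n`` returns n regardless of the curves.
    """
    if not cv_result.factor_counts:
        raise InvalidParameterError("empty CV result")
    mse = np.asarray(cv_result.mse_cv)
    if rule == "min_cv_mse":
        return cv_result.factor_counts[int(np.argmin(mse))]
    if rule == "parsimony":
        threshold = (1.0 + tol) * mse.min()
        idx = int(np.flatnonzero(mse <= threshold)[0])
        return cv_result.factor_counts[idx]
    if rule.startswith("fixed:"):
        try:
            return int(rule.split(":", 1)[1])
        except ValueError:
            raise InvalidParameterError(f"malformed fixed rule {rule!r}") from None
    raise InvalidParameterError(f"unknown selection rule {rule!r}")
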