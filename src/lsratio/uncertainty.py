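"""Bootstrap prediction intervals for concentrations and L/S ratios.

The construction is a regression prediction-interval bootstrap: calibration
(spectrum, concentration) pairs are resampled with replacement — by whole
measurement sessions when session labels are available, since spectra within
a session share instrument state — the calibration model is refitted on each
resample, the test spectra are predicted, and a residual drawn from the
refit's out-of-bag calibration residuals is added to each prediction.  The
interval is the empirical (alpha/2, 1-alpha/2) percentile band of the
bootstrap values, so it captures both model (coefficient) uncertainty and
single-observation noise without assuming residual normality.  The reported
point prediction comes from the model fitted on the full calibration set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .chemometrics import predict
from .errors import DegenerateInputError, InvalidParameterError
from .model_selection import _fit

__all__ = [
    "ModelSpec",
    "PredictionInterval",
    "IntervalSummary",
    "bootstrap_samples",
    "bootstrap_pi",
    "ratio_pi",
    "intervals_from_samples",
    "ratio_intervals_from_samples",
    "summarize_intervals",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to refit on each bootstrap resample."""

    kind: Literal["pcr", "plsr"]
    n_factors: int
    preprocessing: str = ""


@dataclass(frozen=True)
class PredictionInterval:
    """Point prediction with an empirical percentile interval."""

    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise InvalidParameterError("level must be in (0, 1)")
        if not self.lower < self.upper:
            raise InvalidParameterError(
                f"degenerate interval [{self.lower}, {self.upper}]"
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class IntervalSummary:
    """Per-point interval extents, maximized/averaged over a test set."""

    max_positive: float
    max_negative: float
    max_range: float
    mean_positive: float
    mean_negative: float


def _resample_indices(
    rng: np.random.Generator, n: int, X: np.ndarray, max_retries: int = 10
) -> np.ndarray:
    """Draw a bootstrap index set, retrying degenerate (single-row) resamples."""
    for _ in range(max_retries):
        idx = rng.integers(0, n, n)
        if np.ptp(X[idx], axis=0).max() > 0:
            return idx
    raise DegenerateInputError(
        f"bootstrap resample degenerate after {max_retries} retries"
    )


def bootstrap_samples(
    X_cal: np.ndarray,
    Y_cal: np.ndarray,
    spec: ModelSpec,
    X_test: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    groups: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap predictive draws for every test spectrum and response.

    Returns ``(points, samples)`` where ``points`` is (n_test, m) from the
    full-calibration fit and ``samples`` is (n_boot, n_test, m); each sample
    is a refit prediction plus a residual resampled from that refit's
    calibration residuals.

    When ``groups`` (one label per calibration row, e.g. session ids) is
    given, whole groups are resampled with replacement instead of rows.
    Calibration spectra from one session share background and gain state, so
    the session is the independent sampling unit; resampling rows would
    understate between-session uncertainty and produce intervals that
    under-cover fresh sessions.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    Y_cal = np.atleast_2d(np.asarray(Y_cal, dtype=float))
    if Y_cal.shape[0] == 1 and X_cal.shape[0] != 1:
        Y_cal = Y_cal.T
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    n, _ = X_cal.shape
    if n_boot < 200:
        raise InvalidParameterError(f"n_boot must be >= 200, got {n_boot}")
    if n < 20:
        raise InvalidParameterError(f"calibration set too small ({n} < 20 spectra)")

    rng = np.random.default_rng(seed)
    full_model = _fit(spec.kind, X_cal, Y_cal, spec.n_factors)
    points = predict(full_model, X_test)

    group_rows = None
    if groups is not None:
        groups = np.asarray(groups)
        if groups.size != n:
            raise InvalidParameterError("groups must have one label per calibration row")
        group_rows = [np.flatnonzero(groups == g) for g in np.unique(groups)]

    n_test, m = points.shape
    samples = np.empty((n_boot, n_test, m))
    for b in range(n_boot):
        if group_rows is not None:
            chosen = rng.integers(0, len(group_rows), len(group_rows))
            idx = np.concatenate([group_rows[g] for g in chosen])
        else:
            idx = _resample_indices(rng, n, X_cal)
        model_b = _fit(spec.kind, X_cal[idx], Y_cal[idx], spec.n_factors)
        pred_b = predict(model_b, X_test)
        # Residual pool: the bootstrap model's errors on the out-of-bag
        # calibration rows.  OOB rows were not fitted by this refit, so
        # their errors are honestly sized prediction errors rather than
        # shrunken in-sample fit errors; if a resample leaves almost no
        # rows out, the whole calibration set is used instead.
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        pool = np.flatnonzero(oob)
        if pool.size < 5:
            pool = np.arange(n)
        resid_b = Y_cal[pool] - predict(model_b, X_cal[pool])
        draw = rng.integers(0, pool.size, n_test)
        samples[b] = pred_b + resid_b[draw]
    return points, samples


def _percentile_interval(
    values: np.ndarray, point: float, level: float, n_boot: int, seed: int, meta: dict
) -> PredictionInterval:
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    if hi <= lo:
        # Degenerate band (e.g. noiseless calibration): keep the strict
        # lower < upper contract with a negligible symmetric widening.
        eps = max(abs(float(lo)), 1.0) * 1e-12
        lo, hi = float(lo) - eps, float(hi) + eps
    return PredictionInterval(
        point=float(point),
        lower=float(lo),
        upper=float(hi),
        level=level,
        n_boot=n_boot,
        seed=seed,
        meta=meta,
    )


def intervals_from_samples(
    points: np.ndarray,
    samples: np.ndarray,
    response: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> list[PredictionInterval]:
    """Percentile intervals for one response from precomputed bootstrap draws."""
    n_boot = samples.shape[0]
    return [
        _percentile_interval(
            samples[:, i, response], points[i, response], level, n_boot, seed, {}
        )
        for i in range(points.shape[0])
    ]


def bootstrap_pi(
    X_cal: np.ndarray,
    Y_cal: np.ndarray,
    spec: ModelSpec,
    X_test: np.ndarray,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    response: int = 0,
    groups: Sequence | None = None,
) -> list[PredictionInterval]:
    """Percentile prediction intervals for one response over a test set."""
    points, samples = bootstrap_samples(X_cal, Y_cal, spec, X_test, n_boot, seed, groups)
    return intervals_from_samples(points, samples, response, level, seed)


def ratio_pi(
    X_cal: np.ndarray,
    Y_cal: np.ndarray,
    spec: ModelSpec,
    X_test: np.ndarray,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    eps: float = 0.05,
    dppc_index: int = 0,
    sm_index: int = 1,
    groups: Sequence | None = None,
) -> list[PredictionInterval]:
    """Percentile prediction intervals for the L/S (DPPC/SM) ratio.

    Each bootstrap replicate's ratio uses that replicate's predicted
    concentrations including residual draws.  Replicates whose SM prediction
    falls at or below ``eps`` (mM) are rejected per test point; if more than
    5% of replicates are rejected for a point, the interval's ``meta``
    carries a ``high_rejection_rate`` warning.
    """
    points, samples = bootstrap_samples(X_cal, Y_cal, spec, X_test, n_boot, seed, groups)
    return ratio_intervals_from_samples(
        points, samples, level=level, seed=seed, eps=eps,
        dppc_index=dppc_index, sm_index=sm_index,
    )


def ratio_intervals_from_samples(
    points: np.ndarray,
    samples: np.ndarray,
    level: float = 0.95,
    seed: int = 0,
    eps: float = 0.05,
    dppc_index: int = 0,
    sm_index: int = 1,
) -> list[PredictionInterval]:
    """L/S-ratio percentile intervals from precomputed bootstrap draws."""
    n_boot = samples.shape[0]
    intervals: list[PredictionInterval] = []
    for i in range(points.shape[0]):
        dppc = samples[:, i, dppc_index]
        sm = samples[:, i, sm_index]
        valid = sm > eps
        n_rejected = int(n_boot - valid.sum())
        if not valid.any():
            raise DegenerateInputError(
                f"test point {i}: every bootstrap SM prediction <= {eps} mM"
            )
        ratios = dppc[valid] / sm[valid]
        meta: dict = {"n_rejected": n_rejected}
        if n_rejected > 0.05 * n_boot:
            meta["high_rejection_rate"] = True
        point_sm = points[i, sm_index]
        if point_sm <= eps:
            raise DegenerateInputError(
                f"test point {i}: point SM prediction {point_sm} <= {eps} mM"
            )
        point_ratio = points[i, dppc_index] / point_sm
        intervals.append(
            _percentile_interval(ratios, point_ratio, level, n_boot, seed, meta)
        )
    return intervals


def summarize_intervals(intervals: Sequence[PredictionInterval]) -> IntervalSummary:
    """Maximum and mean interval extents over a test set."""
    if not intervals:
        raise InvalidParameterError("empty interval list")
    pos = np.array([iv.upper - iv.point for iv in intervals])
    neg = np.array([iv.point - iv.lower for iv in intervals])
    rng_ = np.array([iv.upper - iv.lower for iv in intervals])
    return IntervalSummary(
        max_positive=float(pos.max()),
        max_negative=float(neg.max()),
        max_range=float(rng_.max()),
        mean_positive=float(pos.mean()),
        mean_negative=float(neg.mean()),
    )
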