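"""Transport-grasp coordination via lagged cross-correlation.

Spatial coordination is the maximum Pearson correlation between transport
velocity and grasp aperture over integer lags; temporal coordination is the
lag at which that maximum occurs.  Sign convention: positive lag means
transport velocity leads aperture.  Each lag's coefficient is normalized over
its own overlap (a true sliding Pearson), so it is bounded in [-1, 1] at every
lag.  Coefficients are aggregated across trials on the Fisher-z scale and
back-transformed for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atanh, ceil, floor, tanh
from typing import TYPE_CHECKING

import numpy as np

from .errors import DegenerateCoordinationError, ParameterError

if TYPE_CHECKING:  # avoid a runtime import cycle with the generator modules
    from .events import MovementWindow


@dataclass
class CoordinationResult:
    r_max: float
    lag_samples: int
    lag_ms: float
    n_overlap: int


def _pearson_at_lag(v: np.ndarray, a: np.ndarray, k: int) -> tuple[float, int]:
    """Pearson r between v and a shifted by k samples; positive k = v leads.

    a(t) responding later than v(t) by L samples means a[t + L] tracks v[t],
    so the correlation of v[:n-k] with a[k:] peaks at k = +L.
    """
    if k >= 0:
        x, y = v[: v.shape[0] - k], a[k:]
    else:
        x, y = v[-k:], a[: a.shape[0] + k]
    m = x.shape[0]
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(xc.dot(xc) * yc.dot(yc))
    if denom == 0.0:
        return np.nan, m
    return float(xc.dot(yc) / denom), m


def cross_correlate(
    velocity: np.ndarray,
    aperture: np.ndarray,
    window: "MovementWindow | None" = None,
    fs: float = 120.0,
    max_lag_fraction: float = 0.5,
    min_overlap_fraction: float = 0.5,
    use_abs: bool = False,
    tie_tol: float = 1e-12,
) -> CoordinationResult:
    """Maximum cross-correlation coefficient and its signed lag.

    The maximizer is the signed maximum over lags (``use_abs`` switches to the
    maximum magnitude).  Ties within ``tie_tol`` resolve to the smallest |lag|,
    then to the positive lag.
    """
    v = np.asarray(velocity, dtype=float)
    a = np.asarray(aperture, dtype=float)
    if window is not None:
        v = v[window.start_index : window.end_index + 1]
        a = a[window.start_index : window.end_index + 1]
    if v.shape != a.shape or v.ndim != 1:
        raise ParameterError(f"series shapes must match, got {v.shape} vs {a.shape}")
    n = v.shape[0]
    if n < 8:
        raise ParameterError(f"window must span at least 8 samples, got {n}")
    if np.ptp(v) == 0.0 or np.ptp(a) == 0.0:
        raise DegenerateCoordinationError("zero variance in velocity or aperture window")

    max_lag = floor(max_lag_fraction * n)
    min_overlap = max(3, ceil(min_overlap_fraction * n))
    lags = [k for k in range(-max_lag, max_lag + 1) if n - abs(k) >= min_overlap]
    if not lags:
        raise DegenerateCoordinationError(
            f"no lag in +-{max_lag} leaves at least {min_overlap} overlapping samples"
        )

    results = {k: _pearson_at_lag(v, a, k) for k in lags}
    scores = {k: (abs(r) if use_abs else r) for k, (r, _) in results.items() if np.isfinite(r)}
    if not scores:
        raise DegenerateCoordinationError("all lags degenerate (zero overlap variance)")
    best = max(scores.values())
    # ties: smallest |k| first, positive before negative
    candidates = sorted(
        (k for k, s in scores.items() if s >= best - tie_tol),
        key=lambda k: (abs(k), 0 if k >= 0 else 1),
    )
    k_best = candidates[0]
    r_best, overlap = results[k_best]
    return CoordinationResult(
        r_max=r_best,
        lag_samples=k_best,
        lag_ms=1000.0 * k_best / fs,
        n_overlap=overlap,
    )


def fisher_z(r: float, clip: bool = False) -> float:
    """Variance-stabilizing z = atanh(r); |r| >= 1 is rejected unless clipped."""
    if abs(r) >= 1.0:
        if not clip:
            raise ParameterError(f"|r| must be < 1 for the Fisher transform, got {r}")
        import logging

        logging.getLogger(__name__).warning("clipping |r| = %s to 0.999999 for Fisher z", r)
        r = float(np.sign(r)) * 0.999999
    return atanh(r)


def inverse_fisher_z(z: float) -> float:
    return tanh(z)


def aggregate_coordination(results: list[CoordinationResult]) -> tuple[float, float]:
    """Across-trial mean coefficient (via Fisher-z averaging) and mean lag in ms."""
    if not results:
        raise ParameterError("cannot aggregate an empty list of coordination results")
    z_mean = float(np.mean([fisher_z(res.r_max) for res in results]))
    lag_mean = float(np.mean([res.lag_ms for res in results]))
    return inverse_fisher_z(z_mean), lag_mean
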