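"""Cross-correlation coordination and Fisher-z handling."""

import numpy as np
import pytest

from rtg.coordination import (
    aggregate_coordination,
    cross_correlate,
    fisher_z,
    inverse_fisher_z,
)
from rtg.errors import DegenerateCoordinationError, ParameterError

FS = 120.0


def brute_force_best_lag(v, a, max_lag, min_overlap, use_abs=False):
    """Independent oracle: plain loop with np.corrcoef per lag, then the
    stated tie policy (ties within 1e-12 -> smallest |lag|, then positive)."""
    table = {}
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            x, y = v[: len(v) - k], a[k:]
        else:
            x, y = v[-k:], a[: len(a) + k]
        if len(x) < min_overlap or np.std(x) == 0 or np.std(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        table[k] = (abs(r) if use_abs else r, r)
    top = max(score for score, _ in table.values())
    ties = [k for k, (score, _) in table.items() if score >= top - 1e-12]
    k_best = min(ties, key=lambda k: (abs(k), 0 if k >= 0 else 1))
    return k_best, table[k_best][1]


def bell(n, center, width):
    i = np.arange(n)
    return np.exp(-0.5 * ((i - center) / width) ** 2)


class TestCrossCorrelate:
    def test_identical_series(self):
        v = bell(100, 50, 12)
        res = cross_correlate(v, v, fs=FS)
        assert res.lag_samples == 0
        assert res.r_max == pytest.approx(1.0, abs=1e-12)

    def test_delayed_copy_positive_lag_means_velocity_leads(self):
        v = bell(120, 50, 10)
        a = np.roll(v, 5)  # aperture trails velocity by 5 samples
        res = cross_correlate(v, a, fs=FS)
        assert res.lag_samples == 5
        assert res.r_max > 0.999
        assert res.lag_ms == pytest.approx(5000 / FS)

    def test_sign_flip_with_abs_max(self):
        v = bell(100, 50, 12)
        res = cross_correlate(v, -v, fs=FS, use_abs=True)
        assert res.lag_samples == 0
        assert res.r_max == pytest.approx(-1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        v = bell(100, 40, 9) + 0.05 * rng.normal(size=100)
        a = bell(100, 55, 14) + 0.05 * rng.normal(size=100)
        r1 = cross_correlate(v, a, fs=FS)
        r2 = cross_correlate(2.5 * v + 1.0, 0.3 * a + 7.0, fs=FS)
        assert r1.lag_samples == r2.lag_samples
        assert r1.r_max == pytest.approx(r2.r_max, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateCoordinationError):
            cross_correlate(np.ones(50), np.arange(50.0), fs=FS)

    def test_window_too_short_rejected(self):
        with pytest.raises(ParameterError):
            cross_correlate(np.arange(5.0), np.arange(5.0), fs=FS)

    def test_matches_brute_force_oracle(self, rng):
        from math import ceil, floor

        for _ in range(100):
            n = int(rng.integers(12, 80))
            v = rng.normal(size=n).cumsum()
            a = rng.normal(size=n).cumsum()
            if np.ptp(v) == 0 or np.ptp(a) == 0:
                continue
            res = cross_correlate(v, a, fs=FS)
            k, r = brute_force_best_lag(v, a, floor(0.5 * n), max(3, ceil(0.5 * n)))
            assert res.lag_samples == k
            assert res.r_max == pytest.approx(r, abs=1e-12)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_value(self):
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)

    def test_round_trip(self):
        assert inverse_fisher_z(fisher_z(0.87)) == pytest.approx(0.87, abs=1e-12)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_unit_correlation_rejected(self, r):
        with pytest.raises(ParameterError):
            fisher_z(r)

    def test_clip_policy(self):
        assert fisher_z(1.0, clip=True) == pytest.approx(np.arctanh(0.999999))


class TestAggregation:
    def make(self, rs):
        from rtg.coordination import CoordinationResult

        return [CoordinationResult(r, 2, 2000 / FS, 50) for r in rs]

    def test_single_trial_passthrough(self):
        r, lag = aggregate_coordination(self.make([0.7]))
        assert r == pytest.approx(0.7, abs=1e-12)
        assert lag == pytest.approx(2000 / FS)

    def test_equal_coefficients_unchanged(self):
        r, _ = aggregate_coordination(self.make([0.6, 0.6, 0.6]))
        assert r == pytest.approx(0.6, abs=1e-12)

    def test_z_average_differs_from_arithmetic_mean(self):
        # tanh(mean(atanh([0.2, 0.9]))) = 0.684470 — above the arithmetic 0.55
        r, _ = aggregate_coordination(self.make([0.2, 0.9]))
        assert r == pytest.approx(0.6844698817, abs=1e-9)
        assert r > 0.55

    def test_aggregate_bounded_by_extremes(self, rng):
        rs = rng.uniform(-0.9, 0.95, size=12)
        r, _ = aggregate_coordination(self.make(list(rs)))
        assert rs.min() <= r <= rs.max()

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_coordination([])
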