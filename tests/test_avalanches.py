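import numpy as np
import pytest

from cros.avalanches import (compute_threshold, extract_avalanches,
                             kappa_index)
from cros.synthetic import bounded_powerlaw_ppf, sample_bounded_powerlaw


class TestThreshold:
    def test_half_median(self):
        assert compute_threshold([0, 2, 4, 2, 0], 0.5) == 1.0

    def test_gamma_one_is_median(self, small_trace):
        med = np.median(small_trace.A)
        if med > 0:
            assert compute_threshold(small_trace.A, 1.0) == med

    def test_constant_trace(self):
        assert compute_threshold(np.full(100, 6), 0.75) == 4.5

    def test_zero_median_warns(self):
        with pytest.warns(RuntimeWarning):
            assert compute_threshold([0, 0, 0, 5], 0.5) == 0.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            compute_threshold([1, 2], 0.0)
        with pytest.raises(ValueError):
            compute_threshold([], 0.5)


class TestExtraction:
    def test_single_event_bookkeeping(self):
        cat = extract_avalanches(np.array([0, 0, 3, 5, 2, 0, 0]), 1.5)
        assert len(cat) == 1
        assert cat.t_start[0] == 2 and cat.t_end[0] == 5
        assert cat.T[0] == 3
        assert cat.s_g[0] == 10
        assert cat.s_theta[0] == 5.5
        assert np.array_equal(cat.profiles[0], [3, 5, 2])

    def test_two_unit_events(self):
        cat = extract_avalanches(np.array([0, 3, 0, 4, 0]), 1.0)
        assert list(cat.T) == [1, 1]
        assert list(cat.s_g) == [3, 4]

    def test_all_subthreshold_empty(self):
        assert len(extract_avalanches(np.zeros(10), 0.5)) == 0

    def test_censored_boundary_events_dropped(self):
        cat = extract_avalanches(np.array([5, 5, 0, 3, 0, 7, 7]), 1.0)
        assert len(cat) == 1 and cat.s_g[0] == 3
        assert cat.n_censored == 2

    def test_strict_inequality_at_threshold(self):
        cat = extract_avalanches(np.array([0, 2, 2, 0]), 2.0)
        assert len(cat) == 0

    def test_s_theta_never_exceeds_s_g(self, small_trace):
        theta = compute_threshold(small_trace.A, 0.5)
        cat = extract_avalanches(small_trace.A, theta)
        assert np.all(cat.s_theta <= cat.s_g)
        assert np.all(cat.s_theta >= 0)
        assert np.all(cat.T >= 1)
        # events disjoint and ordered
        assert np.all(cat.t_start[1:] >= cat.t_end[:-1])

    def test_raising_threshold_shrinks_total_duration(self, small_trace):
        durations = []
        for g in (0.25, 0.5, 1.0):
            theta = compute_threshold(small_trace.A, g)
            durations.append(extract_avalanches(small_trace.A, theta).T.sum())
        assert durations[0] >= durations[1] >= durations[2]


class TestKappa:
    MU, XMIN, XMAX = 1.5, 1.0, 1000.0

    def test_plotting_position_sample_gives_unity(self):
        n = 10000
        q = (np.arange(n) + 0.5) / n
        x = bounded_powerlaw_ppf(q, self.MU, self.XMIN, self.XMAX)
        k = kappa_index(x, self.MU, self.XMIN, self.XMAX)
        assert k == pytest.approx(1.0, abs=1.0 / n)

    def test_large_powerlaw_sample_near_unity(self):
        x = sample_bounded_powerlaw(self.MU, self.XMIN, self.XMAX, 10 ** 5,
                                    seed=4)
        assert abs(kappa_index(x, self.MU, self.XMIN, self.XMAX) - 1) < 0.02

    def test_exponential_sample_subcritical(self):
        rng = np.random.default_rng(8)
        x = self.XMIN + rng.exponential(3.0, 10 ** 5)
        assert kappa_index(x, self.MU, self.XMIN, self.XMAX) < 1

    def test_bump_sample_supercritical(self):
        x = np.concatenate([
            sample_bounded_powerlaw(self.MU, self.XMIN, self.XMAX, 9 * 10 ** 4,
                                    seed=5),
            np.full(10 ** 4, 0.9 * self.XMAX),
        ])
        assert kappa_index(x, self.MU, self.XMIN, self.XMAX) > 1

    def test_invariant_under_reordering_and_rescaling(self):
        x = sample_bounded_powerlaw(self.MU, self.XMIN, self.XMAX, 5000, seed=6)
        k1 = kappa_index(x, self.MU, self.XMIN, self.XMAX)
        k2 = kappa_index(x[::-1], self.MU, self.XMIN, self.XMAX)
        k3 = kappa_index(10 * x, self.MU, 10 * self.XMIN, 10 * self.XMAX)
        assert k1 == k2
        assert k3 == pytest.approx(k1, abs=1e-12)

    def test_empty_restriction_signalled(self):
        with pytest.raises(ValueError):
            kappa_index([5000.0], self.MU, 1.0, 1000.0)
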