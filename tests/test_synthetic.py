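import numpy as np
import pytest
from scipy import integrate, stats

from cros.avalanches import bounded_powerlaw_cdf
from cros.synthetic import (colored_noise, oscillatory_signal, profile_family,
                            sample_bounded_powerlaw, sample_truncated_powerlaw)


class TestBoundedPowerlaw:
    def test_mean_matches_closed_form(self):
        # mu=2 on [1, 10]: density C/x^2 with C = 1/0.9, mean = C ln 10
        x = sample_bounded_powerlaw(2.0, 1.0, 10.0, 10 ** 6, seed=1)
        expected = np.log(10.0) / 0.9
        assert x.mean() == pytest.approx(expected, rel=0.005)

    def test_ks_distance_vanishes(self):
        x = sample_bounded_powerlaw(1.5, 1.0, 1000.0, 10 ** 6, seed=2)
        d = stats.kstest(x, lambda h: bounded_powerlaw_cdf(h, 1.5, 1.0,
                                                           1000.0)).statistic
        assert d <= 0.002

    def test_degenerate_support(self):
        x = sample_bounded_powerlaw(1.5, 1.0, 1.0 + 1e-12, 1000, seed=3)
        assert np.allclose(x, 1.0)

    def test_bounds_respected_and_reproducible(self):
        a = sample_bounded_powerlaw(1.5, 2.0, 50.0, 5000, seed=4)
        b = sample_bounded_powerlaw(1.5, 2.0, 50.0, 5000, seed=4)
        assert np.array_equal(a, b)
        assert a.min() >= 2.0 and a.max() <= 50.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sample_bounded_powerlaw(-1.0, 1.0, 10.0, 10, seed=0)
        with pytest.raises(ValueError):
            sample_bounded_powerlaw(1.5, 5.0, 2.0, 10, seed=0)


class TestTruncatedPowerlaw:
    def test_cutoff_free_limit_matches_pure_powerlaw(self):
        x = sample_truncated_powerlaw(1.5, 1e12, 1.0, 10 ** 5, seed=5)
        pure_cdf = lambda h: 1.0 - h ** (-0.5)
        assert stats.kstest(x, pure_cdf).statistic <= 0.005

    def test_density_shape_via_histogram(self):
        x = sample_truncated_powerlaw(1.5, 50.0, 1.0, 2 * 10 ** 5, seed=6)
        # compare binned frequencies with the normalized density
        edges = np.logspace(0, 2.5, 30)
        counts, _ = np.histogram(x, bins=edges)
        hist, _ = np.histogram(x, bins=edges, density=True)
        f = lambda t: t ** -1.5 * np.exp(-t / 50.0)
        Z, _ = integrate.quad(f, 1.0, np.inf)
        centers = np.sqrt(edges[1:] * edges[:-1])
        expected = f(centers) / Z
        mask = counts >= 200  # well-populated bins only
        assert np.allclose(hist[mask], expected[mask], rtol=0.15)

    def test_small_mu_branch(self):
        x = sample_truncated_powerlaw(0.5, 20.0, 1.0, 10 ** 4, seed=7)
        assert x.min() >= 1.0
        # mean of x^{-0.5} e^{-x/20} on [1, inf)
        f = lambda t: t ** -0.5 * np.exp(-t / 20.0)
        Z, _ = integrate.quad(f, 1.0, np.inf)
        m, _ = integrate.quad(lambda t: t * f(t), 1.0, np.inf)
        assert x.mean() == pytest.approx(m / Z, rel=0.05)


class TestColoredNoise:
    def test_standardized_output(self):
        x = colored_noise(1.0, 2 ** 16, seed=8)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0, rel=1e-12)

    def test_log_periodogram_slope_matches_exponent(self):
        """Regression over one decade returns -v within 0.05 (10 seeds)."""
        slopes = []
        for s in range(10):
            x = colored_noise(0.5, 2 ** 18, seed=s)
            p = np.abs(np.fft.rfft(x)) ** 2
            f = np.fft.rfftfreq(x.size)
            band = (f >= 0.001) & (f <= 0.01)
            # average log-power in log-spaced bins to tame periodogram noise
            edges = np.logspace(-3, -2, 12)
            idx = np.digitize(f[band], edges)
            lp = [np.log10(p[band][idx == i].mean())
                  for i in range(1, 12) if (idx == i).any()]
            lf = [np.log10(f[band][idx == i]).mean()
                  for i in range(1, 12) if (idx == i).any()]
            slopes.append(stats.linregress(lf, lp).slope)
        assert np.mean(slopes) == pytest.approx(-0.5, abs=0.05)

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            colored_noise(2.5, 1024, seed=0)


class TestFixtures:
    def test_oscillatory_signal_amplitude_zero_is_pure_noise(self):
        x = oscillatory_signal(10.0, 0.0, 1.0, 4096, seed=9)
        assert np.abs(np.mean(x)) < 0.1

    def test_profile_family_positive_and_scaled(self):
        cat = profile_family(1.679, [12, 24, 48], noise_sd=0.1,
                             samples_per_T=5, seed=10)
        assert all((p > 0).all() for p in cat.profiles)
        assert len(cat) == 15
        # total size grows ~ T^gamma0
        s12 = cat.s_g[cat.T == 12].mean()
        s48 = cat.s_g[cat.T == 48].mean()
        assert np.log(s48 / s12) / np.log(4.0) == pytest.approx(1.679, abs=0.1)
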