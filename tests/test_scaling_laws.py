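import numpy as np
import pytest

from cros.avalanches import AvalancheCatalog
from cros.scaling_laws import (crackling_check, mean_size_vs_duration,
                               shape_collapse)
from cros.synthetic import profile_family

DURATIONS = [12, 16, 22, 30, 41, 56, 76, 104]


def _catalog_with_sizes(T, s):
    T = np.asarray(T)
    s = np.asarray(s, dtype=float)
    return AvalancheCatalog(theta=0.0, gamma=0.5,
                            t_start=np.zeros(T.size, int), t_end=T,
                            s_g=s, s_theta=s,
                            profiles=[np.ones(int(d)) for d in T])


class TestMeanSizeVsDuration:
    def test_noiseless_quadratic_scaling(self):
        T = np.repeat(DURATIONS, 12)
        fit = mean_size_vs_duration(_catalog_with_sizes(T, 3.0 * T ** 2.0))
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_exponent_recovery(self):
        rng = np.random.default_rng(11)
        T = np.repeat(DURATIONS, 10 ** 4 // len(DURATIONS))
        s = 2.0 * T ** 1.6 * rng.lognormal(0.0, 0.3, T.size)
        fit = mean_size_vs_duration(_catalog_with_sizes(T, s))
        assert fit.exponent == pytest.approx(1.6, abs=0.05)

    def test_duration_constraints_enforced(self):
        # durations <= 10 ms and under-sampled durations are excluded
        T = np.concatenate([np.repeat([2, 4, 8], 100), np.repeat(300, 3),
                            np.repeat(DURATIONS, 12)])
        fit = mean_size_vs_duration(_catalog_with_sizes(T, 1.0 * T ** 2))
        assert fit.durations.min() > 10
        assert 300 not in fit.durations

    def test_too_few_durations_fails(self):
        T = np.repeat([12, 20, 30], 50)
        with pytest.raises(ValueError):
            mean_size_vs_duration(_catalog_with_sizes(T, 1.0 * T))


class TestShapeCollapse:
    def test_recovers_construction_exponent(self):
        cat = profile_family(2.0, DURATIONS, noise_sd=0.0, samples_per_T=12,
                             seed=0)
        res = shape_collapse(cat)
        assert res.gamma == pytest.approx(2.0, abs=0.01)

    def test_recovers_2d_dp_rhs_value(self):
        cat = profile_family(1.679, DURATIONS, noise_sd=0.02,
                             samples_per_T=25, seed=1)
        res = shape_collapse(cat)
        assert res.gamma == pytest.approx(1.68, abs=0.01)

    def test_duration_independent_profiles_need_no_rescaling(self):
        cat = profile_family(1.0, DURATIONS, noise_sd=0.0, samples_per_T=12,
                             seed=2)
        assert shape_collapse(cat).gamma == pytest.approx(1.0, abs=0.01)

    def test_error_curve_unimodal_with_argmin_reported(self):
        cat = profile_family(1.8, DURATIONS, noise_sd=0.0, samples_per_T=12,
                             seed=3)
        res = shape_collapse(cat)
        assert res.collapse_error == res.error_curve.min()
        k = np.argmin(res.error_curve)
        assert np.all(np.diff(res.error_curve[:k]) < 0)
        assert np.all(np.diff(res.error_curve[k:]) > 0)

    def test_consistency_with_mean_size_fit(self):
        cat = profile_family(1.7, DURATIONS, noise_sd=0.01, samples_per_T=30,
                             seed=4)
        col = shape_collapse(cat)
        msf = mean_size_vs_duration(cat)
        assert col.gamma == pytest.approx(msf.exponent, abs=0.05)

    def test_too_few_durations_fails(self):
        cat = profile_family(2.0, [12, 20], noise_sd=0.0, samples_per_T=12,
                             seed=5)
        with pytest.raises(ValueError):
            shape_collapse(cat)


class TestCracklingCheck:
    def test_mean_field_dp_rhs(self):
        chk = crackling_check(tau=1.5, tau_t=2.0, one_over_snz=2.0)
        assert chk.rhs == pytest.approx(2.0)

    def test_2d_dp_rhs(self):
        chk = crackling_check(tau=1.268, tau_t=1.450, one_over_snz=1.0)
        assert chk.rhs == pytest.approx(1.6791, abs=1e-4)

    def test_error_propagation(self):
        chk = crackling_check(1.5, 2.0, 1.8, tau_err=0.05, tau_t_err=0.05,
                              one_over_snz_err=0.1)
        assert chk.rhs_err == pytest.approx(
            np.hypot(0.05 / 0.5, 1.0 * 0.05 / 0.25), rel=1e-9)
        assert chk.difference == pytest.approx(-0.2)

    def test_tau_at_unity_rejected(self):
        with pytest.raises(ValueError):
            crackling_check(1.0, 1.5, 1.0)
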