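"""Closed-form attenuation mathematics against Monte-Carlo and quadrature oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import forcematch as fm
from forcematch.models import skewnormal_moments

ATT = fm.AttenuationParams(1.61, 0.152)
IND = fm.IndirectLevelParams(2.0, 2.0, 0.3)


class TestSubtractiveMoments:
    def test_zero_attenuation_is_identity(self):
        m = fm.subtractive_moments(fm.AttenuationParams(0.0, 0.0), IND)
        assert (m.mean, m.sd, m.skew) == (2.0, 0.3, 0.0)

    def test_sum_of_normals(self):
        m = fm.subtractive_moments(fm.AttenuationParams(0.5, 0.1), IND)
        assert m.mean == pytest.approx(2.5)
        assert m.sd == pytest.approx(0.316228, abs=1e-6)
        assert m.skew == 0.0
        # commutes: swapping the two component distributions changes nothing
        swapped = fm.subtractive_moments(
            fm.AttenuationParams(2.0, 0.3), fm.IndirectLevelParams(2.0, 0.5, 0.1)
        )
        assert (swapped.mean, swapped.sd) == (m.mean, m.sd)


class TestDivisiveMoments:
    def test_sd_zero_reduces_to_scaled_normal(self):
        m = fm.divisive_moments(fm.AttenuationParams(1.5, 0.0), IND)
        assert (m.mean, m.sd, m.skew) == (3.0, pytest.approx(0.45), 0.0)
        m1 = fm.divisive_moments(fm.AttenuationParams(1.0, 0.0), IND)
        assert (m1.mean, m1.sd, m1.skew) == (2.0, 0.3, 0.0)

    def test_product_moments_match_monte_carlo(self):
        m = fm.divisive_moments(ATT, IND)
        assert m.mean == pytest.approx(3.22)
        assert m.sd == pytest.approx(0.57254, abs=5e-5)
        assert m.skew == pytest.approx(0.21405, abs=5e-5)
        rng = np.random.default_rng(42)
        n = 10**6
        z = rng.normal(1.61, 0.152, n) * rng.normal(2.0, 0.3, n)
        assert z.mean() == pytest.approx(m.mean, abs=3 * m.sd / np.sqrt(n))
        assert z.std() == pytest.approx(m.sd, abs=3 * m.sd / np.sqrt(2 * n) * 2)
        zskew = np.mean(((z - z.mean()) / z.std()) ** 3)
        assert zskew == pytest.approx(m.skew, abs=0.005)

    @given(
        mk=st.floats(0.8, 2.5),
        sk=st.floats(0.01, 0.5),
        mi=st.floats(0.5, 4.0),
        si=st.floats(0.05, 0.6),
    )
    @settings(max_examples=200, deadline=None)
    def test_sd_forms_agree_and_skew_positive(self, mk, sk, mi, si):
        """The explicit and delta-form SD expressions agree; skew > 0."""
        m = fm.divisive_moments(
            fm.AttenuationParams(mk, sk), fm.IndirectLevelParams(mi, mi, si)
        )
        dk, di = mk / sk, mi / si
        sd_delta = sk * si * np.sqrt(1.0 + dk**2 + di**2)
        assert abs(m.sd - sd_delta) < 1e-12 * max(1.0, sd_delta)
        assert m.skew > 0
        # excess variability at the distribution level: sd >= mean_K * sd_FI
        assert m.sd >= mk * si


class TestSkewNormal:
    def test_symmetric_case(self):
        p = fm.skewnormal_from_moments(fm.MomentTriple(0.0, 1.0, 0.0))
        assert (p.location, p.scale, p.shape) == (0.0, 1.0, 0.0)

    def test_moment_matching_example(self):
        p = fm.skewnormal_from_moments(fm.MomentTriple(3.22, 0.57254, 0.21405))
        assert p.location == pytest.approx(2.766, abs=1e-3)
        assert p.scale == pytest.approx(0.7307, abs=1e-4)
        assert p.shape == pytest.approx(1.241, abs=1e-3)

    @given(
        mean=st.floats(-2.0, 5.0),
        sd=st.floats(0.05, 2.0),
        skew=st.floats(-0.99, 0.99),
    )
    @settings(max_examples=300, deadline=None)
    def test_round_trip_is_identity(self, mean, sd, skew):
        p = fm.skewnormal_from_moments(fm.MomentTriple(mean, sd, skew))
        back = skewnormal_moments(p)
        assert abs(back.mean - mean) < 1e-8
        assert abs(back.sd - sd) < 1e-8
        assert abs(back.skew - skew) < 1e-8

    def test_excess_skew_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipping"):
            p = fm.skewnormal_from_moments(fm.MomentTriple(0.0, 1.0, 2.0))
        assert skewnormal_moments(p).skew == pytest.approx(0.995)

    def test_logdensity_reduces_to_normal(self):
        p = fm.SkewNormalParams(1.3, 0.7, 0.0)
        x = np.linspace(-3, 6, 50)
        assert np.allclose(
            fm.skewnormal_logdensity(x, p), stats.norm.logpdf(x, 1.3, 0.7)
        )
        assert fm.skewnormal_logdensity(0.0, fm.SkewNormalParams(0.0, 1.0, 0.0)) == (
            pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)))
        )

    def test_density_integrates_to_one(self):
        p = fm.skewnormal_from_moments(fm.MomentTriple(3.22, 0.57254, 0.21405))
        val, _ = integrate.quad(
            lambda x: np.exp(fm.skewnormal_logdensity(x, p)), -10, 20
        )
        assert val == pytest.approx(1.0, abs=1e-6)


class TestLikelihood:
    def test_subtractive_peak_value(self):
        m = fm.subtractive_moments(ATT, IND)
        ll = fm.direct_force_loglik([m.mean], ATT, IND, "subtractive")
        assert ll == pytest.approx(stats.norm.logpdf(0, 0, m.sd))

    def test_divisive_reduces_to_normal_at_zero_sd_K(self):
        att = fm.AttenuationParams(1.61, 0.0)
        x = [2.9, 3.2, 3.6]
        ll = fm.direct_force_loglik(x, att, IND, "divisive")
        expected = stats.norm.logpdf(x, 1.61 * 2.0, 1.61 * 0.3).sum()
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_divisive_close_to_exact_product_density(self):
        """Skew-normal approximation within 0.01/observation of quadrature."""
        rng = np.random.default_rng(7)
        x = fm.sample_direct(ATT, IND, "divisive", 200, rng)
        approx = np.array(
            [fm.direct_force_loglik([xi], ATT, IND, "divisive") for xi in x]
        )
        exact = fm.product_normal_logpdf(x, 1.61, 0.152, 2.0, 0.3)
        assert np.mean(np.abs(approx - exact)) < 0.01


class TestSampling:
    def test_degenerate_and_deterministic(self):
        att = fm.AttenuationParams(1.5, 0.0)
        ind = fm.IndirectLevelParams(2.0, 2.0, 1e-12)
        draws = fm.sample_direct(att, ind, "divisive", 10, np.random.default_rng(0))
        assert np.allclose(draws, 3.0)
        a = fm.sample_direct(ATT, IND, "divisive", 100, np.random.default_rng(5))
        b = fm.sample_direct(ATT, IND, "divisive", 100, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_sample_moments_match_closed_form(self):
        n = 10**6
        z = fm.sample_direct(ATT, IND, "divisive", n, np.random.default_rng(11))
        m = fm.divisive_moments(ATT, IND)
        assert z.mean() == pytest.approx(m.mean, abs=3 * m.sd / np.sqrt(n))
        zskew = np.mean(((z - z.mean()) / z.std()) ** 3)
        assert zskew == pytest.approx(m.skew, abs=0.01)


class TestAttenuationFraction:
    @pytest.mark.parametrize(
        "k, expected", [(1.61, 0.38), (1.0, 0.0), (2.0, 0.5)]
    )
    def test_values(self, k, expected):
        assert round(fm.attenuation_fraction(k), 2) == expected

    def test_delta_method_sd(self):
        assert fm.attenuation_fraction_sd(1.61, 0.152) == pytest.approx(
            0.152 / 1.61**2
        )

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            fm.attenuation_fraction(0.0)
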