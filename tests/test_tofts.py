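"""Tofts model: convolution oracle, fitting, iAUGC60."""

import numpy as np
import pytest

from dceprost.aif import AifCurve, AifSpec
from dceprost.conversion import ConcentrationCurve
from dceprost.tofts import (
    ToftsParams,
    fit_tofts,
    fit_tofts_volume,
    iaugc60,
    tofts_forward,
    tofts_forward_many,
)


def exp_aif(amplitude, rate_per_min, times):
    """Single-exponential test AIF Cp = A * exp(-m t), m in min^-1."""
    cp = amplitude * np.exp(-rate_per_min / 60.0 * times)
    return AifCurve(times=times, blood_conc=cp * 0.58, plasma_conc=cp, spec=AifSpec())


def closed_form_ct(ktrans, ve, amplitude, rate_per_min, times):
    """Analytic Tofts solution for the single-exponential AIF."""
    kep = ktrans / ve / 60.0
    m = rate_per_min / 60.0
    if abs(kep - m) < 1e-12:
        return (ktrans / 60.0) * amplitude * times * np.exp(-m * times)
    return (
        (ktrans / 60.0)
        * amplitude
        * (np.exp(-m * times) - np.exp(-kep * times))
        / (kep - m)
    )


class TestForward:
    def test_zero_ktrans_gives_zero_curve(self, parker, times36):
        out = tofts_forward(0.0, 0.3, parker, times36)
        assert np.all(out.conc == 0.0)

    def test_zero_ve_with_transfer_is_domain_error(self, parker, times36):
        with pytest.raises(ValueError, match="ve"):
            tofts_forward(0.2, 0.0, parker, times36)

    def test_closed_form_single_exponential(self, times36):
        fine = np.arange(0.0, times36.max() + 1.0, 0.25)
        aif = exp_aif(5.0, 3.0, fine)
        ct = tofts_forward(0.25, 0.30, aif, times36).conc
        expected = closed_form_ct(0.25, 0.30, 5.0, 3.0, times36)
        assert np.abs(ct - expected).max() < 1e-4

    def test_closed_form_biexponential_superposition(self, times36):
        """Weinmann-style biexponential AIF: solution is a sum of two terms."""
        fine = np.arange(0.0, times36.max() + 1.0, 0.25)
        a1, m1, a2, m2 = 0.399, 0.144, 0.478, 0.0111
        cp = a1 * np.exp(-m1 / 60 * fine) + a2 * np.exp(-m2 / 60 * fine)
        aif = AifCurve(times=fine, blood_conc=cp * 0.58, plasma_conc=cp, spec=AifSpec())
        ct = tofts_forward(0.8, 0.45, aif, times36).conc
        expected = closed_form_ct(0.8, 0.45, a1, m1, times36) + closed_form_ct(
            0.8, 0.45, a2, m2, times36
        )
        assert np.abs(ct - expected).max() < 1e-4

    def test_random_draw_oracle_equivalence(self, times36, rng):
        fine = np.arange(0.0, times36.max() + 1.0, 0.25)
        aif = exp_aif(4.0, 2.0, fine)
        for _ in range(50):
            kt = rng.uniform(0.02, 4.5)
            ve = rng.uniform(0.05, 1.0)
            ct = tofts_forward(kt, ve, aif, times36).conc
            assert np.abs(ct - closed_form_ct(kt, ve, 4.0, 2.0, times36)).max() < 1e-4

    def test_early_enhancement_monotone_in_ktrans(self, parker, times36):
        early = times36[times36 < 90.0]
        prev = None
        for kt in (0.05, 0.2, 0.8):
            ct = tofts_forward(kt, 0.3, parker, early).conc
            if prev is not None:
                assert np.all(ct[early > 20] > prev[early > 20])
            prev = ct

    def test_many_matches_scalar_path(self, parker, times36, rng):
        kts = rng.uniform(0.05, 1.5, 8)
        ves = rng.uniform(0.1, 0.8, 8)
        many = tofts_forward_many(kts, ves, parker, times36)
        for i in range(8):
            one = tofts_forward(kts[i], ves[i], parker, times36).conc
            np.testing.assert_allclose(many[i], one, atol=1e-12)


class TestFit:
    @pytest.mark.parametrize("kt", [0.05, 0.25, 1.0])
    @pytest.mark.parametrize("ve", [0.1, 0.3, 0.6])
    def test_noiseless_recovery_within_one_percent(self, parker, times36, kt, ve):
        truth = tofts_forward(kt, ve, parker, times36)
        fit = fit_tofts(truth, parker)
        assert fit.ktrans == pytest.approx(kt, rel=0.01)
        assert fit.ve == pytest.approx(ve, rel=0.01)
        assert fit.converged

    def test_zero_curve_degenerate_contract(self, parker, times36):
        fit = fit_tofts(ConcentrationCurve(times=times36, conc=np.zeros_like(times36)), parker)
        assert fit.ktrans == 0.0
        assert np.isnan(fit.ve)
        assert not fit.converged

    def test_all_flagged_curve_degenerate(self, parker, times36):
        curve = ConcentrationCurve(
            times=times36,
            conc=np.ones_like(times36),
            flagged=np.ones(times36.shape, dtype=bool),
        )
        fit = fit_tofts(curve, parker)
        assert fit.ktrans == 0.0 and not fit.converged

    def test_deterministic(self, parker, times36, rng):
        truth = tofts_forward(0.4, 0.35, parker, times36)
        noisy = ConcentrationCurve(
            times=times36, conc=truth.conc + rng.normal(0, 0.02, times36.size)
        )
        a = fit_tofts(noisy, parker)
        b = fit_tofts(noisy, parker)
        assert (a.ktrans, a.ve, a.rmse) == (b.ktrans, b.ve, b.rmse)

    def test_too_few_post_onset_samples(self, parker):
        t = np.arange(0, 36, 3.6)
        with pytest.raises(ValueError, match="post-onset"):
            fit_tofts(ConcentrationCurve(times=t, conc=np.ones_like(t)), parker)

    def test_kep_is_always_derived(self):
        p = ToftsParams(ktrans=0.3, ve=0.25)
        assert p.kep == pytest.approx(0.3 / 0.25, rel=1e-15)


class TestVolumeFit:
    def test_agrees_with_reference_fitter(self, parker, times36, rng):
        kts = rng.uniform(0.05, 1.2, 30)
        ves = rng.uniform(0.1, 0.7, 30)
        conc = tofts_forward_many(kts, ves, parker, times36)
        res = fit_tofts_volume(conc, times36, parker)
        np.testing.assert_allclose(res["ktrans"], kts, rtol=5e-3)
        np.testing.assert_allclose(res["ve"], ves, rtol=5e-3)
        # spot-check three voxels against the per-curve fitter
        for i in (0, 10, 29):
            ref = fit_tofts(ConcentrationCurve(times=times36, conc=conc[i]), parker)
            assert res["ktrans"][i] == pytest.approx(ref.ktrans, rel=5e-3)
            assert res["ve"][i] == pytest.approx(ref.ve, rel=5e-3)

    def test_degenerate_rows_flagged(self, parker, times36):
        conc = np.zeros((3, times36.size))
        conc[1] = tofts_forward(0.3, 0.3, parker, times36).conc
        res = fit_tofts_volume(conc, times36, parker)
        assert not res["converged"][0] and res["ktrans"][0] == 0.0
        assert res["converged"][1]


class TestIaugc:
    def test_constant_one_millimolar(self):
        t = np.arange(0, 200, 3.6)
        curve = ConcentrationCurve(times=t, conc=np.ones_like(t))
        assert iaugc60(curve, t_start=30.0) == pytest.approx(1.0, abs=1e-12)

    def test_linear_ramp_analytic(self):
        """Trapezoid is exact for a piecewise-linear integrand."""
        t = np.arange(0, 200, 3.6)
        t0 = 36.0
        conc = np.clip((t - t0) / 60.0, 0.0, None)
        curve = ConcentrationCurve(times=t, conc=conc)
        # area of the triangle over [t0, t0+60]: 0.5 * 60 s * 1 mM -> 0.5 mM min
        assert iaugc60(curve, t_start=t0) == pytest.approx(0.5, abs=1e-12)

    def test_zero_curve(self):
        t = np.arange(0, 200, 3.6)
        curve = ConcentrationCurve(times=t, conc=np.zeros_like(t))
        assert iaugc60(curve, t_start=10.0) == 0.0

    def test_start_beyond_curve_is_error(self):
        t = np.arange(0, 100, 3.6)
        with pytest.raises(ValueError):
            iaugc60(ConcentrationCurve(times=t, conc=np.ones_like(t)), t_start=200.0)

    def test_truncated_window_warns(self):
        t = np.arange(0, 80, 3.6)
        curve = ConcentrationCurve(times=t, conc=np.ones_like(t))
        with pytest.warns(UserWarning, match="truncated"):
            value = iaugc60(curve, t_start=40.0)
        assert value < 1.0
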