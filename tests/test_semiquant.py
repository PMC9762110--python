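"""Piecewise-linear curve parameterisation: exactness and search optimality."""

import numpy as np
import pytest

from dceprost.conversion import SignalCurve
from dceprost.semiquant import (
    MIN_SEG,
    auc_normalised,
    fit_piecewise_linear,
    fit_semiquant_volume,
    normalise_signal,
)
from conftest import trapezoid_curve


def brute_force_best_sse(y, times, min_seg=MIN_SEG):
    """Independent exhaustive search with explicit basis least squares.

    Enumerates every breakpoint triple (and no-washout pair) with the same
    model class and sign rules: solutions with IRW > 0 fall back to the
    no-washout pair, ME < 0 to the flat model.
    """
    n = times.size
    m = min_seg - 1
    yy = float(y @ y)
    best = yy  # flat model

    def phi1(i, j):
        out = np.zeros(n)
        seg = (times > times[i]) & (times < times[j])
        out[seg] = (times[seg] - times[i]) / (times[j] - times[i])
        out[times >= times[j]] = 1.0
        return out

    for i in range(m, n - 1 - m):
        for j in range(i + m, n - m):
            p1 = phi1(i, j)
            # no-washout candidate
            me = max(float(p1 @ y) / float(p1 @ p1), 0.0)
            best = min(best, yy - 2 * me * float(p1 @ y) + me**2 * float(p1 @ p1))
            for k in range(j + m, n - m):
                p2 = np.where(times > times[k], times - times[k], 0.0)
                g = np.array([[p1 @ p1, p1 @ p2], [p1 @ p2, p2 @ p2]])
                b = np.array([p1 @ y, p2 @ y])
                try:
                    me4, irw4 = np.linalg.solve(g, b)
                except np.linalg.LinAlgError:
                    continue
                if me4 < 0 or irw4 > 0:
                    continue
                resid = y - me4 * p1 - irw4 * p2
                best = min(best, float(resid @ resid))
    return best


class TestNormalise:
    def test_baseline_maps_to_zero(self):
        curve = SignalCurve(times=np.arange(12.0), signal=np.full(12, 80.0), n_baseline=5)
        np.testing.assert_allclose(normalise_signal(curve), 0.0, atol=1e-14)

    def test_doubled_signal_maps_to_one(self):
        sig = np.full(12, 50.0)
        sig[8] = 100.0
        curve = SignalCurve(times=np.arange(12.0), signal=sig, n_baseline=5)
        assert normalise_signal(curve)[8] == pytest.approx(1.0)

    def test_invariant_under_positive_scaling(self, rng):
        sig = 100.0 + rng.uniform(0, 60, 20)
        t = np.arange(20.0)
        a = normalise_signal(SignalCurve(times=t, signal=sig, n_baseline=5))
        b = normalise_signal(SignalCurve(times=t, signal=7.3 * sig, n_baseline=5))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_non_positive_baseline_rejected(self):
        curve = SignalCurve(times=np.arange(10.0), signal=np.zeros(10), n_baseline=5)
        with pytest.raises(ValueError, match="unanalysable"):
            normalise_signal(curve)


class TestExactRecovery:
    def test_on_grid_trapezoid_recovered_exactly(self, times36):
        """Noiseless on-grid breakpoints: every parameter exact."""
        y = trapezoid_curve(times36, 28.8, 36.0, 0.8, 302.4, -0.001)
        p = fit_piecewise_linear(y, times36)
        assert p.t_onset == pytest.approx(28.8)
        assert p.ttp == pytest.approx(36.0)
        assert p.ire == pytest.approx(0.8 / 36.0)
        assert p.me == pytest.approx(0.8)
        assert p.t_washout == pytest.approx(302.4)
        assert p.irw == pytest.approx(-0.001)
        assert p.sse < 1e-10
        assert not p.non_enhancing

    def test_off_grid_onset_recovered_to_grid_resolution(self, times36):
        """A 30 s onset (between 3.6 s samples) lands within one grid step."""
        y = trapezoid_curve(times36, 30.0, 36.0, 0.8, 300.0, -0.001)
        p = fit_piecewise_linear(y, times36)
        assert abs(p.t_onset - 30.0) <= 3.6
        assert abs(p.ttp - 36.0) <= 2 * 3.6
        assert p.me == pytest.approx(0.8, rel=0.05)

    def test_flat_curve_non_enhancing(self, times36):
        p = fit_piecewise_linear(np.zeros_like(times36), times36)
        assert p.non_enhancing
        assert p.ire == p.me == p.auc == 0.0

    def test_monotone_rise_sets_no_washout_sentinels(self, times36):
        """Contrast still accumulating at the end: sentinel pair (0, 0)."""
        y = trapezoid_curve(times36, 28.8, 360.0, 1.5, 1e9, 0.0)
        p = fit_piecewise_linear(y, times36)
        assert p.t_washout == 0.0 and p.irw == 0.0
        assert p.me > 0

    def test_me_equals_ire_times_ttp(self, times36, rng):
        y = trapezoid_curve(times36, 36.0, 72.0, 1.2, 288.0, -0.002)
        y = y + rng.normal(0, 0.02, y.size)
        p = fit_piecewise_linear(y, times36)
        assert p.me == pytest.approx(p.ire * p.ttp, rel=1e-9)

    def test_time_params_scale_invariant_amplitudes_scale(self, times36):
        y = trapezoid_curve(times36, 28.8, 36.0, 0.8, 302.4, -0.001)
        a = fit_piecewise_linear(y, times36)
        b = fit_piecewise_linear(3.0 * y, times36)
        assert (a.t_onset, a.ttp, a.t_washout) == (b.t_onset, b.ttp, b.t_washout)
        assert b.me == pytest.approx(3 * a.me)
        assert b.ire == pytest.approx(3 * a.ire)
        assert b.irw == pytest.approx(3 * a.irw)

    def test_needs_at_least_eight_samples(self):
        t = np.arange(6.0)
        with pytest.raises(ValueError):
            fit_piecewise_linear(np.zeros(6), t)


class TestSearchOptimality:
    @pytest.mark.parametrize("case", range(6))
    def test_matches_brute_force_on_short_curves(self, case, rng):
        """Returned SSE equals an independent exhaustive enumeration."""
        n = 24 + 2 * case
        times = np.arange(n) * 7.2
        base = trapezoid_curve(
            times,
            times[2 + case % 3],
            times[6] - times[2],
            rng.uniform(0.4, 1.5),
            times[n - 8 + case % 4],
            -rng.uniform(0.0005, 0.003),
        )
        y = base + rng.normal(0, 0.05, n)
        p = fit_piecewise_linear(y, times)
        assert p.sse == pytest.approx(brute_force_best_sse(y, times), rel=1e-9, abs=1e-12)

    def test_pure_noise_curve_matches_brute_force(self, rng):
        times = np.arange(20) * 7.2
        y = rng.normal(0, 0.3, 20)
        p = fit_piecewise_linear(y, times)
        assert p.sse == pytest.approx(brute_force_best_sse(y, times), rel=1e-9, abs=1e-12)


class TestAuc:
    def test_zero(self, times36):
        assert auc_normalised(np.zeros_like(times36), times36) == 0.0

    def test_constant_half_over_360s(self):
        t = np.linspace(0.0, 360.0, 101)
        assert auc_normalised(np.full(101, 0.5), t) == pytest.approx(180.0)

    def test_trapezoid_analytic_area(self, times36):
        y = trapezoid_curve(times36, 28.8, 36.0, 0.8, 302.4, -0.001)
        # analytic signed area of the sampled trapezoid via fine integration
        fine = np.arange(0.0, times36.max() + 0.01, 0.01)
        expected = np.trapezoid(
            trapezoid_curve(fine, 28.8, 36.0, 0.8, 302.4, -0.001), fine
        )
        assert auc_normalised(y, times36) == pytest.approx(expected, rel=1e-3)

    def test_negative_excursions_count_signed(self):
        t = np.linspace(0, 100, 51)
        y = np.full(51, -0.2)
        assert auc_normalised(y, t) == pytest.approx(-20.0)


class TestVolume:
    def test_matches_single_curve_path(self, rng):
        times = np.arange(60) * 7.2
        sigs = []
        for _ in range(6):
            y = trapezoid_curve(
                times, 36.0, 43.2, rng.uniform(0.5, 2), 288.0, -rng.uniform(0.001, 0.003)
            )
            sigs.append(120.0 * (1 + y) + rng.normal(0, 0.5, 60))
        sigs = np.array(sigs)
        params, report = fit_semiquant_volume(sigs, times, n_baseline=5)
        for i in range(6):
            curve = SignalCurve(times=times, signal=sigs[i], n_baseline=5)
            ref = fit_piecewise_linear(normalise_signal(curve), times)
            assert params["ttp"][i] == pytest.approx(ref.ttp)
            assert params["me"][i] == pytest.approx(ref.me)
            assert params["irw"][i] == pytest.approx(ref.irw)
        assert report["n_voxels"] == 6

    def test_quality_report_counts(self):
        times = np.arange(60) * 7.2
        sigs = np.zeros((3, 60))
        sigs[0] = 100.0  # flat -> non-enhancing
        sigs[1] = 0.0  # zero baseline -> unanalysable
        sigs[2] = 100.0 * (1 + trapezoid_curve(times, 36.0, 43.2, 1.0, 1e9, 0.0))
        params, report = fit_semiquant_volume(sigs, times, n_baseline=5)
        assert report["n_unanalysable"] == 1
        assert report["n_non_enhancing"] == 1
        assert report["n_no_washout"] == 1
        assert not params["analysable"][1]
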